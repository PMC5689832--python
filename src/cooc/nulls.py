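"""Null distributions for the co-occurrence count of a taxon pair.

Three nulls for the number of co-present sites ``x`` are provided:

* the *standard* null: x ~ Binomial(n_occupied, 1/3), where n_occupied is
  the number of sites occupied by at least one of the two taxa.  It encodes
  the assumption that every taxon has 50% prevalence (so a, b, c are
  expected equal and J = 1/3 under independence) and is kept here because
  its failure off 50% prevalence is exactly what the prevalence-specific
  null corrects;

* the *prevalence-specific hypergeometric* null: with species 1 occupying m
  of the N sites and species 2 occupying k, placing the k sites uniformly
  at random gives

      P(X = x) = C(m, x) * C(N - m, k - x) / C(N, k)

  — a finite-population sampling problem, conditioned on both observed
  prevalences.  This is the null the package's significance tests use;

* a seeded Monte-Carlo null that draws the two occupied-site sets uniformly
  at random with fixed sizes; it exists to demonstrate agreement with the
  hypergeometric form and for plotting.

Tail probabilities are exact sums over the pmf, with the observed point
included in each one-sided tail (standard exact-test convention, no mid-P).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .data import ContingencyTable
from .metrics import phi_coefficient

__all__ = [
    "StandardNullParams",
    "HypergeomNullParams",
    "NullDistribution",
    "TailProbabilities",
    "standard_binomial_null",
    "hypergeometric_null",
    "tail_probabilities",
    "simulate_null",
    "classify_direction",
    "r_significance",
]

#: exact success probability of the standard null; the printed two-decimal
#: form 0.33 is a display rounding of the equal-thirds argument behind it
ONE_THIRD = Fraction(1, 3)


@dataclass(frozen=True)
class StandardNullParams:
    """Binomial null for x out of the pair's occupied sites."""

    n_occupied: int
    p_cooccur: float = float(ONE_THIRD)

    def __post_init__(self) -> None:
        if self.n_occupied < 0:
            raise ValueError("n_occupied must be >= 0")
        if not (0.0 < self.p_cooccur < 1.0):
            raise ValueError("p_cooccur must lie in (0, 1)")


@dataclass(frozen=True)
class HypergeomNullParams:
    """Hypergeometric null: m sites hold species 1, n_unocc do not, k hold species 2."""

    m: int
    n_unocc: int
    k: int

    def __post_init__(self) -> None:
        if min(self.m, self.n_unocc, self.k) < 0:
            raise ValueError("m, n_unocc, k must be >= 0")
        if self.k > self.m + self.n_unocc:
            raise ValueError(
                f"k={self.k} exceeds the number of sites N={self.m + self.n_unocc}"
            )

    @property
    def n_sites(self) -> int:
        return self.m + self.n_unocc


@dataclass(frozen=True)
class NullDistribution:
    """Explicit support and pmf for a co-occurrence count."""

    support: np.ndarray
    pmf: np.ndarray
    source: str  # standard_binomial | hypergeometric | monte_carlo

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=np.int64))
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=np.float64))
        if self.support.shape != self.pmf.shape:
            raise ValueError("support and pmf must have matching shapes")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def to_text(self, path: str, delimiter: str = "\t") -> None:
        """Two-column (x, probability) export for plotting."""
        with open(path, "w") as fh:
            fh.write(f"x{delimiter}probability\n")
            for x, p in zip(self.support, self.pmf):
                fh.write(f"{x}{delimiter}{p:.17g}\n")


@dataclass(frozen=True)
class TailProbabilities:
    """Exact decomposition P(X<x), P(X=x), P(X>x) at the observed count."""

    p_lt: float
    p_eq: float
    p_gt: float

    @property
    def p_le(self) -> float:
        return min(1.0, self.p_lt + self.p_eq)

    @property
    def p_ge(self) -> float:
        return min(1.0, self.p_gt + self.p_eq)


def standard_binomial_null(params: StandardNullParams) -> NullDistribution:
    """Binomial null over 0..n_occupied with success probability p_cooccur."""
    n = params.n_occupied
    support = np.arange(n + 1)
    pmf = stats.binom.pmf(support, n, params.p_cooccur)
    return NullDistribution(support, pmf, "standard_binomial")


def hypergeometric_null(params: HypergeomNullParams) -> NullDistribution:
    """Prevalence-specific null over max(0, k-n_unocc)..min(m, k)."""
    m, n_unocc, k = params.m, params.n_unocc, params.k
    lo = max(0, k - n_unocc)
    hi = min(m, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, m + n_unocc, m, k)
    return NullDistribution(support, pmf, "hypergeometric")


def tail_probabilities(dist: NullDistribution, x_obs: int) -> TailProbabilities:
    """Exact tail sums at x_obs; counts outside the support clamp to 0/1 tails."""
    support, pmf = dist.support, dist.pmf
    if len(support) == 0:
        raise ValueError("empty null distribution")
    lt = float(pmf[support < x_obs].sum())
    eq = float(pmf[support == x_obs].sum())
    gt = float(pmf[support > x_obs].sum())
    return TailProbabilities(min(1.0, lt), min(1.0, eq), min(1.0, gt))


def simulate_null(
    N_sites: int,
    occ1: int,
    occ2: int,
    trials: int = 100_000,
    seed: int | None = None,
    chunk: int = 20_000,
) -> tuple[NullDistribution, np.ndarray]:
    """Monte-Carlo null for the co-occurrence count at fixed prevalences.

    Each trial places occ1 and occ2 occupied sites uniformly at random and
    independently of each other, and records the overlap x and the implied
    J = x/(occ1 + occ2 - x).  Returns the empirical pmf of x (support
    0..min(occ1, occ2)) and the per-trial J values (NaN where both taxa are
    empty).
    """
    if not (0 <= occ1 <= N_sites and 0 <= occ2 <= N_sites):
        raise ValueError("occupancies must satisfy 0 <= occ <= N_sites")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    hi = min(occ1, occ2)
    counts = np.zeros(hi + 1, dtype=np.int64)
    j_values = np.empty(trials, dtype=np.float64)
    done = 0
    while done < trials:
        t = min(chunk, trials - done)
        # ranks of iid uniforms give uniformly random subsets of fixed size
        u1 = rng.random((t, N_sites)).argsort(axis=1) < occ1
        u2 = rng.random((t, N_sites)).argsort(axis=1) < occ2
        x = np.sum(u1 & u2, axis=1)
        counts += np.bincount(x, minlength=hi + 1)
        denom = occ1 + occ2 - x
        with np.errstate(invalid="ignore", divide="ignore"):
            j_values[done : done + t] = np.where(denom > 0, x / denom, np.nan)
        done += t
    support = np.arange(hi + 1)
    return NullDistribution(support, counts / trials, "monte_carlo"), j_values


def classify_direction(tails: TailProbabilities, alpha: float) -> str:
    """'positive', 'negative' or 'none' from the one-sided tails at level alpha.

    Each tail is tested separately at alpha (the observed count falling to
    the extreme right of the null means positive association, extreme left
    negative).  If both tails pass — possible only on tiny supports — the
    smaller tail wins.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    pos = tails.p_ge <= alpha
    neg = tails.p_le <= alpha
    if pos and neg:
        return "positive" if tails.p_ge <= tails.p_le else "negative"
    if pos:
        return "positive"
    if neg:
        return "negative"
    return "none"


def r_significance(
    t: ContingencyTable, alpha: float, method: str = "chisq"
) -> tuple[float | None, bool, str]:
    """Two-sided significance of the phi coefficient.

    method='chisq' (default): p from the asymptotic chi-square statistic
    N*r^2 with 1 df.  method='exact': conditional test on the co-occurrence
    count under the prevalence-specific hypergeometric null, doubling the
    smaller tail (capped at 1).  Returns (p, significant, direction); a
    degenerate table yields (None, False, 'none').
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    r = phi_coefficient(t)
    if not r.defined:
        return None, False, "none"
    assert r.value is not None
    if method == "chisq":
        n = t.n_sites
        p = float(stats.chi2.sf(n * r.value**2, df=1))
    elif method == "exact":
        params = HypergeomNullParams(m=t.a + t.b, n_unocc=t.c + t.d, k=t.a + t.c)
        tails = tail_probabilities(hypergeometric_null(params), t.a)
        p = min(1.0, 2.0 * min(tails.p_le, tails.p_ge))
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "positive" if r.value > 0 else ("negative" if r.value < 0 else "none")
    significant = p <= alpha and r.value != 0
    return p, significant, direction
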
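"""All-pairs co-occurrence screening with familywise error control.

The central object is :class:`PairwiseCooccurrence`, a model over a
taxon-by-sample presence/absence matrix.  ``fit()`` evaluates, for every
unordered taxon pair, Jaccard's index against the prevalence-specific
hypergeometric null (the recommended test), Jaccard's index against the
standard 50%-prevalence binomial null, and the phi coefficient with a
two-sided significance test — all at a Bonferroni-corrected per-test level
alpha = family_alpha / n_pairs.  The returned :class:`CooccurrenceResults`
carries the per-pair table plus the comparison diagnostics: a significance
concordance summary (which pairs each metric calls, and whether directions
agree), prevalence-binned significance grids, and rare-pair composition
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CountTable,
    PresenceAbsenceMatrix,
    threshold_counts,
)

__all__ = [
    "AnalysisConfig",
    "PairwiseCooccurrence",
    "CooccurrenceResults",
    "ConcordanceSummary",
    "PrevalenceGrid",
    "n_unique_pairs",
    "analyze_all_pairs",
    "concordance_summary",
    "prevalence_grid",
    "rare_pair_fractions",
]

#: stable column order of the per-pair result table
PAIR_COLUMNS = [
    "taxon_i", "taxon_j", "a", "b", "c", "d",
    "prevalence_i", "prevalence_j", "r", "J",
    "p_J_le_hyper", "p_J_ge_hyper", "p_J_le_standard", "p_J_ge_standard",
    "p_r", "sig_J", "sig_r", "sig_r_tail", "dir_J", "dir_J_standard",
    "dir_r", "degenerate",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the all-pairs screen.

    family_alpha
        Familywise error rate across all pair tests (default 0.05).
    correction
        Multiple-testing correction; only 'bonferroni' is implemented
        (per-test alpha = family_alpha / n_pairs).
    rare_cutoff / common_cutoff
        Prevalence fractions defining 'rare' (<0.10) and 'moderately
        common' (>0.20) taxa in stratified summaries.
    bin_width
        Prevalence bin width of the significance grids (default 0.05).
    r_test_method
        'chisq' (asymptotic N*r^2, 1 df, two-sided) or 'exact'
        (conditional hypergeometric, doubled smaller tail).
    eq3_p_mode
        'third' uses exactly 1/3 as the standard null's success
        probability; 'literal' replicates the printed 0.33.
    """

    family_alpha: float = 0.05
    correction: str = "bonferroni"
    rare_cutoff: float = 0.10
    common_cutoff: float = 0.20
    bin_width: float = 0.05
    r_test_method: str = "chisq"
    eq3_p_mode: str = "third"

    def __post_init__(self) -> None:
        if not (0.0 < self.family_alpha < 1.0):
            raise ValueError("family_alpha must lie in (0, 1)")
        if self.correction != "bonferroni":
            raise ValueError(f"unsupported correction {self.correction!r}")
        if not (0.0 < self.bin_width <= 1.0):
            raise ValueError("bin_width must lie in (0, 1]")
        if not (0.0 <= self.rare_cutoff < self.common_cutoff <= 1.0):
            raise ValueError("need 0 <= rare_cutoff < common_cutoff <= 1")
        if self.r_test_method not in ("chisq", "exact"):
            raise ValueError(f"unknown r_test_method {self.r_test_method!r}")
        if self.eq3_p_mode not in ("third", "literal"):
            raise ValueError(f"unknown eq3_p_mode {self.eq3_p_mode!r}")

    @property
    def eq3_p(self) -> float:
        return 0.33 if self.eq3_p_mode == "literal" else 1.0 / 3.0


def n_unique_pairs(n_taxa: int) -> int:
    """Number of unordered distinct taxon pairs, n(n-1)/2."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to form pairs")
    return n_taxa * (n_taxa - 1) // 2


def _direction_from_tails(
    p_le: np.ndarray, p_ge: np.ndarray, alpha: float, defined: np.ndarray
) -> np.ndarray:
    """Vectorized tail classification; ties on tiny supports go to the smaller tail."""
    pos = (p_ge <= alpha) & defined
    neg = (p_le <= alpha) & defined
    both = pos & neg
    out = np.full(p_le.shape, "none", dtype=object)
    out[pos] = "positive"
    out[neg] = "negative"
    out[both] = np.where(p_ge[both] <= p_le[both], "positive", "negative")
    return out


class PairwiseCooccurrence:
    """Model: all-pairs presence/absence co-occurrence screen.

    Parameters
    ----------
    pa : PresenceAbsenceMatrix
        Binary taxon-by-sample occupancy.
    config : AnalysisConfig, optional
        Test and binning configuration; defaults reproduce the standard
        workflow (familywise 5%, Bonferroni, 5% prevalence bins).
    """

    def __init__(self, pa: PresenceAbsenceMatrix, config: AnalysisConfig | None = None):
        if pa.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if pa.n_sites < 1:
            raise ValueError("need at least 1 sample")
        self.pa = pa
        self.config = config or AnalysisConfig()

    @classmethod
    def from_counts(
        cls,
        counts: CountTable,
        min_reads: int = 100,
        config: AnalysisConfig | None = None,
    ) -> "PairwiseCooccurrence":
        """Build the model from raw read counts, binarizing at > min_reads."""
        return cls(threshold_counts(counts, min_reads=min_reads), config)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: AnalysisConfig | None = None
    ) -> "PairwiseCooccurrence":
        """Build the model from a binary taxon-by-sample DataFrame."""
        return cls(PresenceAbsenceMatrix.from_frame(df), config)

    @property
    def n_pairs(self) -> int:
        return n_unique_pairs(self.pa.n_taxa)

    @property
    def alpha_per_test(self) -> float:
        return self.config.family_alpha / self.n_pairs

    def fit(self) -> "CooccurrenceResults":
        """Evaluate every unordered pair; deterministic given data and config."""
        cfg = self.config
        X = self.pa.occupancy.astype(np.int64)
        N = self.pa.n_sites
        occ = X.sum(axis=1)
        co = X @ X.T
        ii, jj = np.triu_indices(self.pa.n_taxa, k=1)
        a = co[ii, jj]
        si, sj = occ[ii], occ[jj]
        b = si - a
        c = sj - a
        d = N - si - sj + a
        alpha = self.alpha_per_test

        prev_i = si / N
        prev_j = sj / N

        # phi coefficient; undefined when any marginal is zero
        defined_r = (si > 0) & (si < N) & (sj > 0) & (sj < N)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * d - b * c) / (
                np.sqrt(si * (N - si).astype(float)) * np.sqrt(sj * (N - sj).astype(float))
            )
        r = np.clip(r, -1.0, 1.0)
        r[~defined_r] = np.nan

        # Jaccard; undefined when both taxa absent everywhere
        n_occ = si + sj - a
        defined_j = n_occ > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            J = np.where(defined_j, a / np.where(n_occ > 0, n_occ, 1), np.nan)

        # prevalence-specific hypergeometric tails on the co-occurrence count
        p_ge_h = stats.hypergeom.sf(a - 1, N, si, sj)
        p_le_h = stats.hypergeom.cdf(a, N, si, sj)

        # standard binomial null on a out of the occupied sites
        p = cfg.eq3_p
        p_ge_s = stats.binom.sf(a - 1, n_occ, p)
        p_le_s = stats.binom.cdf(a, n_occ, p)

        # phi significance
        if cfg.r_test_method == "chisq":
            with np.errstate(invalid="ignore"):
                p_r = stats.chi2.sf(N * r**2, df=1)
        else:
            p_r = np.minimum(1.0, 2.0 * np.minimum(p_le_h, p_ge_h))
            p_r = np.where(defined_r, p_r, np.nan)

        dir_J = _direction_from_tails(p_le_h, p_ge_h, alpha, defined_j)
        dir_J_std = _direction_from_tails(p_le_s, p_ge_s, alpha, defined_j)
        sig_J = dir_J != "none"
        sig_r = defined_r & (p_r <= alpha) & (r != 0)
        sig_r_tail = defined_r & (p_r / 2.0 <= alpha) & (r != 0)
        dir_r = np.full(r.shape, "none", dtype=object)
        dir_r[defined_r & (r > 0)] = "positive"
        dir_r[defined_r & (r < 0)] = "negative"
        degenerate = ~(defined_j & defined_r)

        pairs = pd.DataFrame(
            {
                "taxon_i": np.asarray(self.pa.taxon_ids, dtype=object)[ii],
                "taxon_j": np.asarray(self.pa.taxon_ids, dtype=object)[jj],
                "a": a, "b": b, "c": c, "d": d,
                "prevalence_i": prev_i, "prevalence_j": prev_j,
                "r": r, "J": J,
                "p_J_le_hyper": p_le_h, "p_J_ge_hyper": p_ge_h,
                "p_J_le_standard": p_le_s, "p_J_ge_standard": p_ge_s,
                "p_r": p_r,
                "sig_J": sig_J, "sig_r": sig_r, "sig_r_tail": sig_r_tail,
                "dir_J": dir_J, "dir_J_standard": dir_J_std, "dir_r": dir_r,
                "degenerate": degenerate,
            },
            columns=PAIR_COLUMNS,
        )
        return CooccurrenceResults(model=self, pairs=pairs)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Venn-style agreement between the two metrics' significant pair sets."""

    n_pairs: int
    n_sig_J: int
    n_sig_r: int
    n_sig_both: int
    n_sig_J_only: int
    n_sig_r_only: int
    frac_r_only_of_sig_r: float | None
    frac_J_only_of_sig_J: float | None
    frac_both_of_union: float | None
    direction_match_count: int

    def __post_init__(self) -> None:
        assert self.n_sig_both + self.n_sig_J_only == self.n_sig_J
        assert self.n_sig_both + self.n_sig_r_only == self.n_sig_r


@dataclass(frozen=True)
class PrevalenceGrid:
    """Per-cell pair counts over symmetrized prevalence bins.

    Pairs are placed by (min prevalence -> row, max prevalence -> column),
    so only the upper triangle including the diagonal is populated.  Bins
    are half-open [lo, hi) with the final bin closed at 1.0.
    """

    bin_edges: np.ndarray
    total: np.ndarray
    sig_J: np.ndarray
    sig_r: np.ndarray
    difference: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def empty_cells(self) -> np.ndarray:
        return self.total == 0


def analyze_all_pairs(
    pa: PresenceAbsenceMatrix, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Functional wrapper: fit the model and return the per-pair table."""
    return PairwiseCooccurrence(pa, config).fit().pairs


def concordance_summary(pairs: pd.DataFrame) -> ConcordanceSummary:
    """Counts and mismatch fractions between sig_J and sig_r pair sets.

    The three fractions use three distinct denominators — the r-significant
    set, the J-significant set, and their union — because they answer three
    different questions about metric disagreement.
    """
    if len(pairs) == 0:
        raise ValueError("empty result table")
    sig_j = pairs["sig_J"].to_numpy(dtype=bool)
    sig_r = pairs["sig_r"].to_numpy(dtype=bool)
    both = sig_j & sig_r
    n_both = int(both.sum())
    n_j = int(sig_j.sum())
    n_r = int(sig_r.sum())
    union = n_j + n_r - n_both
    match = int(
        (pairs.loc[both, "dir_J"].to_numpy() == pairs.loc[both, "dir_r"].to_numpy()).sum()
    )
    return ConcordanceSummary(
        n_pairs=len(pairs),
        n_sig_J=n_j,
        n_sig_r=n_r,
        n_sig_both=n_both,
        n_sig_J_only=n_j - n_both,
        n_sig_r_only=n_r - n_both,
        frac_r_only_of_sig_r=(n_r - n_both) / n_r if n_r else None,
        frac_J_only_of_sig_J=(n_j - n_both) / n_j if n_j else None,
        frac_both_of_union=n_both / union if union else None,
        direction_match_count=match,
    )


def _bin_index(p: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor(p / bin_width).astype(np.int64)
    return np.minimum(idx, n_bins - 1)  # prevalence 1.0 falls in the last bin


def prevalence_grid(
    pairs: pd.DataFrame, config: AnalysisConfig | None = None
) -> PrevalenceGrid:
    """Bin every pair by its two prevalences and count significance per cell."""
    if len(pairs) == 0:
        raise ValueError("empty result table")
    cfg = config or AnalysisConfig()
    n_bins = math.ceil(round(1.0 / cfg.bin_width, 9))
    edges = np.minimum(np.arange(n_bins + 1) * cfg.bin_width, 1.0)
    lo = np.minimum(pairs["prevalence_i"], pairs["prevalence_j"]).to_numpy()
    hi = np.maximum(pairs["prevalence_i"], pairs["prevalence_j"]).to_numpy()
    rows = _bin_index(lo, cfg.bin_width, n_bins)
    cols = _bin_index(hi, cfg.bin_width, n_bins)
    flat = rows * n_bins + cols
    size = n_bins * n_bins

    def layer(mask: np.ndarray) -> np.ndarray:
        return np.bincount(flat[mask], minlength=size).reshape(n_bins, n_bins)

    all_mask = np.ones(len(pairs), dtype=bool)
    total = layer(all_mask)
    sig_j = layer(pairs["sig_J"].to_numpy(dtype=bool))
    sig_r = layer(pairs["sig_r"].to_numpy(dtype=bool))
    return PrevalenceGrid(
        bin_edges=edges,
        total=total,
        sig_J=sig_j,
        sig_r=sig_r,
        difference=sig_j.astype(np.int64) - sig_r.astype(np.int64),
    )


def rare_pair_fractions(
    pa: PresenceAbsenceMatrix, config: AnalysisConfig | None = None
) -> tuple[float, float]:
    """(fraction of pairs with >=1 rare member, fraction with both rare).

    'Rare' is strict: prevalence < rare_cutoff.
    """
    if pa.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    cfg = config or AnalysisConfig()
    prev = pa.occupancy.sum(axis=1) / pa.n_sites
    n = pa.n_taxa
    n_rare = int((prev < cfg.rare_cutoff).sum())
    total = n_unique_pairs(n)
    both = n_rare * (n_rare - 1) // 2
    none_rare = (n - n_rare) * (n - n_rare - 1) // 2
    at_least_one = total - none_rare
    return at_least_one / total, both / total


class CooccurrenceResults:
    """Results of the all-pairs screen.

    Attributes
    ----------
    pairs : pandas.DataFrame
        One row per unordered pair, columns in :data:`PAIR_COLUMNS`.
    """

    def __init__(self, model: PairwiseCooccurrence, pairs: pd.DataFrame):
        self.model = model
        self.pairs = pairs

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def alpha_per_test(self) -> float:
        return self.model.alpha_per_test

    def concordance(self) -> ConcordanceSummary:
        return concordance_summary(self.pairs)

    def prevalence_grid(self) -> PrevalenceGrid:
        return prevalence_grid(self.pairs, self.config)

    def rare_pair_fractions(self) -> tuple[float, float]:
        return rare_pair_fractions(self.model.pa, self.config)

    def significant_edges(self, metric: str = "J") -> pd.DataFrame:
        """Edge list of significant pairs for downstream network tools."""
        if metric == "J":
            mask = self.pairs["sig_J"]
            cols = ["taxon_i", "taxon_j", "dir_J", "J", "p_J_ge_hyper", "p_J_le_hyper"]
        elif metric == "r":
            mask = self.pairs["sig_r"]
            cols = ["taxon_i", "taxon_j", "dir_r", "r", "p_r"]
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return self.pairs.loc[mask, cols].reset_index(drop=True)

    def to_csv(self, path: str, delimiter: str = "\t") -> None:
        self.pairs.to_csv(path, sep=delimiter, index=False)

    def summary(self) -> str:
        """Human-readable run summary."""
        conc = self.concordance()
        frac_one, frac_both = self.rare_pair_fractions()
        cfg = self.config
        fmt = lambda v: "undefined" if v is None else f"{v:.4f}"  # noqa: E731
        lines = [
            "Pairwise co-occurrence screen",
            "=============================",
            f"taxa:                {self.model.pa.n_taxa}",
            f"samples (sites):     {self.model.pa.n_sites}",
            f"unordered pairs:     {self.n_pairs}",
            f"familywise alpha:    {cfg.family_alpha} ({cfg.correction})",
            f"per-test alpha:      {self.alpha_per_test:.3e}",
            f"r test:              {cfg.r_test_method}",
            "",
            f"significant by J (hypergeometric null): {conc.n_sig_J}",
            f"significant by r:                       {conc.n_sig_r}",
            f"significant by both:                    {conc.n_sig_both}",
            f"frac of sig-r pairs not sig-J:          {fmt(conc.frac_r_only_of_sig_r)}",
            f"frac of sig-J pairs not sig-r:          {fmt(conc.frac_J_only_of_sig_J)}",
            f"frac of union significant in both:      {fmt(conc.frac_both_of_union)}",
            f"direction matches among both-sig:       "
            f"{conc.direction_match_count}/{conc.n_sig_both}",
            "",
            f"pairs with >=1 rare member (<{cfg.rare_cutoff:.0%}): {frac_one:.3f}",
            f"pairs with both members rare:           {frac_both:.3f}",
            f"degenerate pairs:                       {int(self.pairs['degenerate'].sum())}",
        ]
        return "\n".join(lines)
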
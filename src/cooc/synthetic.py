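"""Synthetic presence/absence data with known structure.

Three generators cover the testing needs of the rest of the package:

* :func:`generate_pair` — two binary site vectors with specified marginal
  prevalences (p1, p2) and a specified joint co-occurrence probability p11;
  independence is p11 = p1*p2, and any p11 inside the Fréchet bounds
  max(0, p1+p2-1) <= p11 <= min(p1, p2) yields a valid joint law.

* :func:`generate_fixed_margin_pair` — two site subsets of exact sizes
  drawn uniformly and independently; the overlap count is then distributed
  exactly as the prevalence-specific hypergeometric null, which makes this
  the simulation arm of that null's validation.

* :func:`generate_community` — a whole taxon-by-sample matrix whose
  prevalences are drawn from a long-tailed Beta family, with optional
  injected associated pairs and a truth table for recovery tests.  The
  default Beta(1.0, 6.45) over 286 samples x 1300 taxa reproduces the
  shape of a shotgun skin-microbiome occupancy table: roughly three
  quarters of pairs have at least one member below 10% prevalence and the
  median co-absent fraction per pair is near 77%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PresenceAbsenceMatrix

__all__ = [
    "PairSpec",
    "CommunitySpec",
    "generate_pair",
    "generate_fixed_margin_pair",
    "generate_community",
]


def frechet_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Attainable range of the joint co-occurrence probability p11."""
    return max(0.0, p1 + p2 - 1.0), min(p1, p2)


@dataclass(frozen=True)
class PairSpec:
    """Joint law of one taxon pair: marginals p1, p2 and joint p11."""

    N_sites: int
    p1: float
    p2: float
    p11: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N_sites < 1:
            raise ValueError("N_sites must be >= 1")
        for name in ("p1", "p2", "p11"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = frechet_bounds(self.p1, self.p2)
        if not (lo - 1e-12 <= self.p11 <= hi + 1e-12):
            raise ValueError(
                f"p11={self.p11} outside Fréchet bounds [{lo}, {hi}] "
                f"for marginals ({self.p1}, {self.p2})"
            )

    @property
    def independent(self) -> bool:
        return abs(self.p11 - self.p1 * self.p2) < 1e-12

    def cell_probabilities(self) -> np.ndarray:
        """(p11, p10, p01, p00) — the per-site joint law."""
        p11 = min(max(self.p11, max(0.0, self.p1 + self.p2 - 1.0)), min(self.p1, self.p2))
        probs = np.array(
            [p11, self.p1 - p11, self.p2 - p11, 1.0 - self.p1 - self.p2 + p11]
        )
        return np.clip(probs, 0.0, 1.0)


@dataclass(frozen=True)
class InjectedPair:
    """An associated pair occupying two designated taxon slots of a community."""

    i: int
    j: int
    p1: float
    p2: float
    p11: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("injected pair must reference two distinct taxon slots")
        PairSpec(N_sites=1, p1=self.p1, p2=self.p2, p11=self.p11)  # bounds check


@dataclass(frozen=True)
class CommunitySpec:
    """A long-tailed community: prevalences ~ Beta(shape_a, shape_b).

    Defaults (286 sites, 1300 taxa, Beta(1.0, 6.45)) emulate the occupancy
    structure of a deeply classified shotgun microbiome survey dominated by
    rare taxa.
    """

    N_sites: int = 286
    n_taxa: int = 1300
    shape_a: float = 1.0
    shape_b: float = 6.45
    injections: tuple[InjectedPair, ...] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N_sites < 1 or self.n_taxa < 2:
            raise ValueError("need N_sites >= 1 and n_taxa >= 2")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        used: set[int] = set()
        for inj in self.injections:
            for slot in (inj.i, inj.j):
                if not (0 <= slot < self.n_taxa):
                    raise ValueError(f"injected slot {slot} out of range")
                if slot in used:
                    raise ValueError(f"taxon slot {slot} used by two injections")
                used.add(slot)


def generate_pair(spec: PairSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample two binary site vectors from the joint law of a PairSpec."""
    rng = np.random.default_rng(spec.seed)
    return _pair_from_rng(spec, rng)


def _pair_from_rng(spec: PairSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    probs = spec.cell_probabilities()
    probs = probs / probs.sum()
    states = rng.choice(4, size=spec.N_sites, p=probs)
    x1 = ((states == 0) | (states == 1)).astype(np.uint8)
    x2 = ((states == 0) | (states == 2)).astype(np.uint8)
    return x1, x2


def generate_fixed_margin_pair(
    N_sites: int, occ1: int, occ2: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two binary vectors with exact occupancy counts, placed independently."""
    if not (0 <= occ1 <= N_sites and 0 <= occ2 <= N_sites):
        raise ValueError("occupancy counts must satisfy 0 <= occ <= N_sites")
    rng = np.random.default_rng(seed)
    x1 = np.zeros(N_sites, dtype=np.uint8)
    x2 = np.zeros(N_sites, dtype=np.uint8)
    x1[rng.choice(N_sites, size=occ1, replace=False)] = 1
    x2[rng.choice(N_sites, size=occ2, replace=False)] = 1
    return x1, x2


def generate_community(
    spec: CommunitySpec,
) -> tuple[PresenceAbsenceMatrix, pd.DataFrame]:
    """Generate a community matrix plus the truth table of injected pairs.

    Background taxa are independent: each draws a prevalence from the Beta
    family and fills sites as iid Bernoulli.  Injected pairs overwrite
    their two slots with draws from the specified joint law.  The returned
    truth table has one row per injection (taxon_i, taxon_j, p1, p2, p11,
    independent flag).
    """
    rng = np.random.default_rng(spec.seed)
    prevalences = rng.beta(spec.shape_a, spec.shape_b, size=spec.n_taxa)
    occupancy = (
        rng.random((spec.n_taxa, spec.N_sites)) < prevalences[:, None]
    ).astype(np.uint8)

    rows = []
    for inj in spec.injections:
        pair_spec = PairSpec(
            N_sites=spec.N_sites, p1=inj.p1, p2=inj.p2, p11=inj.p11
        )
        x1, x2 = _pair_from_rng(pair_spec, rng)
        occupancy[inj.i] = x1
        occupancy[inj.j] = x2
        rows.append(
            {
                "taxon_i": f"taxon_{inj.i:05d}",
                "taxon_j": f"taxon_{inj.j:05d}",
                "p1": inj.p1,
                "p2": inj.p2,
                "p11": inj.p11,
                "independent": abs(inj.p11 - inj.p1 * inj.p2) < 1e-12,
            }
        )

    pa = PresenceAbsenceMatrix(
        taxon_ids=[f"taxon_{i:05d}" for i in range(spec.n_taxa)],
        sample_ids=[f"sample_{j:04d}" for j in range(spec.N_sites)],
        occupancy=occupancy,
    )
    truth = pd.DataFrame(
        rows, columns=["taxon_i", "taxon_j", "p1", "p2", "p11", "independent"]
    )
    return pa, truth
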
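"""Binary association metrics on 2x2 contingency tables.

Two metrics are computed from the per-pair cells (a, b, c, d):

* the phi coefficient, Pearson's product-moment correlation applied to two
  binary vectors,

      r = (a*d - b*c) / sqrt((a+b)(c+d)(a+c)(b+d)),   r in [-1, 1]

* Jaccard's index of similarity,

      J = a / (a + b + c),                            J in [0, 1]

J deliberately ignores co-absences (d).  r does not: holding a, b, c fixed
and growing d drives r upward and can flip its sign, which is the pathology
the co-absence sweep makes visible.  In occupancy data dominated by rare
taxa, d is large for most pairs, so the two metrics routinely disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data import ContingencyTable

__all__ = [
    "AssociationValue",
    "phi_coefficient",
    "jaccard_index",
    "coabsence_sweep",
    "predicted_jaccard_independence",
]


@dataclass(frozen=True)
class AssociationValue:
    """A metric value with an explicit degenerate-denominator flag.

    When ``defined`` is False (zero denominator: e.g. a taxon present or
    absent everywhere), ``value`` is None rather than a sentinel number, so
    degenerate pairs can be counted instead of silently polluting summaries.
    """

    metric: str
    value: float | None
    defined: bool

    def __float__(self) -> float:
        if not self.defined or self.value is None:
            return float("nan")
        return self.value


def phi_coefficient(t: ContingencyTable) -> AssociationValue:
    """Phi coefficient r = (ad - bc)/sqrt((a+b)(c+d)(a+c)(b+d)).

    Undefined when any marginal is zero.  The radicand is evaluated as a
    product of two pairwise square roots so the intermediate stays within
    float range for cell counts up to ~1e6.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    if min(m1, m2, m3, m4) == 0:
        return AssociationValue("phi", None, False)
    r = (a * d - b * c) / (math.sqrt(m1 * m2) * math.sqrt(m3 * m4))
    # clip float fuzz at the boundary of the admissible range
    r = max(-1.0, min(1.0, r))
    return AssociationValue("phi", r, True)


def jaccard_index(t: ContingencyTable) -> AssociationValue:
    """Jaccard's index J = a/(a+b+c); undefined when both taxa are absent everywhere."""
    n_occ = t.a + t.b + t.c
    if n_occ == 0:
        return AssociationValue("jaccard", None, False)
    return AssociationValue("jaccard", t.a / n_occ, True)


def coabsence_sweep(
    a: int, b: int, c: int, d_values: Iterable[int]
) -> list[tuple[int, float | None]]:
    """Sweep the co-absence cell d at fixed (a, b, c), returning (d, r) pairs.

    J is constant across the sweep since it does not involve d; r is not,
    and typically increases (and can reverse sign) as co-absences accumulate.
    """
    if a == b == c == 0:
        raise ValueError("a, b, c must not all be zero")
    d_list: Sequence[int] = list(d_values)
    if not d_list:
        raise ValueError("d_values must be nonempty")
    out: list[tuple[int, float | None]] = []
    for d in d_list:
        r = phi_coefficient(ContingencyTable(a, b, c, d))
        out.append((int(d), r.value))
    return out


def predicted_jaccard_independence(p1: float, p2: float) -> AssociationValue:
    """Expected J for two independently placed taxa with prevalences p1, p2.

    Under independence the expected cell fractions are a=p1*p2, b=p1(1-p2),
    c=(1-p1)p2, giving J = p1*p2 / (p1 + p2 - p1*p2).  At p1 = p2 = 0.5 this
    is exactly 1/3, the expectation the 50%-prevalence null hard-codes.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("prevalences must lie in [0, 1]")
    denom = p1 + p2 - p1 * p2
    if denom == 0.0:
        return AssociationValue("jaccard", None, False)
    return AssociationValue("jaccard", (p1 * p2) / denom, True)
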
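"""Subgenome dominance statistics.

After a WGD, duplicated gene deletion is not random between the two sister
(paralogous) compartments: one block - the dominant (D) one - retains more
ancestral genes than its sensitive (S) sister.  The null hypothesis of
equal deletion is tested per compartment pair with a Pearson chi-square
test against an equal split of the observed retained-gene total:

    E = (n_a + n_b) / 2,   chi2 = (n_a - E)^2 / E + (n_b - E)^2 / E,  df = 1

The larger count is labelled D and the smaller S when p < alpha (default
0.05, no continuity correction, no multiple-testing correction by default;
a Bonferroni option is exposed for users who want one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import round_half_away


@dataclass(frozen=True)
class DominanceResult:
    compartment_a: str
    compartment_b: str
    n_a: int
    n_b: int
    chi2: float
    p: float
    labels: tuple[str, str]  # ("D","S"), ("S","D") or ("ns","ns")


@dataclass(frozen=True)
class CompartmentRates:
    compartment: str
    annotated: int
    retained: int
    shuffled: int

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.retained / self.annotated

    @property
    def shuffle_permil(self) -> float:
        return 1000.0 * self.shuffled / self.annotated


def chi_square_dominance(
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
    compartment_a: str = "A",
    compartment_b: str = "B",
) -> DominanceResult:
    """Test equal retention between two paralogous compartments."""
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    if n_a + n_b == 0:
        raise ValueError("both counts are zero")
    e = (n_a + n_b) / 2.0
    chi2 = (n_a - e) ** 2 / e + (n_b - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    if p < alpha:
        labels = ("D", "S") if n_a > n_b else ("S", "D")
    else:
        labels = ("ns", "ns")
    return DominanceResult(compartment_a, compartment_b, n_a, n_b, chi2, p, labels)


def count_retention(annotated: int, retained: int) -> tuple[int, int, int]:
    """(annotated, retained, deleted percentage) with half-away rounding."""
    if annotated <= 0:
        raise ValueError("annotated count must be positive")
    deleted_pct = round_half_away(100.0 * (1.0 - retained / annotated))
    return annotated, retained, deleted_pct


def compartment_rates(
    counts: Mapping[str, tuple[int, int, int]]
) -> list[CompartmentRates]:
    """Per-compartment retention/shuffling rates from
    ``{compartment: (annotated, retained, shuffled)}``."""
    return [
        CompartmentRates(comp, ann, ret, shuf)
        for comp, (ann, ret, shuf) in sorted(counts.items())
    ]


def cross_species_mean(values: Sequence[float]) -> int:
    """Unweighted arithmetic mean across species, rounded for display."""
    if not values:
        raise ValueError("no values")
    return round_half_away(float(np.mean(values)))


def dominance_table(
    pair_counts: Iterable[tuple[str, str, int, int]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[DominanceResult]:
    """Run the chi-square dominance test over compartment pairs.

    ``pair_counts`` yields (compartment_a, compartment_b, n_a, n_b).  With
    ``bonferroni`` the per-test alpha is divided by the number of pairs.
    """
    rows = list(pair_counts)
    a = alpha / len(rows) if (bonferroni and rows) else alpha
    return [chi_square_dominance(na, nb, a, ca, cb) for ca, cb, na, nb in rows]
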
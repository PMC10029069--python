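"""Cohort-level summaries and contingency statistics.

The enrichment analyses in this framework are 2x2 contingency tests: Fisher's
exact test (two-sided, probability-mass definition) for small tables such as
the ClinVar benign-enrichment comparison, and the Pearson chi-square with an
optional Yates correction plus a Bonferroni helper for post hoc class
comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import CATEGORY_ORDER, CurationResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, of every table at most as probable as the observed one. Degenerate
    margins (an empty row or column) return 1.0 by convention.
    """
    arr = t.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def chi_square_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df=1) with optional Yates correction."""
    arr = t.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        raise ValueError("chi-square undefined for a zero margin")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value for ``m`` tests, capped at 1."""
    return min(1.0, p * m)


def summarize_results(results: list[CurationResult]) -> dict:
    """Verdict, flag and primary-reason distributions for a curated cohort."""
    if not results:
        warnings.warn("summarize_results called with empty input", stacklevel=2)
        return {
            "n": 0,
            "verdict_counts": {},
            "verdict_proportions": {},
            "flag_counts": {},
            "flag_counts_by_category": {},
            "primary_reasons": {},
        }
    n = len(results)
    verdict_counts: dict[str, int] = {}
    flag_counts: dict[str, int] = {}
    by_category: dict[str, dict[str, int]] = {}
    primary: dict[str, int] = {}
    for r in results:
        verdict_counts[r.verdict.value] = verdict_counts.get(r.verdict.value, 0) + 1
        primary[r.primary_reason] = primary.get(r.primary_reason, 0) + 1
        for f in sorted(r.flags, key=lambda f: (CATEGORY_ORDER[f.category], f.name)):
            flag_counts[f.name] = flag_counts.get(f.name, 0) + 1
            by_category.setdefault(f.category.value, {})
            by_category[f.category.value][f.name] = (
                by_category[f.category.value].get(f.name, 0) + 1
            )
    return {
        "n": n,
        "verdict_counts": dict(sorted(verdict_counts.items())),
        "verdict_proportions": {k: v / n for k, v in sorted(verdict_counts.items())},
        "flag_counts": dict(sorted(flag_counts.items())),
        "flag_counts_by_category": {
            k: dict(sorted(v.items())) for k, v in sorted(by_category.items())
        },
        "primary_reasons": dict(sorted(primary.items())),
    }
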
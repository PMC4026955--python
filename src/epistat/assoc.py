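"""Contingency-table statistics for case-control genotype data.

Implements the exact conventions used throughout the pipeline:

* Hardy-Weinberg chi-square on one group's genotype counts (df = 1, expected
  counts ``n p^2, 2npq, n q^2`` from the sample allele frequency, no
  continuity correction).
* 2x3 genotype association (Pearson chi-square; genotype classes empty in the
  pooled margin are dropped and df shrinks accordingly — needed for
  deletion-type loci with no heterozygote class).
* 2x2 chi-square with a *conditional* Yates continuity correction and odds
  ratios with a *conditional* Haldane-Anscombe +0.5 correction: both fire iff
  any observed cell is below ``small_cell_threshold`` (default 10).  The
  confidence interval is Woolf's log-OR interval on the (possibly corrected)
  cells.
* Bonferroni adjustment with a caller-supplied number of tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_data import GenotypeCounts

SMALL_CELL_THRESHOLD = 10


class DegenerateTableError(ValueError):
    """Raised when a test is undefined for the given counts."""


@dataclass(frozen=True)
class Table2x2:
    """2x2 counts: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DegenerateTableError("2x2 counts must be nonnegative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise DegenerateTableError("both row margins must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def min_cell(self) -> int:
        return min(self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssocResult:
    chi2: float
    df: int
    p: float
    yates_applied: bool = False
    or_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    haldane_applied: bool = False
    p_adj: float | None = None


def hwe_chi2(counts: GenotypeCounts) -> AssocResult:
    """Pearson chi-square for departure from Hardy-Weinberg proportions.

    df = 1 (three classes, one estimated allele frequency).  Raises for a
    monomorphic sample, where the statistic is undefined.
    """
    n = counts.total
    if n < 1:
        raise DegenerateTableError("need at least one genotyped subject")
    p = counts.allele_freq(which=0)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise DegenerateTableError("monomorphic sample: HWE test undefined")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = counts.as_array()
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return AssocResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def genotype_chi2_2x3(case_counts: GenotypeCounts,
                      control_counts: GenotypeCounts) -> AssocResult:
    """Pearson chi-square comparing genotype distributions of cases vs controls.

    Genotype classes empty in the pooled margin are dropped; df = retained
    classes - 1.
    """
    obs = np.vstack([case_counts.as_array(), control_counts.as_array()])
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 genotype classes observed")
    if obs.sum(axis=1).min() == 0:
        raise DegenerateTableError("one group has no genotyped subjects")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return AssocResult(chi2=float(chi2), df=int(df), p=float(p))


def chi2_2x2(t: Table2x2,
             small_cell_threshold: int = SMALL_CELL_THRESHOLD) -> AssocResult:
    """2x2 chi-square with conditional Yates correction (any cell < threshold)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if a + c == 0 or b + d == 0:
        warnings.warn("zero column margin: chi-square set to 0", stacklevel=2)
        return AssocResult(chi2=0.0, df=1, p=1.0)
    denom = float((a + b) * (c + d) * (a + c) * (b + d))
    yates = t.min_cell < small_cell_threshold
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff ** 2 / denom
    return AssocResult(chi2=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)),
                       yates_applied=yates)


def odds_ratio_ci(t: Table2x2, z: float = 1.96,
                  small_cell_threshold: int = SMALL_CELL_THRESHOLD) -> AssocResult:
    """Cross-product odds ratio with Woolf CI; Haldane-Anscombe +0.5 applied
    to all four cells when any observed cell < threshold."""
    haldane = t.min_cell < small_cell_threshold
    if not haldane and t.min_cell == 0:
        # threshold lowered by the caller but a zero cell makes the plain OR
        # undefined: correct unconditionally
        warnings.warn("zero cell: Haldane-Anscombe correction forced",
                      stacklevel=2)
        haldane = True
    shift = 0.5 if haldane else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    res = chi2_2x2(t, small_cell_threshold=small_cell_threshold)
    res.or_value = float(or_value)
    res.ci_low = float(math.exp(math.log(or_value) - z * se))
    res.ci_high = float(math.exp(math.log(or_value) + z * se))
    res.haldane_applied = haldane
    return res


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m*p)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    return min(1.0, m * p)
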
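"""Post hoc two-locus genotype-combination association scan.

For every pair of loci in a pool (typically the hits from the set-association
and MDR stages) and every 3x3 pair of genotype codes, subjects carrying
exactly that genotype combination are contrasted against all other subjects
in a 2x2 table (cases vs controls), using the conditional Yates/Haldane
small-cell rules of :mod:`epistat.assoc`.  Bonferroni adjustment uses the
number of combinations actually evaluated in the stratum (zero-carrier
combinations are skipped and not counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocResult, SMALL_CELL_THRESHOLD, Table2x2, bonferroni, \
    odds_ratio_ci
from .study_data import CohortTable, stratify


@dataclass
class ComboResult:
    locus_a: int
    locus_b: int
    geno_a: int
    geno_b: int
    label: str
    table: Table2x2
    assoc: AssocResult
    m_tests: int = 0
    p_adj: float = 1.0


def _combo_label(cohort: CohortTable, i: int, g: int) -> str:
    locus = cohort.loci[i]
    if locus.genotype_labels:
        return f"{locus.name} {locus.genotype_labels[g]}"
    maj, mnr = locus.alleles
    geno = {0: maj + maj, 1: maj + mnr, 2: mnr + mnr}[g]
    return f"{locus.name} {geno}"


def scan_pairs(cohort: CohortTable, locus_pool: list[int],
               min_carriers: int = 1,
               sex: str | None = None, subtype: str | None = None,
               small_cell_threshold: int = SMALL_CELL_THRESHOLD,
               z: float = 1.96) -> list[ComboResult]:
    """All two-locus genotype-combination tests in a (possibly stratified) cohort.

    Subjects missing either genotype of a pair are excluded from that pair's
    tables only.  Results are sorted by unadjusted p ascending.
    """
    if sex is not None or subtype is not None:
        cohort = stratify(cohort, sex=sex, subtype=subtype)
    pool = sorted(set(int(i) for i in locus_pool))
    for i in pool:
        if not 0 <= i < cohort.n_loci:
            raise ValueError(f"pool locus index {i} not in cohort")
    if len(pool) < 2:
        raise ValueError("locus pool must contain at least two loci")

    results: list[ComboResult] = []
    pheno = cohort.phenotype
    for ai in range(len(pool)):
        for bi in range(ai + 1, len(pool)):
            i, j = pool[ai], pool[bi]
            gi = cohort.genotypes[:, i]
            gj = cohort.genotypes[:, j]
            valid = (gi >= 0) & (gj >= 0)
            for ga in range(3):
                for gb in range(3):
                    carrier = valid & (gi == ga) & (gj == gb)
                    a = int((carrier & pheno).sum())
                    c = int((carrier & ~pheno).sum())
                    if a + c < min_carriers:
                        continue
                    b = int((valid & pheno).sum()) - a
                    d = int((valid & ~pheno).sum()) - c
                    table = Table2x2(a, b, c, d)
                    res = odds_ratio_ci(table, z=z,
                                        small_cell_threshold=small_cell_threshold)
                    label = (f"{_combo_label(cohort, i, ga)} x "
                             f"{_combo_label(cohort, j, gb)}")
                    results.append(ComboResult(
                        locus_a=i, locus_b=j, geno_a=ga, geno_b=gb,
                        label=label, table=table, assoc=res))
    m = len(results)
    for r in results:
        r.m_tests = m
        r.p_adj = bonferroni(r.assoc.p, m)
    results.sort(key=lambda r: (r.assoc.p, r.label))
    return results


def significant_combos(results: list[ComboResult], alpha: float = 0.05) -> list[ComboResult]:
    """Combinations whose Bonferroni-adjusted p is at or below ``alpha``."""
    return [r for r in results if r.p_adj <= alpha]


def combos_frame(results: list[ComboResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "combination": r.label,
            "case_n": t.a, "case_pct": 100.0 * t.a / (t.a + t.b),
            "control_n": t.c, "control_pct": 100.0 * t.c / (t.c + t.d),
            "chi2": r.assoc.chi2, "p": r.assoc.p,
            "or": r.assoc.or_value,
            "ci_low": r.assoc.ci_low, "ci_high": r.assoc.ci_high,
            "p_adj": r.p_adj, "m_tests": r.m_tests,
            "yates": r.assoc.yates_applied, "haldane": r.assoc.haldane_applied,
        })
    return pd.DataFrame(rows)
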
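import numpy as np
import pytest

from epistat.simulate import default_panel, make_epistasis_model, simulate, \
    simulate_study
from epistat.study_data import CohortTable, LocusDef


@pytest.fixture(scope="session")
def study_cohort():
    """Null-model cohort with the emulated study's stratum structure."""
    names, mafs = default_panel()
    spec = make_epistasis_model("null", mafs, baseline=0.1, locus_names=names)
    return simulate_study(spec, seed=101).cohort


@pytest.fixture(scope="session")
def xor_cohort():
    """Purely epistatic two-locus cohort (six-locus panel, causal pair 0,1)."""
    mafs = np.full(6, 0.3)
    mafs[:2] = 0.5
    spec = make_epistasis_model("xor", mafs, model_loci=(0, 1),
                                high=0.9, low=0.1)
    return simulate(spec, 400, 400, seed=202).cohort


def cohort_from_counts(case_counts, control_counts, n_loci=1, locus=0):
    """Build a single-stratum cohort realizing exact per-genotype counts.

    ``case_counts``/``control_counts`` are (n0, n1, n2) for ``locus``; other
    loci are filled with code 0.
    """
    rows, pheno = [], []
    for counts, is_case in ((case_counts, True), (control_counts, False)):
        for code, k in zip((0, 1, 2), counts):
            for _ in range(k):
                g = np.zeros(n_loci, dtype=np.int8)
                g[locus] = code
                rows.append(g)
                pheno.append(is_case)
    pheno = np.array(pheno)
    return CohortTable(
        loci=[LocusDef(name=f"L{j}") for j in range(n_loci)],
        genotypes=np.vstack(rows),
        phenotype=pheno,
        sex=np.full(len(pheno), "U"),
        subtype=np.where(pheno, "unknown", "control"),
    )
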
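import warnings

import numpy as np
import pytest

from epistat.study_data import (CohortError, CohortTable, GenotypeCounts,
                                LocusDef, genotype_counts,
                                orient_to_control_minor, read_cohort,
                                stratify, write_cohort)

from conftest import cohort_from_counts


def _write(tmp_path, text, name="cohort.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


TOY = """id\tstatus\tsex\tsubtype\tSNP1
s1\tcase\tM\tallergic\tA/A
s2\tcase\tF\tallergic\tA/G
s3\tcontrol\tM\t\tG/G
s4\tcontrol\tF\t\tA/A
s5\tcontrol\tM\t\tA/A
s6\tcontrol\tF\t\tA/A
"""

TOY_SWAPPED = TOY.replace("A/G", "G/A")


def test_tabular_encoding_counts_minor_allele(tmp_path):
    cohort = read_cohort(_write(tmp_path, TOY))
    # G is the rare allele among controls -> code = G count
    assert cohort.genotypes[:, 0].tolist() == [0, 1, 2, 0, 0, 0]
    assert cohort.loci[0].alleles == ("A", "G")


def test_encoding_invariant_to_allele_order_in_cells(tmp_path):
    a = read_cohort(_write(tmp_path, TOY, "a.tsv"))
    b = read_cohort(_write(tmp_path, TOY_SWAPPED, "b.tsv"))
    assert np.array_equal(a.genotypes, b.genotypes)


def test_orientation_flips_when_minor_allele_listed_first(tmp_path):
    # G (rare in controls) appears first in the file, so the first-pass
    # coding counts A; control-frequency reorientation must flip it back
    reordered = (
        "id\tstatus\tsex\tsubtype\tSNP1\n"
        "s3\tcontrol\tM\t\tG/G\n"
        "s1\tcase\tM\tallergic\tA/A\n"
        "s2\tcase\tF\tallergic\tA/G\n"
        "s4\tcontrol\tF\t\tA/A\n"
        "s5\tcontrol\tM\t\tA/A\n"
        "s6\tcontrol\tF\t\tA/A\n"
    )
    with pytest.warns(UserWarning, match="reoriented"):
        cohort = read_cohort(_write(tmp_path, reordered))
    assert cohort.genotypes[:, 0].tolist() == [2, 0, 1, 0, 0, 0]
    assert cohort.loci[0].alleles == ("A", "G")


def test_orientation_is_idempotent(study_cohort):
    once = orient_to_control_minor(study_cohort, warn=False)
    twice = orient_to_control_minor(once, warn=False)
    assert np.array_equal(once.genotypes, twice.genotypes)
    # after orientation, control minor-allele frequency <= 0.5 everywhere
    for j in range(once.n_loci):
        assert genotype_counts(once, j, "controls").allele_freq(2) <= 0.5 + 1e-12


def test_duplicate_subject_id_rejected(tmp_path):
    bad = TOY.replace("s2", "s1")
    with pytest.raises(CohortError, match="duplicate"):
        read_cohort(_write(tmp_path, bad))


def test_high_missingness_flagged_but_kept(tmp_path):
    text = TOY.replace("s2\tcase\tF\tallergic\tA/G", "s2\tcase\tF\tallergic\t.")
    with pytest.warns(UserWarning, match="missing"):
        cohort = read_cohort(_write(tmp_path, text))
    assert cohort.n_subjects == 6
    assert cohort.genotypes[1, 0] == -1


@pytest.mark.parametrize("fmt", ["tabular", "pedmap"])
def test_write_read_roundtrip(tmp_path, study_cohort, fmt):
    # orient first: the reader always returns control-minor orientation,
    # so round-trip identity is defined on oriented tables
    sub = orient_to_control_minor(study_cohort, warn=False)
    path = tmp_path / ("c.tsv" if fmt == "tabular" else "c.ped")
    write_cohort(sub, path, format=fmt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        back = read_cohort(path, format=fmt)
    assert np.array_equal(back.genotypes, sub.genotypes)
    assert np.array_equal(back.phenotype, sub.phenotype)
    assert np.array_equal(back.sex, sub.sex)
    assert list(back.subtype) == list(sub.subtype)
    assert [l.name for l in back.loci] == [l.name for l in sub.loci]


def test_stratify_reproduces_study_group_sizes(study_cohort):
    nm = stratify(study_cohort, sex="M", subtype="nonallergic")
    assert (nm.n_cases, nm.n_controls) == (29, 105)
    fa = stratify(study_cohort, sex="F", subtype="allergic")
    assert (fa.n_cases, fa.n_controls) == (92, 109)
    # controls are never filtered by subtype
    assert stratify(study_cohort, subtype="allergic").n_controls == 214


def test_stratify_identity_and_errors(study_cohort):
    same = stratify(study_cohort)
    assert same.n_subjects == study_cohort.n_subjects
    with pytest.raises(CohortError, match="stratum"):
        stratify(study_cohort, sex="X")


def test_stratum_counts_sum_to_whole_cohort(study_cohort):
    j = 5
    whole = genotype_counts(study_cohort, j, "cases")
    parts = [genotype_counts(stratify(study_cohort, sex=s), j, "cases")
             for s in ("M", "F")]
    assert whole.as_array().tolist() == (parts[0].as_array()
                                         + parts[1].as_array()).tolist()


def test_genotype_counts_match_construction():
    cohort = cohort_from_counts((97, 52, 7), (90, 108, 16))
    assert genotype_counts(cohort, 0, "controls") == GenotypeCounts(90, 108, 16)
    assert genotype_counts(cohort, 0, "cases") == GenotypeCounts(97, 52, 7)


def test_minor_allele_frequency_from_counts():
    # GSR allergic-case genotype counts -> C allele frequency 0.638
    counts = GenotypeCounts(17, 79, 60)
    assert counts.allele_freq(2) == pytest.approx(0.638, abs=5e-4)


def test_all_missing_counts_warn():
    cohort = cohort_from_counts((5, 0, 0), (5, 0, 0), n_loci=2)
    cohort.genotypes[:, 1] = -1
    with pytest.warns(UserWarning, match="missing"):
        counts = genotype_counts(cohort, 1, "cases")
    assert counts.total == 0


def test_controls_must_be_labeled_control():
    with pytest.raises(CohortError, match="control"):
        CohortTable(loci=[LocusDef(name="L0")],
                    genotypes=np.zeros((2, 1), dtype=np.int8),
                    phenotype=np.array([True, False]),
                    sex=np.array(["M", "F"]),
                    subtype=np.array(["allergic", "allergic"], dtype=object))
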
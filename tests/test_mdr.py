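import numpy as np
import pytest

from epistat.mdr import (FoldError, HIGH, LOW, MdrConfig, UNCLASSIFIED,
                         cell_partition, evaluate_model, search)
from epistat.simulate import make_epistasis_model, simulate
from epistat.study_data import CohortTable, LocusDef
from epistat.validation import brute_force_cell_labels


def _cohort(geno, pheno):
    geno = np.asarray(geno, dtype=np.int8)
    pheno = np.asarray(pheno, dtype=bool)
    return CohortTable(
        loci=[LocusDef(name=f"L{j}") for j in range(geno.shape[1])],
        genotypes=geno, phenotype=pheno,
        sex=np.full(len(pheno), "U"),
        subtype=np.where(pheno, "unknown", "control"))


def test_separable_single_locus_partition():
    geno = np.array([[2]] * 10 + [[0]] * 5 + [[1]] * 5)
    pheno = np.array([True] * 10 + [False] * 10)
    labels = cell_partition(_cohort(geno, pheno), (0,), threshold=1.0)
    assert labels.tolist() == [LOW, LOW, HIGH]


def test_tie_cells_follow_tie_rule():
    geno = np.array([[0]] * 6)
    pheno = np.array([True] * 3 + [False] * 3)
    cohort = _cohort(geno, pheno)
    assert cell_partition(cohort, (0,), threshold=1.0,
                          tie_rule="high_risk")[0] == HIGH
    assert cell_partition(cohort, (0,), threshold=1.0,
                          tie_rule="low_risk")[0] == LOW


def test_empty_cell_rule():
    geno = np.array([[0]] * 6)
    pheno = np.array([True] * 3 + [False] * 3)
    cohort = _cohort(geno, pheno)
    assert cell_partition(cohort, (0,), empty_cell_rule="low_risk")[2] == LOW
    assert cell_partition(cohort, (0,),
                          empty_cell_rule="unclassified")[2] == UNCLASSIFIED


def test_partition_matches_brute_force_oracle():
    """Vectorized cell labeling equals the per-cell enumeration oracle on
    random small instances (both tie rules)."""
    rng = np.random.default_rng(11)
    for _ in range(60):
        n = int(rng.integers(6, 31))
        L = int(rng.integers(1, 4))
        geno = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        pheno = rng.random(n) < 0.5
        pheno[0], pheno[-1] = True, False
        loci = tuple(range(L))
        thr = pheno.sum() / (~pheno).sum()
        cohort = _cohort(geno, pheno)
        for tie in ("high_risk", "low_risk"):
            ours = cell_partition(cohort, loci, tie_rule=tie)
            oracle = brute_force_cell_labels(geno, pheno, loci, thr, tie_rule=tie)
            assert np.array_equal(ours, oracle)


def test_fully_penetrant_locus_classified_perfectly():
    spec = make_epistasis_model("main_effect", np.array([0.5]), model_loci=(0,),
                                baseline=0.0, grr=1.0)
    spec.penetrance = np.array([0.0, 0.0, 1.0])
    sim = simulate(spec, 100, 100, seed=5)
    model = evaluate_model(sim.cohort, (0,), MdrConfig(orders=(1,), n_seeds=2,
                                                       seed=0))
    assert model.test_acc == pytest.approx(1.0)
    assert model.prediction_error_pct == pytest.approx(0.0)


def test_prediction_error_identity_and_training_floor():
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 3, size=(120, 3)).astype(np.int8)
    pheno = np.arange(120) < 60
    model = evaluate_model(_cohort(geno, pheno), (0, 1),
                           MdrConfig(orders=(2,), n_seeds=2, seed=1))
    assert model.prediction_error_pct + 100 * model.test_acc == pytest.approx(100.0)
    assert model.train_acc >= 0.5 - 1e-12


def test_label_permuted_data_scores_at_chance():
    rng = np.random.default_rng(17)
    devs = []
    for rep in range(20):
        geno = rng.integers(0, 3, size=(200, 2)).astype(np.int8)
        pheno = rng.permutation(np.arange(200) < 100)
        model = evaluate_model(_cohort(geno, pheno), (0, 1),
                               MdrConfig(orders=(2,), n_seeds=1, seed=rep))
        devs.append(model.test_acc - 0.5)
    assert abs(np.mean(devs)) < 0.05


def test_exhaustive_search_enumerates_all_pairs(xor_cohort):
    case_idx = np.nonzero(xor_cohort.phenotype)[0][:100]
    ctrl_idx = np.nonzero(~xor_cohort.phenotype)[0][:100]
    sub = xor_cohort.subset(np.sort(np.concatenate([case_idx, ctrl_idx])))
    models = search(sub, MdrConfig(orders=(2,), n_seeds=1, seed=0))
    assert models[2].n_evaluated == 15  # C(6,2) on the full panel
    # 4-locus pool -> C(4,2) combinations
    pooled = search(sub, MdrConfig(orders=(2,), n_seeds=1, seed=0,
                                   pool=(0, 1, 2, 3)))[2]
    assert pooled.n_evaluated == 6


def test_forced_single_model_has_full_cvc(xor_cohort):
    cfg = MdrConfig(orders=(4,), n_seeds=2, seed=0, search_mode="forced",
                    pool=(0, 1, 2, 3))
    m = search(xor_cohort, cfg)[4]
    assert m.n_evaluated == 1
    assert m.cvc_pct == pytest.approx(100.0)


def test_xor_recovery_with_full_cvc(xor_cohort):
    models = search(xor_cohort, MdrConfig(orders=(2,), n_seeds=5, seed=3))
    best = models[2]
    assert best.loci == (0, 1)
    assert best.cvc_pct == pytest.approx(100.0)
    assert best.prediction_error_pct < 35.0


def test_search_deterministic_under_seed(xor_cohort):
    cfg = MdrConfig(orders=(2,), n_seeds=2, seed=12)
    a = search(xor_cohort, cfg)[2]
    b = search(xor_cohort, cfg)[2]
    assert a.loci == b.loci
    assert a.test_acc == b.test_acc
    assert a.cvc_pct == b.cvc_pct


def test_order_larger_than_pool_errors(xor_cohort):
    with pytest.raises(ValueError, match="pool"):
        search(xor_cohort, MdrConfig(orders=(3,), pool=(0, 1), n_seeds=1))


def test_unbalanced_folds_raise():
    geno = np.zeros((12, 1), dtype=np.int8)
    pheno = np.arange(12) < 3
    with pytest.raises(FoldError):
        evaluate_model(_cohort(geno, pheno), (0,),
                       MdrConfig(k_folds=10, orders=(1,), n_seeds=1))


def test_missing_genotypes_excluded_per_combination():
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 3, size=(80, 2)).astype(np.int8)
    geno[:40, 1] = -1
    pheno = np.tile([True, False], 40)
    cohort = _cohort(geno, pheno)
    labels0 = cell_partition(cohort, (0,))
    oracle0 = brute_force_cell_labels(geno, pheno, (0,),
                                      pheno.sum() / (~pheno).sum())
    assert np.array_equal(labels0, oracle0)  # locus 0 unaffected by locus 1 missing
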
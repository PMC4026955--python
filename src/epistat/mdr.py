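"""Multifactor dimensionality reduction (MDR).

Each combination of loci defines a grid of multilocus genotype cells.  On a
training set, a cell is labeled *high risk* when its case:control ratio
reaches a threshold (by default the training set's overall case:control
ratio), collapsing the multilocus predictor to one dimension.  Models are
evaluated by stratified k-fold cross-validation repeated over several
subject-order shuffles ("seeds"); the model selected most often across folds
(cross-validation consistency, CVC) is the best model per order, and its
held-out balanced accuracy yields the prediction error.  Significance comes
from a Monte-Carlo permutation test that re-runs the search on
label-permuted data.

Conventions (configurable): accuracy is balanced accuracy (mean of
sensitivity and specificity); ties at the threshold are labeled high risk;
cells empty in training default to low risk so every subject is classifiable.
Subjects missing a genotype at any locus of a combination are excluded from
that combination only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .study_data import CohortTable

HIGH, LOW, UNCLASSIFIED = 1, 0, -1


class FoldError(ValueError):
    """A cross-validation fold lacks cases or controls; use fewer folds."""


@dataclass
class MdrConfig:
    k_folds: int = 10
    n_seeds: int = 10
    orders: tuple[int, ...] = (2, 3, 4)
    threshold_mode: str = "ratio"      # or "fixed"
    threshold_value: float | None = None
    tie_rule: str = "high_risk"        # or "low_risk"
    empty_cell_rule: str = "low_risk"  # or "unclassified"
    search_mode: str = "exhaustive"    # or "forced"
    pool: tuple[int, ...] | None = None
    n_perm: int = 1000
    seed: int = 0
    accuracy: str = "balanced"         # or "raw"

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if isinstance(self.orders, int):
            self.orders = (self.orders,)
        if min(self.orders) < 1:
            raise ValueError("orders must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold mode needs threshold_value")


@dataclass
class MdrModel:
    loci: tuple[int, ...]
    locus_names: tuple[str, ...]
    cell_labels: np.ndarray            # (3^k,) labels fit on the full data
    train_acc: float
    test_acc: float
    cvc_pct: float
    perm_p: float | None = None
    n_evaluated: int = 0               # combinations enumerated in the search

    @property
    def prediction_error_pct(self) -> float:
        return 100.0 * (1.0 - self.test_acc)

    def cells_dict(self) -> dict[str, str]:
        k = len(self.loci)
        out = {}
        names = {HIGH: "high", LOW: "low", UNCLASSIFIED: "unclassified"}
        for idx, lab in enumerate(self.cell_labels):
            digits = []
            v = idx
            for _ in range(k):
                digits.append(v % 3)
                v //= 3
            key = ",".join(str(d) for d in digits)
            out[key] = names[int(lab)]
        return out


# ---------------------------------------------------------------------------
# cell labeling
# ---------------------------------------------------------------------------

def _cell_index(genotypes: np.ndarray, loci: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-radix cell index over the selected loci.

    Returns (valid_mask, cell_idx over valid subjects).
    """
    sub = genotypes[:, list(loci)]
    valid = (sub >= 0).all(axis=1)
    idx = np.zeros(valid.sum(), dtype=np.int64)
    for pos, _ in enumerate(loci):
        idx += sub[valid, pos].astype(np.int64) * (3 ** pos)
    return valid, idx


def _fit_cells(cell_idx: np.ndarray, pheno: np.ndarray, ncells: int,
               threshold: float, tie_rule: str, empty_cell_rule: str) -> np.ndarray:
    """Label every cell high/low(/unclassified) from training counts."""
    case_counts = np.bincount(cell_idx[pheno], minlength=ncells)
    ctrl_counts = np.bincount(cell_idx[~pheno], minlength=ncells)
    labels = np.full(ncells, LOW, dtype=np.int8)
    ratio_hits = (case_counts >= threshold * ctrl_counts) if tie_rule == "high_risk" \
        else (case_counts > threshold * ctrl_counts)
    labels[ratio_hits] = HIGH
    labels[(ctrl_counts == 0) & (case_counts > 0)] = HIGH
    empty = (case_counts == 0) & (ctrl_counts == 0)
    labels[empty] = LOW if empty_cell_rule == "low_risk" else UNCLASSIFIED
    return labels


def cell_partition(cohort: CohortTable, loci: tuple[int, ...],
                   threshold: float | None = None,
                   tie_rule: str = "high_risk",
                   empty_cell_rule: str = "low_risk") -> np.ndarray:
    """High/low risk label per multilocus genotype cell, fit on ``cohort``.

    ``threshold`` defaults to the case:control ratio of the data.  Returns a
    flat array over the 3^k cells in mixed-radix order (first locus varies
    fastest).
    """
    loci = tuple(loci)
    if len(set(loci)) != len(loci):
        raise ValueError("loci in a combination must be distinct")
    valid, idx = _cell_index(cohort.genotypes, loci)
    pheno = cohort.phenotype[valid]
    if pheno.sum() == 0 or (~pheno).sum() == 0:
        raise ValueError("training data needs at least one case and one control")
    if threshold is None:
        threshold = pheno.sum() / (~pheno).sum()
    return _fit_cells(idx, pheno, 3 ** len(loci), threshold, tie_rule,
                      empty_cell_rule)


def _score(labels: np.ndarray, cell_idx: np.ndarray, pheno: np.ndarray,
           accuracy: str) -> float:
    """(Balanced) accuracy of 'high-risk => case' on one subject set."""
    pred = labels[cell_idx]
    include = pred != UNCLASSIFIED
    pred_high = pred == HIGH
    cases = pheno & include
    ctrls = (~pheno) & include
    if accuracy == "raw":
        denom = include.sum()
        if denom == 0:
            return 0.5
        return float((pred_high[cases].sum() + (~pred_high)[ctrls].sum()) / denom)
    sens = pred_high[cases].mean() if cases.any() else 0.5
    spec = (~pred_high)[ctrls].mean() if ctrls.any() else 0.5
    return float((sens + spec) / 2.0)


# ---------------------------------------------------------------------------
# cross-validated evaluation and search
# ---------------------------------------------------------------------------

def _fold_plan(pheno: np.ndarray, config: MdrConfig) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified folds for each shuffle seed (list over seeds of (train, test) masks)."""
    n = len(pheno)
    plans = []
    for s in range(config.n_seeds):
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                              random_state=(config.seed + 9973 * s) % (2 ** 31))
        folds = []
        try:
            splits = list(skf.split(np.zeros(n), pheno))
        except ValueError as exc:
            raise FoldError(
                f"cannot build {config.k_folds} stratified folds: {exc}; "
                "reduce k_folds or enlarge the cohort") from exc
        for train_idx, test_idx in splits:
            train = np.zeros(n, dtype=bool)
            test = np.zeros(n, dtype=bool)
            train[train_idx] = True
            test[test_idx] = True
            if pheno[train].sum() == 0 or (~pheno[train]).sum() == 0 \
                    or pheno[test].sum() == 0 or (~pheno[test]).sum() == 0:
                raise FoldError(
                    "a cross-validation fold has no cases or no controls; "
                    "reduce k_folds or enlarge the cohort")
            folds.append((train, test))
        plans.append(folds)
    return plans


def _threshold_for(pheno_train: np.ndarray, config: MdrConfig) -> float:
    if config.threshold_mode == "fixed":
        return float(config.threshold_value)
    n_ctrl = (~pheno_train).sum()
    return pheno_train.sum() / n_ctrl if n_ctrl else np.inf


def _eval_combo_on_folds(cohort: CohortTable, loci: tuple[int, ...],
                         plans, config: MdrConfig) -> tuple[np.ndarray, np.ndarray]:
    """Training and test accuracy arrays of shape (n_seeds, k_folds)."""
    valid, idx_valid = _cell_index(cohort.genotypes, loci)
    idx_full = np.full(cohort.n_subjects, -1, dtype=np.int64)
    idx_full[valid] = idx_valid
    pheno = cohort.phenotype
    ncells = 3 ** len(loci)
    S, K = len(plans), config.k_folds
    train_acc = np.empty((S, K))
    test_acc = np.empty((S, K))
    for s, folds in enumerate(plans):
        for k, (train, test) in enumerate(folds):
            tr = train & valid
            te = test & valid
            labels = _fit_cells(idx_full[tr], pheno[tr], ncells,
                                _threshold_for(pheno[tr], config),
                                config.tie_rule, config.empty_cell_rule)
            train_acc[s, k] = _score(labels, idx_full[tr], pheno[tr], config.accuracy)
            test_acc[s, k] = _score(labels, idx_full[te], pheno[te], config.accuracy)
    return train_acc, test_acc


def evaluate_model(cohort: CohortTable, loci: tuple[int, ...],
                   config: MdrConfig | None = None) -> MdrModel:
    """Cross-validated evaluation of one locus combination.

    ``cvc_pct`` is 100 by construction here (a single candidate is always
    "selected"); use :func:`search` for competitive CVC values.
    """
    config = config or MdrConfig()
    loci = tuple(loci)
    plans = _fold_plan(cohort.phenotype, config)
    train_acc, test_acc = _eval_combo_on_folds(cohort, loci, plans, config)
    return MdrModel(
        loci=loci,
        locus_names=tuple(cohort.loci[i].name for i in loci),
        cell_labels=cell_partition(
            cohort, loci,
            threshold=None if config.threshold_mode == "ratio" else config.threshold_value,
            tie_rule=config.tie_rule, empty_cell_rule=config.empty_cell_rule),
        train_acc=float(train_acc.mean()),
        test_acc=float(test_acc.mean()),
        cvc_pct=100.0,
        n_evaluated=1,
    )


def _candidate_combos(cohort: CohortTable, order: int,
                      config: MdrConfig) -> list[tuple[int, ...]]:
    pool = tuple(config.pool) if config.pool is not None else tuple(range(cohort.n_loci))
    if config.search_mode == "forced" and config.pool is None:
        raise ValueError("forced search needs a locus pool")
    if order > len(pool):
        raise ValueError(f"order {order} exceeds pool size {len(pool)}")
    return list(itertools.combinations(sorted(pool), order))


def search(cohort: CohortTable, config: MdrConfig | None = None,
           _plans=None) -> dict[int, MdrModel]:
    """Best model per order (max mean CVC; ties by test accuracy, then locus
    order), plus the overall best under key ``"best"``."""
    config = config or MdrConfig()
    plans = _plans if _plans is not None else _fold_plan(cohort.phenotype, config)
    S, K = len(plans), config.k_folds
    results: dict[int, MdrModel] = {}
    for order in config.orders:
        combos = _candidate_combos(cohort, order, config)
        n_combos = len(combos)
        train = np.empty((n_combos, S, K))
        test = np.empty((n_combos, S, K))
        for ci, combo in enumerate(combos):
            train[ci], test[ci] = _eval_combo_on_folds(cohort, combo, plans, config)
        # per seed and fold, the combination with the best *training* accuracy
        # is selected (first index wins ties -> lexicographic combo order)
        selected = train.argmax(axis=0)                    # (S, K)
        counts = np.zeros((n_combos, S), dtype=int)
        for s in range(S):
            for k in range(K):
                counts[selected[s, k], s] += 1
        cvc_pct = 100.0 * counts.mean(axis=1) / K          # mean over seeds
        mean_test = test.mean(axis=(1, 2))
        best_ci = max(range(n_combos),
                      key=lambda ci: (cvc_pct[ci], mean_test[ci],
                                      tuple(-x for x in combos[ci])))
        combo = combos[best_ci]
        results[order] = MdrModel(
            loci=combo,
            locus_names=tuple(cohort.loci[i].name for i in combo),
            cell_labels=cell_partition(
                cohort, combo,
                threshold=None if config.threshold_mode == "ratio" else config.threshold_value,
                tie_rule=config.tie_rule, empty_cell_rule=config.empty_cell_rule),
            train_acc=float(train[best_ci].mean()),
            test_acc=float(mean_test[best_ci]),
            cvc_pct=float(cvc_pct[best_ci]),
            n_evaluated=n_combos,
        )
    best = max(results.values(),
               key=lambda m: (m.cvc_pct, m.test_acc, -len(m.loci)))
    results["best"] = best
    return results


def permutation_test(cohort: CohortTable, model: MdrModel,
                     config: MdrConfig | None = None) -> float:
    """Monte-Carlo significance of an MDR model.

    Phenotype labels are permuted ``n_perm`` times; the search is re-run at
    the model's order and the best model's test accuracy forms the null.
    ``p = (r + 1) / (n_perm + 1)`` with r = replicates at or above the
    observed test accuracy.
    """
    config = config or MdrConfig()
    order = len(model.loci)
    perm_config = replace(config, orders=(order,))
    rng = np.random.default_rng(config.seed + 1)
    r = 0
    for _rep in range(config.n_perm):
        permuted = _permute_labels(cohort, rng)
        best = search(permuted, perm_config)["best"]
        if best.test_acc >= model.test_acc - 1e-12:
            r += 1
    return (r + 1) / (config.n_perm + 1)


def _permute_labels(cohort: CohortTable, rng: np.random.Generator) -> CohortTable:
    perm = rng.permutation(cohort.n_subjects)
    pheno = cohort.phenotype[perm]
    subtype = np.where(pheno, "unknown", "control").astype(object)
    return CohortTable(loci=cohort.loci, genotypes=cohort.genotypes,
                       phenotype=pheno, sex=cohort.sex, subtype=subtype,
                       ids=cohort.ids)


def models_frame(models: dict[int, MdrModel]) -> pd.DataFrame:
    rows = []
    for order, m in models.items():
        if order == "best":
            continue
        rows.append({
            "order": order,
            "loci": " x ".join(m.locus_names),
            "cvc_pct": m.cvc_pct,
            "test_acc": m.test_acc,
            "prediction_error_pct": m.prediction_error_pct,
            "perm_p": m.perm_p,
        })
    return pd.DataFrame(rows)
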
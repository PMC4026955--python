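"""Information-theoretic interaction analysis.

Mutual information between genotypes and phenotype (plug-in estimate,
base-2 logs) and the pairwise interaction gain

    IG(A; B; Y) = I(A,B; Y) - I(A; Y) - I(B; Y)

quantify synergy (IG > 0: the pair carries information about disease beyond
its marginals — the entropy signature of epistasis) versus redundancy
(IG < 0: the loci share information about disease).  Pairs are classified on
|IG| as a fraction of the phenotype entropy H(Y) and summarized by an
average-linkage dendrogram on the dissimilarity ``max IG - IG``, so the most
synergistic pairs merge first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .study_data import CohortTable

CLASS_LABELS = ("strong redundancy", "redundancy", "neutral",
                "synergy", "strong synergy")


def _entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of a count vector."""
    counts = np.asarray(counts, dtype=float).ravel()
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_info(cohort: CohortTable, loci: int | tuple[int, ...]) -> float:
    """I(X; Y) in bits where X is the genotype (or 9-cell joint genotype for a
    pair of loci) and Y the case/control phenotype.

    Subjects missing a genotype at any involved locus are excluded.
    """
    if isinstance(loci, (int, np.integer)):
        loci = (int(loci),)
    loci = tuple(loci)
    sub = cohort.genotypes[:, list(loci)]
    valid = (sub >= 0).all(axis=1)
    x = np.zeros(valid.sum(), dtype=np.int64)
    for pos in range(len(loci)):
        x += sub[valid, pos].astype(np.int64) * (3 ** pos)
    y = cohort.phenotype[valid].astype(np.int64)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("phenotype must have both classes among complete subjects")
    nx = 3 ** len(loci)
    joint = np.bincount(x * 2 + y, minlength=nx * 2).reshape(nx, 2)
    return _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - _entropy(joint)


def phenotype_entropy(cohort: CohortTable) -> float:
    return _entropy(np.array([cohort.n_cases, cohort.n_controls]))


def interaction_gain(cohort: CohortTable, locus_a: int, locus_b: int) -> float:
    """IG(A; B; Y) in bits: positive = synergy, negative = redundancy."""
    return (mutual_info(cohort, (locus_a, locus_b))
            - mutual_info(cohort, locus_a) - mutual_info(cohort, locus_b))


def classify_ig(ig: float, h_y: float, strong: float = 0.02,
                weak: float = 0.005) -> str:
    """Label an interaction gain by its magnitude relative to H(Y)."""
    frac = ig / h_y
    if frac >= strong:
        return "strong synergy"
    if frac >= weak:
        return "synergy"
    if frac <= -strong:
        return "strong redundancy"
    if frac <= -weak:
        return "redundancy"
    return "neutral"


@dataclass
class InteractionResult:
    locus_names: list[str]
    loci: list[int]
    h_y: float
    main_effect: np.ndarray            # I(X_i; Y) per locus, bits
    ig_matrix: np.ndarray              # symmetric, diagonal = nan
    classes: np.ndarray = field(repr=False, default=None)  # object matrix of labels

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.loci)):
            for j in range(i + 1, len(self.loci)):
                ig = self.ig_matrix[i, j]
                rows.append({
                    "locus_a": self.locus_names[i],
                    "locus_b": self.locus_names[j],
                    "ig_bits": ig,
                    "ig_pct_of_hy": 100.0 * ig / self.h_y,
                    "class": self.classes[i, j],
                })
        return pd.DataFrame(rows)


def interaction_analysis(cohort: CohortTable, loci: list[int] | None = None,
                         strong: float = 0.02, weak: float = 0.005) -> InteractionResult:
    """Main-effect information and all pairwise interaction gains."""
    loci = list(loci) if loci is not None else list(range(cohort.n_loci))
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    h_y = phenotype_entropy(cohort)
    main = np.array([mutual_info(cohort, i) for i in loci])
    m = len(loci)
    ig = np.full((m, m), np.nan)
    classes = np.full((m, m), "", dtype=object)
    for i in range(m):
        for j in range(i + 1, m):
            val = interaction_gain(cohort, loci[i], loci[j])
            ig[i, j] = ig[j, i] = val
            classes[i, j] = classes[j, i] = classify_ig(val, h_y, strong, weak)
    return InteractionResult(locus_names=[cohort.loci[i].name for i in loci],
                             loci=loci, h_y=h_y, main_effect=main,
                             ig_matrix=ig, classes=classes)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]
    newick: str


def build_dendrogram(result: InteractionResult) -> Dendrogram:
    """Average-linkage tree on D(A,B) = max IG - IG(A,B).

    Larger synergy means smaller dissimilarity, so the most synergistic pairs
    merge first; merge heights are nondecreasing (average linkage produces no
    inversions).  Ties resolve deterministically from the input locus order.
    """
    m = len(result.loci)
    if m < 2:
        raise ValueError("dendrogram needs at least two loci")
    ig = result.ig_matrix.copy()
    iu = np.triu_indices(m, k=1)
    dist = ig[iu].max() - ig
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, result.locus_names)
    buf = StringIO()
    tree.write(buf, format="newick")
    return Dendrogram(linkage_matrix=Z, labels=list(result.locus_names),
                      newick=buf.getvalue().strip())


def plot_dendrogram(dend: Dendrogram, path: str) -> None:
    """Basic matplotlib render of the merge tree (no styling parity intended)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as _scipy_dend

    fig, ax = plt.subplots(figsize=(8, 4))
    _scipy_dend(dend.linkage_matrix, labels=dend.labels, ax=ax,
                leaf_rotation=90)
    ax.set_ylabel("average-linkage dissimilarity (max IG - IG, bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
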
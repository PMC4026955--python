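"""Synthetic case-control cohorts with known genetic ground truth.

A :class:`PenetranceSpec` fixes per-locus minor-allele frequencies (genotypes
drawn from Hardy-Weinberg proportions, optionally perturbed toward
disequilibrium), up to three causal loci, and a multilocus penetrance table
mapping their joint genotype to disease probability.  Cohorts are sampled
retrospectively: subjects are drawn from the prospective model and rejected
until the case and control quotas (optionally per sex and case subtype) are
filled, so odds ratios — not risk ratios — are the recoverable effect
measure, as in a case-control study.

Model families
--------------
``null``            constant penetrance (no locus affects disease).
``main_effect``     one locus, multiplicative per-allele genotype relative risk.
``multiplicative``  up to three loci, risk multiplies across minor alleles.
``threshold``       two loci, elevated risk iff both carry a minor allele.
``xor``             two loci, elevated risk iff *exactly one* is heterozygous —
                    at MAF 0.5 this is purely epistatic: both single-locus
                    marginal penetrances equal the mean penetrance exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .study_data import CohortTable, LocusDef

# (group sizes of the emulated study: 215 cases / 214 controls, with
#  allergic 64 M / 92 F, nonallergic 29 M / 27 F, controls 105 M / 109 F;
#  3 cases of unknown subtype, 2 M / 1 F, complete the case group)
STUDY_STRATA: dict[tuple[str, str], int] = {
    ("allergic", "M"): 64, ("allergic", "F"): 92,
    ("nonallergic", "M"): 29, ("nonallergic", "F"): 27,
    ("unknown", "M"): 2, ("unknown", "F"): 1,
    ("control", "M"): 105, ("control", "F"): 109,
}


def default_panel() -> tuple[list[str], np.ndarray]:
    """Names and minor-allele frequencies of the bundled 46-locus panel.

    The frequency spectrum replicates the control-group minor-allele
    frequencies of the emulated candidate-gene study (21 printed values,
    cycled to fill 46 slots).
    """
    with resources.files("epistat.data").joinpath("panel_mafs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return list(df["locus"]), df["maf"].to_numpy(dtype=float)


@dataclass
class PenetranceSpec:
    """Generative disease model: MAFs plus a multilocus penetrance table."""

    mafs: np.ndarray
    model_loci: tuple[int, ...] = ()
    penetrance: np.ndarray | None = None   # shape (3,)*k over model_loci, or scalar table for k=0
    baseline: float = 0.1
    sex_modifier: dict[str, float] | None = None
    hwd_delta: np.ndarray | None = None
    locus_names: list[str] | None = None

    def __post_init__(self):
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any((self.mafs <= 0) | (self.mafs > 0.5)):
            raise ValueError("MAFs must be in (0, 0.5]")
        self.model_loci = tuple(self.model_loci)
        if len(self.model_loci) > 3:
            raise ValueError("at most three causal loci supported")
        k = len(self.model_loci)
        if self.penetrance is None:
            self.penetrance = np.full((3,) * k if k else (), self.baseline)
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.penetrance.shape != (3,) * k:
            raise ValueError(f"penetrance table must have shape {(3,) * k}")
        if np.any((self.penetrance < 0) | (self.penetrance > 1)):
            raise ValueError("penetrances must lie in [0, 1]")
        if self.locus_names is None:
            self.locus_names = [f"L{i + 1:02d}" for i in range(len(self.mafs))]

    def genotype_probs(self) -> np.ndarray:
        """(L, 3) genotype probabilities: HWE, optionally HWD-perturbed."""
        q = self.mafs
        probs = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)
        if self.hwd_delta is not None:
            delta = np.asarray(self.hwd_delta, dtype=float)
            p1 = np.clip(probs[:, 1] + delta, 0.0, 1.0)
            rest = probs[:, [0, 2]]
            scale = np.where(rest.sum(axis=1) > 0,
                             (1 - p1) / rest.sum(axis=1), 0.0)
            probs = np.column_stack([rest[:, 0] * scale, p1, rest[:, 1] * scale])
        return probs

    def expected_prevalence(self) -> float:
        """Population disease probability implied by the model."""
        k = len(self.model_loci)
        if k == 0:
            return float(self.penetrance)
        probs = self.genotype_probs()[list(self.model_loci)]
        prev = 0.0
        it = np.ndindex(*(3,) * k)
        for cell in it:
            w = 1.0
            for pos, g in enumerate(cell):
                w *= probs[pos, g]
            prev += w * self.penetrance[cell]
        return float(prev)

    def to_json(self) -> str:
        return json.dumps({
            "mafs": self.mafs.tolist(),
            "model_loci": list(self.model_loci),
            "penetrance": self.penetrance.tolist(),
            "baseline": self.baseline,
            "sex_modifier": self.sex_modifier,
            "hwd_delta": None if self.hwd_delta is None
            else np.asarray(self.hwd_delta).tolist(),
            "locus_names": self.locus_names,
        }, indent=2)


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    spec: PenetranceSpec = field(repr=False)
    seed: int = 0
    realized_prevalence: float = float("nan")


def make_epistasis_model(name: str, mafs, model_loci: tuple[int, ...] | None = None,
                         baseline: float = 0.1, grr: float = 2.0,
                         high: float = 0.9, low: float = 0.1,
                         **kwargs) -> PenetranceSpec:
    """Construct a named penetrance model over the given MAF panel."""
    mafs = np.asarray(mafs, dtype=float)
    if name == "null":
        return PenetranceSpec(mafs=mafs, model_loci=(), baseline=baseline, **kwargs)
    if model_loci is None:
        need = {"main_effect": 1, "xor": 2, "threshold": 2, "multiplicative": 2}
        if name not in need:
            raise ValueError(f"unknown model family {name!r}")
        model_loci = tuple(range(need[name]))
    model_loci = tuple(model_loci)
    k = len(model_loci)
    if name == "main_effect":
        if k != 1:
            raise ValueError("main_effect is a single-locus model")
        pen = np.clip(baseline * grr ** np.arange(3), 0, 1)
    elif name == "multiplicative":
        grid = np.indices((3,) * k).sum(axis=0)   # total minor-allele count
        pen = np.clip(baseline * grr ** grid, 0, 1)
    elif name == "xor":
        if k != 2:
            raise ValueError("xor is a two-locus model")
        g1, g2 = np.indices((3, 3))
        pen = np.where((g1 == 1) ^ (g2 == 1), high, low)
    elif name == "threshold":
        if k != 2:
            raise ValueError("threshold is a two-locus model")
        g1, g2 = np.indices((3, 3))
        pen = np.where((g1 >= 1) & (g2 >= 1), high, low)
    else:
        raise ValueError(f"unknown model family {name!r}")
    return PenetranceSpec(mafs=mafs, model_loci=model_loci, penetrance=pen,
                          baseline=baseline, **kwargs)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _disease_prob(spec: PenetranceSpec, genotypes: np.ndarray,
                  sexes: np.ndarray) -> np.ndarray:
    k = len(spec.model_loci)
    if k == 0:
        prob = np.full(len(genotypes), float(spec.penetrance))
    else:
        cells = tuple(genotypes[:, i] for i in spec.model_loci)
        prob = spec.penetrance[cells]
    if spec.sex_modifier:
        mult = np.array([spec.sex_modifier.get(s, 1.0) for s in sexes])
        prob = np.clip(prob * mult, 0.0, 1.0)
    return prob


def simulate(spec: PenetranceSpec, n_cases: int, n_controls: int,
             sex_fractions: dict[str, float] | None = None,
             seed: int = 0, case_subtype: str = "unknown",
             max_attempts: int = 400) -> SimulatedCohort:
    """Rejection-sample a cohort to the requested case/control quotas.

    ``sex_fractions`` gives the probability of each sex among sampled
    subjects (default all male 0.5 / female 0.5); quotas are on phenotype
    only.  For the full per-stratum study structure use
    :func:`simulate_study`.
    """
    quotas = {}
    sex_fractions = sex_fractions or {"M": 0.5, "F": 0.5}
    for sx, fr in sex_fractions.items():
        quotas[(case_subtype, sx)] = int(round(n_cases * fr))
        quotas[("control", sx)] = int(round(n_controls * fr))
    # rounding drift goes to the last sex listed
    drift_case = n_cases - sum(v for (st, _), v in quotas.items() if st != "control")
    drift_ctrl = n_controls - sum(v for (st, _), v in quotas.items() if st == "control")
    last = list(sex_fractions)[-1]
    quotas[(case_subtype, last)] += drift_case
    quotas[("control", last)] += drift_ctrl
    return _simulate_quotas(spec, quotas, seed, max_attempts)


def simulate_study(spec: PenetranceSpec, seed: int = 0,
                   strata: dict[tuple[str, str], int] | None = None,
                   max_attempts: int = 400) -> SimulatedCohort:
    """Sample a cohort with the emulated study's per-sex, per-subtype sizes."""
    return _simulate_quotas(spec, dict(strata or STUDY_STRATA), seed, max_attempts)


def _simulate_quotas(spec: PenetranceSpec, quotas: dict[tuple[str, str], int],
                     seed: int, max_attempts: int) -> SimulatedCohort:
    rng = np.random.default_rng(seed)
    probs = spec.genotype_probs()
    L = len(spec.mafs)
    sexes = sorted({sx for _, sx in quotas})
    need = {key: n for key, n in quotas.items() if n > 0}
    total_needed = sum(need.values())
    case_subtypes = sorted({st for st, _ in need if st != "control"})

    collected: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in need}
    n_drawn = 0
    n_diseased = 0
    batch = max(2048, 4 * total_needed)
    cum = probs.cumsum(axis=1)
    for _attempt in range(max_attempts):
        if all(len(v) >= need[k] for k, v in collected.items()):
            break
        u = rng.random((batch, L))
        geno = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
        sex_draw = rng.choice(sexes, size=batch)
        disease = rng.random(batch) < _disease_prob(spec, geno, sex_draw)
        n_drawn += batch
        n_diseased += int(disease.sum())
        for i in range(batch):
            sx = sex_draw[i]
            if disease[i]:
                # fill case subtypes in declared order
                for st in case_subtypes:
                    key = (st, sx)
                    if key in need and len(collected[key]) < need[key]:
                        collected[key].append(geno[i])
                        break
            else:
                key = ("control", sx)
                if key in need and len(collected[key]) < need[key]:
                    collected[key].append(geno[i])
    if not all(len(v) >= need[k] for k, v in collected.items()):
        short = {k: need[k] - len(v) for k, v in collected.items() if len(v) < need[k]}
        raise RuntimeError(f"could not fill quotas after {max_attempts} batches: "
                           f"missing {short} (is the penetrance achievable?)")

    rows, pheno, sex_col, subtype_col = [], [], [], []
    for (st, sx), genos in sorted(collected.items()):
        for g in genos[: need[(st, sx)]]:
            rows.append(g)
            pheno.append(st != "control")
            sex_col.append(sx)
            subtype_col.append(st)
    geno_mat = np.vstack(rows)
    loci = [LocusDef(name=nm, alleles=("A", "B"))
            for nm in spec.locus_names[:L]]
    cohort = CohortTable(
        loci=loci, genotypes=geno_mat,
        phenotype=np.array(pheno),
        sex=np.array(sex_col, dtype="U1"),
        subtype=np.array(subtype_col, dtype=object),
    )
    return SimulatedCohort(cohort=cohort, spec=spec, seed=seed,
                           realized_prevalence=n_diseased / n_drawn)


def write_truth(sim: SimulatedCohort, path: str | Path) -> None:
    """Write the ground-truth sidecar (spec + seed + realized prevalence)."""
    payload = json.loads(sim.spec.to_json())
    payload["seed"] = sim.seed
    payload["realized_prevalence"] = sim.realized_prevalence
    Path(path).write_text(json.dumps(payload, indent=2))
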
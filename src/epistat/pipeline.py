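"""Orchestration of the full per-stratum analysis.

Runs, per configured (sex, subtype) stratum: single-locus association,
the set-association scan, the MDR search, the entropy/dendrogram analysis,
and the post hoc two-locus combination scan (its locus pool built from the
upstream hits), writing delimited reports plus a JSON manifest.  Reports are
deterministic for a fixed config and seed; wall-clock timings live in a
separate ``timing.json`` so the analytic outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import Table2x2, bonferroni, genotype_chi2_2x3, hwe_chi2, odds_ratio_ci
from .combo import combos_frame, scan_pairs
from .entropy import build_dendrogram, interaction_analysis
from .mdr import MdrConfig, models_frame, permutation_test, search
from .saa import SaaConfig, saa_scan
from .study_data import CohortTable, genotype_counts, read_cohort, stratify

log = logging.getLogger("epistat")


@dataclass
class RunConfig:
    input: str
    format: str = "tabular"
    strata: list[tuple[str | None, str | None]] = field(
        default_factory=lambda: [(None, None)])
    stages: tuple[str, ...] = ("single_locus", "saa", "mdr", "entropy", "combo")
    saa: SaaConfig = field(default_factory=SaaConfig)
    mdr: MdrConfig = field(default_factory=MdrConfig)
    combo_pool_rule: str = "union"     # saa_hits | mdr_hits | union | explicit
    combo_pool: list[str] = field(default_factory=list)
    mdr_permutations: bool = False
    alpha: float = 0.05
    out_dir: str = "epistat_out"
    seed: int = 0

    def __post_init__(self):
        if not self.stages:
            raise ValueError("at least one stage must be enabled")
        self.strata = [tuple(s) for s in self.strata]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "saa" in raw:
            raw["saa"] = SaaConfig(**raw["saa"])
        if "mdr" in raw:
            mdr = dict(raw["mdr"])
            if "orders" in mdr:
                mdr["orders"] = tuple(mdr["orders"])
            raw["mdr"] = MdrConfig(**mdr)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "strata" in raw:
            raw["strata"] = [tuple(x if x != "all" else None for x in pair)
                             for pair in raw["strata"]]
        return cls(**raw)


def _stratum_tag(sex, subtype) -> str:
    return f"{subtype or 'all'}_{sex or 'all'}"


def _single_locus_frame(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    m = cohort.n_loci
    for j, locus in enumerate(cohort.loci):
        cases = genotype_counts(cohort, j, "cases")
        ctrls = genotype_counts(cohort, j, "controls")
        row = {"locus": locus.name,
               "case_n0": cases.n0, "case_n1": cases.n1, "case_n2": cases.n2,
               "ctrl_n0": ctrls.n0, "ctrl_n1": ctrls.n1, "ctrl_n2": ctrls.n2}
        try:
            row["control_hwe_chi2"] = hwe_chi2(ctrls).chi2
        except ValueError:
            row["control_hwe_chi2"] = np.nan
        try:
            res = genotype_chi2_2x3(cases, ctrls)
            row.update(assoc_chi2=res.chi2, assoc_df=res.df, assoc_p=res.p,
                       assoc_p_adj=bonferroni(res.p, m))
        except ValueError:
            row.update(assoc_chi2=np.nan, assoc_df=0, assoc_p=np.nan,
                       assoc_p_adj=np.nan)
        # minor-allele carrier (codes 1+2) vs major homozygote odds ratio
        try:
            t = Table2x2(cases.n1 + cases.n2, cases.n0,
                         ctrls.n1 + ctrls.n2, ctrls.n0)
            orr = odds_ratio_ci(t)
            row.update(carrier_or=orr.or_value, carrier_ci_low=orr.ci_low,
                       carrier_ci_high=orr.ci_high)
        except ValueError:
            row.update(carrier_or=np.nan, carrier_ci_low=np.nan,
                       carrier_ci_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages per stratum; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    cohort = read_cohort(config.input, format=config.format)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "input": str(config.input),
        "n_subjects": cohort.n_subjects,
        "n_loci": cohort.n_loci,
        "settings": {
            "saa": asdict(config.saa),
            "mdr": asdict(config.mdr),
            "combo_pool_rule": config.combo_pool_rule,
            "alpha": config.alpha,
            "stages": list(config.stages),
        },
        "strata": {},
    }
    timing: dict = {}
    for sex, subtype in config.strata:
        tag = _stratum_tag(sex, subtype)
        try:
            sub = stratify(cohort, sex=sex, subtype=subtype)
        except ValueError as exc:
            log.warning("skipping stratum %s: %s", tag, exc)
            manifest["strata"][tag] = {"skipped": str(exc)}
            continue
        sdir = out / tag
        sdir.mkdir(exist_ok=True)
        entry: dict = {"n_cases": sub.n_cases, "n_controls": sub.n_controls}
        saa_hits: list[int] = []
        mdr_hits: list[int] = []
        t_stage = {}
        try:
            if "single_locus" in config.stages:
                t0 = time.perf_counter()
                _write_tsv(_single_locus_frame(sub), sdir / "single_locus.tsv")
                t_stage["single_locus"] = time.perf_counter() - t0
            if "saa" in config.stages:
                t0 = time.perf_counter()
                saa_cfg = replace(config.saa, seed=config.seed)
                res = saa_scan(sub, saa_cfg)
                _write_tsv(res.markers_frame(), sdir / "saa_markers.tsv")
                _write_tsv(res.curve_frame(), sdir / "saa_curve.tsv")
                (sdir / "saa_summary.json").write_text(
                    json.dumps(res.summary(), indent=2))
                saa_hits = [int(i) for i in res.order[: res.n_star]]
                entry["saa"] = res.summary()
                t_stage["saa"] = time.perf_counter() - t0
            if "mdr" in config.stages:
                t0 = time.perf_counter()
                mdr_cfg = replace(config.mdr, seed=config.seed)
                models = search(sub, mdr_cfg)
                if config.mdr_permutations:
                    best = models["best"]
                    best.perm_p = permutation_test(sub, best, mdr_cfg)
                _write_tsv(models_frame(models), sdir / "mdr_models.tsv")
                (sdir / "mdr_best_cells.json").write_text(
                    json.dumps(models["best"].cells_dict(), indent=2))
                mdr_hits = sorted({i for o, m in models.items()
                                   if o != "best" for i in m.loci})
                entry["mdr_best"] = {
                    "loci": list(models["best"].locus_names),
                    "cvc_pct": models["best"].cvc_pct,
                    "prediction_error_pct": models["best"].prediction_error_pct,
                    "perm_p": models["best"].perm_p,
                }
                t_stage["mdr"] = time.perf_counter() - t0
            if "entropy" in config.stages:
                t0 = time.perf_counter()
                pool = sorted(set(saa_hits) | set(mdr_hits)) or list(range(sub.n_loci))
                ia = interaction_analysis(sub, loci=pool)
                _write_tsv(ia.edges_frame(), sdir / "ig_edges.tsv")
                (sdir / "dendrogram.nwk").write_text(build_dendrogram(ia).newick + "\n")
                t_stage["entropy"] = time.perf_counter() - t0
            if "combo" in config.stages:
                t0 = time.perf_counter()
                pool = _combo_pool(config, cohort, saa_hits, mdr_hits, sub)
                if len(pool) >= 2:
                    combos = scan_pairs(sub, pool)
                    _write_tsv(combos_frame(combos), sdir / "combos.tsv")
                    entry["combo"] = {
                        "m_tests": combos[0].m_tests if combos else 0,
                        "significant": [r.label for r in combos
                                        if r.p_adj <= config.alpha],
                    }
                else:
                    log.warning("stratum %s: combo pool smaller than 2 loci, "
                                "skipping combo scan", tag)
                t_stage["combo"] = time.perf_counter() - t0
        except Exception as exc:
            raise RuntimeError(f"stage failure in stratum {tag}: {exc}") from exc
        manifest["strata"][tag] = entry
        timing[tag] = t_stage
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "timing.json").write_text(json.dumps(timing, indent=2))
    return manifest


def _combo_pool(config: RunConfig, cohort: CohortTable,
                saa_hits: list[int], mdr_hits: list[int],
                sub: CohortTable) -> list[int]:
    rule = config.combo_pool_rule
    if rule == "explicit":
        return [cohort.locus_index(n) for n in config.combo_pool]
    if rule == "saa_hits":
        return saa_hits
    if rule == "mdr_hits":
        return mdr_hits
    if rule == "union":
        pool = sorted(set(saa_hits) | set(mdr_hits))
        return pool if pool else list(range(min(sub.n_loci, 8)))
    raise ValueError(f"unknown combo_pool_rule {rule!r}")
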
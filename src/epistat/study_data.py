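"""Domain types and I/O for case-control SNP genotype panels.

The universal container is :class:`CohortTable`: one row per subject with a
case/control flag, sex, an asthma-subtype label, and an integer genotype code
per biallelic locus.  Codes count copies of the *minor* allele, where "minor"
is defined by allele frequency among controls:

====  ==========================================
code  meaning
====  ==========================================
 0    homozygote for the control-major allele
 1    heterozygote
 2    homozygote for the control-minor allele
-1    missing / failed genotype
====  ==========================================

Deletion-type polymorphisms (expressor vs. null, where assays cannot
distinguish heterozygotes) are represented as binary loci using codes 0 and 2
with code 1 simply never occurring; all downstream 2x3 machinery tolerates
the empty middle class.

Two text formats are supported: a simple delimited table (header row naming
``id``, ``status``, ``sex``, ``subtype`` followed by one column per locus,
genotype cells either allele pairs like ``A/G`` or single code digits), and
PLINK-style ped/map pairs.  ped files have no subtype column, so the family-ID
field is used to carry the subtype label; files written by
:func:`write_cohort` round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("M", "F", "U")
SUBTYPES = ("allergic", "nonallergic", "unknown", "control")

GENOTYPE_CODES = (-1, 0, 1, 2)

_SEX_ALIASES = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "2": "F",
    "u": "U", "unknown": "U", "0": "U", "": "U",
}
_CASE_ALIASES = {"case": True, "1": True, "2": True, "asthma": True,
                 "control": False, "0": False, "ctrl": False}


class CohortError(ValueError):
    """Raised for malformed cohort files or invalid stratification requests."""


@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus: display name, allele pair (major, minor), optional ids."""

    name: str
    alleles: tuple[str, str] = ("A", "B")
    rs_id: str | None = None
    genotype_labels: tuple[str, str, str] | None = None

    def __post_init__(self):
        if not self.name:
            raise CohortError("locus name must be nonempty")
        if self.alleles[0] == self.alleles[1]:
            raise CohortError(f"locus {self.name}: alleles must be distinct")


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotype classes within one group (missing excluded)."""

    n0: int
    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2

    def allele_freq(self, which: int = 2) -> float:
        """Frequency of the allele counted by class ``which`` (2 = n2 allele).

        For code orientation this is the minor-allele frequency when
        ``which=2``: ``(2*n2 + n1) / (2*(n0 + n1 + n2))``.
        """
        if self.total == 0:
            return float("nan")
        if which == 2:
            return (2 * self.n2 + self.n1) / (2 * self.total)
        if which == 0:
            return (2 * self.n0 + self.n1) / (2 * self.total)
        raise ValueError("which must be 0 or 2")

    def as_array(self) -> np.ndarray:
        return np.array([self.n0, self.n1, self.n2], dtype=float)


@dataclass
class CohortTable:
    """Per-subject genotypes, phenotype, sex, and disease-subtype labels."""

    loci: list[LocusDef]
    genotypes: np.ndarray  # (n_subjects, n_loci) int8, codes -1/0/1/2
    phenotype: np.ndarray  # bool, True = case
    sex: np.ndarray        # '<U1', one of M/F/U
    subtype: np.ndarray    # str, one of SUBTYPES
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        self.sex = np.asarray(self.sex, dtype="U1")
        self.subtype = np.asarray(self.subtype, dtype=object)
        n = len(self.phenotype)
        if self.ids is None:
            self.ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != n:
            raise CohortError("genotype matrix shape inconsistent with phenotype")
        if self.genotypes.shape[1] != len(self.loci):
            raise CohortError("genotype matrix width inconsistent with locus list")
        for arr, what in ((self.sex, "sex"), (self.subtype, "subtype"), (self.ids, "ids")):
            if len(arr) != n:
                raise CohortError(f"{what} length inconsistent with phenotype")
        bad = ~np.isin(self.genotypes, GENOTYPE_CODES)
        if bad.any():
            raise CohortError("genotype codes must be in {-1, 0, 1, 2}")
        if len(set(self.ids)) != n:
            raise CohortError("duplicate subject ids")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise CohortError("duplicate locus names in panel")
        if not set(self.sex) <= set(SEXES):
            raise CohortError(f"sex labels must be in {SEXES}")
        if not set(self.subtype) <= set(SUBTYPES):
            raise CohortError(f"subtype labels must be in {SUBTYPES}")
        if (~self.phenotype & (self.subtype != "control")).any():
            raise CohortError("every control must have subtype 'control'")
        if (self.phenotype & (self.subtype == "control")).any():
            raise CohortError("cases may not carry subtype 'control'")

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.phenotype)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.phenotype).sum())

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise CohortError(f"locus {name!r} not in panel") from None

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            loci=self.loci,
            genotypes=self.genotypes[mask],
            phenotype=self.phenotype[mask],
            sex=self.sex[mask],
            subtype=self.subtype[mask],
            ids=self.ids[mask],
        )


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_to_control_minor(cohort: CohortTable, warn: bool = True) -> CohortTable:
    """Flip genotype codes so code 2 counts the allele that is minor in controls.

    Ties (control MAF exactly 0.5) keep the current orientation, i.e. break
    toward the file's second allele.  Idempotent.
    """
    geno = cohort.genotypes.copy()
    loci = list(cohort.loci)
    controls = ~cohort.phenotype
    flipped = []
    for j, locus in enumerate(loci):
        col = geno[controls, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        freq2 = (2 * np.sum(col == 2) + np.sum(col == 1)) / (2 * col.size)
        if freq2 > 0.5:
            obs = geno[:, j] >= 0
            geno[obs, j] = 2 - geno[obs, j]
            loci[j] = LocusDef(
                name=locus.name,
                alleles=(locus.alleles[1], locus.alleles[0]),
                rs_id=locus.rs_id,
                genotype_labels=(tuple(reversed(locus.genotype_labels))
                                 if locus.genotype_labels else None),
            )
            flipped.append(locus.name)
    if flipped and warn:
        warnings.warn(
            "reoriented loci so code 2 counts the control-minor allele: "
            + ", ".join(flipped), stacklevel=2)
    return CohortTable(loci=loci, genotypes=geno, phenotype=cohort.phenotype,
                       sex=cohort.sex, subtype=cohort.subtype, ids=cohort.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_sex(value) -> str:
    s = str(value).strip().lower()
    if s not in _SEX_ALIASES:
        raise CohortError(f"unknown sex label {value!r}")
    return _SEX_ALIASES[s]


def _parse_status(value) -> bool:
    s = str(value).strip().lower()
    if s not in _CASE_ALIASES:
        raise CohortError(f"unknown case/control status {value!r}")
    return _CASE_ALIASES[s]


def _is_missing(cell: str) -> bool:
    return cell in ("", ".", "./.", "0/0", "nan", "NA")


def read_cohort(path: str | Path, format: str = "tabular") -> CohortTable:
    """Read a cohort file; genotype codes are oriented to the control-minor allele."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    if format == "tabular":
        cohort = _read_tabular(path)
    elif format in ("ped/map", "pedmap", "ped"):
        cohort = _read_pedmap(path)
    else:
        raise CohortError(f"unknown format {format!r}")
    _warn_high_missingness(cohort)
    return orient_to_control_minor(cohort)


def _warn_high_missingness(cohort: CohortTable) -> None:
    if cohort.n_loci == 0:
        return
    frac = (cohort.genotypes < 0).mean(axis=1)
    for i in np.nonzero(frac > 0.5)[0]:
        warnings.warn(
            f"subject {cohort.ids[i]} has >50% missing genotypes (kept)",
            stacklevel=3)


def _read_tabular(path: Path) -> CohortTable:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    required = ["id", "status", "sex", "subtype"]
    for col in required:
        if col not in df.columns:
            raise CohortError(f"tabular cohort file must have a {col!r} column")
    locus_cols = [c for c in df.columns if c not in required]
    ids = df["id"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate subject id in cohort file")
    phenotype = np.array([_parse_status(v) for v in df["status"]])
    sex = np.array([_parse_sex(v) for v in df["sex"]], dtype="U1")
    subtype = np.array([str(v).strip().lower() or "unknown" for v in df["subtype"]],
                       dtype=object)
    subtype[~phenotype] = "control"

    n = len(df)
    geno = np.full((n, len(locus_cols)), -1, dtype=np.int8)
    loci: list[LocusDef] = []
    for j, col in enumerate(locus_cols):
        cells = [str(v).strip() for v in df[col]]
        if all(_is_missing(c) or c in ("0", "1", "2", "-1") for c in cells):
            # pre-coded column
            for i, c in enumerate(cells):
                geno[i, j] = -1 if _is_missing(c) or c == "-1" else int(c)
            loci.append(LocusDef(name=col))
            continue
        allele_order: list[str] = []
        pairs: list[tuple[str, str] | None] = []
        for c in cells:
            if _is_missing(c):
                pairs.append(None)
                continue
            raw = c.replace("|", "/").split("/") if "/" in c else list(c)
            if len(raw) != 2 or not all(raw):
                raise CohortError(f"cannot parse genotype cell {c!r} at locus {col}")
            for a in raw:
                if a not in allele_order:
                    allele_order.append(a)
            pairs.append((raw[0], raw[1]))
        if len(allele_order) > 2:
            raise CohortError(
                f"locus {col}: more than two alleles {allele_order} (unknown symbol?)")
        while len(allele_order) < 2:
            allele_order.append("?")
        major, minor = allele_order[0], allele_order[1]
        for i, pr in enumerate(pairs):
            if pr is None:
                continue
            geno[i, j] = sum(a == minor for a in pr)
        loci.append(LocusDef(name=col, alleles=(major, minor)))
    return CohortTable(loci=loci, genotypes=geno, phenotype=phenotype,
                       sex=sex, subtype=subtype, ids=ids)


def write_cohort(cohort: CohortTable, path: str | Path,
                 format: str = "tabular", sep: str = "\t") -> None:
    path = Path(path)
    if format == "tabular":
        _write_tabular(cohort, path, sep)
    elif format in ("ped/map", "pedmap", "ped"):
        _write_pedmap(cohort, path)
    else:
        raise CohortError(f"unknown format {format!r}")


def _geno_cell(locus: LocusDef, code: int) -> str:
    maj, mnr = locus.alleles
    return {0: f"{maj}/{maj}", 1: f"{maj}/{mnr}", 2: f"{mnr}/{mnr}"}.get(code, ".")


def _write_tabular(cohort: CohortTable, path: Path, sep: str) -> None:
    data = {
        "id": cohort.ids,
        "status": np.where(cohort.phenotype, "case", "control"),
        "sex": cohort.sex,
        "subtype": cohort.subtype,
    }
    for j, locus in enumerate(cohort.loci):
        data[locus.name] = [_geno_cell(locus, g) for g in cohort.genotypes[:, j]]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


_PED_SEX = {"M": "1", "F": "2", "U": "0"}
_PED_SEX_BACK = {v: k for k, v in _PED_SEX.items()}


def _write_pedmap(cohort: CohortTable, path: Path) -> None:
    """Write <stem>.ped and <stem>.map; FID carries the subtype label."""
    stem = path.with_suffix("")
    with open(stem.with_suffix(".map"), "w") as fh:
        for locus in cohort.loci:
            fh.write(f"0\t{locus.name}\t0\t0\n")
    with open(stem.with_suffix(".ped"), "w") as fh:
        for i in range(cohort.n_subjects):
            row = [str(cohort.subtype[i]), str(cohort.ids[i]), "0", "0",
                   _PED_SEX[cohort.sex[i]],
                   "2" if cohort.phenotype[i] else "1"]
            for j, locus in enumerate(cohort.loci):
                code = cohort.genotypes[i, j]
                maj, mnr = locus.alleles
                al = {0: (maj, maj), 1: (maj, mnr), 2: (mnr, mnr)}.get(code, ("0", "0"))
                row.extend(al)
            fh.write(" ".join(row) + "\n")


def _read_pedmap(path: Path) -> CohortTable:
    stem = path.with_suffix("")
    map_path, ped_path = stem.with_suffix(".map"), stem.with_suffix(".ped")
    if not map_path.exists() or not ped_path.exists():
        raise CohortError(f"need both {ped_path} and {map_path}")
    locus_names = [line.split()[1] for line in map_path.read_text().splitlines() if line.strip()]
    ids, phenotype, sex, subtype, rows = [], [], [], [], []
    allele_orders: list[list[str]] = [[] for _ in locus_names]
    for line in ped_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(locus_names):
            raise CohortError("ped row has wrong number of fields")
        fid, iid, _, _, sx, ph = parts[:6]
        ids.append(iid)
        phenotype.append(ph == "2")
        sex.append(_PED_SEX_BACK.get(sx, "U"))
        subtype.append(fid if fid in SUBTYPES else "unknown")
        alleles = parts[6:]
        row = []
        for j in range(len(locus_names)):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                row.append(None)
                continue
            for a in (a1, a2):
                if a not in allele_orders[j]:
                    allele_orders[j].append(a)
            row.append((a1, a2))
        rows.append(row)
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate subject id in ped file")
    loci = []
    geno = np.full((len(rows), len(locus_names)), -1, dtype=np.int8)
    for j, name in enumerate(locus_names):
        order = allele_orders[j]
        if len(order) > 2:
            raise CohortError(f"locus {name}: more than two alleles in ped file")
        while len(order) < 2:
            order.append("?")
        major, minor = order
        for i, row in enumerate(rows):
            pr = row[j]
            if pr is not None:
                geno[i, j] = sum(a == minor for a in pr)
        loci.append(LocusDef(name=name, alleles=(major, minor)))
    phenotype = np.array(phenotype)
    subtype = np.array(subtype, dtype=object)
    subtype[~phenotype] = "control"
    return CohortTable(loci=loci, genotypes=geno, phenotype=phenotype,
                       sex=np.array(sex, dtype="U1"), subtype=subtype,
                       ids=np.array(ids, dtype=object))


# ---------------------------------------------------------------------------
# stratification and counting
# ---------------------------------------------------------------------------

def stratify(cohort: CohortTable, sex: str | None = None,
             subtype: str | None = None) -> CohortTable:
    """Subset by sex and/or case subtype.

    Sex filters everyone; subtype filters cases only — controls are the
    comparison group of every subtype stratum and are never dropped by the
    subtype filter.
    """
    mask = np.ones(cohort.n_subjects, dtype=bool)
    if sex is not None:
        if sex not in SEXES:
            raise CohortError(f"unknown sex stratum {sex!r}")
        mask &= cohort.sex == sex
    if subtype is not None:
        if subtype not in SUBTYPES:
            raise CohortError(f"unknown subtype stratum {subtype!r}")
        mask &= ~cohort.phenotype | (cohort.subtype == subtype)
    sub = cohort.subset(mask)
    label = f"(sex={sex}, subtype={subtype})"
    if sub.n_subjects == 0:
        raise CohortError(f"empty stratum {label}")
    if subtype is not None and sub.n_cases == 0:
        raise CohortError(f"no cases in stratum {label}")
    return sub


def genotype_counts(cohort: CohortTable, locus: int | str,
                    group: str = "cases") -> GenotypeCounts:
    """Count the three genotype classes at one locus in cases or controls."""
    j = cohort.locus_index(locus) if isinstance(locus, str) else locus
    if not 0 <= j < cohort.n_loci:
        raise CohortError(f"locus index {j} out of range")
    if group == "cases":
        col = cohort.genotypes[cohort.phenotype, j]
    elif group == "controls":
        col = cohort.genotypes[~cohort.phenotype, j]
    else:
        raise CohortError("group must be 'cases' or 'controls'")
    col = col[col >= 0]
    if col.size == 0:
        warnings.warn(f"all genotypes missing at locus {cohort.loci[j].name} "
                      f"in {group}", stacklevel=2)
    return GenotypeCounts(int(np.sum(col == 0)), int(np.sum(col == 1)),
                          int(np.sum(col == 2)))
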
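"""Data model and I/O for biallelic SNP case-control cohorts.

Genotypes are stored internally as minor-allele dose (0/1/2) per locus;
phase is never represented here.  Missing genotypes use the sentinel -1
and are excluded locus-wise (available-case analysis).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: covariate columns of the native TSV dialect, in header order
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "smoking",
    "drinking",
    "copd",
    "family_history",
)


@dataclasses.dataclass(frozen=True)
class LocusSpec:
    """Identity and allele coding of one biallelic SNP.

    ``major_allele`` is the common allele, ``minor_allele`` the rarer
    one whose copies the dose counts.
    """

    name: str
    gene: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        for a in (self.major_allele, self.minor_allele):
            if len(a) != 1 or a not in "ACGT":
                raise ValueError(f"{self.name}: allele {a!r} is not a single base")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.name}: major and minor allele are identical")

    def dose_from_alleles(self, a1: str, a2: str) -> int:
        """Minor-allele count of an unordered allele pair; -1 if unparseable."""
        dose = 0
        for a in (a1, a2):
            if a == self.minor_allele:
                dose += 1
            elif a != self.major_allele:
                return MISSING
        return dose


def _check_panel(panel: Sequence[LocusSpec]) -> tuple[LocusSpec, ...]:
    panel = tuple(panel)
    names = [l.name for l in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names in panel")
    return panel


@dataclasses.dataclass
class CohortTable:
    """Individual-level case/control records.

    ``table`` holds ``id``, ``status`` (1=case, 0=control), optional
    covariates, and one integer dose column per panel locus.  ``phase``
    is an optional side-channel of true haplotypes (simulator output)
    used only to validate phase inference; the analysis never reads it.
    """

    table: pd.DataFrame
    panel: tuple[LocusSpec, ...]
    phase: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.panel = _check_panel(self.panel)
        if "status" not in self.table.columns:
            raise ValueError("cohort table lacks a status column")
        status = self.table["status"].to_numpy()
        if not np.isin(status, [0, 1]).all():
            raise ValueError("status must be 0/1 for every subject")
        for locus in self.panel:
            if locus.name not in self.table.columns:
                raise ValueError(f"missing dose column for locus {locus.name}")
            dose = self.table[locus.name].to_numpy()
            if not np.isin(dose, [MISSING, 0, 1, 2]).all():
                raise ValueError(f"{locus.name}: doses must be 0/1/2 or missing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def status(self) -> np.ndarray:
        return self.table["status"].to_numpy(dtype=int)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    def locus(self, name: str) -> LocusSpec:
        for l in self.panel:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in panel")

    def doses(self, loci: Iterable[str] | None = None) -> np.ndarray:
        """Dose matrix (subjects x loci), -1 where missing."""
        names = [l.name for l in self.panel] if loci is None else list(loci)
        for n in names:
            self.locus(n)
        return self.table[names].to_numpy(dtype=int)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        phase = None if self.phase is None else self.phase.loc[mask].reset_index(drop=True)
        return CohortTable(self.table.loc[mask].reset_index(drop=True), self.panel, phase)


@dataclasses.dataclass(frozen=True)
class GenotypeCountTable:
    """3x2 genotype counts (major-hom, het, minor-hom) by case/control."""

    locus: LocusSpec
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.case_counts, self.control_counts):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValueError("counts must be three nonnegative integers")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    def as_array(self) -> np.ndarray:
        """2x3 array, rows = (cases, controls)."""
        return np.array([self.case_counts, self.control_counts], dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, panel: Sequence[LocusSpec], format: str = "tsv") -> CohortTable:
    """Read an individual-level cohort in the native TSV dialect or PLINK PED.

    Doses are recoded to minor-allele counts using the panel's allele
    coding; for TSV an allele outside {major, minor} is a hard error
    naming the line and column, while the PED convention treats ``0`` as
    the missing allele.
    """
    panel = _check_panel(panel)
    if format == "tsv":
        return _read_tsv(Path(path), panel)
    if format == "ped":
        return _read_ped(Path(path), panel)
    raise ValueError(f"unknown cohort format {format!r}")


def _read_tsv(path: Path, panel: tuple[LocusSpec, ...]) -> CohortTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "status", *COVARIATE_COLUMNS, *[l.name for l in panel]]
        if header != expected:
            raise ValueError(
                f"{path}: malformed header; expected {' '.join(expected)!r}, got {' '.join(header)!r}"
            )
        records = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            rec: dict = {"id": fields[0], "status": int(fields[1])}
            for j, cov in enumerate(COVARIATE_COLUMNS, start=2):
                rec[cov] = float(fields[j]) if fields[j] not in ("", "NA") else np.nan
            for j, locus in enumerate(panel, start=2 + len(COVARIATE_COLUMNS)):
                geno = fields[j]
                if geno == "NN":
                    rec[locus.name] = MISSING
                    continue
                if len(geno) != 2:
                    raise ValueError(f"{path}:{lineno}: column {locus.name}: bad genotype {geno!r}")
                dose = locus.dose_from_alleles(geno[0], geno[1])
                if dose == MISSING:
                    raise ValueError(
                        f"{path}:{lineno}: column {locus.name}: allele not in "
                        f"{{{locus.major_allele},{locus.minor_allele}}}: {geno!r}"
                    )
                rec[locus.name] = dose
            records.append(rec)
    return CohortTable(pd.DataFrame.from_records(records), panel)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the native TSV dialect (inverse of :func:`read_cohort`)."""
    loci = [l.name for l in cohort.panel]
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "status", *COVARIATE_COLUMNS, *loci]) + "\n")
        for _, row in cohort.table.iterrows():
            fields = [str(row["id"]), str(int(row["status"]))]
            for cov in COVARIATE_COLUMNS:
                v = row.get(cov, np.nan)
                fields.append("NA" if pd.isna(v) else repr(float(v)))
            for locus in cohort.panel:
                dose = int(row[locus.name])
                if dose == MISSING:
                    fields.append("NN")
                else:
                    fields.append(
                        locus.minor_allele * dose + locus.major_allele * (2 - dose)
                    )
            fh.write("\t".join(fields) + "\n")


def read_map(path: str | Path) -> list[str]:
    """Locus names in order from a PLINK .map file (2nd column)."""
    names = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if fields:
                names.append(fields[1])
    return names


def _read_ped(path: Path, panel: tuple[LocusSpec, ...]) -> CohortTable:
    """PLINK .ped: 6 leading columns then two alleles per locus; 0 = missing.

    Locus order must match the panel (pair with :func:`read_map` to
    reorder the panel first).  Phenotype 2 = case, 1 = control.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(panel):
                raise ValueError(
                    f"{path}:{lineno}: expected {6 + 2 * len(panel)} fields, got {len(fields)}"
                )
            pheno = fields[5]
            if pheno not in ("1", "2"):
                raise ValueError(f"{path}:{lineno}: phenotype {pheno!r} not in {{1,2}}")
            rec: dict = {"id": fields[1], "status": int(pheno == "2"),
                         "sex": {"1": 1.0, "2": 0.0}.get(fields[4], np.nan)}
            for cov in COVARIATE_COLUMNS:
                rec.setdefault(cov, np.nan)
            for j, locus in enumerate(panel):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    rec[locus.name] = MISSING
                    continue
                dose = locus.dose_from_alleles(a1, a2)
                if dose == MISSING:
                    raise ValueError(
                        f"{path}:{lineno}: locus {locus.name}: allele not in "
                        f"{{{locus.major_allele},{locus.minor_allele}}}: {a1} {a2}"
                    )
                rec[locus.name] = dose
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: empty ped file")
    return CohortTable(pd.DataFrame.from_records(records), panel)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def count_genotypes(cohort: CohortTable, locus: LocusSpec | str) -> GenotypeCountTable:
    """3x2 genotype counts for one locus, missing doses excluded."""
    if isinstance(locus, str):
        locus = cohort.locus(locus)
    else:
        cohort.locus(locus.name)
    dose = cohort.table[locus.name].to_numpy(dtype=int)
    status = cohort.status
    rows = []
    for grp in (1, 0):
        sel = dose[(status == grp) & (dose != MISSING)]
        rows.append(tuple(int((sel == d).sum()) for d in (0, 1, 2)))
    return GenotypeCountTable(locus, rows[0], rows[1])


def allele_frequency(counts: Sequence[int]) -> float:
    """Minor-allele frequency from (n_majhom, n_het, n_minhom)."""
    n0, n1, n2 = counts
    total = n0 + n1 + n2
    if total <= 0:
        raise ValueError("allele_frequency of empty counts")
    return (n1 + 2 * n2) / (2 * total)


def expand_counts_to_cohort(tables: Sequence[GenotypeCountTable], seed: int) -> CohortTable:
    """Individual-level cohort whose per-locus marginals equal the inputs.

    Cross-locus joint assignment is random under ``seed`` (single-locus
    statistics are invariant to it).  This lets every single-locus
    statistic be recomputed from published marginal genotype counts.
    """
    if not tables:
        raise ValueError("no count tables given")
    n_cases = tables[0].n_cases
    n_controls = tables[0].n_controls
    for t in tables:
        if t.n_cases != n_cases or t.n_controls != n_controls:
            raise ValueError(
                f"{t.locus.name}: group sizes {t.n_cases}/{t.n_controls} "
                f"inconsistent with {n_cases}/{n_controls}"
            )
    rng = np.random.default_rng(seed)
    status = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    cols: dict = {
        "id": [f"S{i:05d}" for i in range(len(status))],
        "status": status,
    }
    for cov in COVARIATE_COLUMNS:
        cols[cov] = np.full(len(status), np.nan)
    for t in tables:
        parts = []
        for row in (t.case_counts, t.control_counts):
            doses = np.repeat([0, 1, 2], row)
            rng.shuffle(doses)
            parts.append(doses)
        cols[t.locus.name] = np.concatenate(parts)
    return CohortTable(pd.DataFrame(cols), tuple(t.locus for t in tables))
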
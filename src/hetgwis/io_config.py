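"""Tabular I/O, validated domain containers, and run configuration.

Genotypes travel as a dense dosage matrix (minor-allele counts 0/1/2 with
``NaN`` marking missing calls) read from either PLINK ``.raw`` additive
exports or a headerized TSV dialect.  Phenotypes are long-format
subject-visit tables.  Everything downstream of this module consumes the
validated containers defined here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigError, FormatError, ValidationError

logger = logging.getLogger("hetgwis")

SMOKING_LEVELS = ("never", "former", "current")

PHENOTYPE_COLUMNS = (
    "subject_id",
    "visit",
    "time",
    "fev1",
    "age0",
    "sex",
    "height",
    "bmi",
    "smoking",
    "pack_years",
)

_PLINK_META_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    snp_ids : list of str
        Unique SNP identifiers, one per column.
    dosages : ndarray of float, shape (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2}; missing calls are ``NaN``.
    allele_labels : list of (str, str)
        (minor, major) allele character pair per SNP; ``"?"`` when unknown.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    allele_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValidationError(f"dosages outside {{0,1,2}}: e.g. {bad[:3]}")
        if not self.allele_labels:
            self.allele_labels = [("?", "?")] * m
        if len(self.allele_labels) != m:
            raise ValidationError("allele_labels length mismatch")
        self.allele_labels = [tuple(a) for a in self.allele_labels]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return np.isnan(self.dosages).mean(axis=0)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.dosages[:, j]

    def dosage_series(self, snp_id: str) -> pd.Series:
        """Dosages of one SNP indexed by sample id."""
        return pd.Series(self.column(snp_id), index=self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


def _parse_dosage_cell(cell: str) -> float:
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return np.nan
    if v in (0.0, 1.0, 2.0):
        return v
    return np.nan


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype dosage file.

    ``plink_raw`` expects whitespace-separated columns
    FID IID PAT MAT SEX PHENOTYPE then one ``SNP_A`` column per variant
    (counted-allele suffix).  ``tsv`` expects a ``sample_id`` header column
    followed by one column per SNP, optionally preceded by a line
    ``#alleles<TAB>snp=minor/major ...`` carrying allele labels.

    Unparseable dosage cells become missing and are counted in a logged
    missingness report.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"genotype file not found: {path}")
    if dialect == "plink_raw":
        gm = _read_plink_raw(path)
    elif dialect == "tsv":
        gm = _read_genotype_tsv(path)
    else:
        raise FormatError(f"unknown genotype dialect: {dialect!r}")
    miss = gm.missingness()
    n_missing = int(np.isnan(gm.dosages).sum())
    if n_missing:
        worst = gm.snp_ids[int(np.argmax(miss))]
        logger.info(
            "read_genotypes: %d missing calls across %d SNPs (worst %s at %.3f)",
            n_missing, int((miss > 0).sum()), worst, miss.max(),
        )
    return gm


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_PLINK_META_COLUMNS)] != list(_PLINK_META_COLUMNS):
            raise FormatError(
                f"{path}: not a PLINK .raw header (expected {' '.join(_PLINK_META_COLUMNS)} ...)"
            )
        snp_headers = header[len(_PLINK_META_COLUMNS):]
        snp_ids, alleles = [], []
        for h in snp_headers:
            if "_" in h:
                sid, minor = h.rsplit("_", 1)
            else:
                sid, minor = h, "?"
            snp_ids.append(sid)
            alleles.append((minor, "?"))
        sample_ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise FormatError(f"{path}: row for {parts[0]} has {len(parts)} fields, expected {len(header)}")
            sample_ids.append(parts[1])  # IID
            rows.append([_parse_dosage_cell(c) for c in parts[len(_PLINK_META_COLUMNS):]])
    dosages = np.array(rows, dtype=float).reshape(len(sample_ids), len(snp_ids))
    return GenotypeMatrix(sample_ids, snp_ids, dosages, alleles)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    allele_line = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#alleles"):
            allele_line = first.rstrip("\n")
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise FormatError(f"{path}: TSV genotype header must start with 'sample_id'")
        snp_ids = header[1:]
        sample_ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}: row for {parts[0]} has {len(parts)} fields, expected {len(header)}")
            sample_ids.append(parts[0])
            rows.append([_parse_dosage_cell(c) for c in parts[1:]])
    alleles = [("?", "?")] * len(snp_ids)
    if allele_line is not None:
        lookup = {}
        for tok in allele_line.split("\t")[1:]:
            m = re.fullmatch(r"(.+)=(\S+)/(\S+)", tok)
            if m:
                lookup[m.group(1)] = (m.group(2), m.group(3))
        alleles = [lookup.get(s, ("?", "?")) for s in snp_ids]
    dosages = np.array(rows, dtype=float).reshape(len(sample_ids), len(snp_ids))
    return GenotypeMatrix(sample_ids, snp_ids, dosages, alleles)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a genotype matrix in one of the supported dialects."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("#alleles\t" + "\t".join(
                f"{s}={a[0]}/{a[1]}" for s, a in zip(gm.snp_ids, gm.allele_labels)) + "\n")
            fh.write("sample_id\t" + "\t".join(gm.snp_ids) + "\n")
            for i, sid in enumerate(gm.sample_ids):
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in gm.dosages[i]]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")
    elif dialect == "plink_raw":
        with open(path, "w") as fh:
            heads = [f"{s}_{a[0]}" for s, a in zip(gm.snp_ids, gm.allele_labels)]
            fh.write(" ".join(_PLINK_META_COLUMNS) + " " + " ".join(heads) + "\n")
            for i, sid in enumerate(gm.sample_ids):
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in gm.dosages[i]]
                fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(cells) + "\n")
    else:
        raise FormatError(f"unknown genotype dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# phenotype container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LongitudinalRecord:
    """One subject-visit row of the response model."""

    subject_id: str
    visit: int
    time: float
    fev1: float
    age0: float
    sex: int
    height: float
    bmi: float
    smoking: str
    pack_years: float


class PhenotypeTable:
    """Validated long-format phenotype/covariate table.

    One row per subject-visit.  Construction enforces the record
    invariants: visits are 1..n_i without gaps, time starts at 0 and is
    non-decreasing, smoking status is constant within subject, and
    pack-years are identically zero for never smokers.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = df[list(PHENOTYPE_COLUMNS)]
        df["subject_id"] = df["subject_id"].astype(str)
        df["visit"] = df["visit"].astype(int)
        for c in ("time", "fev1", "age0", "height", "bmi", "pack_years"):
            df[c] = df[c].astype(float)
        df["sex"] = df["sex"].astype(int)
        df = df.sort_values(["subject_id", "visit"], kind="mergesort").reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_status = set(df["smoking"]) - set(SMOKING_LEVELS)
        if bad_status:
            raise ValidationError(f"unknown smoking status values: {sorted(bad_status)}")
        if not df["sex"].isin((0, 1)).all():
            raise ValidationError("sex must be coded 0/1")
        num = df[["time", "fev1", "age0", "height", "bmi", "pack_years"]].to_numpy()
        if not np.isfinite(num).all():
            raise ValidationError("non-finite phenotype or covariate values")
        if (df["pack_years"] < 0).any():
            raise ValidationError("negative pack_years")
        for sid, g in df.groupby("subject_id", sort=False):
            visits = g["visit"].to_numpy()
            if visits[0] != 1 or not np.array_equal(visits, np.arange(1, len(visits) + 1)):
                raise ValidationError(f"subject {sid}: visit indices must be 1..n without gaps, got {visits.tolist()}")
            times = g["time"].to_numpy()
            if times[0] != 0.0:
                raise ValidationError(f"subject {sid}: time must be 0 at visit 1")
            if (np.diff(times) < 0).any():
                raise ValidationError(f"subject {sid}: time must be non-decreasing across visits")
            if g["smoking"].nunique() != 1:
                raise ValidationError(f"subject {sid}: smoking status changes across visits")
            if g["smoking"].iloc[0] == "never" and (g["pack_years"] > 0).any():
                raise ValidationError(f"subject {sid}: never smoker with positive pack_years")
            if g["age0"].nunique() != 1 or g["sex"].nunique() != 1:
                raise ValidationError(f"subject {sid}: baseline age/sex must be constant")

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def max_visits(self) -> int:
        return int(self.df["visit"].max())

    @property
    def records(self) -> list[LongitudinalRecord]:
        return [LongitudinalRecord(**row) for row in self.df.to_dict("records")]

    def smoking_of(self) -> pd.Series:
        """Baseline smoking status per subject."""
        return self.df.groupby("subject_id", sort=False)["smoking"].first()

    def stratum(self, which: str) -> "PhenotypeTable":
        """Subset by smoking stratum: never/former/current or 'ever'."""
        if which == "ever":
            mask = self.df["smoking"].isin(("former", "current"))
        elif which in SMOKING_LEVELS:
            mask = self.df["smoking"] == which
        else:
            raise ValidationError(f"unknown stratum {which!r}")
        return PhenotypeTable(self.df[mask])

    def subset_subjects(self, keep: Iterable[str]) -> "PhenotypeTable":
        keep = set(map(str, keep))
        return PhenotypeTable(self.df[self.df["subject_id"].isin(keep)])


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read and validate a long-format phenotype TSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"phenotype file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse phenotype TSV: {exc}") from exc
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative settings shared by the CLI subcommands."""

    max_visits: int = 3
    n_pcs: int = 10
    alpha: float = 0.05
    filter_top_k: int = 4
    seed: int = 0
    covariance: str = "unstructured_marginal"
    # optional screening thresholds; None disables (the discovery scan
    # reports HWE/MAF without filtering beyond polymorphism)
    maf_min: float | None = None
    max_missing: float | None = None
    smoking_coding_candidates: tuple[str, ...] = ("two_level", "three_level")
    covariance_candidates: tuple[str, ...] = (
        "independence",
        "random_intercept",
        "unstructured_marginal",
    )
    units: str = "liters"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems = []
        if self.n_pcs < 0:
            problems.append("n_pcs must be >= 0")
        if self.filter_top_k < 1:
            problems.append("filter_top_k must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            problems.append("alpha must lie in (0, 1)")
        if self.max_visits < 1:
            problems.append("max_visits must be >= 1")
        if self.covariance not in ("independence", "random_intercept",
                                   "unstructured_marginal"):
            problems.append(f"unknown covariance structure {self.covariance!r}")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"extra"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extra = {k: v for k, v in d.items() if k not in known}
        for key in ("smoking_coding_candidates", "covariance_candidates"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(extra=extra, **kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


def config_hash(d: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a deterministic JSON run manifest (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
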
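"""Cohort data structures and tabular / VCF input-output.

Genotypes are additively coded: 0 = homozygous for the major allele,
1 = heterozygous, 2 = homozygous for the minor allele, where the minor
allele is defined as the less frequent allele *in the control group*.
Missing genotypes are stored as ``MISSING`` (-1).

The tabular genotype format is a delimited text file with header
``individual_id[,status],<snp_1>,...,<snp_m>`` and one row per
individual; genotype cells are ``0``, ``1``, ``2`` or one of the
missing tokens ``NA``, ``.`` or the empty string.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
MISSING_TOKENS = frozenset({"NA", "", ".", "na", "NaN", "nan"})

GENDER_VALUES = frozenset({"male", "female"})
LOCATION_VALUES = frozenset({"colon", "ileum", "ileocolonic"})

#: binary clinical variables carried by a phenotype table
BINARY_PHENOTYPES = (
    "anal",
    "inflammatory",
    "stenosing",
    "non_perianal_fistulae",
    "perianal_fistulae",
    "surgery",
)

PHENOTYPE_COLUMNS = (
    "individual_id",
    "gender",
    "age_at_diagnosis",
    "location",
) + BINARY_PHENOTYPES


class GenotypeParseError(ValueError):
    """Structurally malformed genotype input (wrong row length, no data...)."""


class GenotypeValueError(ValueError):
    """A genotype cell outside {0, 1, 2, missing-token}."""


@dataclass
class SnpInfo:
    """Marker metadata for one biallelic SNP.

    ``control_minor_freq`` is the frequency of the coded (minor) allele
    in the control group; once orientation has been resolved it is
    <= 0.5 by construction.
    """

    snp_id: str
    locus_label: str = ""
    minor_allele: str = ""
    control_minor_freq: float = float("nan")


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs, additively coded with a missing mask.

    ``values`` is an (n, m) int8 array with entries in {-1, 0, 1, 2};
    -1 marks a missing genotype.  ``status`` optionally labels each
    individual (e.g. ``"case"`` / ``"control"``).
    """

    individual_ids: list[str]
    snps: list[SnpInfo]
    values: np.ndarray
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"{len(self.individual_ids)} individual ids but {n} genotype rows"
            )
        if m != len(self.snps):
            raise ValueError(f"{len(self.snps)} SNPs but {m} genotype columns")
        bad = (self.values < -1) | (self.values > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValueError(
                f"genotype out of range at individual {self.individual_ids[i]!r},"
                f" SNP {self.snps[j].snp_id!r}: {int(self.values[i, j])}"
            )
        if self.status is not None:
            self.status = np.asarray(self.status, dtype=object)
            if self.status.shape != (n,):
                raise ValueError("status must have one entry per individual")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def missing_rate_per_snp(self) -> np.ndarray:
        """Fraction of missing entries per SNP, each in [0, 1]."""
        return self.missing_mask.mean(axis=0)

    # -- subsetting -----------------------------------------------------
    def subset(self, rows: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in rows],
            snps=list(self.snps),
            values=self.values[rows].copy(),
            status=None if self.status is None else self.status[rows].copy(),
        )

    def by_status(self, label: str) -> "GenotypeMatrix":
        if self.status is None:
            raise ValueError("genotype matrix carries no status column")
        return self.subset(np.flatnonzero(self.status == label))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.snp_ids)
        df.insert(0, "individual_id", self.individual_ids)
        if self.status is not None:
            df.insert(1, "status", self.status)
        return df


# ----------------------------------------------------------------------
# genotype readers / writers
# ----------------------------------------------------------------------

def _parse_genotype_cell(token: str, line_no: int, snp_id: str) -> int:
    token = token.strip()
    if token in MISSING_TOKENS:
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise GenotypeValueError(
        f"invalid genotype token {token!r} at line {line_no}, SNP {snp_id!r}"
    )


def load_genotypes(path, dialect: str = "tabular", delimiter: str = ",") -> GenotypeMatrix:
    """Read a genotype matrix from a delimited table or a VCF.

    Tabular files must carry a header ``individual_id[,status],<snp ids>``;
    VCF ingestion keeps biallelic records only and codes GT fields
    0/0 -> 0, 0/1 -> 1, 1/1 -> 2 and any half or no call -> missing.
    """
    if dialect == "tabular":
        return _load_genotypes_tabular(path, delimiter)
    if dialect == "vcf":
        return _load_genotypes_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_genotypes_tabular(path, delimiter: str) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if not header or header[0] != "individual_id":
            raise GenotypeParseError(
                f"{path}: first header column must be 'individual_id', got {header[:1]!r}"
            )
        has_status = len(header) > 1 and header[1] == "status"
        first_snp_col = 2 if has_status else 1
        snp_ids = header[first_snp_col:]
        if not snp_ids:
            raise GenotypeParseError(f"{path}: header lists no SNP columns")
        if len(set(snp_ids)) != len(snp_ids):
            raise GenotypeParseError(f"{path}: duplicated SNP ids in header")

        ids: list[str] = []
        status: list[str] = []
        rows: list[list[int]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # tolerate trailing blank lines
            if len(row) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {line_no} has {len(row)} fields, expected {len(header)}"
                )
            ids.append(row[0].strip())
            if has_status:
                status.append(row[1].strip())
            rows.append(
                [
                    _parse_genotype_cell(tok, line_no, snp_ids[j])
                    for j, tok in enumerate(row[first_snp_col:])
                ]
            )
    if not rows:
        raise GenotypeParseError(f"{path}: no data rows")
    return GenotypeMatrix(
        individual_ids=ids,
        snps=[SnpInfo(snp_id=s) for s in snp_ids],
        values=np.array(rows, dtype=np.int8),
        status=np.array(status, dtype=object) if status else None,
    )


def _load_genotypes_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires cyvcf2") from exc

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                "(only biallelic SNPs are supported)"
            )
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        col = np.full(len(ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        snps.append(SnpInfo(snp_id=snp_id, minor_allele=variant.ALT[0]))
        columns.append(col)
    if not snps:
        raise GenotypeParseError(f"{path}: VCF contains no usable records")
    return GenotypeMatrix(
        individual_ids=ids, snps=snps, values=np.column_stack(columns)
    )


def write_genotypes(gm: GenotypeMatrix, path, delimiter: str = ",") -> None:
    """Write a genotype matrix in the tabular format (missing -> NA)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = ["individual_id"]
        if gm.status is not None:
            header.append("status")
        header += gm.snp_ids
        writer.writerow(header)
        for i in range(gm.n):
            row = [gm.individual_ids[i]]
            if gm.status is not None:
                row.append(str(gm.status[i]))
            row += ["NA" if v == MISSING else str(int(v)) for v in gm.values[i]]
            writer.writerow(row)


# ----------------------------------------------------------------------
# minor-allele orientation
# ----------------------------------------------------------------------

def orient_to_control_minor(
    raw: GenotypeMatrix, control_ids: Iterable[str]
) -> GenotypeMatrix:
    """Recode SNPs so the coded allele is the control-group minor allele.

    For every SNP whose coded-allele frequency among controls exceeds
    0.5, genotypes are flipped g -> 2 - g for *all* individuals.  A
    50/50 tie keeps the input orientation.  SNPs with no observed
    control genotype are left untouched with a warning.  Idempotent.
    """
    control_ids = set(control_ids)
    if not control_ids:
        raise ValueError("control subset is empty")
    ctrl_rows = [i for i, iid in enumerate(raw.individual_ids) if iid in control_ids]
    if not ctrl_rows:
        raise ValueError("no control ids found in the genotype matrix")

    values = raw.values.copy()
    snps = [replace(s) for s in raw.snps]
    ctrl = values[ctrl_rows]
    observed = ctrl != MISSING
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        coded_freq = np.where(
            n_obs > 0,
            np.where(observed, ctrl, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)),
            np.nan,
        )

    for j, freq in enumerate(coded_freq):
        if np.isnan(freq):
            warnings.warn(
                f"SNP {snps[j].snp_id!r}: all control genotypes missing; "
                "orientation left unchanged"
            )
            continue
        if freq > 0.5:
            col = values[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
            snps[j].control_minor_freq = 1.0 - freq
        else:
            if freq == 0.5:
                warnings.warn(
                    f"SNP {snps[j].snp_id!r}: 50/50 allele frequency in controls; "
                    "keeping input orientation"
                )
            snps[j].control_minor_freq = float(freq)

    return GenotypeMatrix(
        individual_ids=list(raw.individual_ids),
        snps=snps,
        values=values,
        status=None if raw.status is None else raw.status.copy(),
    )


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Typed per-individual clinical table.

    Columns: gender (male/female), age_at_diagnosis (years), location
    (colon / ileum / ileocolonic, mutually exclusive), and the binary
    flags anal, inflammatory, stenosing, non_perianal_fistulae,
    perianal_fistulae and surgery.  Anal disease is recorded
    independently of location.  All columns may contain missing values.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks columns: {missing_cols}")
        bad_gender = set(self.df["gender"].dropna()) - GENDER_VALUES
        if bad_gender:
            raise ValueError(f"invalid gender values: {sorted(bad_gender)}")
        bad_loc = set(self.df["location"].dropna()) - LOCATION_VALUES
        if bad_loc:
            raise ValueError(f"invalid location values: {sorted(bad_loc)}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.df["individual_id"])

    def missing_counts(self) -> dict[str, int]:
        return {
            c: int(self.df[c].isna().sum())
            for c in PHENOTYPE_COLUMNS
            if c != "individual_id"
        }

    def summary(self) -> dict:
        """Load report: margins mirroring a cohort characteristics table."""
        df = self.df
        out: dict = {
            "n": self.n,
            "missing": self.missing_counts(),
            "male": int((df["gender"] == "male").sum()),
            "female": int((df["gender"] == "female").sum()),
            "median_age_at_diagnosis": (
                float(df["age_at_diagnosis"].median())
                if df["age_at_diagnosis"].notna().any()
                else float("nan")
            ),
            "location": {
                loc: int((df["location"] == loc).sum())
                for loc in sorted(LOCATION_VALUES)
            },
        }
        for col in BINARY_PHENOTYPES:
            out[col] = int((df[col] == 1).sum())
        return out

    def binary_view(self) -> pd.DataFrame:
        """Boolean design columns for association tests and forests.

        Expands gender to ``male`` and location to one indicator per
        category; keeps the native binary flags.  Missing stays missing.
        """
        df = self.df
        out = pd.DataFrame(index=df.index)
        out["male"] = df["gender"].map({"male": 1, "female": 0}).astype("Float64")
        for loc in ("colon", "ileum", "ileocolonic"):
            out[loc] = df["location"].map(
                lambda v, loc=loc: np.nan if pd.isna(v) else float(v == loc)
            ).astype("Float64")
        for col in BINARY_PHENOTYPES:
            out[col] = df[col].astype("Float64")
        return out


def _parse_bool(token: str, line_no: int, col: str):
    token = token.strip()
    if token in MISSING_TOKENS:
        return pd.NA
    if token in ("0", "1"):
        return int(token)
    raise ValueError(f"invalid boolean {token!r} at line {line_no}, column {col!r}")


def load_phenotypes(path, delimiter: str = ",") -> PhenotypeTable:
    """Read a phenotype table; boolean columns are coded 0/1/NA."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty phenotype file") from None
        unknown = [c for c in header if c not in PHENOTYPE_COLUMNS]
        if unknown:
            raise ValueError(f"{path}: unknown phenotype columns {unknown}")
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"{path}: phenotype columns absent: {missing_cols}")
        idx = {c: header.index(c) for c in header}

        records = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {line_no} has {len(row)} fields, expected {len(header)}"
                )
            rec: dict = {"individual_id": row[idx["individual_id"]].strip()}
            g = row[idx["gender"]].strip()
            if g in MISSING_TOKENS:
                rec["gender"] = pd.NA
            elif g in GENDER_VALUES:
                rec["gender"] = g
            else:
                raise ValueError(f"{path}: invalid gender {g!r} at line {line_no}")
            age = row[idx["age_at_diagnosis"]].strip()
            rec["age_at_diagnosis"] = (
                np.nan if age in MISSING_TOKENS else float(age)
            )
            loc = row[idx["location"]].strip()
            if loc in MISSING_TOKENS:
                rec["location"] = pd.NA
            elif loc in LOCATION_VALUES:
                rec["location"] = loc
            else:
                raise ValueError(f"{path}: invalid location {loc!r} at line {line_no}")
            for col in BINARY_PHENOTYPES:
                rec[col] = _parse_bool(row[idx[col]], line_no, col)
            records.append(rec)

    df = pd.DataFrame.from_records(records, columns=list(PHENOTYPE_COLUMNS))
    for col in BINARY_PHENOTYPES:
        df[col] = df[col].astype("Int64")
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path, delimiter: str = ",") -> None:
    df = pt.df.copy()
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")
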
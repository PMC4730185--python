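"""Validated in-memory containers and TSV/GMT readers and writers.

Every on-disk artifact of the pipeline is plain tab-delimited UTF-8 text
(or GMT for gene sets, the MSigDB exchange format).  Readers reject malformed
input with row/column context rather than silently coercing; writer/reader
pairs are exact inverses on valid data, with numbers serialized at full
(shortest round-trip) precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An on-disk artifact or in-memory container violates its contract."""


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, rows = features, columns = samples.

    Wraps a pandas DataFrame whose index holds unique feature ids and whose
    columns hold unique sample ids; all values must be finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = pd.Index(self.data.index.astype(str))
        cols = pd.Index(self.data.columns.astype(str))
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[g]!r}, sample {cols[s]!r}"
            )
        self.data = pd.DataFrame(values, index=idx, columns=cols)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first col = feature id)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    bad = raw.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-numeric cell {raw.iat[g, s]!r} at feature "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    # astype(float) is correctly rounded (to_numeric's fast path is not),
    # keeping write->read bit-faithful
    return ExpressionMatrix(raw.astype(float))


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    # repr-level precision so read(write(m)) is bit-faithful
    matrix.data.to_csv(path, sep="\t", index_label="feature_id",
                       float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Paired tumor/adjacent design


@dataclass
class PairedDesign:
    """Tumor/adjacent sample pairing per patient, plus batch labels per sample."""

    patient_ids: list[str]
    tumor_col: dict[str, str]
    adjacent_col: dict[str, str]
    batch: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValidationError("duplicate patient ids in design")
        tumor = set(self.tumor_col.values())
        adjacent = set(self.adjacent_col.values())
        if tumor & adjacent:
            raise ValidationError(
                f"tumor and adjacent columns overlap: {sorted(tumor & adjacent)[0]!r}"
            )
        for p in self.patient_ids:
            if p not in self.tumor_col or p not in self.adjacent_col:
                raise ValidationError(f"patient {p!r} lacks a tumor or adjacent column")

    @property
    def sample_ids(self) -> list[str]:
        out = [self.tumor_col[p] for p in self.patient_ids]
        out += [self.adjacent_col[p] for p in self.patient_ids]
        return out

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValidationError(f"design samples absent from matrix: {sorted(missing)}")


def read_design(path: str | Path) -> PairedDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "patient_id", "tissue", "batch"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: design header must contain {sorted(required)}")
    tumor, adjacent, batch = {}, {}, {}
    patients: list[str] = []
    for row in df.itertuples(index=False):
        if row.tissue == "tumor":
            tumor[row.patient_id] = row.sample_id
        elif row.tissue == "adjacent":
            adjacent[row.patient_id] = row.sample_id
        else:
            raise ValidationError(f"{path}: unknown tissue label {row.tissue!r}")
        if row.patient_id not in patients:
            patients.append(row.patient_id)
        batch[row.sample_id] = row.batch
    return PairedDesign(patients, tumor, adjacent, batch)


def write_design(design: PairedDesign, path: str | Path) -> None:
    rows = []
    for p in design.patient_ids:
        s = design.tumor_col[p]
        rows.append((s, p, "tumor", design.batch.get(s, "1")))
    for p in design.patient_ids:
        s = design.adjacent_col[p]
        rows.append((s, p, "adjacent", design.batch.get(s, "1")))
    pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "batch"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Target prediction tables


@dataclass
class PredictionTable:
    """(miRNA, gene, score) rows from one in-silico target-prediction program."""

    program_id: str
    table: pd.DataFrame  # columns: mirna_id, gene_id, score

    def __post_init__(self) -> None:
        cols = ["mirna_id", "gene_id", "score"]
        if list(self.table.columns) != cols:
            self.table = self.table.reindex(columns=cols)
        if self.table["score"].isna().any() and len(self.table):
            raise ValidationError(f"program {self.program_id}: missing score")
        dup = self.table.duplicated(subset=["mirna_id", "gene_id"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValidationError(
                f"program {self.program_id}: duplicate pair "
                f"({row.mirna_id!r}, {row.gene_id!r})"
            )

    def targets_of(self, mirna_id: str) -> pd.DataFrame:
        return self.table[self.table["mirna_id"] == mirna_id]

    def scores_of(self, mirna_id: str) -> dict[str, float]:
        sub = self.targets_of(mirna_id)
        return dict(zip(sub["gene_id"], sub["score"].astype(float)))


def read_predictions(path: str | Path, program_id: str) -> PredictionTable:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    required = {"mirna_id", "gene_id", "score"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: prediction header must contain {sorted(required)}")
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    return PredictionTable(program_id, df[["mirna_id", "gene_id", "score"]])


def write_predictions(pred: PredictionTable, path: str | Path) -> None:
    pred.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT) and the pathway hierarchy


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicate genes within a set are collapsed at read time."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {set_id!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (id, description, genes)"
                )
            set_id, desc, *genes = fields
            if set_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                log.warning("GMT set %s: %d duplicate gene(s) collapsed",
                            set_id, len(genes) - len(unique))
            sets[set_id] = unique
            descriptions[set_id] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, genes in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


@dataclass
class PathwayHierarchy:
    """pathway -> group -> category mapping (two levels above individual pathways)."""

    table: pd.DataFrame  # columns: pathway_id, group_id, category_id

    def __post_init__(self) -> None:
        cols = ["pathway_id", "group_id", "category_id"]
        self.table = self.table.reindex(columns=cols)
        dup = self.table["pathway_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"pathway {self.table['pathway_id'][dup].iloc[0]!r} mapped to multiple groups"
            )
        g2c = self.table.groupby("group_id")["category_id"].nunique()
        if (g2c > 1).any():
            raise ValidationError(
                f"group {g2c[g2c > 1].index[0]!r} mapped to multiple categories"
            )

    def group_of(self, pathway_id: str) -> str:
        sub = self.table[self.table["pathway_id"] == pathway_id]
        if sub.empty:
            raise ValidationError(f"pathway {pathway_id!r} absent from hierarchy")
        return sub["group_id"].iloc[0]

    def category_of_group(self, group_id: str) -> str:
        sub = self.table[self.table["group_id"] == group_id]
        if sub.empty:
            raise ValidationError(f"group {group_id!r} absent from hierarchy")
        return sub["category_id"].iloc[0]

    @property
    def pathway_ids(self) -> set[str]:
        return set(self.table["pathway_id"])


def read_hierarchy(path: str | Path) -> PathwayHierarchy:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pathway_id", "group_id", "category_id"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: hierarchy header must contain {sorted(required)}")
    return PathwayHierarchy(df)


def write_hierarchy(hierarchy: PathwayHierarchy, path: str | Path) -> None:
    hierarchy.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical covariates

#: Declared level dictionaries for categorical covariates.  "unknown" entries
#: are parsed as missing and never appear as a level.
CLINICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age_group": (">60", "<=60"),
    "hepatitis": ("HBV", "HCV", "none"),
    "cirrhosis": ("yes", "no"),
    "stage": ("low", "high"),
    "grade": ("low", "high"),
    "tumor_size": (">5cm", "<=5cm"),
    "encapsulation": ("complete", "incomplete"),
    "afp": (">400", "<=400"),
}

CLINICAL_CATEGORICAL = tuple(CLINICAL_LEVELS)
CLINICAL_COLUMNS = CLINICAL_CATEGORICAL + ("relapse_time", "relapse_event")


@dataclass
class ClinicalTable:
    """One row per patient; categorical levels per CLINICAL_LEVELS, NaN = unknown.

    Relapse is encoded as a (time, event) pair; both are NaN when relapse
    status is unknown.
    """

    table: pd.DataFrame  # index: patient_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate patient id {dup!r} in clinical table")
        missing = set(CLINICAL_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"clinical table lacks columns {sorted(missing)}")
        for col, levels in CLINICAL_LEVELS.items():
            vals = self.table[col].dropna()
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(
                    f"clinical column {col!r}: unknown level {sorted(bad)[0]!r}"
                )

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, design: PairedDesign) -> None:
        extra = set(self.patient_ids) - set(design.patient_ids)
        if extra:
            raise ValidationError(f"clinical patients absent from design: {sorted(extra)}")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col="patient_id", dtype=str,
                     keep_default_na=False)
    out = pd.DataFrame(index=df.index.astype(str))
    for col in CLINICAL_CATEGORICAL:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing clinical column {col!r}")
        vals = df[col].mask(df[col].isin(["unknown", ""]))
        out[col] = vals
    for col in ("relapse_time", "relapse_event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing clinical column {col!r}")
        vals = df[col].mask(df[col].isin(["unknown", ""]))
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: unparseable {col}: {exc}") from None
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.table.copy()
    for col in CLINICAL_CATEGORICAL:
        out[col] = out[col].fillna("unknown")
    out.to_csv(path, sep="\t", index_label="patient_id", na_rep="unknown")
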
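"""Core data types and file I/O for the ATRA-sensitivity pipeline.

The pipeline exchanges four plain-text formats:

* growth tables — long-format TSV, one optical-density reading per row
  (columns ``cell_line, concentration_uM, day, replicate, od``);
* expression matrices — TSV, genes in rows, samples in columns;
* sample annotations — TSV with phenotype labels per sample;
* gene sets — standard GMT.

Concentrations are in micromolar; concentration 0 is the vehicle (DMSO)
sentinel. All parsers raise typed errors on malformed input rather than
silently dropping rows, and each writer round-trips through its parser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("atrasens")

GROWTH_COLUMNS = ["cell_line", "concentration_uM", "day", "replicate", "od"]
ANNOTATION_COLUMNS = ["sample", "lineage", "er", "her2", "subtype"]

LINEAGES = {"Luminal", "Basal", "unknown"}
RECEPTOR_STATUS = {"+", "-", "unknown"}
SUBTYPES = {"LumA", "LumB", "HER2", "TN", "Lum", "unknown"}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class AtrasensError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(AtrasensError):
    """A file is missing required columns or fields."""


class FormatError(AtrasensError):
    """A file line cannot be interpreted in its declared format."""


class ValidationError(AtrasensError):
    """Parsed data violates a domain invariant."""


class NonGrowthError(AtrasensError):
    """A culture shows no net growth, so a growth-based quantity is undefined."""


class NormalizationError(AtrasensError):
    """Vehicle normalization is impossible (no net vehicle growth)."""


# ---------------------------------------------------------------------------
# GrowthAssay
# ---------------------------------------------------------------------------

@dataclass
class GrowthAssay:
    """Replicate-level optical densities for one cell line.

    ``data`` is tidy: one row per (concentration, day, replicate) with the
    measured optical density (arbitrary absorbance units).
    """

    cell_line: str
    data: pd.DataFrame  # columns: concentration_uM, day, replicate, od

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"concentration_uM", "day", "replicate", "od"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"growth assay missing columns: {sorted(missing)}")
        if (self.data["od"] < 0).any():
            raise ValidationError(
                f"negative optical density in assay for {self.cell_line!r}"
            )
        if 0.0 not in set(self.data["concentration_uM"]):
            raise ValidationError(
                f"no vehicle (concentration 0) rows for cell line {self.cell_line!r}"
            )
        if self.data["day"].nunique() < 2:
            raise ValidationError(
                f"assay for {self.cell_line!r} needs >= 2 distinct days"
            )

    @property
    def concentrations(self) -> list[float]:
        return sorted(self.data["concentration_uM"].unique())

    @property
    def days(self) -> list[float]:
        return sorted(self.data["day"].unique())

    def mean_od(self, concentration: float, day: float) -> float:
        """Replicate-mean OD at one (concentration, day) cell."""
        mask = (self.data["concentration_uM"] == concentration) & (
            self.data["day"] == day
        )
        sub = self.data.loc[mask, "od"]
        if sub.empty:
            raise ValidationError(
                f"no readings at concentration {concentration} day {day} "
                f"for {self.cell_line!r}"
            )
        return float(sub.mean())


def parse_growth_table(path: str | Path) -> dict[str, GrowthAssay]:
    """Parse a long-format growth TSV into one :class:`GrowthAssay` per line.

    Row order is irrelevant; cell lines are returned in first-appearance order.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"growth table {path} missing columns: {missing}")
    if df.empty:
        return {}
    for col in ("concentration_uM", "day", "od"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"growth table column {col!r} is not numeric")
    if (df["od"] < 0).any():
        bad = df.index[df["od"] < 0][0]
        raise ValidationError(f"negative od at row {bad} of {path}")
    assays: dict[str, GrowthAssay] = {}
    for line, sub in df.groupby("cell_line", sort=False):
        assays[str(line)] = GrowthAssay(
            cell_line=str(line),
            data=sub[["concentration_uM", "day", "replicate", "od"]].copy(),
        )
    return assays


def write_growth_table(assays: Mapping[str, GrowthAssay] | Iterable[GrowthAssay],
                       path: str | Path) -> None:
    """Write assays back to the long-format growth TSV."""
    if isinstance(assays, Mapping):
        assays = list(assays.values())
    frames = []
    for assay in assays:
        sub = assay.data.copy()
        sub.insert(0, "cell_line", assay.cell_line)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.17g")


# ---------------------------------------------------------------------------
# ExpressionMatrix & SampleAnnotation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a platform tag.

    Values are log2 intensity (microarray) or fpkm / log2(fpkm+1) (rnaseq)
    depending on the transform applied at parse time.
    """

    values: pd.DataFrame  # index: genes, columns: samples
    platform: str = "other"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], platform=self.platform)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], platform=self.platform)


def parse_expression_matrix(path: str | Path, transform: str = "none",
                            platform: str = "other") -> ExpressionMatrix:
    """Parse a genes-x-samples TSV.

    With ``transform="log2p1"`` every value v is stored as log2(v+1) (the
    variance-stabilizing choice for fpkm). Duplicate gene rows collapse by
    mean with a logged warning.
    """
    if transform not in {"none", "log2p1"}:
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    try:
        values = df.astype(float)
    except ValueError as exc:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.nonzero(bad.to_numpy())[0][0])
                raise FormatError(
                    f"non-numeric cell at gene row {df.index[i]!r}, "
                    f"sample column {col!r} in {path}"
                ) from exc
        raise FormatError(f"non-numeric cell in {path}") from exc
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.warning(
            "collapsing %d duplicate gene rows by mean in %s", n_dup, path
        )
        values = values.groupby(level=0, sort=False).mean()
    if transform == "log2p1":
        if (values < 0).any().any():
            raise ValidationError("log2p1 transform requires nonnegative values")
        values = np.log2(values + 1.0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    # %.17g round-trips doubles exactly through the text format
    out.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class SampleAnnotation:
    """Phenotype labels per sample.

    ``table`` is indexed by sample id with columns lineage, er, her2, subtype
    plus ``tertile`` / ``group`` columns that are only filled in by the
    growth-scoring stage.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("lineage", "er", "her2", "subtype"):
            if col not in self.table.columns:
                self.table[col] = "unknown"
        for col in ("tertile", "group"):
            if col not in self.table.columns:
                self.table[col] = "unset"
        bad = set(self.table["lineage"]) - LINEAGES
        if bad:
            raise ValidationError(f"unknown lineage labels: {sorted(bad)}")
        for col in ("er", "her2"):
            bad = set(self.table[col]) - RECEPTOR_STATUS
            if bad:
                raise ValidationError(f"unknown {col} labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.samples) - set(matrix.samples)
        if missing:
            raise ValidationError(
                f"annotated samples absent from matrix: {sorted(missing)}"
            )

    def select(self, **criteria: str | Sequence[str]) -> list[str]:
        """Sample ids matching all criteria, e.g. ``lineage="Luminal"``."""
        mask = pd.Series(True, index=self.table.index)
        for col, wanted in criteria.items():
            if col not in self.table.columns:
                raise KeyError(f"no annotation column {col!r}")
            if isinstance(wanted, str):
                wanted = [wanted]
            mask &= self.table[col].isin(list(wanted))
        return list(self.table.index[mask])


def parse_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise SchemaError(f"annotation table {path} missing 'sample' column")
    df = df.set_index("sample")
    return SampleAnnotation(df)


def write_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    out = annot.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GeneSet / GMT
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """A named gene list, optionally signed by direction of association."""

    name: str
    genes: list[str]
    direction: str = "unsigned"  # up | down | unsigned
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")
        if self.direction not in {"up", "down", "unsigned"}:
            raise ValidationError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def parse_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a standard GMT file: name, description, tab-separated gene ids.

    Duplicate genes within a line are removed, first occurrence wins.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} of {path} has {len(fields)} fields (< 3)"
                )
            name, description = fields[0], fields[1]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            if not seen:
                raise FormatError(
                    f"GMT line {lineno} of {path} defines an empty gene set"
                )
            sets.append(GeneSet(name=name, genes=list(seen),
                                description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = s.description or s.direction
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# SliceCohort
# ---------------------------------------------------------------------------

@dataclass
class SlicePatient:
    """One patient's paired vehicle/ATRA tissue-slice measurements."""

    patient_id: str
    subtype: str  # "Lum" | "TN"
    expr_vehicle: pd.Series
    expr_atra: pd.Series
    ki67_fields: dict[str, list[tuple[int, int]]] | None = None
    # ki67_fields: condition ("vehicle"|"atra") -> [(positive, total), ...]

    def __post_init__(self) -> None:
        if not self.expr_vehicle.index.equals(self.expr_atra.index):
            raise ValidationError(
                f"patient {self.patient_id!r}: vehicle/ATRA gene universes differ"
            )
        if self.ki67_fields is not None:
            for cond, fields in self.ki67_fields.items():
                for pos, tot in fields:
                    if not (0 <= pos <= tot):
                        raise ValidationError(
                            f"patient {self.patient_id!r}: bad Ki67 count "
                            f"({pos}/{tot}) in condition {cond!r}"
                        )


@dataclass
class SliceCohort:
    """Paired vehicle/ATRA slice expression plus Ki67 counts per patient."""

    patients: list[SlicePatient] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.patients:
            genes = self.patients[0].expr_vehicle.index
            for p in self.patients[1:]:
                if not p.expr_vehicle.index.equals(genes):
                    raise ValidationError(
                        "slice cohort patients do not share one gene universe"
                    )

    @property
    def genes(self) -> list[str]:
        return list(self.patients[0].expr_vehicle.index) if self.patients else []

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subtype_of(self, patient_id: str) -> str:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p.subtype
        raise KeyError(patient_id)

    def filter_subtype(self, subtype: str) -> "SliceCohort":
        return SliceCohort([p for p in self.patients if p.subtype == subtype])

    def log2_ratio_matrix(self) -> pd.DataFrame:
        """Genes x patients matrix of log2(ATRA) - log2(vehicle).

        Expression values are assumed already on the log2 scale, so the
        paired difference is the per-gene log2 treatment ratio.
        """
        cols = {p.patient_id: p.expr_atra - p.expr_vehicle for p in self.patients}
        return pd.DataFrame(cols)


def parse_slice_cohort(expr_path: str | Path, subtype_path: str | Path,
                       ki67_path: str | Path | None = None) -> SliceCohort:
    """Read a slice cohort from its three TSV pieces.

    ``expr_path``: genes x (patient:condition) TSV with columns named
    ``<patient>:vehicle`` / ``<patient>:atra``. ``subtype_path``: columns
    patient, subtype. ``ki67_path`` (optional): columns patient, condition,
    field, positive, total.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0,
                       float_precision="round_trip")
    subtype_df = pd.read_csv(subtype_path, sep="\t", dtype=str)
    if not {"patient", "subtype"} <= set(subtype_df.columns):
        raise SchemaError(f"{subtype_path} needs columns patient, subtype")
    subtypes = dict(zip(subtype_df["patient"], subtype_df["subtype"]))

    ki67: dict[str, dict[str, list[tuple[int, int]]]] = {}
    if ki67_path is not None:
        kdf = pd.read_csv(ki67_path, sep="\t")
        need = {"patient", "condition", "field", "positive", "total"}
        if not need <= set(kdf.columns):
            raise SchemaError(f"{ki67_path} needs columns {sorted(need)}")
        for _, row in kdf.iterrows():
            ki67.setdefault(str(row["patient"]), {}).setdefault(
                str(row["condition"]), []
            ).append((int(row["positive"]), int(row["total"])))

    patients = []
    for pid in subtype_df["patient"]:
        v_col, a_col = f"{pid}:vehicle", f"{pid}:atra"
        if v_col not in expr.columns or a_col not in expr.columns:
            raise SchemaError(
                f"expression matrix lacks paired columns for patient {pid!r}"
            )
        patients.append(SlicePatient(
            patient_id=str(pid),
            subtype=subtypes[pid],
            expr_vehicle=expr[v_col].astype(float),
            expr_atra=expr[a_col].astype(float),
            ki67_fields=ki67.get(str(pid)),
        ))
    return SliceCohort(patients)


def write_slice_cohort(cohort: SliceCohort, expr_path: str | Path,
                       subtype_path: str | Path,
                       ki67_path: str | Path | None = None) -> None:
    cols = {}
    for p in cohort.patients:
        cols[f"{p.patient_id}:vehicle"] = p.expr_vehicle
        cols[f"{p.patient_id}:atra"] = p.expr_atra
    expr = pd.DataFrame(cols)
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep="\t", float_format="%.17g")

    pd.DataFrame({
        "patient": cohort.patient_ids,
        "subtype": [p.subtype for p in cohort.patients],
    }).to_csv(subtype_path, sep="\t", index=False)

    if ki67_path is not None:
        rows = []
        for p in cohort.patients:
            if p.ki67_fields is None:
                continue
            for cond, fields in p.ki67_fields.items():
                for i, (pos, tot) in enumerate(fields):
                    rows.append((p.patient_id, cond, i, pos, tot))
        pd.DataFrame(
            rows, columns=["patient", "condition", "field", "positive", "total"]
        ).to_csv(ki67_path, sep="\t", index=False)
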
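"""Expression-matrix containers and tab-delimited / XLSX readers.

All cross-object alignment downstream is by probe / sample identifier, never
by position. Matrices carry an explicit intensity scale (``log2`` or
``linear``) so that scale contracts can be enforced at module boundaries:
differential testing runs on log2 intensities while signature averaging and
mixture deconvolution operate on linear intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["log2", "linear"]

METADATA_COLUMNS = [
    "sample_id",
    "study_id",
    "disease",
    "lesional",
    "subject_id",
    "timepoint",
    "severity",
    "tissue_layer",
]


class ExpressionIOError(ValueError):
    """Raised when an expression table violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A probe x sample matrix of normalized intensities.

    Parameters
    ----------
    data
        DataFrame with probe ids as index and sample ids as columns.
    scale
        ``"log2"`` (post-RMA) or ``"linear"`` (anti-logged intensities).
        Linear-scale values must be strictly positive.
    """

    data: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ExpressionIOError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate probe ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionIOError(
                f"non-finite value at probe {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.scale == "linear" and values.size and (values <= 0).any():
            bad = np.argwhere(values <= 0)[0]
            raise ExpressionIOError(
                "linear-scale values must be strictly positive; offending cell "
                f"probe {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        probes = [p for p in probes if p in self.data.index]
        return ExpressionMatrix(self.data.loc[probes], self.scale)


@dataclass
class SignatureMatrix:
    """Probe x cell-type matrix of averaged linear-scale intensities.

    The design matrix for deconvolution: each column is a cell type's mean
    expression profile over its reference replicates (linear scale), restricted
    to the selected marker-probe union.
    """

    data: pd.DataFrame  # probes x cell types, linear scale
    G: int | None = None
    condition_number: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ExpressionIOError("duplicate probe ids in signature")
        if self.data.columns.has_duplicates:
            raise ExpressionIOError("duplicate cell-type columns in signature")
        values = self.data.to_numpy()
        if values.size and ((values <= 0).any() or not np.isfinite(values).all()):
            raise ExpressionIOError("signature values must be finite and > 0 (linear scale)")

    @property
    def probe_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.data.columns.tolist()


@dataclass
class ProbeMap:
    """Many-to-many probe identifier mapping (e.g. across array platforms)."""

    records: pd.DataFrame  # columns: source_id, target_id

    def __post_init__(self) -> None:
        req = {"source_id", "target_id"}
        if not req.issubset(self.records.columns):
            raise ExpressionIOError("probe map needs source_id and target_id columns")
        self.records = self.records.drop_duplicates(ignore_index=True)


def read_expression_table(path: str | Path, scale: Scale) -> ExpressionMatrix:
    """Read a tab-delimited expression table (first column probe ids).

    Duplicate probe rows are collapsed by their mean with a logged warning;
    duplicate sample columns or non-numeric cells are errors. ``scale``
    declares how the stored intensities are to be interpreted.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently rename these
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ExpressionIOError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    missing = df.isna()
    if bad.to_numpy().any() or missing.to_numpy().any():
        mask = (bad | missing).to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ExpressionIOError(
            f"non-numeric value {df.iat[r, c]!r} at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate probe rows by mean", path, n_dup)
        warnings.warn(f"{path}: {n_dup} duplicate probe rows collapsed by mean")
        # groupby(sort=False) keeps first-appearance order
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric, scale)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV at 12 significant digits."""
    matrix.data.to_csv(path, sep="\t", float_format="%.12g", index_label="probe_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV; returns a frame indexed by sample_id."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in md.columns:
        raise ExpressionIOError("metadata must have a sample_id column")
    if md["sample_id"].duplicated().any():
        raise ExpressionIOError("duplicate sample_id in metadata")
    if "timepoint" in md.columns:
        md["timepoint"] = pd.to_numeric(md["timepoint"], errors="coerce")
    return md.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    """Check every metadata sample is present in its companion matrix."""
    missing = set(metadata.index) - set(matrix.sample_ids)
    if missing:
        raise ExpressionIOError(f"metadata samples absent from matrix: {sorted(missing)[:5]}")


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionIOError("probe map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["source_id", "target_id"]
    return ProbeMap(df)


def read_signature_table(path: str | Path) -> SignatureMatrix:
    """Read a signature matrix from TSV (probe ids, then one column per type)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df)


def write_signature_table(sig: SignatureMatrix, path: str | Path) -> None:
    sig.data.to_csv(path, sep="\t", float_format="%.12g", index_label="probe_id")


def read_signature_xlsx(
    path: str | Path,
    sheet: int | str = 0,
    n_annotation_columns: int = 0,
) -> SignatureMatrix:
    """Read a published signature-matrix workbook.

    The first column holds probe ids; ``n_annotation_columns`` further columns
    (gene symbols etc.) may precede the per-cell-type intensity columns and are
    skipped. Values are linear-scale mean intensities.
    """
    import openpyxl

    # pandas silently renames duplicate columns, so check the raw header first
    wb = openpyxl.load_workbook(path, read_only=True)
    ws = wb[sheet] if isinstance(sheet, str) else wb.worksheets[sheet]
    header = [c.value for c in next(ws.iter_rows(max_row=1))]
    wb.close()
    type_names = header[1 + n_annotation_columns :]
    if len(set(type_names)) != len(type_names):
        dups = sorted({t for t in type_names if type_names.count(t) > 1})
        raise ExpressionIOError(f"duplicate cell-type column: {dups}")
    df = pd.read_excel(path, sheet_name=sheet, index_col=0, engine="openpyxl")
    if n_annotation_columns:
        df = df.iloc[:, n_annotation_columns:]
    if df.index.isna().any() or (df.index.astype(str).str.strip() == "").any():
        raise ExpressionIOError("blank probe id in signature workbook")
    df = df.apply(pd.to_numeric)
    return SignatureMatrix(df)


def map_probes(
    matrix: ExpressionMatrix,
    probe_map: ProbeMap,
    collision_policy: Literal["mean", "max", "first"] = "mean",
) -> ExpressionMatrix:
    """Re-key matrix rows to target identifiers via a probe map.

    Many-to-one collisions are resolved by ``collision_policy``; unmapped
    source rows are dropped (count logged). Errors if no probe maps at all.
    """
    if collision_policy not in ("mean", "max", "first"):
        raise ExpressionIOError(f"unknown collision policy {collision_policy!r}")
    rec = probe_map.records
    rec = rec[rec["source_id"].isin(matrix.data.index)]
    if rec.empty:
        raise ExpressionIOError("probe map covers none of the matrix probes")
    n_unmapped = matrix.shape[0] - matrix.data.index.isin(rec["source_id"]).sum()
    if n_unmapped:
        logger.info("map_probes: dropping %d unmapped probes", n_unmapped)
    expanded = matrix.data.loc[rec["source_id"]].set_axis(rec["target_id"].to_numpy(), axis=0)
    grouped = expanded.groupby(level=0, sort=False)
    if collision_policy == "mean":
        out = grouped.mean()
    elif collision_policy == "max":
        out = grouped.max()
    else:
        out = grouped.first()
    return ExpressionMatrix(out, matrix.scale)


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Anti-log a log2-scale matrix (elementwise 2**x)."""
    if matrix.scale != "log2":
        raise ExpressionIOError("to_linear expects a log2-scale matrix")
    return ExpressionMatrix(np.exp2(matrix.data), "linear")


def to_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform a linear-scale matrix; non-positive values are errors."""
    if matrix.scale != "linear":
        raise ExpressionIOError("to_log2 expects a linear-scale matrix")
    if (matrix.data.to_numpy() <= 0).any():
        raise ExpressionIOError("to_log2: non-positive value")
    return ExpressionMatrix(np.log2(matrix.data), "log2")


def as_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a linear-scale view regardless of the declared input scale."""
    return matrix if matrix.scale == "linear" else to_linear(matrix)
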
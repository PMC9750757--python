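"""Panel reading, assay-level QC, extraction, filtering and transformation.

Preprocessing follows the fixed order used throughout the analysis:
extract the immune panel -> drop analytes with >20% missing values ->
impute remaining gaps with the per-analyte observed minimum (a detection
limit proxy) -> log2 transform.  :func:`preprocess_panel` drives the
sequence; the individual steps are exposed for testing and reuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PanelError

__all__ = [
    "SampleQC",
    "read_expression",
    "read_manifest",
    "read_qc",
    "qc_filter",
    "extract_panel",
    "filter_missingness",
    "impute_min",
    "log2_transform",
    "preprocess_panel",
]

HYB_RANGE = (0.4, 2.5)
CAL_RANGE = (0.8, 1.2)
MAX_MISSING_FRACTION = 0.20


@dataclass(frozen=True)
class SampleQC:
    """Per-record assay QC: hybridization and calibration scale factors."""

    sample_id: str
    hybridization_scale_factor: float
    calibration_scale_factor: float

    def __post_init__(self):
        if self.hybridization_scale_factor <= 0 or self.calibration_scale_factor <= 0:
            raise PanelError(f"{self.sample_id}: scale factors must be positive")


def read_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    required = {"analyte_id", "family", "role"}
    if not required.issubset(df.columns):
        raise PanelError(
            f"manifest missing columns: {sorted(required - set(df.columns))}"
        )
    if df["analyte_id"].duplicated().any():
        raise PanelError("duplicate analyte_id in manifest")
    return df.set_index("analyte_id")


def read_qc(qc_path) -> list[SampleQC]:
    df = pd.read_csv(qc_path)
    return [
        SampleQC(str(r["sample_id"]), float(r["hyb_sf"]), float(r["cal_sf"]))
        for _, r in df.iterrows()
    ]


def read_expression(matrix_path, metadata_path, manifest_path):
    """Read an expression TSV (analytes x samples), sample metadata CSV and
    manifest CSV into aligned structures.

    Blank/NA cells become masked missing values.  Samples present in the
    matrix but absent from the metadata are a contract violation.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        raise PanelError(f"{matrix_path}: duplicate analyte ids")
    if values.columns.duplicated().any():
        raise PanelError(f"{matrix_path}: duplicate sample ids")
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()
                              & values[col].notna()]
            raise PanelError(
                f"{matrix_path}: non-numeric cell in column {col!r}"
                + (f" at row {bad.index[0]!r}" if len(bad) else "")
            )
    meta = pd.read_csv(metadata_path, index_col=0)
    unmatched = values.columns.difference(meta.index)
    if len(unmatched):
        raise PanelError(
            f"{metadata_path}: metadata lacks matrix samples: {list(unmatched)[:5]}"
        )
    manifest = read_manifest(manifest_path)
    matrix = ExpressionMatrix(
        values=values, scale="raw", sample_meta=meta.loc[values.columns]
    )
    return matrix, manifest, meta


def qc_filter(
    qc: Iterable[SampleQC],
    hyb_range: tuple = HYB_RANGE,
    cal_range: tuple = CAL_RANGE,
):
    """Partition QC records by the accepted scale-factor ranges.

    A record passes iff both factors lie inside the closed intervals
    (hybridization 0.4-2.5, calibration 0.8-1.2 by default).  Returns
    (pass_ids, fail_ids, pass_fraction).
    """
    qc = list(qc)
    if not qc:
        raise PanelError("qc_filter: empty QC input")
    if hyb_range[0] > hyb_range[1] or cal_range[0] > cal_range[1]:
        raise PanelError("qc_filter: ranges must be ordered (low, high)")
    pass_ids, fail_ids = [], []
    for rec in qc:
        ok = (
            hyb_range[0] <= rec.hybridization_scale_factor <= hyb_range[1]
            and cal_range[0] <= rec.calibration_scale_factor <= cal_range[1]
        )
        (pass_ids if ok else fail_ids).append(rec.sample_id)
    return pass_ids, fail_ids, len(pass_ids) / len(qc)


def extract_panel(
    matrix: ExpressionMatrix,
    manifest: pd.DataFrame,
    roles: Iterable[str] = ("mediator", "soluble_receptor"),
) -> ExpressionMatrix:
    """Sub-matrix of analytes whose manifest role is in ``roles``, preserving
    matrix row order.  The result carries family counts in
    ``matrix.family_counts`` for reporting."""
    roles = set(roles)
    annotated = manifest.index.intersection(matrix.values.index)
    wanted = manifest.loc[annotated]
    wanted = wanted[wanted["role"].isin(roles)]
    keep = [a for a in matrix.values.index if a in set(wanted.index)]
    if not keep:
        raise PanelError(f"extract_panel: no analytes with roles {sorted(roles)}")
    sub = matrix.subset_analytes(keep)
    sub.family_counts = manifest.loc[keep, "family"].value_counts().to_dict()
    return sub


def filter_missingness(
    matrix: ExpressionMatrix, max_missing_fraction: float = MAX_MISSING_FRACTION
):
    """Remove analytes with strictly more than ``max_missing_fraction`` of
    values missing; exactly at the threshold is retained.  Returns
    (filtered matrix, removed analyte ids)."""
    if matrix.n_analytes == 0:
        raise PanelError("filter_missingness: empty matrix")
    frac = matrix.mask.mean(axis=1)
    removed = list(frac.index[frac > max_missing_fraction])
    kept = [a for a in matrix.values.index if a not in set(removed)]
    if not kept:
        raise PanelError("filter_missingness: all analytes removed")
    return matrix.subset_analytes(kept), removed


def impute_min(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill each missing cell with that analyte's observed minimum (the
    detection-limit reading of missingness); observed cells unchanged."""
    values = matrix.values
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        raise PanelError(
            f"impute_min: analytes with no observed values: "
            f"{list(values.index[all_missing])[:5]}"
        )
    mins = values.min(axis=1)
    filled = values.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    return matrix.with_values(filled)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; requires a raw/normalized matrix of positives."""
    if matrix.scale == "log2":
        raise PanelError("log2_transform: matrix already log2-transformed")
    vals = matrix.values.to_numpy(dtype=float)
    nonpos = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
    if len(nonpos):
        i, j = nonpos[0]
        raise PanelError(
            f"log2_transform: non-positive value at analyte "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
        )
    return matrix.with_values(np.log2(matrix.values), scale="log2")


def preprocess_panel(
    matrix: ExpressionMatrix,
    manifest: pd.DataFrame,
    roles: Iterable[str] = ("mediator", "soluble_receptor"),
    max_missing_fraction: float = MAX_MISSING_FRACTION,
    sample_ids: Optional[Iterable[str]] = None,
):
    """Fixed-order preprocessing driver: extract -> missingness filter ->
    minimum imputation -> log2.  ``sample_ids`` restricts to an analysis
    subset first (the missingness filter is re-applied per analysis).

    Returns (log2 matrix, report dict with the counts at each step).
    """
    if matrix.scale == "log2":
        raise PanelError("preprocess_panel: input must be raw/normalized, not log2")
    if sample_ids is not None:
        matrix = matrix.subset_samples(sample_ids)
    report = {"n_input_analytes": matrix.n_analytes, "n_samples": matrix.n_samples}
    panel = extract_panel(matrix, manifest, roles)
    report["n_panel_analytes"] = panel.n_analytes
    report["family_counts"] = getattr(panel, "family_counts", {})
    filtered, removed = filter_missingness(panel, max_missing_fraction)
    report["n_removed_missingness"] = len(removed)
    report["removed_analytes"] = removed
    imputed = impute_min(filtered)
    out = log2_transform(imputed)
    report["n_output_analytes"] = out.n_analytes
    return out, report
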
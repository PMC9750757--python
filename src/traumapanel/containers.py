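"""Core data containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, an analytes-by-samples grid
backed by a pandas DataFrame in which ``NaN`` marks a missing (censored or
unreported) measurement.  A ``scale`` tag tracks where the matrix sits in the
preprocessing pipeline (``raw`` → ``normalized`` → ``log2``) so that
transformations can refuse to run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MEDIATOR_FAMILIES = ("IL", "CCL", "CXCL", "IFN", "TNFSF")
RECEPTOR_FAMILIES = ("IL_R", "IFN_R", "TNFRSF")
FAMILIES = MEDIATOR_FAMILIES + RECEPTOR_FAMILIES

OUTCOME_GROUPS = ("ENS", "R", "NR", "CONTROL")
VALID_SCALES = ("raw", "normalized", "log2")


class PanelError(ValueError):
    """Raised on contract violations in panel handling."""


def role_for_family(family: str) -> str:
    """Mediator families are cytokine/chemokine ligands; *_R/TNFRSF are
    soluble receptors; anything else is outside the immune panel."""
    if family in MEDIATOR_FAMILIES:
        return "mediator"
    if family in RECEPTOR_FAMILIES:
        return "soluble_receptor"
    return "other"


@dataclass(frozen=True)
class AnalyteAnnotation:
    """One manifest row: panel membership of a single analyte."""

    analyte_id: str
    symbol: str
    family: str
    role: str

    def __post_init__(self):
        expected = role_for_family(self.family)
        if self.role != expected:
            raise PanelError(
                f"analyte {self.analyte_id}: role {self.role!r} inconsistent "
                f"with family {self.family!r} (expected {expected!r})"
            )


def manifest_to_frame(manifest: Iterable[AnalyteAnnotation]) -> pd.DataFrame:
    rows = [
        {"analyte_id": a.analyte_id, "symbol": a.symbol, "family": a.family, "role": a.role}
        for a in manifest
    ]
    df = pd.DataFrame(rows)
    if df["analyte_id"].duplicated().any():
        dupes = df.loc[df["analyte_id"].duplicated(), "analyte_id"].tolist()
        raise PanelError(f"duplicate analyte ids in manifest: {dupes}")
    return df.set_index("analyte_id")


@dataclass(frozen=True)
class Patient:
    """Demographics plus the outcome fields that drive group classification.

    ``death_time`` is hours from admission (None if alive at follow-up);
    ``alive_at_30d`` must be consistent with it (death within 720 h implies
    not alive at 30 days).
    """

    patient_id: str
    age: float
    sex: str  # "M" | "F"
    iss: int
    arm: str  # "TP" | "SOC"
    alive_at_30d: bool
    death_time: Optional[float] = None  # hours
    icu_days: float = 0.0
    vent_days: float = 0.0
    hospital_days: float = 0.0
    is_low_iss_control: bool = False

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"patient {self.patient_id}: sex must be M or F")
        if not 0 <= self.iss <= 75:
            raise ValueError(f"patient {self.patient_id}: ISS {self.iss} outside 0-75")
        if self.death_time is not None and self.death_time <= 720 and self.alive_at_30d:
            raise ValueError(
                f"patient {self.patient_id}: death at {self.death_time} h "
                "inconsistent with alive_at_30d"
            )


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "iss": p.iss,
            "arm": p.arm,
            "alive_at_30d": p.alive_at_30d,
            "death_time": p.death_time if p.death_time is not None else np.nan,
            "icu_days": p.icu_days,
            "vent_days": p.vent_days,
            "hospital_days": p.hospital_days,
            "is_low_iss_control": p.is_low_iss_control,
        }
        for p in patients
    ]
    return pd.DataFrame(rows).set_index("patient_id")


def patients_from_frame(df: pd.DataFrame) -> list[Patient]:
    out = []
    for pid, row in df.iterrows():
        dt = row.get("death_time", np.nan)
        out.append(
            Patient(
                patient_id=str(pid),
                age=float(row["age"]),
                sex=str(row["sex"]),
                iss=int(row["iss"]),
                arm=str(row["arm"]),
                alive_at_30d=bool(row["alive_at_30d"]),
                death_time=None if pd.isna(dt) else float(dt),
                icu_days=float(row.get("icu_days", 0.0)),
                vent_days=float(row.get("vent_days", 0.0)),
                hospital_days=float(row.get("hospital_days", 0.0)),
                is_low_iss_control=bool(row.get("is_low_iss_control", False)),
            )
        )
    return out


@dataclass
class ExpressionMatrix:
    """Analytes x samples expression grid.

    ``values``: DataFrame indexed by analyte_id with sample_id columns; NaN is
    the missingness mask.  ``sample_meta``: per-sample metadata indexed by
    sample_id, carrying at least ``patient_id`` and ``timepoint``.
    """

    values: pd.DataFrame
    scale: str = "raw"
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.scale not in VALID_SCALES:
            raise PanelError(f"unknown scale tag {self.scale!r}")
        if self.values.columns.duplicated().any():
            raise PanelError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise PanelError("duplicate analyte ids")
        if self.scale in ("raw", "normalized"):
            vals = self.values.to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed <= 0).any():
                raise PanelError(f"{self.scale} matrix contains non-positive values")
        if not self.sample_meta.empty:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise PanelError(f"samples missing from metadata: {list(missing)[:5]}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.values.isna()

    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: Optional[str] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            scale=self.scale if scale is None else scale,
            sample_meta=self.sample_meta.loc[values.columns]
            if not self.sample_meta.empty
            else self.sample_meta,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids]
        return self.with_values(self.values[ids])

    def subset_analytes(self, analyte_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [a for a in analyte_ids]
        return self.with_values(self.values.loc[ids])
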
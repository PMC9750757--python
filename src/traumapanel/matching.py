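"""Outcome-group classification, ISS stratification and case-control matching.

Outcome groups: early non-survivors (ENS) died within 72 h of admission;
non-resolvers (NR) died after 72 h or needed >= 7 ICU days; resolvers (R)
were alive at 30 days with < 7 ICU days; CONTROL is reserved for the
low-ISS comparison arm (ISS <= 1, externally flagged).

Matching is greedy nearest-neighbor without replacement on a
tolerance-normalized (age, ISS) distance with exact sex matching, the
standard caliper approach when the original tool's algorithm is not
documented.  An optional many-to-one phase lets leftover cases reuse the
nearest already-matched control, producing balanced-but-unequal group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Patient
from .differential import compare_two_groups

__all__ = ["MatchSpec", "MatchResult", "classify_outcome", "iss_stratum",
           "match_case_control"]

ENS_CUTOFF_HOURS = 72.0
ICU_CUTOFF_DAYS = 7.0


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchSpec:
    age_tolerance: float = 10.0  # years
    iss_tolerance: float = 8.0  # points
    sex_exact: bool = True
    allow_many_to_one: bool = False

    def __post_init__(self):
        if self.age_tolerance < 0 or self.iss_tolerance < 0:
            raise ValueError("MatchSpec: tolerances must be >= 0")


@dataclass
class MatchResult:
    matched_cases: list
    matched_controls: list
    pairs: list  # (case_id, control_id)
    balance: dict  # post-match p-values for age, iss, sex


def classify_outcome(p: Patient) -> str:
    """Assign ENS / R / NR / CONTROL from survival and ICU-course fields."""
    if p.is_low_iss_control:
        if p.iss > 1:
            raise ClassificationError(
                f"{p.patient_id}: control flag with ISS {p.iss} > 1"
            )
        return "CONTROL"
    if p.death_time is not None and p.death_time <= ENS_CUTOFF_HOURS:
        return "ENS"
    died_late = p.death_time is not None and p.death_time > ENS_CUTOFF_HOURS
    if died_late or p.icu_days >= ICU_CUTOFF_DAYS:
        return "NR"
    if p.alive_at_30d and p.icu_days < ICU_CUTOFF_DAYS:
        return "R"
    raise ClassificationError(
        f"{p.patient_id}: inconsistent outcome fields "
        f"(alive_at_30d={p.alive_at_30d}, death_time={p.death_time}, "
        f"icu_days={p.icu_days})"
    )


def iss_stratum(iss: int) -> str:
    """Injury-severity strata: mild 1-15, moderate 16-24, severe >= 25."""
    if not 1 <= iss <= 75:
        raise ValueError(f"iss_stratum: ISS {iss} outside 1-75")
    if iss <= 15:
        return "mild"
    if iss <= 24:
        return "moderate"
    return "severe"


def _distance(case: Patient, control: Patient, spec: MatchSpec) -> float:
    da = (case.age - control.age) / max(spec.age_tolerance, 1e-12)
    di = (case.iss - control.iss) / max(spec.iss_tolerance, 1e-12)
    return float(np.hypot(da, di))


def _admissible(case: Patient, control: Patient, spec: MatchSpec) -> bool:
    if spec.sex_exact and case.sex != control.sex:
        return False
    return (
        abs(case.age - control.age) <= spec.age_tolerance
        and abs(case.iss - control.iss) <= spec.iss_tolerance
    )


def match_case_control(
    cases: list, controls: list, spec: MatchSpec = MatchSpec(), seed: int = 0
) -> MatchResult:
    """Greedy caliper matching of cases to controls on (age, ISS, sex).

    Case processing order is shuffled under ``seed``; each case takes the
    nearest admissible unmatched control (ties broken by lowest control id).
    With ``allow_many_to_one``, cases left unmatched may then reuse the
    nearest admissible control regardless of its matched status.  Patients
    with no admissible partner are dropped; an empty match is returned with
    a warning rather than an error.
    """
    if not cases or not controls:
        raise ValueError("match_case_control: both lists must be nonempty")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(cases)))
    taken: set = set()
    pairs: list = []
    for idx in order:
        case = cases[idx]
        candidates = [
            c for c in controls
            if c.patient_id not in taken and _admissible(case, c, spec)
        ]
        if not candidates:
            continue
        best = min(candidates, key=lambda c: (_distance(case, c, spec), c.patient_id))
        taken.add(best.patient_id)
        pairs.append((case.patient_id, best.patient_id))
    if spec.allow_many_to_one:
        matched_case_ids = {a for a, _ in pairs}
        for idx in order:
            case = cases[idx]
            if case.patient_id in matched_case_ids:
                continue
            candidates = [c for c in controls if _admissible(case, c, spec)]
            if not candidates:
                continue
            best = min(
                candidates, key=lambda c: (_distance(case, c, spec), c.patient_id)
            )
            pairs.append((case.patient_id, best.patient_id))
    if not pairs:
        warnings.warn("match_case_control: no admissible pairs; empty match")
        return MatchResult([], [], [], {})

    case_by_id = {c.patient_id: c for c in cases}
    control_by_id = {c.patient_id: c for c in controls}
    matched_cases = [case_by_id[a] for a, _ in pairs]
    control_ids = sorted({b for _, b in pairs})
    matched_controls = [control_by_id[b] for b in control_ids]

    balance = {}
    for cov in ("age", "iss"):
        va = [getattr(p, cov) for p in matched_cases]
        vb = [getattr(p, cov) for p in matched_controls]
        res = compare_two_groups(va, vb)
        balance[f"{cov}_p"] = res.p_raw if res.testable else None
        balance[f"{cov}_mean_diff"] = float(np.mean(va) - np.mean(vb))
    sex_table = pd.crosstab(
        pd.Series([p.sex for p in matched_cases + matched_controls]),
        pd.Series(["case"] * len(matched_cases) + ["control"] * len(matched_controls)),
    ).to_numpy()
    if sex_table.shape[0] < 2:
        balance["sex_p"] = 1.0  # single sex on both sides: perfectly balanced
    else:
        balance["sex_p"] = float(stats.chi2_contingency(sex_table, correction=False)[1])
    return MatchResult(matched_cases, matched_controls, pairs, balance)
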
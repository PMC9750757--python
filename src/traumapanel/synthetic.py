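"""Synthetic trauma-cohort generator.

Emulates the measurement structure of a longitudinal aptamer-based plasma
panel of immune mediators after severe injury: three outcome groups (early
non-survivors ENS, resolvers R, non-resolvers NR) plus low-ISS controls,
sampled at 0/24/72 h (ENS and controls at 0 h only), a 184-analyte immune
panel (115 mediators across IL/CCL/CXCL/IFN/TNFSF, 69 soluble receptors),
an early broad mediator release scaled by outcome group and injury severity,
and a planted "delayed" mediator subset that rises at 24-72 h more strongly
in non-resolvers.

The signal model on the log2 scale for analyte *a*, patient *p* in group *g*
at time *t* is

    log2 x = b_a + A_a * s_g * (1 + k * ISS_p) * 2^(-t/h)   (early release)
           + ramp(t) * d_g[a in delayed subset]             (delayed release)
           + u_{p,a} + e                                    (patient effect, noise)

with raw values 2^(log2 x).  Missingness has a censoring component (values
below a per-analyte detection-limit quantile) and an independent
completely-at-random component.  Every parameter that was actually used is
recorded in a :class:`TruthLedger` so that recovery tests can score the
downstream analysis against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    MEDIATOR_FAMILIES,
    RECEPTOR_FAMILIES,
    OUTCOME_GROUPS,
    Patient,
    patients_to_frame,
    role_for_family,
)

__all__ = [
    "GeneratorConfig",
    "TruthLedger",
    "ConfigError",
    "generate_cohort",
    "simulate_covariates",
    "mediator_mean",
    "write_fixture",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


TIMEPOINT_HOURS = {"0h": 0.0, "24h": 24.0, "72h": 72.0}

# Panel entry counts as assayed: 115 mediators + 69 soluble receptors = 184.
DEFAULT_FAMILY_COUNTS = {
    "IL": 40,
    "CCL": 23,
    "CXCL": 10,
    "IFN": 27,
    "TNFSF": 15,
    "IL_R": 38,
    "IFN_R": 5,
    "TNFRSF": 26,
}

# Group-level covariate calibration: age/ISS means and SDs, male fraction and
# thawed-plasma arm fraction per outcome group (trauma groups match the PAMPer
# demographics table; controls are the younger low-ISS STAAMP arm).
DEFAULT_COVARIATES = {
    "ENS": {"age_mean": 49.4, "age_sd": 23.1, "iss_mean": 32.6, "iss_sd": 19.0,
            "male_frac": 29 / 38, "tp_frac": 12 / 38},
    "R": {"age_mean": 46.4, "age_sd": 18.4, "iss_mean": 19.9, "iss_sd": 8.31,
          "male_frac": 25 / 34, "tp_frac": 13 / 34},
    "NR": {"age_mean": 46.4, "age_sd": 20.1, "iss_mean": 31.0, "iss_sd": 13.6,
           "male_frac": 59 / 78, "tp_frac": 40 / 78},
    "CONTROL": {"age_mean": 36.6, "age_sd": 15.0, "iss_mean": 0.5, "iss_sd": 0.5,
                "male_frac": 0.7, "tp_frac": 0.5},
}

# Hospital-course calibration (days): ICU/ventilation/hospital length of stay.
DEFAULT_OUTCOME_PARAMS = {
    "ENS": {"icu": (0.895, 0.798), "vent": (1.18, 0.652), "hosp": (1.24, 0.634)},
    "R": {"icu": (3.35, 1.81), "vent": (1.76, 1.56), "hosp": (12.4, 8.91)},
    "NR": {"icu": (14.8, 8.72), "vent": (11.1, 6.18), "hosp": (21.4, 13.4)},
    "CONTROL": {"icu": (0.0, 0.0), "vent": (0.0, 0.0), "hosp": (1.0, 1.0)},
}


@dataclass
class GeneratorConfig:
    group_sizes: dict = field(
        default_factory=lambda: {"ENS": 38, "R": 34, "NR": 78, "CONTROL": 29}
    )
    timepoints: tuple = ("0h", "24h", "72h")
    n_analytes_per_family: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS))
    # Early-release multiplier per group; ordering ENS >= NR > R > control is
    # the qualitative pattern the heatmaps show.
    early_release_scale: dict = field(
        default_factory=lambda: {"ENS": 1.0, "NR": 0.9, "R": 0.45, "CONTROL": 0.0}
    )
    delayed_subset_fraction: float = 0.15
    delayed_effect_size: float = 1.0  # log2 units, NR minus R at 72 h
    delayed_r_level: float = 0.5  # log2 rise of the delayed subset in R at 72 h
    iss_effect_slope: float = 0.02  # per-ISS-point multiplier on the early term
    decay_half_life: dict = field(
        default_factory=lambda: {"mediator": 24.0, "soluble_receptor": 48.0}
    )
    baseline_mean: float = 10.0  # log2 RFU
    baseline_sd: float = 1.5
    amplitude_mean: float = 1.0  # log2 units of early release at ISS 0
    amplitude_sd: float = 0.4
    noise_sd: float = 0.5
    patient_sd: float = 0.3
    missing_rate: float = 0.03
    lod_quantile: float = 0.02
    covariate_params: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COVARIATES.items()
    })
    nr_late_death_frac: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in OUTCOME_GROUPS:
                raise ConfigError(f"group_sizes: unknown group {g!r}")
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ConfigError(f"group_sizes[{g}]: count must be a positive integer")
        for fam, n in self.n_analytes_per_family.items():
            if n <= 0:
                raise ConfigError(f"n_analytes_per_family[{fam}]: count must be positive")
        for name in ("delayed_subset_fraction", "missing_rate", "lod_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: {v} outside [0, 1]")
        s = self.early_release_scale
        if not (s["ENS"] >= s["NR"] > s["R"]):
            raise ConfigError("early_release_scale: ordering ENS >= NR > R required")
        for name in ("noise_sd", "patient_sd", "baseline_sd", "amplitude_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be nonnegative")
        for tp in self.timepoints:
            if tp not in TIMEPOINT_HOURS:
                raise ConfigError(f"timepoints: unknown label {tp!r}")

    @property
    def n_mediators(self) -> int:
        return sum(
            n for f, n in self.n_analytes_per_family.items() if f in MEDIATOR_FAMILIES
        )

    @property
    def n_receptors(self) -> int:
        return sum(
            n for f, n in self.n_analytes_per_family.items() if f in RECEPTOR_FAMILIES
        )


@dataclass
class TruthLedger:
    """Ground truth of a generated cohort: one row per analyte with its
    family, role, baseline, early-release amplitude and delayed-subset flag,
    plus the config that produced it.  ``mediator_mean`` reconstructs the
    exact group x time x ISS mean used for any cell."""

    table: pd.DataFrame  # index analyte_id; family, role, baseline, amplitude, delayed
    config: GeneratorConfig

    @property
    def delayed_analytes(self) -> list[str]:
        return list(self.table.index[self.table["delayed"]])

    def to_json(self, path) -> None:
        payload = {
            "analytes": self.table.reset_index().to_dict(orient="records"),
            "config": _config_to_jsonable(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["timepoints"] = list(d["timepoints"])
    return d


def _delayed_ramp(t_hours: float) -> float:
    # Delayed subset is flat at 0 h, halfway up at 24 h, fully up at 72 h.
    return {0.0: 0.0, 24.0: 0.5, 72.0: 1.0}[t_hours]


def mediator_mean(
    analyte_id: str,
    group: str,
    timepoint: str,
    iss: float,
    truth: TruthLedger,
) -> float:
    """Expected log2 level of one analyte for a given group/timepoint/ISS.

    baseline + early release (amplitude x group scale x ISS factor, decaying
    exponentially from 0 h) + delayed term (delayed-subset analytes only,
    nonzero at 24/72 h, larger in NR than R by exactly the configured
    delayed effect size at 72 h).
    """
    if analyte_id not in truth.table.index:
        raise KeyError(f"unknown analyte {analyte_id!r}")
    if group not in OUTCOME_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    cfg = truth.config
    row = truth.table.loc[analyte_id]
    t = TIMEPOINT_HOURS[timepoint]
    half_life = cfg.decay_half_life[row["role"]]
    early = (
        row["amplitude"]
        * cfg.early_release_scale[group]
        * (1.0 + cfg.iss_effect_slope * iss)
        * 2.0 ** (-t / half_life)
    )
    delayed = 0.0
    if row["delayed"]:
        level = {
            "NR": cfg.delayed_r_level + cfg.delayed_effect_size,
            "R": cfg.delayed_r_level,
        }.get(group, 0.0)
        delayed = _delayed_ramp(t) * level
    return float(row["baseline"] + early + delayed)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, low, high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_covariates(
    config: GeneratorConfig, group: str, rng: np.random.Generator,
    patient_id: Optional[str] = None,
) -> Patient:
    """Draw one patient's demographics and hospital course for a group.

    Ages come from a truncated normal on [18, 95] (controls included); ISS
    from a truncated normal rounded to an integer in [1, 75], except controls
    whose ISS is 0 or 1.  Durations are drawn so that outcome classification
    recovers the requested group.
    """
    if group not in OUTCOME_GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    cv = config.covariate_params[group]
    oc = DEFAULT_OUTCOME_PARAMS[group]
    age = _truncnorm(rng, cv["age_mean"], cv["age_sd"], 18.0, 95.0)
    if group == "CONTROL":
        iss = int(rng.random() < 0.5)
    else:
        iss = int(round(_truncnorm(rng, cv["iss_mean"], cv["iss_sd"], 1.0, 75.0)))
        iss = int(np.clip(iss, 1, 75))
    sex = "M" if rng.random() < cv["male_frac"] else "F"
    arm = "TP" if rng.random() < cv["tp_frac"] else "SOC"

    death_time: Optional[float] = None
    alive_at_30d = True
    if group == "ENS":
        death_time = float(rng.uniform(1.0, 72.0))
        alive_at_30d = False
        icu = min(_truncnorm(rng, *oc["icu"], 0.0, 7.0), death_time / 24.0)
        vent = min(_truncnorm(rng, *oc["vent"], 0.0, np.inf), death_time / 24.0)
        hosp = death_time / 24.0
    elif group == "R":
        icu = _truncnorm(rng, *oc["icu"], 0.0, 6.99)
        vent = _truncnorm(rng, *oc["vent"], 0.0, np.inf)
        hosp = max(icu, _truncnorm(rng, *oc["hosp"], 0.0, np.inf))
    elif group == "NR":
        icu = _truncnorm(rng, *oc["icu"], 7.0, np.inf)
        vent = _truncnorm(rng, *oc["vent"], 0.0, np.inf)
        hosp = max(icu, _truncnorm(rng, *oc["hosp"], 0.0, np.inf))
        if rng.random() < config.nr_late_death_frac:
            death_time = float(rng.uniform(73.0, hosp * 24.0 + 73.0))
            alive_at_30d = death_time > 720.0
    else:  # CONTROL
        icu = 0.0
        vent = 0.0
        hosp = _truncnorm(rng, *oc["hosp"], 0.0, np.inf)

    return Patient(
        patient_id=patient_id or f"{group}-x",
        age=age,
        sex=sex,
        iss=iss,
        arm=arm,
        alive_at_30d=alive_at_30d,
        death_time=death_time,
        icu_days=icu,
        vent_days=vent,
        hospital_days=hosp,
        is_low_iss_control=(group == "CONTROL"),
    )


def _build_truth(config: GeneratorConfig, rng: np.random.Generator) -> TruthLedger:
    records = []
    for family, n in config.n_analytes_per_family.items():
        role = role_for_family(family)
        for i in range(1, n + 1):
            records.append({
                "analyte_id": f"{family}{i:03d}",
                "symbol": f"{family}{i}",
                "family": family,
                "role": role,
            })
    table = pd.DataFrame(records).set_index("analyte_id")
    table["baseline"] = rng.normal(config.baseline_mean, config.baseline_sd, len(table))
    table["amplitude"] = np.abs(
        rng.normal(config.amplitude_mean, config.amplitude_sd, len(table))
    )
    mediator_ids = table.index[table["role"] == "mediator"]
    n_delayed = int(round(config.delayed_subset_fraction * len(mediator_ids)))
    delayed_ids = rng.choice(mediator_ids, size=n_delayed, replace=False)
    table["delayed"] = table.index.isin(delayed_ids)
    # Delayed-subset analytes start low: no early-release burst at 0 h.
    table.loc[table["delayed"], "amplitude"] = 0.0
    return TruthLedger(table=table, config=config)


def generate_cohort(config: Optional[GeneratorConfig] = None):
    """Generate (patients, raw expression matrix, truth ledger).

    ENS patients and controls carry a 0 h sample only; R and NR carry all
    configured timepoints.  Values are raw-scale positives (2^log2 signal)
    with censoring/MCAR missingness applied.  Covariates, analyte parameters,
    measurement noise and missingness each draw from an independent stream
    spawned from the config seed, so changing the panel size does not
    reshuffle the covariates.
    """
    config = config or GeneratorConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cov_ss, analyte_ss, noise_ss, missing_ss = ss.spawn(4)
    cov_rng = np.random.default_rng(cov_ss)
    truth = _build_truth(config, np.random.default_rng(analyte_ss))
    noise_rng = np.random.default_rng(noise_ss)
    missing_rng = np.random.default_rng(missing_ss)

    patients: list[Patient] = []
    for group in ("ENS", "R", "NR", "CONTROL"):
        n = config.group_sizes.get(group, 0)
        for i in range(1, n + 1):
            patients.append(
                simulate_covariates(config, group, cov_rng, patient_id=f"{group}-{i:03d}")
            )

    group_of = {p.patient_id: p.patient_id.rsplit("-", 1)[0] for p in patients}
    sample_rows = []
    for p in patients:
        g = group_of[p.patient_id]
        tps = (config.timepoints[0],) if g in ("ENS", "CONTROL") else config.timepoints
        for tp in tps:
            sample_rows.append({
                "sample_id": f"{p.patient_id}_{tp}",
                "patient_id": p.patient_id,
                "timepoint": tp,
                "group": g,
            })
    sample_meta = pd.DataFrame(sample_rows).set_index("sample_id")

    analyte_ids = truth.table.index
    n_analytes = len(analyte_ids)
    baselines = truth.table["baseline"].to_numpy()
    amplitudes = truth.table["amplitude"].to_numpy()
    delayed_mask = truth.table["delayed"].to_numpy()
    half_lives = truth.table["role"].map(config.decay_half_life).to_numpy(dtype=float)

    patient_effects = {
        p.patient_id: noise_rng.normal(0.0, config.patient_sd, n_analytes)
        if config.patient_sd > 0 else np.zeros(n_analytes)
        for p in patients
    }
    patient_by_id = {p.patient_id: p for p in patients}

    log2 = np.empty((n_analytes, len(sample_meta)))
    for j, (sid, srow) in enumerate(sample_meta.iterrows()):
        p = patient_by_id[srow["patient_id"]]
        g = srow["group"]
        t = TIMEPOINT_HOURS[srow["timepoint"]]
        early = (
            amplitudes
            * config.early_release_scale[g]
            * (1.0 + config.iss_effect_slope * p.iss)
            * 2.0 ** (-t / half_lives)
        )
        level = {
            "NR": config.delayed_r_level + config.delayed_effect_size,
            "R": config.delayed_r_level,
        }.get(g, 0.0)
        delayed = delayed_mask * _delayed_ramp(t) * level
        mean = baselines + early + delayed
        noise = (
            noise_rng.normal(0.0, config.noise_sd, n_analytes)
            if config.noise_sd > 0 else 0.0
        )
        log2[:, j] = mean + patient_effects[p.patient_id] + noise

    raw = 2.0 ** log2
    mask = np.zeros_like(raw, dtype=bool)
    if config.lod_quantile > 0:
        lod = np.quantile(raw, config.lod_quantile, axis=1, keepdims=True)
        mask |= raw < lod
    if config.missing_rate > 0:
        mask |= missing_rng.random(raw.shape) < config.missing_rate
    values = pd.DataFrame(raw, index=analyte_ids, columns=sample_meta.index)
    values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))

    matrix = ExpressionMatrix(values=values, scale="raw", sample_meta=sample_meta)
    return patients, matrix, truth


def write_fixture(outdir, config: Optional[GeneratorConfig] = None) -> dict:
    """Write a complete synthetic input set: expression TSV, sample metadata
    CSV, manifest CSV, truth-ledger JSON and config YAML.  Returns the paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients, matrix, truth = generate_cohort(config)
    config = truth.config

    paths = {
        "matrix": outdir / "expression.tsv",
        "metadata": outdir / "sample_metadata.csv",
        "manifest": outdir / "manifest.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    matrix.values.rename_axis("analyte_id").to_csv(paths["matrix"], sep="\t")
    pdf = patients_to_frame(patients)
    meta = matrix.sample_meta.join(pdf, on="patient_id")
    meta.rename_axis("sample_id").to_csv(paths["metadata"])
    truth.table[["symbol", "family", "role"]].rename_axis("analyte_id").to_csv(
        paths["manifest"]
    )
    truth.to_json(paths["truth"])
    paths["config"].write_text(yaml.safe_dump(_config_to_jsonable(config)))
    return {k: str(v) for k, v in paths.items()}
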
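"""Synthetic patient-level cohorts with the trial's data-generating structure.

The real trial data are not public, so analyses are exercised against
generated cohorts that emulate the observed structure: arm-dependent
Bernoulli cardioversion within the 90-minute window, conversion times drawn
from a normal distribution truncated to (0, 90] whose *post-truncation*
moments match the configured targets, the exclusion flow (not infused,
atrial flutter at randomization, in-window electrical cardioversion),
electrical cardioversion of non-converters, sinus-rhythm status at 3 h /
24 h / 30 days, eligibility-bounded covariates and a dose-dependent
transient QTcF excursion peaking 45 minutes after the start of infusion.

``fig1_fixture`` builds a deterministic 66-patient cohort that hard-codes
the published patient flow and endpoint counts, for end-to-end checks of the
analysis pipeline against the printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PatientRecord",
    "CohortParams",
    "QTCF_GRID_MIN",
    "arm_label",
    "generate_cohort",
    "generate_qtcf",
    "fig1_fixture",
]

PLACEBO = "placebo"

# ECG extraction grid, minutes from start of infusion (24 h = 1440 min).
QTCF_GRID_MIN: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 180.0, 1440.0)


def arm_label(dose: Optional[float]) -> str:
    """Canonical arm label: "placebo" or e.g. "3 mg/kg"."""
    return PLACEBO if dose is None else f"{dose:g} mg/kg"


def cohort_params_from_dict(data: Mapping) -> "CohortParams":
    """Build :class:`CohortParams` from a (possibly partial) plain mapping.

    Unknown keys raise a validation error naming them; tuple-valued fields
    accept lists. Used by the YAML config front end.
    """
    valid = {f.name for f in fields(CohortParams)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown cohort parameter(s): {unknown}")
    kwargs = {}
    for key, value in data.items():
        if key == "conversion_time":
            value = {arm: tuple(map(float, pair)) for arm, pair in value.items()}
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    params = replace(CohortParams(), **kwargs)
    params.validate()
    return params


@dataclass
class PatientRecord:
    """One randomized patient.

    ``converted`` is None when conversion status is not evaluable (patient
    not infused, or electrically cardioverted inside the 90-min window).
    Sinus-rhythm statuses are None when unavailable, which is what drives
    the varying denominators of the follow-up endpoints.
    """

    id: int
    arm: str
    dose: Optional[float]
    infused: bool
    flutter_at_randomization: bool
    dccv_within_90min: bool
    converted: Optional[bool] = None
    conversion_time_min: Optional[float] = None
    recurrence_1min: Optional[bool] = None
    relapse_5min: Optional[bool] = None
    dccv_performed: Optional[bool] = None
    dccv_success: Optional[bool] = None
    sinus_3h: Optional[bool] = None
    sinus_24h: Optional[bool] = None
    sinus_30d: Optional[bool] = None
    age: Optional[float] = None
    male: Optional[bool] = None
    weight_kg: Optional[float] = None
    af_duration_h: Optional[float] = None
    baseline_qtcf_ms: Optional[float] = None
    dqtcf_ms: Optional[tuple[float, ...]] = None

    @property
    def primary_success(self) -> Optional[bool]:
        """Cardioversion within 90 min with no AF recurrence within 1 min."""
        if self.converted is None:
            return None
        return bool(self.converted) and not bool(self.recurrence_1min)


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; defaults emulate the published trial conditions.

    Conversion probabilities and follow-up proportions follow the observed
    arm-level rates; conversion-time targets (mean, sd) are the reported
    47 +/- 23 and 41 +/- 24 minutes, interpreted as the moments of the
    distribution *after* truncation to (0, 90]. Exclusion rates reproduce
    the published flow (3/66 not infused, 3/66 flutter, 1/66 in-window
    electrical cardioversion). The placebo conversion probability defaults
    to a small nonzero 0.02 — the trial observed 0/25, but a structural zero
    would make simulated superiority trivial.
    """

    p_convert: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: 0.02, "3 mg/kg": 0.42, "5 mg/kg": 0.55}
    )
    conversion_time: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            PLACEBO: (45.0, 23.0),
            "3 mg/kg": (47.0, 23.0),
            "5 mg/kg": (41.0, 24.0),
        }
    )
    conversion_window_min: float = 90.0
    recurrence_1min_p: float = 0.02
    relapse_5min_p: float = 0.02
    dccv_success_p: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: 0.88, "3 mg/kg": 1.0, "5 mg/kg": 1.0}
    )
    sinus_3h_p: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: 0.84, "3 mg/kg": 1.0, "5 mg/kg": 0.952}
    )
    sinus_24h_p: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: 0.76, "3 mg/kg": 1.0, "5 mg/kg": 1.0}
    )
    sinus_30d_p: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: 0.64, "3 mg/kg": 0.90, "5 mg/kg": 0.714}
    )
    status_missing_p: float = 0.04
    not_infused_rate: float = 3 / 66
    flutter_rate: float = 3 / 66
    early_dccv_rate: float = 1 / 66
    # Eligibility-bounded covariates.
    age_mean: float = 65.0
    age_sd: float = 9.5
    age_bounds: tuple[float, float] = (18.0, 80.0)
    weight_bounds_kg: tuple[float, float] = (50.0, 110.0)
    male_fraction: float = 0.72
    af_duration_bounds_h: tuple[float, float] = (3.0, 168.0)
    qtcf_mean_ms: float = 410.0
    qtcf_sd_ms: float = 22.0
    qtcf_cap_ms: float = 450.0
    # Transient QTcF excursion: amplitude per arm at the 45-min peak, Gaussian
    # bump width, a common late offset (rhythm-change artifact) and noise.
    qtcf_amplitude_ms: Mapping[str, float] = field(
        default_factory=lambda: {PLACEBO: -1.3, "3 mg/kg": 19.4, "5 mg/kg": 37.7}
    )
    qtcf_peak_min: float = 45.0
    qtcf_width_min: float = 25.0
    qtcf_late_offset_ms: float = 12.0
    qtcf_noise_sd_ms: float = 8.0

    def validate(self) -> None:
        bad: list[str] = []
        prob_fields = [
            ("recurrence_1min_p", self.recurrence_1min_p),
            ("relapse_5min_p", self.relapse_5min_p),
            ("status_missing_p", self.status_missing_p),
            ("not_infused_rate", self.not_infused_rate),
            ("flutter_rate", self.flutter_rate),
            ("early_dccv_rate", self.early_dccv_rate),
            ("male_fraction", self.male_fraction),
        ]
        for mapping_name in ("p_convert", "dccv_success_p", "sinus_3h_p", "sinus_24h_p", "sinus_30d_p"):
            for arm, p in getattr(self, mapping_name).items():
                prob_fields.append((f"{mapping_name}[{arm}]", p))
        for name, p in prob_fields:
            if not 0.0 <= p <= 1.0:
                bad.append(f"{name}={p} outside [0,1]")
        for name, value in [
            ("conversion_window_min", self.conversion_window_min),
            ("age_sd", self.age_sd),
            ("qtcf_sd_ms", self.qtcf_sd_ms),
            ("qtcf_width_min", self.qtcf_width_min),
        ]:
            if value <= 0:
                bad.append(f"{name}={value} must be positive")
        for arm, (m, s) in self.conversion_time.items():
            if m <= 0 or s <= 0:
                bad.append(f"conversion_time[{arm}]=({m},{s}) must be positive")
        if bad:
            raise ValueError("invalid cohort parameters: " + "; ".join(bad))


@lru_cache(maxsize=64)
def _truncnorm_parent_params(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) so the truncated-to-(lo, hi] normal has the target moments.

    Truncation pulls the moments toward the window center, so the parent
    parameters are solved for numerically rather than used directly.
    """

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - target_mean, np.sqrt(v) - target_sd])

    sol = optimize.root(moments, x0=np.array([target_mean, np.log(target_sd)]), tol=1e-12)
    if not sol.success:
        raise RuntimeError(
            f"could not match truncated-normal moments ({target_mean}, {target_sd})"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _draw_conversion_times(
    n: int, target: tuple[float, float], window: float, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = _truncnorm_parent_params(target[0], target[1], 0.0, window)
    a, b = (0.0 - mu) / sigma, (window - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_qtcf(
    params: CohortParams, record: PatientRecord, rng: np.random.Generator
) -> tuple[float, ...]:
    """Draw a patient's delta-QTcF series on the fixed time grid.

    The mean trajectory is a Gaussian bump of arm-specific amplitude peaking
    at 45 min (exactly the amplitude at the peak) plus a common, arm-
    independent offset ramping in after the 90-min window — emulating the
    observed residual >10 ms change at 24 h in every arm, attributed to
    comparing baselines measured in AF against follow-ups in sinus rhythm.
    Gaussian measurement noise is added independently per timepoint.
    """
    amplitude = params.qtcf_amplitude_ms[record.arm]
    t = np.asarray(QTCF_GRID_MIN)
    bump = amplitude * np.exp(-0.5 * ((t - params.qtcf_peak_min) / params.qtcf_width_min) ** 2)
    late = params.qtcf_late_offset_ms * np.clip((t - 90.0) / (1440.0 - 90.0), 0.0, 1.0)
    noise = rng.normal(0.0, params.qtcf_noise_sd_ms, size=t.size) if params.qtcf_noise_sd_ms > 0 else 0.0
    return tuple(float(v) for v in bump + late + noise)


def _draw_covariates(params: CohortParams, rng: np.random.Generator) -> dict:
    a, b = params.age_bounds
    az, bz = (a - params.age_mean) / params.age_sd, (b - params.age_mean) / params.age_sd
    age = float(stats.truncnorm.rvs(az, bz, loc=params.age_mean, scale=params.age_sd, random_state=rng))
    qz_hi = (params.qtcf_cap_ms - params.qtcf_mean_ms) / params.qtcf_sd_ms
    qtcf = float(
        stats.truncnorm.rvs(-np.inf, qz_hi, loc=params.qtcf_mean_ms, scale=params.qtcf_sd_ms,
                            random_state=rng)
    )
    return {
        "age": age,
        "male": bool(rng.random() < params.male_fraction),
        "weight_kg": float(rng.uniform(*params.weight_bounds_kg)),
        "af_duration_h": float(rng.uniform(*params.af_duration_bounds_h)),
        "baseline_qtcf_ms": qtcf,
    }


def _maybe(value: bool, missing_p: float, rng: np.random.Generator) -> Optional[bool]:
    return None if rng.random() < missing_p else value


def generate_cohort(
    params: CohortParams,
    n_per_arm: Mapping[str, int],
    seed: int | np.random.SeedSequence,
    include_qtcf: bool = True,
) -> list[PatientRecord]:
    """Generate a fully populated cohort, deterministic for a given seed.

    ``n_per_arm`` maps arm labels (see :func:`arm_label`) to randomized
    counts. Exclusion flags are drawn independently at the configured rates;
    conversion outcomes, times, electrical-cardioversion results, follow-up
    statuses and covariates are drawn per arm for evaluable patients.
    """
    params.validate()
    if not n_per_arm or any(n <= 0 for n in n_per_arm.values()):
        raise ValueError(f"n_per_arm must be positive, got {dict(n_per_arm)}")
    unknown = [a for a in n_per_arm if a not in params.p_convert]
    if unknown:
        raise ValueError(f"no conversion probability configured for arm(s) {unknown}")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    pid = 0
    for arm in sorted(n_per_arm):
        dose = None if arm == PLACEBO else float(arm.split()[0])
        for _ in range(n_per_arm[arm]):
            pid += 1
            rec = PatientRecord(
                id=pid,
                arm=arm,
                dose=dose,
                infused=bool(rng.random() >= params.not_infused_rate),
                flutter_at_randomization=bool(rng.random() < params.flutter_rate),
                dccv_within_90min=bool(rng.random() < params.early_dccv_rate),
                **_draw_covariates(params, rng),
            )
            if not rec.infused:
                rec.dccv_within_90min = False
                records.append(rec)
                continue
            if include_qtcf:
                rec.dqtcf_ms = generate_qtcf(params, rec, rng)
            in_fas = not rec.flutter_at_randomization and not rec.dccv_within_90min
            if rec.dccv_within_90min:
                # Electrical cardioversion inside the window: conversion
                # status unevaluable, but the DCCV itself is on record.
                rec.dccv_performed = True
                rec.dccv_success = bool(rng.random() < params.dccv_success_p[arm])
            elif rec.flutter_at_randomization:
                rec.converted = False
            if in_fas:
                rec.converted = bool(rng.random() < params.p_convert[arm])
                if rec.converted:
                    rec.conversion_time_min = float(
                        _draw_conversion_times(1, params.conversion_time[arm],
                                               params.conversion_window_min, rng)[0]
                    )
                    rec.recurrence_1min = bool(rng.random() < params.recurrence_1min_p)
                    rec.dccv_performed = False
                else:
                    rec.dccv_performed = True  # per protocol
                    rec.dccv_success = bool(rng.random() < params.dccv_success_p[arm])
                # No cardioversion (pharmacological or electrical) -> no
                # relapse possible; recorded False so denominators match FAS.
                cardioverted = rec.converted or bool(rec.dccv_success)
                rec.relapse_5min = bool(cardioverted and rng.random() < params.relapse_5min_p)
                rec.sinus_3h = _maybe(rng.random() < params.sinus_3h_p[arm],
                                      params.status_missing_p, rng)
                rec.sinus_24h = _maybe(rng.random() < params.sinus_24h_p[arm],
                                       params.status_missing_p, rng)
                rec.sinus_30d = _maybe(rng.random() < params.sinus_30d_p[arm],
                                       params.status_missing_p, rng)
            records.append(rec)
    return records


def _symmetric_times(mean: float, sd: float, n: int) -> list[float]:
    """Deterministic times with exact sample mean/sd (ddof=1), inside (0, 90]."""
    if n == 1:
        return [mean]
    if n % 2 == 1:
        base = np.arange(n) - (n - 1) / 2
    else:
        half = np.arange(1, n // 2 + 1)
        base = np.concatenate([-half[::-1], half])
    z = base / np.std(base, ddof=1)
    times = mean + sd * z
    if times.min() <= 0 or times.max() > 90:
        raise ValueError("constructed times fall outside (0, 90]")
    return [float(t) for t in np.sort(times)]


def fig1_fixture() -> list[PatientRecord]:
    """Deterministic 66-patient cohort reproducing the published patient flow.

    66 randomized; 3 not infused (one per arm); flutter at randomization for
    one placebo and two 3 mg/kg patients; one 3 mg/kg patient electrically
    cardioverted inside the 90-min window. Full-analysis-set arm sizes are
    25 / 12 / 22 (placebo / 3 / 5 mg/kg) with 0 / 5 / 12 primary-endpoint
    successes, electrical cardioversion of every non-converter with success
    22/25, 7/7 and 10/10, one relapse within 5 min (placebo, after DCCV),
    and sinus-rhythm counts 21/25, 11/11, 20/21 at 3 h; 19/25, 11/11, 21/21
    at 24 h; 16/25, 9/10, 15/21 at 30 days.
    """
    records: list[PatientRecord] = []
    pid = 0

    def add(arm: str, dose: Optional[float], **kw) -> PatientRecord:
        nonlocal pid
        pid += 1
        rec = PatientRecord(
            id=pid, arm=arm, dose=dose,
            infused=kw.pop("infused", True),
            flutter_at_randomization=kw.pop("flutter_at_randomization", False),
            dccv_within_90min=kw.pop("dccv_within_90min", False),
            age=64.0, male=True, weight_kg=85.0, af_duration_h=48.0,
            baseline_qtcf_ms=410.0,
        )
        for key, value in kw.items():
            setattr(rec, key, value)
        return rec

    # --- placebo: 27 randomized, 1 not infused, 1 flutter, FAS 25 ---------
    records.append(add(PLACEBO, None, infused=False))
    records.append(add(PLACEBO, None, flutter_at_randomization=True, converted=False))
    for i in range(25):
        records.append(add(
            PLACEBO, None,
            converted=False,
            dccv_performed=True,
            dccv_success=i < 22,            # 22/25 successful
            relapse_5min=(i == 0),          # the single relapse, 1/25
            sinus_3h=i < 21,                # 21/25
            sinus_24h=i < 19,               # 19/25
            sinus_30d=i < 16,               # 16/25
        ))

    # --- 3 mg/kg: 16 randomized, 1 not infused, 2 flutter, 1 early DCCV ---
    arm3 = arm_label(3.0)
    records.append(add(arm3, 3.0, infused=False))
    for _ in range(2):
        records.append(add(arm3, 3.0, flutter_at_randomization=True, converted=False))
    records.append(add(arm3, 3.0, dccv_within_90min=True,
                       dccv_performed=True, dccv_success=True))
    times3 = _symmetric_times(47.0, 23.0, 5)
    for i in range(12):
        converted = i < 5
        records.append(add(
            arm3, 3.0,
            converted=converted,
            conversion_time_min=times3[i] if converted else None,
            recurrence_1min=False if converted else None,
            relapse_5min=False,
            dccv_performed=not converted,
            dccv_success=True if not converted else None,  # 7/7
            sinus_3h=True if i < 11 else None,             # 11/11, one missing
            sinus_24h=True if i < 11 else None,            # 11/11, one missing
            sinus_30d=(i < 9) if i < 10 else None,         # 9/10, two missing
        ))

    # --- 5 mg/kg: 23 randomized, 1 not infused, FAS 22 --------------------
    arm5 = arm_label(5.0)
    records.append(add(arm5, 5.0, infused=False))
    times5 = _symmetric_times(41.0, 24.0, 12)
    for i in range(22):
        converted = i < 12
        records.append(add(
            arm5, 5.0,
            converted=converted,
            conversion_time_min=times5[i] if converted else None,
            recurrence_1min=False if converted else None,
            relapse_5min=False,
            dccv_performed=not converted,
            dccv_success=True if not converted else None,  # 10/10
            sinus_3h=(i < 20) if i < 21 else None,         # 20/21, one missing
            sinus_24h=True if i < 21 else None,            # 21/21, one missing
            sinus_30d=(i < 15) if i < 21 else None,        # 15/21, one missing
        ))
    assert len(records) == 66
    return records
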
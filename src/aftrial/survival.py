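"""Analysis-set filtering and frequentist companions to the Bayesian analysis.

Covers the efficacy-population bookkeeping (safety set = infused patients;
full analysis set = infused patients with an evaluable conversion status,
i.e. excluding atrial flutter at randomization and in-window electrical
cardioversion), the Kaplan-Meier product-limit curve for time to
pharmacological conversion with administrative censoring at the 90-minute
window end, the two-sample log-rank test, and the descriptive endpoint
table mirroring the published efficacy summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord

__all__ = [
    "SurvivalRecord",
    "AnalysisSets",
    "KaplanMeierCurve",
    "LogRankResult",
    "SchemaError",
    "build_analysis_sets",
    "survival_records",
    "km_estimate",
    "logrank_test",
    "endpoint_summary",
]

WINDOW_MIN = 90.0

EXCLUSION_FLAGS = ("infused", "flutter_at_randomization", "dccv_within_90min")


class SchemaError(ValueError):
    """A required patient-table column/flag is missing."""


@dataclass(frozen=True)
class SurvivalRecord:
    """Time to conversion in minutes; non-events are censored at 90 min."""

    time: float
    event: bool
    arm: str = ""

    def __post_init__(self) -> None:
        if self.event:
            if not 0 < self.time <= WINDOW_MIN:
                raise ValueError(f"event time {self.time} outside (0, {WINDOW_MIN}]")
        elif self.time != WINDOW_MIN:
            raise ValueError("censored records carry the administrative time 90")


@dataclass(frozen=True)
class AnalysisSets:
    """Safety and full-analysis patient-id sets with per-reason exclusions.

    ``exclusions`` counts one primary reason per excluded patient with
    precedence not-infused > flutter > early electrical cardioversion.
    """

    safety: frozenset[int]
    full_analysis: frozenset[int]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_safety(self) -> int:
        return len(self.safety)

    @property
    def n_full_analysis(self) -> int:
        return len(self.full_analysis)


def _check_flags(rec: PatientRecord) -> None:
    for flag in EXCLUSION_FLAGS:
        if getattr(rec, flag, None) is None:
            raise SchemaError(f"patient {getattr(rec, 'id', '?')} is missing flag '{flag}'")


def build_analysis_sets(cohort: Sequence[PatientRecord]) -> AnalysisSets:
    """Partition a randomized cohort into safety and full analysis sets.

    Safety set: all patients who received the infusion. Full analysis set:
    infused patients excluding flutter-at-randomization and in-window
    electrical cardioversion (unevaluable conversion status). Deterministic
    and order-independent.
    """
    safety: set[int] = set()
    fas: set[int] = set()
    exclusions = {"not_infused": 0, "flutter_at_randomization": 0, "dccv_within_90min": 0}
    for rec in cohort:
        _check_flags(rec)
        if not rec.infused:
            exclusions["not_infused"] += 1
            continue
        safety.add(rec.id)
        if rec.flutter_at_randomization:
            exclusions["flutter_at_randomization"] += 1
        elif rec.dccv_within_90min:
            exclusions["dccv_within_90min"] += 1
        else:
            fas.add(rec.id)
    return AnalysisSets(safety=frozenset(safety), full_analysis=frozenset(fas),
                        exclusions=exclusions)


def survival_records(
    cohort: Sequence[PatientRecord], sets: AnalysisSets, arm: Optional[str] = None
) -> list[SurvivalRecord]:
    """Time-to-conversion records for full-analysis-set patients (one arm or all)."""
    out = []
    for rec in cohort:
        if rec.id not in sets.full_analysis:
            continue
        if arm is not None and rec.arm != arm:
            continue
        if rec.converted:
            out.append(SurvivalRecord(time=float(rec.conversion_time_min), event=True, arm=rec.arm))
        else:
            out.append(SurvivalRecord(time=WINDOW_MIN, event=False, arm=rec.arm))
    return out


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Right-continuous product-limit estimate with jumps at event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_incidence_at(self, t: float) -> float:
        """Cumulative conversion incidence 1 - S(t), the reported curve."""
        return 1.0 - self.survival_at(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "survival": self.survival,
            "cumulative_incidence": 1.0 - self.survival,
        })


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of P(not yet converted by t).

    With administrative censoring only at t = 90 every censoring time follows
    every event time, so the estimate coincides with the empirical survival
    function of the converters among all subjects; the general product-limit
    form is used regardless.
    """
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)
    uniq = np.unique(times[events])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in uniq:
        r = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / r
        at_risk.append(r)
        n_ev.append(d)
        surv.append(s)
    return KaplanMeierCurve(
        times=uniq, survival=np.array(surv), n_at_risk=np.array(at_risk),
        n_events=np.array(n_ev), n_total=n,
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed_a: float
    expected_a: float


def logrank_test(a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]) -> LogRankResult:
    """Two-sample log-rank test (chi-square, 1 d.f.) with tie-corrected variance.

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the pooled risk sets; the
    variance term carries the standard multiplicity correction for ties.
    Two-sided p-value from the chi-square(1) upper tail.
    """
    ta = np.array([r.time for r in a]); ea = np.array([r.event for r in a])
    tb = np.array([r.time for r in b]); eb = np.array([r.event for r in b])
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]])) if (ea.any() or eb.any()) else None
    if all_event_times is None or all_event_times.size == 0:
        raise ValueError("log-rank test undefined with zero events in both groups")
    O_a = E_a = V = 0.0
    for t in all_event_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        d_a = int(np.sum((ta == t) & ea))
        d_b = int(np.sum((tb == t) & eb))
        n_j, d_j = n_a + n_b, d_a + d_b
        if n_j == 0 or d_j == 0:
            continue
        O_a += d_a
        E_a += d_j * n_a / n_j
        if n_j > 1:
            V += d_j * (n_a / n_j) * (n_b / n_j) * (n_j - d_j) / (n_j - 1)
    if V == 0.0:
        return LogRankResult(statistic=0.0, p_value=1.0, observed_a=O_a, expected_a=E_a)
    chi2 = (O_a - E_a) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(statistic=float(chi2), p_value=p, observed_a=O_a, expected_a=E_a)


def _count(values: Iterable[Optional[bool]]) -> tuple[int, int]:
    """(#true, #non-missing) over nullable flags."""
    vals = [v for v in values if v is not None]
    return sum(bool(v) for v in vals), len(vals)


def endpoint_summary(
    cohort: Sequence[PatientRecord], sets: AnalysisSets
) -> pd.DataFrame:
    """Per-arm endpoint table over the full analysis set.

    Counts the primary endpoint (conversion within 90 min with no AF
    recurrence within 1 min), relapse within 5 min of any cardioversion,
    sinus rhythm at 3 h / 24 h / 30 days, electrical cardioversions
    performed and their success, and mean +/- sd conversion time among
    converters. Denominators follow non-missing statuses, so they can be
    smaller than the arm's full-analysis-set size.
    """
    fas = [r for r in cohort if r.id in sets.full_analysis]
    if not fas:
        raise ValueError("empty full analysis set")
    rows = []
    arms = sorted({r.arm for r in fas}, key=lambda a: (a != "placebo", a))
    for arm in arms:
        grp = [r for r in fas if r.arm == arm]
        primary_x, _ = _count(r.primary_success for r in grp)
        relapse_x, relapse_n = _count(r.relapse_5min for r in grp)
        s3_x, s3_n = _count(r.sinus_3h for r in grp)
        s24_x, s24_n = _count(r.sinus_24h for r in grp)
        s30_x, s30_n = _count(r.sinus_30d for r in grp)
        dccv_x, _ = _count(r.dccv_performed for r in grp)
        dsucc_x, dsucc_n = _count(r.dccv_success for r in grp if r.dccv_performed)
        conv_times = [r.conversion_time_min for r in grp if r.converted]
        rows.append({
            "arm": arm,
            "fas_n": len(grp),
            "primary_x": primary_x,
            "primary_n": len(grp),
            "relapse_5min_x": relapse_x, "relapse_5min_n": relapse_n,
            "sinus_3h_x": s3_x, "sinus_3h_n": s3_n,
            "sinus_24h_x": s24_x, "sinus_24h_n": s24_n,
            "sinus_30d_x": s30_x, "sinus_30d_n": s30_n,
            "dccv_performed_x": dccv_x, "dccv_performed_n": len(grp),
            "dccv_success_x": dsucc_x, "dccv_success_n": dsucc_n,
            "conversion_time_mean": float(np.mean(conv_times)) if conv_times else np.nan,
            "conversion_time_sd": float(np.std(conv_times, ddof=1)) if len(conv_times) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("arm")
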
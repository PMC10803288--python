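"""Table-2-style analysis report assembly.

Runs the full efficacy pipeline over a patient table — analysis-set
filtering, endpoint summary, exact within-arm intervals, Bayesian
superiority versus pooled placebo, Kaplan-Meier curves and log-rank tests —
and collects everything, raw and render-ready, into one structure. Every
printed percentage stays recomputable from counts carried alongside it;
probabilities are kept at full precision with percent formatting applied
only at render time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import __version__
from .bayes import ArmCounts, exact_binomial_ci, round_half_away
from .cohort import PatientRecord, PLACEBO
from .design import DesignConfig, SuperiorityRecord, final_superiority
from .survival import (
    AnalysisSets,
    build_analysis_sets,
    endpoint_summary,
    km_estimate,
    logrank_test,
    survival_records,
)

__all__ = ["AnalysisReport", "build_report", "format_probability_percent"]


def format_probability_percent(p: float) -> str:
    """Render a posterior probability as a percent, saturating at >99.9%."""
    if p > 0.999:
        return ">99.9%"
    if p < 0.001:
        return "<0.1%"
    return f"{100 * p:.1f}%"


@dataclass
class ArmReport:
    arm: str
    x: int
    n: int
    percent_raw: float
    percent_rounded: int
    ci_lower: float
    ci_upper: float
    ci_percent: tuple[int, int]
    ci_level: float


@dataclass
class AnalysisReport:
    n_randomized: int
    sets: AnalysisSets
    arms: list[ArmReport]
    superiority: list[SuperiorityRecord]
    endpoints: "object"           # pandas DataFrame, one row per arm
    km_tables: dict[str, "object"]
    logrank: dict[str, tuple[float, float]]   # arm -> (chi2, p)
    ci_level: float
    config_hash: str
    version: str = __version__
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "analysis_sets": {
                "randomized": self.n_randomized,
                "safety": self.sets.n_safety,
                "full_analysis": self.sets.n_full_analysis,
                "exclusions": dict(self.sets.exclusions),
            },
            "primary_endpoint": [
                {
                    "arm": a.arm, "x": a.x, "n": a.n,
                    "percent_raw": a.percent_raw, "percent": a.percent_rounded,
                    "ci_lower": a.ci_lower, "ci_upper": a.ci_upper,
                    "ci_percent": list(a.ci_percent), "ci_level": a.ci_level,
                }
                for a in self.arms
            ],
            "superiority": [
                {
                    "dose": rec.dose,
                    "posterior_probability": rec.posterior_probability,
                    "formatted": format_probability_percent(rec.posterior_probability),
                    "superior": rec.superior,
                    "active": {"x": rec.active.x, "n": rec.active.n},
                    "placebo": {"x": rec.placebo.x, "n": rec.placebo.n},
                }
                for rec in self.superiority
            ],
            "secondary_endpoints": json.loads(self.endpoints.to_json(orient="index")),
            "km": {arm: tbl.to_dict(orient="list") for arm, tbl in self.km_tables.items()},
            "logrank_vs_placebo": {
                arm: {"chi2": chi2, "p": p} for arm, (chi2, p) in self.logrank.items()
            },
        }

    def render_text(self) -> str:
        lines = [
            f"aftrial v{self.version}  (config {self.config_hash[:10]})",
            f"Randomized {self.n_randomized}; safety set {self.sets.n_safety}; "
            f"full analysis set {self.sets.n_full_analysis}",
            "Exclusions: " + ", ".join(f"{k}={v}" for k, v in self.sets.exclusions.items()),
            "",
            "Primary endpoint (cardioversion within 90 min, full analysis set):",
        ]
        sup_by_arm = {rec.dose: rec for rec in self.superiority}
        for a in self.arms:
            line = (f"  {a.arm:>10}: {a.x}/{a.n} ({a.percent_rounded}%)  "
                    f"{int(a.ci_level * 100)}% CI {a.ci_percent[0]}-{a.ci_percent[1]}%")
            dose = None if a.arm == PLACEBO else float(a.arm.split()[0])
            if dose is not None and dose in sup_by_arm:
                rec = sup_by_arm[dose]
                call = "superior" if rec.superior else "not superior"
                line += (f"  P(superior to placebo) = "
                         f"{format_probability_percent(rec.posterior_probability)} ({call})")
            lines.append(line)
        lines.append("")
        lines.append("Log-rank vs pooled placebo (time to conversion):")
        for arm, (chi2, p) in self.logrank.items():
            lines.append(f"  {arm:>10}: chi2 = {chi2:.2f}, two-sided p = {p:.2g}")
        return "\n".join(lines)


def config_digest(config: DesignConfig) -> str:
    payload = yaml.safe_dump({
        "dose_ladder": list(config.dose_ladder),
        "target_rate": config.target_rate,
        "thresholds": [config.interim_futility_threshold,
                       config.interim_efficacy_threshold,
                       config.final_superiority_threshold],
        "max_enrollment": config.max_enrollment,
        "prior": [config.prior.alpha, config.prior.beta],
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def build_report(
    cohort: Sequence[PatientRecord],
    config: DesignConfig | None = None,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Run the whole efficacy analysis over a randomized cohort."""
    config = config or DesignConfig()
    sets = build_analysis_sets(cohort)
    if sets.n_full_analysis == 0:
        raise ValueError("empty full analysis set: no analyzable patients")
    endpoints = endpoint_summary(cohort, sets)

    arms: list[ArmReport] = []
    counts_by_arm: dict[str, ArmCounts] = {}
    for arm, row in endpoints.iterrows():
        counts = ArmCounts(n=int(row["primary_n"]), x=int(row["primary_x"]))
        counts_by_arm[arm] = counts
        ci = exact_binomial_ci(counts, level=level)
        pct = 100.0 * counts.proportion
        arms.append(ArmReport(
            arm=arm, x=counts.x, n=counts.n,
            percent_raw=pct, percent_rounded=round_half_away(pct),
            ci_lower=ci.lower, ci_upper=ci.upper,
            ci_percent=ci.as_percent(), ci_level=level,
        ))

    superiority: list[SuperiorityRecord] = []
    logrank: dict[str, tuple[float, float]] = {}
    km_tables: dict[str, "object"] = {}
    placebo_counts = counts_by_arm.get(PLACEBO)
    placebo_surv = survival_records(cohort, sets, arm=PLACEBO)
    for arm, counts in counts_by_arm.items():
        arm_surv = survival_records(cohort, sets, arm=arm)
        km_tables[arm] = km_estimate(arm_surv).to_frame()
        if arm == PLACEBO or placebo_counts is None:
            continue
        dose = float(arm.split()[0])
        superiority.append(final_superiority(counts, placebo_counts, config, dose=dose))
        try:
            res = logrank_test(arm_surv, placebo_surv)
            logrank[arm] = (res.statistic, res.p_value)
        except ValueError:
            pass  # zero events in both groups: test undefined, omitted
    superiority.sort(key=lambda rec: rec.dose)

    return AnalysisReport(
        n_randomized=len(cohort),
        sets=sets,
        arms=arms,
        superiority=superiority,
        endpoints=endpoints,
        km_tables=km_tables,
        logrank=logrank,
        ci_level=level,
        config_hash=config_digest(config),
        seed=seed,
    )
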
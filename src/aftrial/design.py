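"""Adaptive dose-finding decision logic.

The trial design walks a ladder of doses (2-6 mg/kg). At scheduled interims
the open dose's evaluable counts are scored against a target cardioversion
rate (0.65): posterior probability >= 0.90 closes the dose for sufficient
efficacy and opens the next dose down; < 0.10 closes it for futility and
opens the next dose up; anything between continues enrollment. At the end,
each tested dose is compared with the pooled placebo arm by posterior
probability of superiority (> 0.95 declares superiority). Patients are
allocated active:placebo by permuted blocks — 1:1 (blocks of 2) in part 1
and 2:1 (blocks of 3) thereafter.

Threshold strictness follows the design exactly: efficacy fires at >= 0.90,
futility at < 0.10, superiority at > 0.95.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .bayes import ArmCounts, BetaParams, posterior_update, prob_exceeds, prob_superiority

__all__ = [
    "InterimAction",
    "InterimDecision",
    "SuperiorityRecord",
    "DesignConfig",
    "TrialState",
    "EnrollmentClosedError",
    "interim_decision",
    "final_superiority",
    "allocate",
    "step_dose",
]

PLACEBO = "placebo"


class InterimAction(enum.Enum):
    CLOSE_FOR_EFFICACY_OPEN_LOWER = "close_for_efficacy_open_lower"
    CLOSE_FOR_FUTILITY_OPEN_HIGHER = "close_for_futility_open_higher"
    CONTINUE = "continue"


class EnrollmentClosedError(RuntimeError):
    """Raised when an allocation is requested after the cap or a stop."""


@dataclass(frozen=True)
class InterimDecision:
    action: InterimAction
    posterior_prob_above_target: float
    dose_opened: Optional[float] = None


@dataclass(frozen=True)
class SuperiorityRecord:
    """Final Bayesian comparison of one dose arm against pooled placebo."""

    dose: Optional[float]
    posterior_probability: float
    superior: bool
    active: ArmCounts
    placebo: ArmCounts


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters of the adaptive trial.

    Defaults reproduce the realized design: ladder 2-6 mg/kg starting at
    3 mg/kg, target rate 0.65, interim thresholds 0.90/0.10, final
    superiority threshold 0.95, cap 108 patients, 1:1 allocation in part 1
    then 2:1, interims after 32 patients enrolled while the 3 mg/kg dose is
    open and 18 while 5 mg/kg is open, uniform Beta(1,1) prior per arm.

    ``dose_overrides`` maps an open dose to the explicit dose to open when it
    closes, overriding the default one-level ladder step (the monitoring
    committee could skip levels; the actual trial moved 3 -> 5 mg/kg).
    ``interim_interval`` schedules further interims every so-many patients
    enrolled at doses beyond the explicit schedule.
    """

    dose_ladder: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)
    start_dose: float = 3.0
    target_rate: float = 0.65
    interim_efficacy_threshold: float = 0.90
    interim_futility_threshold: float = 0.10
    final_superiority_threshold: float = 0.95
    max_enrollment: int = 108
    allocation_part1: tuple[int, int] = (1, 1)
    allocation_later: tuple[int, int] = (2, 1)
    interim_schedule: tuple[tuple[float, int], ...] = ((3.0, 32), (5.0, 18))
    interim_interval: int = 18
    prior: BetaParams = field(default_factory=lambda: BetaParams(1.0, 1.0))
    dose_overrides: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ladder = tuple(self.dose_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("dose_ladder must be strictly increasing")
        if self.start_dose not in ladder:
            raise ValueError(f"start_dose {self.start_dose} not on the ladder")
        if not 0 < self.interim_futility_threshold < self.interim_efficacy_threshold < 1:
            raise ValueError("need 0 < futility < efficacy < 1")
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0,1)")
        if self.max_enrollment < sum(t for _, t in self.interim_schedule):
            raise ValueError("max_enrollment below the summed interim triggers")

    def interim_trigger(self, dose: float) -> int:
        """Enrollment count while ``dose`` is open that triggers an interim."""
        for d, trigger in self.interim_schedule:
            if d == dose:
                return trigger
        return self.interim_interval

    def to_yaml(self, path) -> None:
        data = {
            "dose_ladder": list(self.dose_ladder),
            "start_dose": self.start_dose,
            "target_rate": self.target_rate,
            "interim_efficacy_threshold": self.interim_efficacy_threshold,
            "interim_futility_threshold": self.interim_futility_threshold,
            "final_superiority_threshold": self.final_superiority_threshold,
            "max_enrollment": self.max_enrollment,
            "allocation_part1": list(self.allocation_part1),
            "allocation_later": list(self.allocation_later),
            "interim_schedule": [list(pair) for pair in self.interim_schedule],
            "interim_interval": self.interim_interval,
            "prior": [self.prior.alpha, self.prior.beta],
            "dose_overrides": {float(k): float(v) for k, v in self.dose_overrides.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "start_dose",
            "target_rate",
            "interim_efficacy_threshold",
            "interim_futility_threshold",
            "final_superiority_threshold",
            "max_enrollment",
            "interim_interval",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "dose_ladder" in data:
            kwargs["dose_ladder"] = tuple(float(d) for d in data["dose_ladder"])
        for key in ("allocation_part1", "allocation_later"):
            if key in data:
                kwargs[key] = tuple(int(v) for v in data[key])
        if "interim_schedule" in data:
            kwargs["interim_schedule"] = tuple(
                (float(d), int(t)) for d, t in data["interim_schedule"]
            )
        if "prior" in data:
            kwargs["prior"] = BetaParams(*map(float, data["prior"]))
        if "dose_overrides" in data:
            kwargs["dose_overrides"] = {
                float(k): float(v) for k, v in data["dose_overrides"].items()
            }
        return cls(**kwargs)


@dataclass
class TrialState:
    """Mutable enrollment state of a running (simulated) trial."""

    config: DesignConfig
    open_dose: float
    closed_doses: set[float] = field(default_factory=set)
    part: int = 1
    total_randomized: int = 0
    enrolled_at_open_dose: int = 0
    stopped: bool = False
    stop_reason: Optional[str] = None
    pending_block: list[str] = field(default_factory=list)

    @classmethod
    def initial(cls, config: DesignConfig) -> "TrialState":
        return cls(config=config, open_dose=config.start_dose)

    @property
    def allocation_ratio(self) -> tuple[int, int]:
        return self.config.allocation_part1 if self.part == 1 else self.config.allocation_later


def interim_decision(
    counts: ArmCounts, config: DesignConfig, open_dose: Optional[float] = None
) -> InterimDecision:
    """Score the open dose's evaluable counts against the target rate.

    Returns the action plus the posterior probability q = P(p > target_rate)
    under the dose's Beta posterior. When ``open_dose`` is supplied the dose
    that would be opened (if any exists in the required direction, honoring
    ``dose_overrides``) is reported as well.
    """
    posterior = posterior_update(config.prior, counts)
    q = prob_exceeds(posterior, config.target_rate)
    if q >= config.interim_efficacy_threshold:
        action = InterimAction.CLOSE_FOR_EFFICACY_OPEN_LOWER
    elif q < config.interim_futility_threshold:
        action = InterimAction.CLOSE_FOR_FUTILITY_OPEN_HIGHER
    else:
        action = InterimAction.CONTINUE
    dose_opened = None
    if action is not InterimAction.CONTINUE and open_dose is not None:
        dose_opened = _next_dose(open_dose, action, config, set())
    return InterimDecision(action=action, posterior_prob_above_target=q, dose_opened=dose_opened)


def final_superiority(
    active: ArmCounts, pooled_placebo: ArmCounts, config: DesignConfig,
    dose: Optional[float] = None,
) -> SuperiorityRecord:
    """Final Bayesian superiority call for one dose versus pooled placebo."""
    if active.n == 0 or pooled_placebo.n == 0:
        raise ValueError("final superiority requires nonempty arms")
    post_active = posterior_update(config.prior, active)
    post_placebo = posterior_update(config.prior, pooled_placebo)
    prob = prob_superiority(post_active, post_placebo)
    return SuperiorityRecord(
        dose=dose,
        posterior_probability=prob,
        superior=prob > config.final_superiority_threshold,
        active=active,
        placebo=pooled_placebo,
    )


def allocate(state: TrialState, rng: np.random.Generator) -> str:
    """Draw one permuted-block arm assignment ("active" or "placebo").

    Blocks contain exactly the part's ratio (2 patients at 1:1, 3 at 2:1) in
    a uniformly shuffled order, so any 3k consecutive part-2 assignments hold
    2k active and k placebo. Deterministic given the generator state.
    """
    if state.stopped:
        raise EnrollmentClosedError(f"trial stopped: {state.stop_reason}")
    if state.total_randomized >= state.config.max_enrollment:
        raise EnrollmentClosedError("maximum enrollment reached")
    if not state.pending_block:
        n_active, n_placebo = state.allocation_ratio
        block = ["active"] * n_active + [PLACEBO] * n_placebo
        state.pending_block = [block[i] for i in rng.permutation(len(block))]
    assignment = state.pending_block.pop()
    state.total_randomized += 1
    state.enrolled_at_open_dose += 1
    return assignment


def _next_dose(
    current: float, action: InterimAction, config: DesignConfig, closed: set[float]
) -> Optional[float]:
    if current in config.dose_overrides:
        override = config.dose_overrides[current]
        if override not in closed and override != current:
            return override
    if action is InterimAction.CLOSE_FOR_EFFICACY_OPEN_LOWER:
        candidates = [d for d in config.dose_ladder if d < current and d not in closed]
        return max(candidates) if candidates else None
    candidates = [d for d in config.dose_ladder if d > current and d not in closed]
    return min(candidates) if candidates else None


def step_dose(state: TrialState, decision: InterimDecision, config: DesignConfig) -> TrialState:
    """Apply an interim decision to the trial state.

    CONTINUE leaves the state untouched. A closing action closes the open
    dose and opens the next one in the required direction (one ladder level
    by default, or the configured override); if none is available the trial
    stops with reason ``LADDER_EXHAUSTED``. Any dose change moves the trial
    to part 2 (2:1 allocation) and discards the unfilled allocation block.
    """
    if decision.action is InterimAction.CONTINUE:
        return state
    state.closed_doses.add(state.open_dose)
    next_dose = _next_dose(state.open_dose, decision.action, config, state.closed_doses)
    if next_dose is None:
        state.stopped = True
        state.stop_reason = "LADDER_EXHAUSTED"
        return state
    state.open_dose = next_dose
    state.enrolled_at_open_dose = 0
    state.part = 2
    state.pending_block = []
    return state
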
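"""Whole-trial simulation for design operating characteristics.

A simulated trial walks the adaptive design patient by patient: permuted-
block allocation at the part's ratio, Bernoulli conversion outcomes drawn
from an assumed truth, evaluability attrition, interim decisions at the
scheduled enrollment triggers, dose transitions on the ladder, the
enrollment cap, an optional exogenous early stop, and a final Bayesian
superiority comparison of every tested dose against the pooled placebo arm.
Replicated runs summarize the design's frequentist behavior (superiority
rates, dose paths, expected enrollment) with Monte Carlo standard errors.

Randomness discipline: one master seed; each replicate consumes an
independent child of ``numpy.random.SeedSequence(seed)`` so results are
exactly replayable and replicates are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .bayes import ArmCounts
from .design import (
    DesignConfig,
    InterimAction,
    InterimDecision,
    SuperiorityRecord,
    TrialState,
    allocate,
    final_superiority,
    interim_decision,
    step_dose,
)

__all__ = ["TruthScenario", "TrialResult", "OCSummary",
           "simulate_trial", "operating_characteristics"]


@dataclass(frozen=True)
class TruthScenario:
    """Assumed true conversion probabilities and attrition for simulation."""

    p_by_dose: Mapping[float, float]
    p_placebo: float
    not_infused_rate: float = 3 / 66
    not_evaluable_rate: float = 4 / 66
    early_stop_after: Optional[int] = None  # total randomized; sponsor hook

    def __post_init__(self) -> None:
        probs = [self.p_placebo, *self.p_by_dose.values(),
                 self.not_infused_rate, self.not_evaluable_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0,1]")

    def p_active(self, dose: float) -> float:
        try:
            return self.p_by_dose[dose]
        except KeyError:
            raise ValueError(f"no true rate configured for dose {dose}") from None


def truth_from_dict(data: Mapping) -> TruthScenario:
    """Build a :class:`TruthScenario` from a plain mapping (YAML front end)."""
    allowed = {"p_by_dose", "p_placebo", "not_infused_rate", "not_evaluable_rate",
               "early_stop_after"}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(f"unknown scenario field(s): {unknown}")
    missing = [k for k in ("p_by_dose", "p_placebo") if k not in data]
    if missing:
        raise ValueError(f"scenario is missing required field(s): {missing}")
    kwargs = dict(data)
    kwargs["p_by_dose"] = {float(k): float(v) for k, v in data["p_by_dose"].items()}
    return TruthScenario(**kwargs)


@dataclass(frozen=True)
class TrialResult:
    """One simulated trial's decision path and final analysis."""

    dose_path: tuple[tuple[float, InterimDecision], ...]
    counts_by_dose: Mapping[float, ArmCounts]
    placebo_counts: ArmCounts
    randomized_by_dose: Mapping[float, int]
    placebo_randomized: int
    superiority: tuple[SuperiorityRecord, ...]
    total_enrolled: int
    stop_reason: Optional[str]
    seed_entropy: int

    @property
    def doses_tested(self) -> tuple[float, ...]:
        seen: list[float] = []
        for dose, _ in self.dose_path:
            if dose not in seen:
                seen.append(dose)
        return tuple(seen)

    @property
    def any_superior(self) -> bool:
        return any(rec.superior for rec in self.superiority)


@dataclass(frozen=True)
class OCSummary:
    """Aggregated operating characteristics over independent replicates."""

    n_reps: int
    seed: int
    superiority_rate_by_dose: dict[float, float]
    superiority_se_by_dose: dict[float, float]
    any_superiority_rate: float
    any_superiority_se: float
    mean_total_enrollment: float
    dose_path_frequencies: dict[tuple[float, ...], float]
    results: tuple[TrialResult, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "superiority_rate_by_dose": {str(k): v for k, v in self.superiority_rate_by_dose.items()},
            "superiority_se_by_dose": {str(k): v for k, v in self.superiority_se_by_dose.items()},
            "any_superiority_rate": self.any_superiority_rate,
            "any_superiority_se": self.any_superiority_se,
            "mean_total_enrollment": self.mean_total_enrollment,
            "dose_path_frequencies": {
                "/".join(f"{d:g}" for d in path): freq
                for path, freq in self.dose_path_frequencies.items()
            },
        }


def simulate_trial(
    design: DesignConfig, truth: TruthScenario, seed: int | np.random.SeedSequence
) -> TrialResult:
    """Run one trial through the adaptive design; deterministic given seed.

    Interim triggers count patients randomized (both arms) while a dose is
    open — 32 while the starting 3 mg/kg dose is open, 18 while 5 mg/kg is,
    and every ``interim_interval`` at other doses. Interim decisions use the
    open dose's evaluable active-arm counts only; the final analysis pools
    placebo across parts.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    state = TrialState.initial(design)
    active: dict[float, list[int]] = {}   # dose -> [n_evaluable, x]
    randomized: dict[float, int] = {}
    placebo = [0, 0]
    placebo_randomized = 0
    dose_path: list[tuple[float, InterimDecision]] = []

    while not state.stopped and state.total_randomized < design.max_enrollment:
        dose = state.open_dose
        assignment = allocate(state, rng)
        infused = rng.random() >= truth.not_infused_rate
        evaluable = infused and rng.random() >= truth.not_evaluable_rate
        if assignment == "placebo":
            placebo_randomized += 1
            if evaluable:
                placebo[0] += 1
                placebo[1] += int(rng.random() < truth.p_placebo)
        else:
            randomized[dose] = randomized.get(dose, 0) + 1
            counts = active.setdefault(dose, [0, 0])
            if evaluable:
                counts[0] += 1
                counts[1] += int(rng.random() < truth.p_active(dose))
        if truth.early_stop_after is not None and state.total_randomized >= truth.early_stop_after:
            state.stopped = True
            state.stop_reason = "EARLY_STOP"
            break
        if state.enrolled_at_open_dose >= design.interim_trigger(dose):
            n_eval, x = active.get(dose, [0, 0])
            decision = interim_decision(ArmCounts(n=n_eval, x=x), design, open_dose=dose)
            dose_path.append((dose, decision))
            if decision.action is InterimAction.CONTINUE:
                state.enrolled_at_open_dose = 0  # next interim one interval later
            else:
                step_dose(state, decision, design)

    if state.total_randomized >= design.max_enrollment and state.stop_reason is None:
        state.stop_reason = "MAX_ENROLLMENT"

    counts_by_dose = {d: ArmCounts(n=c[0], x=c[1]) for d, c in active.items()}
    placebo_counts = ArmCounts(n=placebo[0], x=placebo[1])
    superiority = []
    if placebo_counts.n > 0:
        for dose in sorted(counts_by_dose):
            if counts_by_dose[dose].n > 0:
                superiority.append(
                    final_superiority(counts_by_dose[dose], placebo_counts, design, dose=dose)
                )
    if not dose_path:
        # no interim ever fired; record the dose that enrolled
        dose_path = [(state.open_dose,
                      InterimDecision(InterimAction.CONTINUE, float("nan")))]
    return TrialResult(
        dose_path=tuple(dose_path),
        counts_by_dose=counts_by_dose,
        placebo_counts=placebo_counts,
        randomized_by_dose=randomized,
        placebo_randomized=placebo_randomized,
        superiority=tuple(superiority),
        total_enrolled=state.total_randomized,
        stop_reason=state.stop_reason,
        seed_entropy=int(seq.entropy),
    )


def _rate_se(successes: int, n: int) -> tuple[float, float]:
    rate = successes / n
    return rate, float(np.sqrt(rate * (1.0 - rate) / n))


def operating_characteristics(
    design: DesignConfig,
    truth: TruthScenario,
    n_reps: int,
    seed: int,
    keep_results: bool = False,
) -> OCSummary:
    """Aggregate ``n_reps`` independent simulated trials.

    Per-dose superiority rates are computed over the replicates in which the
    dose was tested at all; the any-superiority rate (the type-I-style rate
    under a null truth) is over all replicates. Rates carry binomial Monte
    Carlo standard errors.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    results = [simulate_trial(design, truth, child) for child in children]

    tested: dict[float, int] = {}
    superior: dict[float, int] = {}
    any_superior = 0
    paths: dict[tuple[float, ...], int] = {}
    for res in results:
        any_superior += int(res.any_superior)
        paths[res.doses_tested] = paths.get(res.doses_tested, 0) + 1
        for rec in res.superiority:
            tested[rec.dose] = tested.get(rec.dose, 0) + 1
            superior[rec.dose] = superior.get(rec.dose, 0) + int(rec.superior)
    rate_by_dose, se_by_dose = {}, {}
    for dose in sorted(tested):
        rate_by_dose[dose], se_by_dose[dose] = _rate_se(superior.get(dose, 0), tested[dose])
    any_rate, any_se = _rate_se(any_superior, n_reps)
    return OCSummary(
        n_reps=n_reps,
        seed=seed,
        superiority_rate_by_dose=rate_by_dose,
        superiority_se_by_dose=se_by_dose,
        any_superiority_rate=any_rate,
        any_superiority_se=any_se,
        mean_total_enrollment=float(np.mean([r.total_enrolled for r in results])),
        dose_path_frequencies={p: c / n_reps for p, c in paths.items()},
        results=tuple(results) if keep_results else (),
    )
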
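"""Growing-bag inference and the trackable NEC risk score.

The growing bag re-evaluates a patient's bag after every new stool sample:
at time t the model sees only the first t instances and emits a confidence
c_it and attention vector A_i^t.  Confidences are translated into a
bounded risk trajectory by accumulating per-sample contributions

    v_t = (d_t - d_{t-1}) * (c_t - 0.5) * (a_t - a_t^min)

(day gap x zero-centered confidence x marginal attention of the newest
sample, with a^min the smallest attention in the current bag).  A sharp
drop in confidence between consecutive evaluations (> drop_threshold)
permanently flips the sign of all later contributions: for unaffected
infants the confidence typically collapses once enough healthy samples
accumulate, and the flip locks the trajectory onto a downward course.
The risk is the clipped cumulative sum r_t = clip(r_{t-1} + v_t / tau, 0, 1)
starting from r_init at birth (d_0 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from necmil.bags import PatientBag
from necmil.mil import MILConfig, MILParams, predict_bag, train_mil

__all__ = [
    "GrowingBagTrace",
    "RiskConfig",
    "RiskTrajectory",
    "growing_bag_trace",
    "contribution",
    "risk_trajectory",
    "classify_risk",
    "lead_time",
    "loo_growing_bag",
]


@dataclass
class GrowingBagTrace:
    patient_id: str
    days: List[int]
    confidences: np.ndarray          # c_i1 ... c_ik
    attention_history: List[np.ndarray]  # A_i^t, length t at step t
    label: int = 0
    onset_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, dtype=float)
        if len(self.days) != len(self.confidences) or len(self.days) != len(self.attention_history):
            raise ValueError("trace lengths disagree")
        for t, a in enumerate(self.attention_history, start=1):
            if len(a) != t or abs(a.sum() - 1.0) > 1e-6:
                raise ValueError(f"attention vector at step {t} invalid")


@dataclass
class RiskConfig:
    r_init: float = 0.5
    tau: float = 30.0               # day-units normalizing the contributions
    drop_threshold: float = 0.75    # sharp-decrease trigger on consecutive confidences
    cutoff: float = 0.35
    drop_mode: str = "consecutive"  # or "from_max": drop measured from the running peak

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.drop_mode not in ("consecutive", "from_max"):
            raise ValueError(f"unknown drop_mode {self.drop_mode!r}")


@dataclass
class RiskTrajectory:
    patient_id: str
    days: List[int]
    risks: np.ndarray
    flipped_from: Optional[int]     # 1-based step where the sign flip triggered
    crossing_day: Optional[int]     # first day with risk > cutoff
    config: RiskConfig
    label: int = 0
    onset_day: Optional[int] = None


def growing_bag_trace(
    bag: PatientBag,
    params: MILParams,
    trained_without: Optional[Sequence[str]] = None,
    strict: bool = False,
) -> GrowingBagTrace:
    """Evaluate the MIL model on every prefix of a patient's bag.

    ``trained_without`` lists the patient ids excluded from the model's
    training set; with ``strict=True`` the call refuses to score a patient
    the model was trained on (the leave-one-patient-out contract).
    """
    if strict:
        if trained_without is None or bag.patient_id not in set(trained_without):
            raise ValueError(
                f"strict mode: model not certified as trained without patient {bag.patient_id}"
            )
    confidences = []
    attns = []
    for t in range(1, len(bag) + 1):
        pred = predict_bag(bag.prefix(t), params)
        confidences.append(pred.confidence)
        attns.append(pred.attention)
    return GrowingBagTrace(
        patient_id=bag.patient_id,
        days=list(bag.days),
        confidences=np.array(confidences),
        attention_history=attns,
        label=bag.label,
        onset_day=bag.onset_day,
    )


def contribution(d_t: float, d_prev: float, c_t: float, a_t: float, a_min: float) -> float:
    """Risk contribution of one new sample:
    (day gap) x (zero-centered confidence) x (marginal attention)."""
    if d_t < d_prev:
        raise ValueError(f"day-of-life went backwards: {d_t} < {d_prev}")
    return (d_t - d_prev) * (c_t - 0.5) * (a_t - a_min)


def risk_trajectory(trace: GrowingBagTrace, config: Optional[RiskConfig] = None) -> RiskTrajectory:
    """Accumulate a bounded risk score from a growing-bag trace.

    Once the confidence falls by more than ``drop_threshold`` between
    consecutive evaluations (or from the running peak, in ``from_max``
    mode), every subsequent contribution is forced negative.
    """
    config = config or RiskConfig()
    c = trace.confidences
    risks = np.empty(len(c))
    r = config.r_init
    flipped = False
    flipped_from: Optional[int] = None
    d_prev = 0.0  # d_0: birth
    peak = -np.inf
    for t in range(len(c)):
        if t > 0:
            ref = peak if config.drop_mode == "from_max" else c[t - 1]
            if not flipped and ref - c[t] > config.drop_threshold:
                flipped = True
                flipped_from = t + 1
        peak = max(peak, c[t])
        a = trace.attention_history[t]
        v = contribution(trace.days[t], d_prev, c[t], float(a[-1]), float(a.min()))
        if flipped:
            v = -abs(v)
        r = float(np.clip(r + v / config.tau, 0.0, 1.0))
        risks[t] = r
        d_prev = trace.days[t]
    crossing = None
    above = np.nonzero(risks > config.cutoff)[0]
    if above.size:
        crossing = int(trace.days[above[0]])
    return RiskTrajectory(
        patient_id=trace.patient_id,
        days=list(trace.days),
        risks=risks,
        flipped_from=flipped_from,
        crossing_day=crossing,
        config=config,
        label=trace.label,
        onset_day=trace.onset_day,
    )


def classify_risk(risk: RiskTrajectory, cutoff: float = 0.35) -> Tuple[int, Optional[int]]:
    """Positive iff any risk value exceeds ``cutoff``; returns the first
    crossing day (or None)."""
    above = np.nonzero(risk.risks > cutoff)[0]
    if above.size == 0:
        return 0, None
    return 1, int(risk.days[above[0]])


def lead_time(crossing_day: Optional[int], onset_day: Optional[int]) -> Optional[int]:
    """Days of warning before disease onset (onset - crossing).

    Negative values are post-onset detections; callers exclude them from
    mean-lead-time summaries.  Undefined inputs give an absent result.
    """
    if crossing_day is None or onset_day is None:
        return None
    return onset_day - crossing_day


def loo_growing_bag(
    bags: Sequence[PatientBag],
    mil_config: Optional[MILConfig] = None,
    risk_config: Optional[RiskConfig] = None,
    seed: int = 0,
    refit=None,
) -> List[RiskTrajectory]:
    """Leave-one-patient-out driver: for each patient, train on all other
    complete bags, trace the held-out patient's growing bag and score it.

    ``refit``, if given, is called with the list of training bags and the
    held-out bag and must return ``(train_bags, holdout_bag)`` — the hook
    through which feature selection is refitted per fold without leakage.
    Every patient is covered exactly once and no model ever saw its
    evaluation patient.
    """
    risk_config = risk_config or RiskConfig()
    out: List[RiskTrajectory] = []
    for i, bag in enumerate(bags):
        others = [b for j, b in enumerate(bags) if j != i]
        if refit is not None:
            others, bag = refit(others, bag)
        params = train_mil(others, config=mil_config, seed=seed * 10007 + i)
        trace = growing_bag_trace(
            bag, params, trained_without=[bag.patient_id], strict=True
        )
        out.append(risk_trajectory(trace, risk_config))
    return out
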
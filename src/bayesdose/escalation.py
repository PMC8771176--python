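"""Dose-escalation decision rules.

After each cohort the posterior drives three rules:

1. *Safe-dose set* (overdose control): dose j is safe iff
   ``P(ARDLT_j >= gamma_toxic) < c_overdose``.
2. *Recommendation*: among safe doses reachable without more than doubling
   the current actual dose (de-escalation is unconstrained), assign the
   next cohort to the dose maximising
   ``P(ARDLT in [gamma - delta, gamma + delta])``; ties go to the lower
   dose.  An empty safe set stops the trial.
3. *Completion*: the trial ends when the maximum sample size is reached or
   all doses are deemed unsafe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DesignConfig, EscalationConstraints, SafetyParams
from .model import DoseGrid, PosteriorState, StandardizedDoses, TrialData

__all__ = [
    "SafetyParams",
    "EscalationConstraints",
    "Decision",
    "dose_probability_table",
    "safe_dose_set",
    "recommend_dose",
    "check_trial_complete",
]


@dataclass(frozen=True)
class Decision:
    """Outcome of one decision point.

    ``action`` is one of ``escalate``, ``de-escalate``, ``stay``,
    ``stop_all_unsafe``; ``recommended_arm`` is the dose index (1..m) the
    next cohort should receive, absent only when stopping.  ``rationale``
    holds the per-dose probability table the decision was read off.
    """

    action: str
    recommended_arm: int | None
    rationale: dict

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "recommended_arm": self.recommended_arm,
            "rationale": self.rationale,
        }


def dose_probability_table(
    post: PosteriorState,
    std_doses: StandardizedDoses,
    safety: SafetyParams,
) -> dict:
    """Per-dose P(overdose) and P(target interval), each an array over doses 1..m.

    Both probabilities are weighted tail/interval masses of the joint
    posterior ARDLT, computed in one pass over the support points.
    """
    risks = post.risk_matrix(std_doses)
    ardlt = risks[:, 1:] - risks[:, [0]]
    w = post.weights
    lo, hi = safety.target_interval
    return {
        "prob_overdose": w @ (ardlt >= safety.gamma_toxic),
        "prob_target": w @ ((ardlt >= lo) & (ardlt <= hi)),
    }


def safe_dose_set(
    post: PosteriorState,
    std_doses: StandardizedDoses,
    safety: SafetyParams,
) -> set[int]:
    """Doses passing overdose control: ``P(ARDLT >= gamma_toxic) < c_overdose``."""
    table = dose_probability_table(post, std_doses, safety)
    return {
        j + 1
        for j, p in enumerate(table["prob_overdose"])
        if p < safety.c_overdose
    }


def recommend_dose(
    post: PosteriorState,
    std_doses: StandardizedDoses,
    safety: SafetyParams,
    current_arm: int | None,
    constraints: EscalationConstraints,
    dose_grid: DoseGrid,
) -> Decision:
    """Pick the next dose: target-interval argmax over the reachable safe set.

    ``current_arm=None`` (no cohort dosed yet) imposes no fold-change
    constraint: the engine then simply proposes the best safe dose, which a
    protocol typically fixes to the lowest dose anyway.
    """
    table = dose_probability_table(post, std_doses, safety)
    safe = sorted(safe_dose_set(post, std_doses, safety))
    if not safe:
        return Decision(
            action="stop_all_unsafe",
            recommended_arm=None,
            rationale=_rationale(table),
        )
    if current_arm is not None:
        current_actual = dose_grid.actual_dose[current_arm - 1]
        ceiling = constraints.max_fold_increase * current_actual
        reachable = [j for j in safe if dose_grid.actual_dose[j - 1] <= ceiling]
        if not constraints.allow_skipping:
            reachable = [j for j in reachable if j <= current_arm + 1]
    else:
        reachable = safe
    if not reachable:
        # safe doses exist but none is administrable from here; fall back to
        # the highest safe dose below the ceiling is empty only if even the
        # lowest dose exceeds it, which cannot happen with fold >= 1 — keep a
        # defensive stop for pathological grids.
        return Decision(
            action="stop_all_unsafe",
            recommended_arm=None,
            rationale=_rationale(table),
        )
    probs = table["prob_target"]
    best = max(reachable, key=lambda j: (probs[j - 1], -j))  # tie -> lower dose
    if current_arm is None or best == current_arm:
        action = "stay"
    elif best > current_arm:
        action = "escalate"
    else:
        action = "de-escalate"
    return Decision(action=action, recommended_arm=best, rationale=_rationale(table))


def _rationale(table: dict) -> dict:
    return {
        "prob_overdose": [float(x) for x in table["prob_overdose"]],
        "prob_target": [float(x) for x in table["prob_target"]],
    }


def check_trial_complete(data: TrialData, config: DesignConfig) -> bool:
    """True iff the accumulated sample size has reached the cap (if any)."""
    max_n = config.cohort.max_n
    if max_n is None:
        return False
    return data.total_patients >= max_n
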
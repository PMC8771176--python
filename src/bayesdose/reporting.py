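"""Safety-Review-Committee style outputs.

Three analyses a safety committee sees at each review:

* :func:`build_report` — per-arm posterior summary table (DLT risk, 95%
  credible interval, ARDLT, overdose and target-interval probabilities)
  plus the model's dose recommendation;
* :func:`what_if` — the recommendation recomputed under every hypothetical
  outcome of one more cohort (a dose-transition-pathway table);
* :func:`sensitivity_partial_dosing` — the three-way analysis for a
  participant who received only part of the dosing schedule: counted as a
  non-DLT, counted as a DLT, or excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DesignConfig
from .escalation import Decision, recommend_dose
from .model import (
    DoseSummary,
    InferenceSettings,
    PosteriorState,
    TrialData,
    query_dose,
    update_posterior,
)

__all__ = ["SrcReport", "WhatIfTable", "build_report", "what_if", "sensitivity_partial_dosing"]


@dataclass
class SrcReport:
    """Posterior summary table plus the model recommendation."""

    table: pd.DataFrame
    decision: Decision
    data: TrialData
    prior_only: bool
    backend: str
    n_support: int

    @property
    def recommended_arm(self) -> int | None:
        return self.decision.recommended_arm


@dataclass
class WhatIfTable:
    """Recommendation under each hypothetical next-cohort outcome.

    ``rows`` is indexed by (treatment DLTs, control DLTs); ``base`` is the
    observed-data-only report the hypotheticals are measured against.
    """

    arm: int
    base: SrcReport
    rows: pd.DataFrame


def _arm_labels(design: DesignConfig) -> list[str]:
    return ["control"] + list(design.dose_grid.labels)


def _posterior(
    design: DesignConfig, data: TrialData, settings: InferenceSettings | None
) -> PosteriorState:
    settings = settings or design.inference
    return update_posterior(design.prior, design.std_doses, data, settings)


def _summary_table(
    design: DesignConfig, post: PosteriorState, data: TrialData
) -> pd.DataFrame:
    s = design.safety
    rows = []
    for j in range(design.m + 1):
        q = query_dose(
            post, design.std_doses, j,
            gamma=s.gamma, delta=s.delta, gamma_toxic=s.gamma_toxic,
        )
        rows.append(
            {
                "arm": _arm_labels(design)[j],
                "n_patients": int(data.n_patients[j]),
                "n_dlt": int(data.n_dlt[j]),
                "mean_dlt_risk": q.mean_risk,
                "ci_low": q.ci_low,
                "ci_high": q.ci_high,
                "ardlt_mean": q.ardlt_mean,
                "prob_overdose": q.prob_overdose,
                "prob_target": q.prob_target,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    design: DesignConfig,
    data: TrialData,
    settings: InferenceSettings | None = None,
    current_arm: int | None = "auto",
) -> SrcReport:
    """Posterior summary table and recommendation for a data snapshot.

    ``current_arm="auto"`` takes the highest dose with any patients (the
    dose-skipping constraint then applies from there); pass ``None`` for an
    unconstrained recommendation or an explicit arm index.  Empty data
    produces a prior-only report, flagged as such.
    """
    if current_arm == "auto":
        dosed = np.nonzero(data.n_patients[1:])[0]
        current_arm = int(dosed[-1]) + 1 if dosed.size else None
    post = _posterior(design, data, settings)
    decision = recommend_dose(
        post, design.std_doses, design.safety, current_arm,
        design.constraints, design.dose_grid,
    )
    return SrcReport(
        table=_summary_table(design, post, data),
        decision=decision,
        data=data.copy(),
        prior_only=data.total_patients == 0,
        backend=post.backend,
        n_support=post.n_support,
    )


def what_if(
    design: DesignConfig,
    data: TrialData,
    hypothetical_arm: int,
    settings: InferenceSettings | None = None,
    full_grid: bool = False,
) -> WhatIfTable:
    """Recommendations under every outcome of one more cohort at one dose.

    By default control DLTs are fixed at zero (a clean control pair added
    to the observed pattern) and treatment DLTs range 0..n_treat;
    ``full_grid=True`` enumerates all (treatment, control) outcome pairs,
    giving (n_treat+1) x (n_control+1) rows.
    """
    if not 1 <= hypothetical_arm <= design.m:
        raise IndexError("hypothetical_arm out of range")
    plan = design.cohort
    base = build_report(design, data, settings)
    control_outcomes = range(plan.n_control + 1) if full_grid else [0]
    rows = []
    for t in range(plan.n_treat + 1):
        for c in control_outcomes:
            hypo = data.with_added(hypothetical_arm, plan.n_treat, t)
            hypo = hypo.with_added(0, plan.n_control, c)
            rep = build_report(design, hypo, settings, current_arm=hypothetical_arm)
            arm_row = rep.table.iloc[hypothetical_arm]
            rows.append(
                {
                    "dlt_treat": t,
                    "dlt_control": c,
                    "mean_dlt_risk": arm_row.mean_dlt_risk,
                    "ci_low": arm_row.ci_low,
                    "ci_high": arm_row.ci_high,
                    "prob_overdose": arm_row.prob_overdose,
                    "prob_target": arm_row.prob_target,
                    "action": rep.decision.action,
                    "recommended_arm": rep.decision.recommended_arm,
                }
            )
    return WhatIfTable(arm=hypothetical_arm, base=base, rows=pd.DataFrame(rows))


def sensitivity_partial_dosing(
    design: DesignConfig,
    data: TrialData,
    arm: int,
    settings: InferenceSettings | None = None,
) -> dict[str, SrcReport]:
    """Three-way sensitivity analysis for one partially dosed participant.

    ``data`` must already count the participant as a non-DLT on ``arm``.
    Variants: ``"included_no_dlt"`` (as given), ``"included_dlt"`` (their
    outcome flipped to a DLT), ``"excluded"`` (removed from the arm).
    """
    if not 0 <= arm <= design.m:
        raise IndexError("arm out of range")
    if data.n_patients[arm] < 1:
        raise ValueError("no participant on that arm to vary")
    as_dlt = data.with_added(arm, 0, 1)  # flip one outcome to DLT
    excluded = data.copy()
    excluded.n_patients[arm] -= 1
    if excluded.n_dlt[arm] > excluded.n_patients[arm]:
        raise ValueError("exclusion would leave more DLTs than patients")
    return {
        "included_no_dlt": build_report(design, data, settings),
        "included_dlt": build_report(design, as_dlt, settings),
        "excluded": build_report(design, excluded, settings),
    }
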
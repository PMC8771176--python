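"""Design configuration: the full parameter roster of the escalation design.

Collects everything a trial statistician fixes before the first cohort:
the dose grid, the safety parameters (target ARDLT and its tolerance, the
unacceptable-toxicity bound and the overdose-control threshold), cohort
structure and randomisation ratio, the maximum sample size, the prior
hyperparameters and the dose-toxicity skeleton.  Serialisable to/from
YAML or JSON dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logit

from .model import (
    DoseGrid,
    PriorSpec,
    Skeleton,
    StandardizedDoses,
    InferenceSettings,
    build_skeleton,
    standardize_doses,
)

__all__ = [
    "SafetyParams",
    "EscalationConstraints",
    "CohortPlan",
    "DesignConfig",
    "default_design",
]


@dataclass(frozen=True)
class SafetyParams:
    """Safety-driven decision parameters, all on the ARDLT scale.

    ``gamma`` is the target additional toxicity, ``delta`` the half-width
    of the acceptable interval around it, ``gamma_toxic`` the unacceptable
    additional-toxicity bound, and ``c_overdose`` the posterior-probability
    threshold of the overdose-control rule
    ``P(ARDLT >= gamma_toxic) < c_overdose``.
    """

    gamma: float = 0.20
    delta: float = 0.05
    gamma_toxic: float = 0.30
    c_overdose: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.gamma - self.delta:
            raise ValueError("gamma - delta must be positive")
        if not self.gamma + self.delta <= self.gamma_toxic <= 1:
            raise ValueError("need gamma + delta <= gamma_toxic <= 1")
        if not 0 < self.c_overdose < 1:
            raise ValueError("c_overdose must lie in (0, 1)")

    @property
    def target_interval(self) -> tuple[float, float]:
        return (self.gamma - self.delta, self.gamma + self.delta)


@dataclass(frozen=True)
class EscalationConstraints:
    """Dose-skipping rule: skipping is allowed but the actual dose may at
    most double in a single escalation; de-escalation is unconstrained."""

    max_fold_increase: float = 2.0
    allow_skipping: bool = True

    def __post_init__(self) -> None:
        if self.max_fold_increase < 1:
            raise ValueError("max_fold_increase must be >= 1")


@dataclass(frozen=True)
class CohortPlan:
    """Cohort structure: ``n_treat`` randomised to the current dose and
    ``n_control`` to control per cohort (2:1 by default), up to ``max_n``
    patients in total (``None`` = no formal cap)."""

    cohort_size: int = 6
    n_treat: int = 4
    n_control: int = 2
    max_n: int | None = 30

    def __post_init__(self) -> None:
        if self.n_treat + self.n_control != self.cohort_size:
            raise ValueError("n_treat + n_control must equal cohort_size")
        if self.max_n is not None and self.max_n % self.cohort_size != 0:
            raise ValueError("max_n must be a multiple of cohort_size when capped")


@dataclass(frozen=True)
class DesignConfig:
    dose_grid: DoseGrid
    safety: SafetyParams = SafetyParams()
    constraints: EscalationConstraints = EscalationConstraints()
    cohort: CohortPlan = CohortPlan()
    # calibrated prior: the roster values 1.10 and 0.30 are the diagonal
    # elements of the prior covariance matrix (variances of theta1 and
    # log theta2); PriorSpec carries standard deviations.
    prior: PriorSpec = PriorSpec(
        mu1=float(logit(0.1)),
        mu2=-0.05,
        sigma1=float(np.sqrt(1.10)),
        sigma2=float(np.sqrt(0.30)),
    )
    skeleton_p0: float = 0.10
    skeleton_nu: float = 0.075
    start_arm: int = 1
    theta2_location: str = "mean"
    inference: InferenceSettings = InferenceSettings()

    def __post_init__(self) -> None:
        if not 1 <= self.start_arm <= self.m:
            raise ValueError("start_arm must index an experimental dose")

    @property
    def m(self) -> int:
        return self.dose_grid.m

    @property
    def skeleton(self) -> Skeleton:
        return build_skeleton(self.skeleton_p0, self.skeleton_nu, self.m)

    @property
    def std_doses(self) -> StandardizedDoses:
        return standardize_doses(self.skeleton, self.prior, self.theta2_location)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "doses": {
                "labels": list(self.dose_grid.labels),
                "actual_mg": list(self.dose_grid.actual_dose),
            },
            "safety": asdict(self.safety),
            "constraints": asdict(self.constraints),
            "cohort": asdict(self.cohort),
            "prior": asdict(self.prior),
            "skeleton": {"p0": self.skeleton_p0, "nu": self.skeleton_nu},
            "start_arm": self.start_arm,
            "theta2_location": self.theta2_location,
            "inference": asdict(self.inference),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        doses = d["doses"]
        grid = DoseGrid(tuple(doses["labels"]), tuple(doses["actual_mg"]))
        kwargs: dict = {"dose_grid": grid}
        if "safety" in d:
            kwargs["safety"] = SafetyParams(**d["safety"])
        if "constraints" in d:
            kwargs["constraints"] = EscalationConstraints(**d["constraints"])
        if "cohort" in d:
            kwargs["cohort"] = CohortPlan(**d["cohort"])
        if "prior" in d:
            kwargs["prior"] = PriorSpec(**d["prior"])
        if "skeleton" in d:
            kwargs["skeleton_p0"] = d["skeleton"]["p0"]
            kwargs["skeleton_nu"] = d["skeleton"]["nu"]
        for key in ("start_arm", "theta2_location"):
            if key in d:
                kwargs[key] = d[key]
        if "inference" in d:
            kwargs["inference"] = InferenceSettings(**d["inference"])
        return cls(**kwargs)


def default_design(**overrides) -> DesignConfig:
    """The calibrated four-dose design: doses 300/400/600/800 mg bd, target
    ARDLT 20% +/- 5%, overdose bound 30% at threshold 0.25, cohorts of six
    randomised 2:1, N = 30, prior mu1 = logit(0.1), mu2 = -0.05,
    prior variances 1.10 for theta1 and 0.30 for log theta2, skeleton
    increment nu = 0.075."""
    grid = DoseGrid(
        labels=("300 mg bd", "400 mg bd", "600 mg bd", "800 mg bd"),
        actual_dose=(300.0, 400.0, 600.0, 800.0),
    )
    return DesignConfig(dose_grid=grid, **overrides)
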
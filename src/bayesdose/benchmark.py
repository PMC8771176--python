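"""Non-parametric optimal benchmark for binary DLT outcomes.

An upper bound on the performance of any dose-finding design: each
simulated patient i receives a latent tolerance u_i ~ Uniform(0,1) that
determines their complete toxicity profile across *all* doses (a DLT at
dose j iff u_i <= true_p_j), as if every patient had been observed on
every dose.  The benchmark then estimates each dose's DLT rate from the
full profiles and selects the dose closest to the target rate.

Profiles are coherent by construction: a DLT at dose j implies a DLT at
every higher dose, since the true risks are nondecreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Scenario

__all__ = ["BenchmarkConfig", "select_dose", "benchmark_replicate", "benchmark_pcs"]


@dataclass(frozen=True)
class BenchmarkConfig:
    """``n_patients`` latent tolerances per replicate; ``target_dlt`` is the
    absolute DLT-rate target (control rate + target ARDLT, 0.30 by
    default).  The benchmark is non-randomised: the control rate is taken
    as known."""

    n_patients: int = 30
    target_dlt: float = 0.30
    n_reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.target_dlt < 1:
            raise ValueError("target_dlt must lie in (0, 1)")


def select_dose(u: np.ndarray, dose_p: np.ndarray, target: float) -> int:
    """Benchmark selection for one replicate's tolerance vector ``u``.

    Per-dose estimate p_hat_j = fraction of tolerances <= p_j; returns the
    1-based dose index minimising |p_hat_j - target| (ties -> lower dose).
    """
    u = np.asarray(u, dtype=float)
    p_hat = (u[:, None] <= dose_p[None, :]).mean(axis=0)
    return int(np.argmin(np.abs(p_hat - target))) + 1


def benchmark_replicate(
    scenario: Scenario, config: BenchmarkConfig, rng: np.random.Generator
) -> int:
    """Draw one replicate's tolerances and return the selected dose (1-based)."""
    dose_p = np.asarray(scenario.true_p[1:], dtype=float)
    u = rng.uniform(size=config.n_patients)
    return select_dose(u, dose_p, config.target_dlt)


def benchmark_pcs(scenario: Scenario, config: BenchmarkConfig) -> np.ndarray:
    """Monte-Carlo per-dose selection proportions over ``config.n_reps`` replicates.

    Vectorised over replicates (chunked to bound memory); proportions sum
    to 1 exactly.
    """
    dose_p = np.asarray(scenario.true_p[1:], dtype=float)
    rng = np.random.default_rng(config.seed)
    counts = np.zeros(scenario.m, dtype=np.int64)
    remaining = config.n_reps
    chunk = 20_000
    while remaining > 0:
        k = min(chunk, remaining)
        u = rng.uniform(size=(k, config.n_patients))
        p_hat = (u[:, :, None] <= dose_p[None, None, :]).mean(axis=1)
        sel = np.argmin(np.abs(p_hat - config.target_dlt), axis=1)
        counts += np.bincount(sel, minlength=scenario.m)
        remaining -= k
    return counts / config.n_reps
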
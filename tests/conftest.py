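"""Shared fixtures and the independent grid-integration oracle.

The oracle evaluates posterior tail/interval probabilities on a fine
uniform grid over ``(theta1, log theta2)`` with hard indicator functions —
a route entirely separate from the package's reference-slab quadrature and
its smoothed indicators, so agreement is evidence, not tautology.
"""

import numpy as np
import pytest
from scipy.special import expit

import bayesdose as bd


@pytest.fixture(scope="session")
def design():
    return bd.default_design()


def grid_oracle(prior, std_doses, data, gamma_toxic=0.30, interval=(0.15, 0.25), n=400):
    """Hard-indicator posterior queries on an n x n uniform grid (+/-10 prior SD).

    Returns (prob_overdose, prob_target, mean_risks) arrays.
    """
    t1 = np.linspace(prior.mu1 - 10 * prior.sigma1, prior.mu1 + 10 * prior.sigma1, n)
    lt2 = np.linspace(prior.mu2 - 10 * prior.sigma2, prior.mu2 + 10 * prior.sigma2, n)
    T1, LT2 = np.meshgrid(t1, lt2, indexing="ij")
    T1, LT2 = T1.ravel(), LT2.ravel()
    d = std_doses.with_control
    eta = T1[:, None] + np.exp(LT2)[:, None] * d[None, :]
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    logw = (
        -0.5 * ((T1 - prior.mu1) / prior.sigma1) ** 2
        - 0.5 * ((LT2 - prior.mu2) / prior.sigma2) ** 2
        + logp @ data.n_dlt
        + log1mp @ (data.n_patients - data.n_dlt)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    risks = expit(eta)
    ardlt = risks[:, 1:] - risks[:, [0]]
    lo, hi = interval
    return (
        w @ (ardlt >= gamma_toxic),
        w @ ((ardlt >= lo) & (ardlt <= hi)),
        w @ risks,
    )


class FixedRiskState:
    """Duck-typed posterior with an explicit per-support-point risk matrix.

    Lets decision-rule tests pin arbitrary per-arm DLT risks (including
    point masses) that no single (theta1, theta2) pair could produce, so
    the rules are exercised directly against enumerable truth.
    """

    def __init__(self, risks, weights=None):
        self._risks = np.atleast_2d(np.asarray(risks, dtype=float))
        n = self._risks.shape[0]
        w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
        self.weights = w / w.sum()

    def risk_matrix(self, std_doses):
        return self._risks


def weighted_state(theta1, theta2, weights):
    theta1 = np.asarray(theta1, float)
    theta2 = np.asarray(theta2, float)
    weights = np.asarray(weights, float)
    return bd.PosteriorState(theta1, theta2, weights / weights.sum(), backend="test")
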
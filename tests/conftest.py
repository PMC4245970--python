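"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately take a different computational route from the
library: the likelihood maximizer is a generic numeric optimizer over the
simplex, and the structure-scoring oracle enumerates credit assignments
exhaustively. They verify the closed forms; they never share code with
them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from shapeseq import DropoffModel, TargetRNA, stop_distribution


@pytest.fixture
def small_target() -> TargetRNA:
    return TargetRNA(name="x", sequence="GGAACC")


@pytest.fixture
def random_target():
    def make(length: int, seed: int, name: str = "t") -> TargetRNA:
        rng = np.random.default_rng(seed)
        return TargetRNA(name=name,
                         sequence="".join(rng.choice(list("ACGU"), size=length)))

    return make


def numeric_mle_theta(plus_counts, minus_counts, n_restarts: int = 25,
                      seed: int = 0) -> np.ndarray:
    """Numerically maximize the stated log-likelihood over (theta, p_mod).

    gamma is profiled from the minus channel (its hazard MLE); the plus
    log-likelihood is then maximized over the open simplex via softmax /
    sigmoid reparameterization with Nelder-Mead restarts. Independent of
    the closed-form path in shapeseq.model.
    """
    x = np.asarray(plus_counts, dtype=float)
    y = np.asarray(minus_counts, dtype=float)
    L = x.size - 1
    reach_y = np.cumsum(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(reach_y[1:] > 0, y[1:] / reach_y[1:], 0.0)
    gamma = np.minimum(gamma, 1.0 - 1e-12)

    def nll(z):
        w = np.exp(z[:L] - z[:L].max())
        theta = w / w.sum()
        p = 1.0 / (1.0 + np.exp(-z[L]))
        model = DropoffModel(gamma=gamma, theta=theta, p_mod=p)
        prob = stop_distribution(model, "plus")
        observed = x > 0
        if np.any(prob[observed] <= 0):
            return 1e12
        return -float(np.sum(x[observed] * np.log(prob[observed])))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        start = rng.normal(scale=1.5, size=L + 1)
        res = minimize(nll, start, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxiter=50_000,
                                    maxfev=50_000))
        if best is None or res.fun < best.fun:
            best = res
    w = np.exp(best.x[:L] - best.x[:L].max())
    return w / w.sum()


def brute_force_score(predicted, accepted, slippage: bool):
    """Exhaustive sensitivity/PPV credit count for small structures.

    Tries every injective assignment of predicted pairs to compatible
    accepted pairs and returns the maximum number credited.
    """
    pred = sorted(predicted.pairs)
    acc = sorted(accepted.pairs)
    if not slippage:
        return len(set(pred) & set(acc)), len(acc), len(pred)

    def compatible(p, a):
        (i, j), (x, y) = p, a
        return (i == x and abs(j - y) <= 1) or (j == y and abs(i - x) <= 1)

    best = 0
    options = [
        [ai for ai, a in enumerate(acc) if compatible(p, a)] + [None]
        for p in pred
    ]
    for assignment in itertools.product(*options):
        used = [a for a in assignment if a is not None]
        if len(used) == len(set(used)):
            best = max(best, len(used))
    return best, len(acc), len(pred)
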
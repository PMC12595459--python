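"""Independent margin oracles used by the tests.

The consolidation loop is never used here: the L1 oracle is a linear program
and the L2 oracle a small QP, both solved with scipy on tiny instances.
"""

import numpy as np
from scipy.optimize import linprog, minimize


def oracle_margin(xi: np.ndarray, i: int, p: float) -> float:
    """Maximum L_p-normalised margin of neuron i with w >= 0 and b >= 0.

    Returns nan if the instance is infeasible and inf if the neuron is
    silent in every pattern (w = 0, b > 0 separates trivially).
    """
    M, N = xi.shape
    y = 2.0 * xi[:, i] - 1.0
    X = xi.astype(float).copy()
    X[:, i] = 0.0  # no autapse
    if np.all(y < 0):
        return np.inf

    if p == 1:
        c = np.concatenate([np.ones(N), [0.0]])
        A_ub = -np.concatenate([y[:, None] * X, -y[:, None]], axis=1)
        res = linprog(
            c, A_ub=A_ub, b_ub=-np.ones(M), bounds=[(0, None)] * (N + 1), method="highs"
        )
        return 1.0 / np.sum(res.x[:N]) if res.success else np.nan

    assert p == 2

    def obj(v):
        return np.sum(v[:N] ** 2)

    def jac(v):
        g = np.zeros(N + 1)
        g[:N] = 2 * v[:N]
        return g

    cons = [
        {
            "type": "ineq",
            "fun": lambda v: y * (X @ v[:N] - v[N]) - 1,
            "jac": lambda v: np.concatenate([y[:, None] * X, -y[:, None]], axis=1),
        }
    ]
    bounds = [(0, None)] * N + [(0, None)]
    for w0, b0 in ((1.0, 0.5), (0.5, 1.0), (2.0, 0.0)):  # SLSQP needs restarts sometimes
        res = minimize(
            obj,
            np.concatenate([np.full(N, w0), [b0]]),
            jac=jac,
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if res.success:
            return 1.0 / np.sqrt(np.sum(res.x[:N] ** 2))
    return np.nan


def model_margins(state, patterns, p: float) -> np.ndarray:
    """Per-neuron L_p-normalised margin achieved by a synaptic state."""
    from synconsol.consolidation import margins

    I = margins(state, patterns)
    y = 2.0 * patterns.xi.T - 1.0
    signed = (y * I).min(axis=1)
    norm = np.sum(state.w**p, axis=1) ** (1.0 / p)
    return np.divide(signed, norm, out=np.zeros_like(signed), where=norm > 0)
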
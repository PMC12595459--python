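"""Stochastic simulator of intrinsic synaptic volatility.

Each synapse is a little dynamical system of z multiplicative factors. The
volatile plasticity tag ``u_1`` receives driftless white noise (scale
``sigma * sqrt(dt)`` per step); between measurements all factors relax
toward their common geometric mean at rate ``relax`` (the stable components
capture the tag's state), a realignment that preserves the weight. The
recorded strength is ``w = prod_k u_k``.

With aligned factors the first-order weight fluctuation is
``|dw| = |d u_1| * prod_{k>=2} u_k ~ w**(1 - 1/z)``: additive
weight-independent noise for single-component synapses, ~sqrt(w) scaling for
two-factor synapses, approaching proportional noise as z grows. The optional
homeostatic mode rescales the whole population multiplicatively after every
step so the synaptic mass ``sum_j w_j**(2/z)`` stays constant, which pins the
q-norm of the population at q = 2/z across time.

Units: time in hours. Defaults (dt = 0.5 h, T = 24 h) mirror dense
longitudinal imaging of dendritic spines (one measurement every 30 min over
a day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectoryTable", "simulate_synapses"]


@dataclass
class TrajectoryTable:
    """Long-format record of synapse strengths over time.

    ``df`` has columns (synapse_id, time, strength); times are strictly
    increasing within each synapse and strengths are nonnegative. ``meta``
    carries the generating parameters (z, sigma, n_synapses, dt, seed, ...)
    when the table comes from the simulator.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"synapse_id", "time", "strength"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        if (self.df["strength"] < 0).any():
            raise ValueError("strengths must be >= 0")
        dt = self.df.groupby("synapse_id")["time"].diff().dropna()
        if (dt <= 0).any():
            raise ValueError("times must be strictly increasing per synapse")

    def pivot(self) -> pd.DataFrame:
        """Wide time x synapse matrix; requires a common time grid."""
        wide = self.df.pivot(index="time", columns="synapse_id", values="strength")
        if wide.isna().any().any():
            raise ValueError("synapses are not sampled on a common time grid")
        return wide

    @property
    def n_synapses(self) -> int:
        return self.df["synapse_id"].nunique()


def simulate_synapses(
    n: int = 1000,
    z: int = 2,
    sigma: float = 0.02,
    relax: float = 2.0,
    T: float = 24.0,
    dt: float = 0.5,
    seed: int | None = None,
    homeostatic: bool = False,
    w0_median: float = 0.35,
    w0_spread: float = 0.5,
) -> TrajectoryTable:
    """Simulate ``n`` independent z-factor synapses and record their strengths.

    Parameters
    ----------
    n, z
        Number of synapses and of multiplicative factors per synapse.
    sigma
        Volatility of the plasticity tag, in strength units per sqrt(hour).
    relax
        Realignment rate (1/hour) of all factors toward their common
        geometric mean; ``relax * dt`` is capped at 1 (full realignment per
        step). Only meaningful for z >= 2. Exponent recovery is robust for
        relax in roughly [0.5, 1/dt]; slower realignment lets misalignment
        accumulate and attenuates the measured exponent.
    T, dt
        Duration and sampling interval in hours; strengths are recorded at
        every multiple of dt from 0 to T.
    homeostatic
        If True, after every step all live strengths are rescaled
        multiplicatively so that ``sum_j w_j**(2/z)`` keeps its initial
        value (population-level homeostatic scaling).
    w0_median, w0_spread
        Median and log-scale spread of the log-normal initial strengths
        (heavy-tailed, as measured spine-size distributions are).

    Boundary behaviour: for z = 1 the tag reflects at zero (a synapse can
    shrink to nothing and regrow); for z >= 2 a tag that random-walks to zero
    prunes the synapse permanently (the weight is absorbed at zero), matching
    the absorbing pruning of multiplicative consolidation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if z < 1:
        raise ValueError("z must be >= 1")
    if not T > dt > 0:
        raise ValueError("need T > dt > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))

    w0 = rng.lognormal(mean=np.log(w0_median), sigma=w0_spread, size=n)
    u = np.tile(w0[:, None] ** (1.0 / z), (1, z))  # aligned start
    alive = np.ones(n, dtype=bool)
    sqrt_dt = np.sqrt(dt)
    q_mass = 2.0 / z
    mass0 = float(np.sum(w0**q_mass))

    times = np.arange(n_steps + 1) * dt
    W = np.empty((n_steps + 1, n))
    W[0] = w0

    for step in range(1, n_steps + 1):
        eps = rng.normal(0.0, sigma * sqrt_dt, size=n)
        if z == 1:
            u[:, 0] = np.abs(u[:, 0] + eps)  # reflecting boundary
        else:
            # consolidation between measurements redistributes strength
            # across components: all factors relax toward their common
            # geometric mean, which preserves the weight (exactly at full
            # realignment, to first order otherwise)
            if alive.any():
                r = min(1.0, relax * dt)
                gm = np.prod(u[alive], axis=1) ** (1.0 / z)
                u[alive] += r * (gm[:, None] - u[alive])
            u[alive, 0] += eps[alive]
            died = alive & (u[:, 0] <= 0)
            if died.any():
                u[died] = 0.0  # absorbing: whole synapse pruned
                alive &= ~died
        w = np.prod(u, axis=1)
        if homeostatic:
            live_mass = float(np.sum(w[w > 0] ** q_mass))
            if live_mass > 0:
                lam = (mass0 / live_mass) ** (z / 2.0)
                u[w > 0] *= lam ** (1.0 / z)
                w = np.prod(u, axis=1)
        W[step] = w

    df = pd.DataFrame(
        {
            "synapse_id": np.tile(np.arange(n), n_steps + 1),
            "time": np.repeat(times, n),
            "strength": W.ravel(),
        }
    )
    meta = {
        "z": z,
        "sigma": sigma,
        "relax": relax,
        "n_synapses": n,
        "T": T,
        "dt": dt,
        "seed": seed,
        "homeostatic": homeostatic,
    }
    return TrajectoryTable(df=df, meta=meta)
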
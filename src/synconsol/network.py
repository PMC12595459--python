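"""Binary recurrent dynamics over multiplicative multi-factor synapses.

The circuit is a recurrent network of N binary neurons. Neuron i fires
(``s_i = 1``) at time ``t+1`` iff its total input current

    I_i(t+1) = sum_j w_ij s_j(t) - I_inh_i

is strictly positive. All excitatory weights are nonnegative and inhibition
is summarised by a per-neuron scalar current ``I_inh_i``. Each weight is the
product of ``z`` nonnegative subsynaptic factors,

    w_ij = prod_k u_ijk,

where component ``k = 0`` (``u_ij1`` in 1-based notation) is the volatile
plasticity tag and the remaining components are slower, more stable
processes. The factor tensor ``u`` is the source of truth; the weight matrix
is materialised from it on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapticState",
    "NetworkState",
    "weights_from_factors",
    "update_step",
    "recall",
    "overlap",
]

#: index of the volatile plasticity-tag component within the factor axis
VOLATILE_INDEX = 0


def weights_from_factors(u: np.ndarray) -> np.ndarray:
    """Materialise the weight matrix ``w_ij = prod_k u_ijk``.

    Parameters
    ----------
    u
        Nonnegative factor tensor of shape ``(N, N, z)``; ``u[i, j, k]`` is
        component ``k`` of the connection from neuron ``j`` onto neuron ``i``.

    Returns
    -------
    ``(N, N)`` nonnegative weight matrix with zero diagonal.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 3 or u.shape[0] != u.shape[1]:
        raise ValueError(f"factor tensor must have shape (N, N, z), got {u.shape}")
    if np.any(u < 0):
        raise ValueError("negative factor: all subsynaptic components must be >= 0")
    w = np.prod(u, axis=2)
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class SynapticState:
    """Factorised synaptic configuration of the whole circuit.

    Attributes
    ----------
    u
        ``(N, N, z)`` nonnegative factor tensor (source of truth).
    I_inh
        Length-``N`` nonnegative inhibitory currents.
    """

    u: np.ndarray
    I_inh: np.ndarray
    volatile_index: int = VOLATILE_INDEX
    _w: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.I_inh = np.asarray(self.I_inh, dtype=float)
        if self.u.ndim != 3 or self.u.shape[0] != self.u.shape[1]:
            raise ValueError(f"u must have shape (N, N, z), got {self.u.shape}")
        if self.I_inh.shape != (self.u.shape[0],):
            raise ValueError("I_inh length must equal the number of neurons")
        if np.any(self.u < 0):
            raise ValueError("negative factor: all subsynaptic components must be >= 0")
        if np.any(self.I_inh < 0):
            raise ValueError("inhibitory currents must be >= 0")
        # no autapses: keep every factor of the diagonal at zero
        n = self.u.shape[0]
        self.u[np.arange(n), np.arange(n), :] = 0.0

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def z(self) -> int:
        return self.u.shape[2]

    @property
    def w(self) -> np.ndarray:
        """Weight matrix, materialised lazily from the factors."""
        if self._w is None:
            self._w = weights_from_factors(self.u)
        return self._w

    def invalidate(self) -> None:
        """Drop the cached weight matrix after mutating ``u`` in place."""
        self._w = None

    def copy(self) -> "SynapticState":
        return SynapticState(self.u.copy(), self.I_inh.copy(), self.volatile_index)

    def density(self, floor: float = 0.0) -> float:
        """Fraction of off-diagonal weights above ``floor`` (connection density)."""
        w = self.w
        n = w.shape[0]
        off = ~np.eye(n, dtype=bool)
        return float(np.mean(w[off] > floor))


@dataclass
class NetworkState:
    """Instantaneous network activity: binary states and input currents."""

    s: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        self.I = np.asarray(self.I, dtype=float)


def update_step(state: NetworkState | np.ndarray, syn: SynapticState) -> NetworkState:
    """One synchronous update of every neuron.

    ``I' = w . s - I_inh`` and ``s'_i = 1`` iff ``I'_i > 0`` (strict
    threshold, so a neuron sitting exactly at threshold stays silent).
    """
    s = state.s if isinstance(state, NetworkState) else np.asarray(state)
    if s.shape != (syn.N,):
        raise ValueError(f"state length {s.shape} does not match N={syn.N}")
    I_new = syn.w @ s.astype(float) - syn.I_inh
    s_new = (I_new > 0).astype(np.int8)
    return NetworkState(s=s_new, I=I_new)


def recall(syn: SynapticState, cue: np.ndarray, steps: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the dynamics from a cue and return the full trajectory.

    Returns
    -------
    (S, I)
        ``S`` of shape ``(steps + 1, N)`` holds the binary states including
        the cue itself; ``I`` of shape ``(steps, N)`` the input currents of
        every update.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    cue = np.asarray(cue).astype(np.int8)
    S = np.empty((steps + 1, syn.N), dtype=np.int8)
    I = np.empty((steps, syn.N), dtype=float)
    S[0] = cue
    state = NetworkState(s=cue, I=np.zeros(syn.N))
    for t in range(steps):
        state = update_step(state, syn)
        S[t + 1] = state.s
        I[t] = state.I
    return S, I


def overlap(s: np.ndarray, xi: np.ndarray, f: float) -> float:
    """Centered, normalised similarity between an activity state and a pattern.

    ``m = sum_i (s_i - f)(xi_i - f) / (N f (1 - f))``; equals 1 when
    ``s == xi`` at coding level ``f = 0.5`` and ~0 for unrelated states.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("coding level f must lie strictly between 0 and 1")
    s = np.asarray(s, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if s.shape != xi.shape:
        raise ValueError("state and pattern must have equal length")
    n = s.size
    return float(np.dot(s - f, xi - f) / (n * f * (1.0 - f)))
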
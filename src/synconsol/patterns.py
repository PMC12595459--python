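"""Synthetic memory patterns and wake-phase imprinting.

Memories are binary activity patterns xi^mu over N neurons, each entry active
with probability f <= 0.5 (the coding level). The storage load is
alpha = M / N. Wake-phase learning imprints every pattern as a fixed point of
the recurrent dynamics with a one-shot, Hopfield-style covariance rule kept
nonnegative by clipping; the imprinted attractors are stable but fragile —
consolidation (see :mod:`synconsol.consolidation`) is what makes them robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SynapticState

__all__ = ["PatternSet", "generate_patterns", "imprint_patterns", "stability_report"]


@dataclass
class PatternSet:
    """M binary patterns over N neurons at coding level f."""

    xi: np.ndarray  # (M, N) matrix with entries in {0, 1}
    f: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi)
        if self.xi.ndim != 2:
            raise ValueError("xi must be an (M, N) matrix")
        vals = np.unique(self.xi)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("pattern entries must be 0 or 1")
        if not 0.0 < self.f <= 0.5:
            raise ValueError("coding level must satisfy 0 < f <= 0.5")
        self.xi = self.xi.astype(np.int8)

    @property
    def M(self) -> int:
        return self.xi.shape[0]

    @property
    def N(self) -> int:
        return self.xi.shape[1]

    @property
    def alpha(self) -> float:
        """Storage load M / N."""
        return self.M / self.N


def generate_patterns(N: int, M: int, f: float, seed: int | None = None) -> PatternSet:
    """Draw M patterns with i.i.d. Bernoulli(f) entries.

    Parameters
    ----------
    N, M
        Neuron and pattern counts (``N >= 2``, ``M >= 1``).
    f
        Coding level, the probability that a neuron is active in a pattern;
        must satisfy ``0 < f <= 0.5``.
    seed
        Seed for the bit generator; the same seed reproduces the same set.
    """
    if N < 2:
        raise ValueError("need at least 2 neurons")
    if M < 1:
        raise ValueError("need at least 1 pattern")
    if not 0.0 < f <= 0.5:
        raise ValueError("coding level must satisfy 0 < f <= 0.5")
    rng = np.random.default_rng(seed)
    xi = (rng.random((M, N)) < f).astype(np.int8)
    return PatternSet(xi=xi, f=f, seed=seed)


def imprint_patterns(patterns: PatternSet, z: int = 2, scale: float = 1.0) -> SynapticState:
    """One-shot wake-phase imprinting of all patterns as fixed points.

    Weights follow the clipped covariance rule

        w_ij = (scale / N) * max(0, sum_mu (xi_i^mu - f)(xi_j^mu - f)),

    with no autapses, and the inhibitory current of each neuron is set to the
    midpoint between its lowest "should fire" input and its highest "should
    stay silent" input across patterns. Factors are initialised aligned,
    ``u_ijk = w_ij ** (1/z)``, and each neuron's factor row is rescaled to
    unit squared norm (an overall per-neuron scale leaves the dynamics
    invariant, so this just fixes the homeostatic set point at 1).

    Patterns that cannot be separated by a midpoint threshold are left
    unstable; check with :func:`stability_report` rather than assuming
    success — the rule is one-shot and has finite capacity.
    """
    if z < 1:
        raise ValueError("z must be >= 1")
    xi = patterns.xi.astype(float)
    f = patterns.f
    N = patterns.N
    centered = xi - f
    w = (scale / N) * np.clip(centered.T @ centered, 0.0, None)
    np.fill_diagonal(w, 0.0)

    # per-neuron threshold: midpoint of the gap between on- and off-inputs
    exc = w @ xi.T  # (N, M): excitatory drive to neuron i under pattern mu
    on = patterns.xi.T == 1  # (N, M)
    I_inh = np.empty(N)
    for i in range(N):
        lo = exc[i, on[i]].min() if on[i].any() else np.inf
        hi = exc[i, ~on[i]].max() if (~on[i]).any() else 0.0
        if np.isinf(lo):  # neuron silent in every pattern: threshold above all drive
            I_inh[i] = hi * (1.0 + 1e-9) + 1e-12
        else:
            I_inh[i] = max(0.0, 0.5 * (lo + hi))  # may be non-separating; flagged later

    u = np.repeat(w[:, :, None] ** (1.0 / z), z, axis=2)
    state = SynapticState(u=u, I_inh=I_inh)

    # normalise each neuron's incoming factor norm to 1 (w and I_inh scale
    # together by lambda**z, which leaves all spike decisions unchanged)
    norms = np.sqrt(np.sum(state.u**2, axis=(1, 2)))
    lam = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 1.0)
    state.u *= lam[:, None, None]
    state.I_inh *= lam**z
    state.invalidate()
    return state


def stability_report(state: SynapticState, patterns: PatternSet) -> np.ndarray:
    """Per-pattern, per-neuron fixed-point check.

    Entry ``(mu, i)`` is True iff neuron i's response to pattern mu matches
    its target, i.e. ``xi_i^mu == Theta(sum_j w_ij xi_j^mu - I_inh_i)`` with
    the strict threshold ``Theta(x) = 1`` iff ``x > 0``.
    """
    if patterns.N != state.N:
        raise ValueError("pattern and state dimensions disagree")
    I = patterns.xi.astype(float) @ state.w.T - state.I_inh[None, :]  # (M, N)
    predicted = (I > 0).astype(np.int8)
    return predicted == patterns.xi
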
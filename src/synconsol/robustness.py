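"""Noise models and tolerated-noise measurement for pattern recall.

Two noise sources perturb recall:

* *neural noise* — each bit of the cue is flipped independently with
  probability ``f_noise``; the induced input-current fluctuation scales as
  ``sqrt(sum_j w_ij^2)`` regardless of the synapse structure;
* *synaptic noise* — white noise of scale ``sigma_noise`` on the volatile
  factor ``u_ij1`` of every connection. On aligned z-factor synapses the
  induced weight perturbation is ``|eps| * w**(1 - 1/z)`` to first order
  (additive for z = 1, ~sqrt(w) for z = 2), so the current fluctuation
  scales as ``sqrt(sum_j w_ij^(2 - 2/z))``.

``tolerated_noise`` measures the largest noise level at which randomized
recall tests still succeed, the operational definition of memory robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SynapticState, overlap, recall
from .patterns import PatternSet

__all__ = [
    "NoiseSpec",
    "apply_neural_noise",
    "apply_synaptic_noise",
    "input_fluctuation_scale",
    "recall_success_fraction",
    "tolerated_noise",
]


@dataclass
class NoiseSpec:
    """Kind and level of a recall perturbation."""

    kind: str  # "neural" | "synaptic"
    f_noise: float = 0.0
    sigma_noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("neural", "synaptic"):
            raise ValueError("kind must be 'neural' or 'synaptic'")
        if not 0.0 <= self.f_noise <= 0.5:
            raise ValueError("f_noise must lie in [0, 0.5]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


def apply_neural_noise(
    s: np.ndarray, f_noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability ``f_noise``."""
    if not 0.0 <= f_noise <= 0.5:
        raise ValueError("f_noise must lie in [0, 0.5]")
    s = np.asarray(s).astype(np.int8)
    flips = rng.random(s.shape) < f_noise
    return np.where(flips, 1 - s, s).astype(np.int8)


def apply_synaptic_noise(
    syn: SynapticState, sigma_noise: float, rng: np.random.Generator
) -> SynapticState:
    """Add Gaussian white noise to the volatile factor of every live synapse.

    ``u_ij1 <- max(0, u_ij1 + eps)`` with ``eps ~ N(0, sigma_noise^2)``;
    stable components are untouched and pruned connections stay pruned (the
    volatile tag of a nonexistent synapse has nothing to perturb).
    """
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    out = syn.copy()
    k = out.volatile_index
    u1 = out.u[:, :, k]
    live = out.w > 0
    eps = rng.normal(0.0, sigma_noise, size=u1.shape)
    u1[live] = np.clip(u1[live] + eps[live], 0.0, None)
    out.invalidate()
    return out


def input_fluctuation_scale(
    syn: SynapticState, pattern: np.ndarray, kind: str
) -> np.ndarray:
    """Per-neuron scale of input-current fluctuations under unit noise.

    ``sqrt(sum_j s_j w_ij^q)`` with q = 2 for neural noise and q = 2 - 2/z
    for synaptic noise on (aligned) z-factor synapses. For z = 1 synaptic
    noise this counts the live active inputs (additive, weight-independent
    noise); neural noise is q = 2 regardless of z.
    """
    if kind == "neural":
        q = 2.0
    elif kind == "synaptic":
        q = 2.0 - 2.0 / syn.z
    else:
        raise ValueError("kind must be 'neural' or 'synaptic'")
    s = np.asarray(pattern, dtype=float)
    w = syn.w
    wq = np.where(w > 0, w, 0.0) ** q if q > 0 else (w > 0).astype(float)
    return np.sqrt(wq @ s)


def recall_success_fraction(
    syn: SynapticState,
    patterns: PatternSet,
    spec: NoiseSpec,
    trials: int,
    rng: np.random.Generator,
    steps: int = 10,
    overlap_threshold: float = 0.95,
) -> float:
    """Fraction of randomized recall tests that retrieve their pattern.

    Neural noise distorts the cue; synaptic noise perturbs the weights with a
    fresh (quenched) draw per trial while the cue stays clean. Success means
    the final overlap after ``steps`` synchronous updates reaches
    ``overlap_threshold`` times the pattern's self-overlap — the
    normalisation makes exact retrieval score 1 for every pattern even when
    its realised on-count deviates from ``N f`` (at low coding levels the
    binomial fluctuation is substantial).
    """
    successes = 0
    total = 0
    self_overlaps = np.array(
        [overlap(patterns.xi[mu], patterns.xi[mu], patterns.f) for mu in range(patterns.M)]
    )
    for _ in range(trials):
        if spec.kind == "synaptic":
            net = apply_synaptic_noise(syn, spec.sigma_noise, rng)
        else:
            net = syn
        for mu in range(patterns.M):
            cue = patterns.xi[mu]
            if spec.kind == "neural":
                cue = apply_neural_noise(cue, spec.f_noise, rng)
            S, _ = recall(net, cue, steps=steps)
            m = overlap(S[-1], patterns.xi[mu], patterns.f)
            successes += m >= overlap_threshold * self_overlaps[mu]
            total += 1
    return successes / total


def tolerated_noise(
    syn: SynapticState,
    patterns: PatternSet,
    kind: str,
    trials: int = 10,
    seed: int | None = None,
    success_threshold: float = 0.9,
    overlap_threshold: float = 0.95,
    steps: int = 10,
    bisection_iters: int = 8,
) -> tuple[float, pd.DataFrame]:
    """Largest noise level whose recall success fraction stays above threshold.

    Bisects over the noise level: neural noise within [0, 0.5]; synaptic
    noise within [0, sigma_max] where sigma_max starts at the mean live
    volatile factor and is doubled until recall fails (or 16x is reached).
    Returns the tolerated level and the (level, success) curve actually
    measured. An unconsolidated imprinted state typically tolerates hardly
    any noise; consolidation is what opens the gap.
    """
    rng = np.random.default_rng(seed)

    def success_at(level: float) -> float:
        spec = (
            NoiseSpec(kind="neural", f_noise=level)
            if kind == "neural"
            else NoiseSpec(kind="synaptic", sigma_noise=level)
        )
        return recall_success_fraction(
            syn, patterns, spec, trials, rng, steps, overlap_threshold
        )

    curve: list[tuple[float, float]] = []
    if success_at(0.0) < success_threshold:
        return 0.0, pd.DataFrame([(0.0, success_at(0.0))], columns=["level", "success"])

    if kind == "neural":
        hi = 0.5
    else:
        live = syn.w > 0
        base = syn.u[:, :, syn.volatile_index][live]
        hi = float(base.mean()) if base.size else 1.0
        for _ in range(4):
            frac = success_at(hi)
            curve.append((hi, frac))
            if frac < success_threshold:
                break
            hi *= 2.0

    lo = 0.0
    for _ in range(bisection_iters):
        mid = 0.5 * (lo + hi)
        frac = success_at(mid)
        curve.append((mid, frac))
        if frac >= success_threshold:
            lo = mid
        else:
            hi = mid
    curve.sort()
    return lo, pd.DataFrame(curve, columns=["level", "success"])
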
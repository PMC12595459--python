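"""End-to-end wake/sleep experiments and load sweeps.

The canonical experiment: generate random patterns (the day's experiences),
imprint them one-shot during "wake" (dense, fragile connectivity), then
consolidate during "sleep" (sparse, robust connectivity), and finally run the
robustness and analysis read-outs on the before/after pair. Storage loads are
normalised by a numerically estimated critical capacity, obtained by
bisecting on per-neuron feasibility of the sign-constrained margin problem.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import analysis as an
from . import io as sio
from .consolidation import ConsolidationConfig, consolidate, snr
from .patterns import PatternSet, generate_patterns, imprint_patterns, stability_report
from .robustness import tolerated_noise

__all__ = [
    "ExperimentSpec",
    "run_wake_sleep",
    "neuron_feasible",
    "estimate_capacity",
    "stabilize_patterns",
    "max_l2_margin_weights",
    "density_vs_load",
]


@dataclass
class ExperimentSpec:
    """Configuration of one wake/sleep run."""

    N: int = 200
    M: int = 20
    f: float = 0.5
    z: int = 2
    consolidation: dict = field(default_factory=dict)
    noise_trials: int = 10
    n_novel: int = 20
    outdir: str | None = None
    seed: int = 0


def neuron_feasible(xi: np.ndarray, i: int) -> bool:
    """Can neuron i store all patterns with some positive margin?

    Feasibility of the sign-constrained problem: exists w >= 0, b >= 0 with
    ``(2 xi_i - 1)(w . xi - b) >= 1`` for every pattern (autapse excluded).
    Checked with an LP; scaling the margin target is immaterial, only the
    sign of the achievable margin matters.
    """
    M, N = xi.shape
    y = 2.0 * xi[:, i] - 1.0
    X = xi.astype(float).copy()
    X[:, i] = 0.0
    c = np.zeros(N + 1)
    A_ub = -np.concatenate([y[:, None] * X, -y[:, None]], axis=1)
    b_ub = -np.ones(M)
    bounds = [(0, None)] * (N + 1)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return bool(res.success)


def estimate_capacity(
    N: int,
    f: float,
    seed: int = 0,
    n_sample: int = 20,
    tol: int | None = None,
    alpha_hi: float = 2.0,
) -> float:
    """Numerical critical capacity alpha_c = M_c / N by bisection.

    A load is deemed storable when every sampled neuron's sign-constrained
    margin problem is feasible (patterns are drawn fresh per probe; the
    capacity is a property of the ensemble). ``n_sample`` neurons suffice
    because the per-neuron problems are statistically exchangeable. The
    result does not depend on z: feasibility concerns the weights only.
    """
    rng = np.random.default_rng(seed)
    tol = tol or max(2, N // 50)

    def feasible(M: int) -> bool:
        pats = generate_patterns(N, M, f, seed=int(rng.integers(2**31 - 1)))
        neurons = rng.choice(N, size=min(n_sample, N), replace=False)
        return all(neuron_feasible(pats.xi, int(i)) for i in neurons)

    lo, hi = 1, int(alpha_hi * N)
    if not feasible(lo):
        return lo / N
    while feasible(hi):
        hi *= 2
    while hi - lo > tol:
        mid = (lo + hi) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo / N


def stabilize_patterns(
    syn,
    patterns: PatternSet,
    margin_rel: float = 0.02,
    relaxation: float = 1.5,
    max_iter: int = 8000,
) -> np.ndarray:
    """Drive every pattern to a fixed point with a small margin cushion, in place.

    One-shot imprinting only stabilises patterns at low load; at loads
    approaching capacity the consolidation precondition — every pattern a
    fixed point — needs an error-correcting wake phase. This uses Motzkin
    relaxation: per sweep, each neuron takes an exact correcting step along
    its single most violated pattern (overshooting by ``relaxation``), which
    converges geometrically whenever the sign-constrained problem is
    feasible. The per-neuron margin target is ``margin_rel`` times the
    neuron's mean excitatory drive — a zero-margin fixed point would be
    knocked back out by the very first consolidation cycle. Factors are
    re-aligned to the corrected weights (``u = w**(1/z)``) at the end.

    Returns the boolean mask of neurons with some pattern still not strictly
    stable after ``max_iter`` sweeps (near or beyond capacity these may be
    genuinely infeasible).
    """
    xi = patterns.xi.astype(float)
    y = 2.0 * patterns.xi.T - 1.0  # (N, M)
    N = syn.N
    w = syn.w.copy()
    b = syn.I_inh.copy()
    norm2 = (xi**2).sum(axis=1) + 1.0
    drive = (w @ xi.T).mean(axis=1)
    kappa = margin_rel * np.where(drive > 0, drive, 1.0)
    active = np.ones(N, dtype=bool)
    for _ in range(max_iter):
        stab = y * (w @ xi.T - b[:, None])
        worst = stab.argmin(axis=1)
        sw = stab[np.arange(N), worst]
        active = sw <= kappa
        if not active.any():
            break
        step = np.zeros(N)
        step[active] = relaxation * (kappa[active] - sw[active]) / norm2[worst[active]]
        ymu = y[np.arange(N), worst]
        upd = (step * ymu)[:, None] * xi[worst]
        np.fill_diagonal(upd, 0.0)
        w += upd
        np.clip(w, 0.0, None, out=w)
        b = np.clip(b - step * ymu, 0.0, None)
    active = (y * (w @ xi.T - b[:, None])).min(axis=1) <= 0
    syn.u = np.repeat(w[:, :, None] ** (1.0 / syn.z), syn.z, axis=2)
    syn.I_inh = b
    syn.invalidate()
    # restore unit factor norms (per-neuron scale invariance)
    norms = np.sqrt(np.sum(syn.u**2, axis=(1, 2)))
    lam = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 1.0)
    syn.u *= lam[:, None, None]
    syn.I_inh *= lam**syn.z
    syn.invalidate()
    return active


def max_l2_margin_weights(
    patterns: PatternSet,
    c_stages: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0),
    iters: tuple[int, ...] = (200, 300, 600, 1200),
    seed: int = 0,
):
    """Direct nonnegative max-L2-margin solution for every neuron at once.

    Solves ``min ||w_i||^2 + C sum_mu [1 - y (w_i . xi_mu - b_i)]_+^2`` with
    ``w >= 0`` and no autapse, by accelerated projected gradient (FISTA) with
    continuation in the hinge stiffness C — as C grows the solution converges
    to the hard max-margin (support-vector) solution, whose density is what
    single-component consolidation converges to. The bias is parameterised as
    ``b = theta + f sum_j w`` (inhibition tracking excitation) for
    conditioning. Runs all neurons simultaneously as one matrix iteration.

    Returns ``(state, margins)``: a z = 1 :class:`SynapticState` and the
    per-neuron L2-normalised margins (non-positive entries flag neurons whose
    problem is infeasible or unconverged).
    """
    xi = patterns.xi.astype(float)
    f = patterns.f
    N = patterns.N
    Xc = xi - f
    Y = 2.0 * patterns.xi.T - 1.0  # (N, M)

    # largest eigenvalue of Xc^T Xc by power iteration (sets the step size)
    v = np.random.default_rng(seed).normal(size=N)
    for _ in range(60):
        v = Xc.T @ (Xc @ v)
        v /= np.linalg.norm(v)
    lam_max = float(v @ (Xc.T @ (Xc @ v)))

    W = np.full((N, N), 1.0 / N)
    np.fill_diagonal(W, 0.0)
    th = np.zeros(N)
    for C, n_it in zip(c_stages, iters):
        L = 1.0 + C * (lam_max + 1.0)
        sq = np.sqrt(1.0 / L)
        mom = (1.0 - sq) / (1.0 + sq)
        Wp, thp = W.copy(), th.copy()
        for _ in range(n_it):
            Vw = W + mom * (W - Wp)
            Vt = th + mom * (th - thp)
            S = Vw @ Xc.T - Vt[:, None]
            R = np.clip(1.0 - Y * S, 0.0, None)
            RY = R * Y
            gW = Vw - C * (RY @ Xc)
            gt = C * RY.sum(axis=1)
            Wp, thp = W, th
            W = np.clip(Vw - gW / L, 0.0, None)
            np.fill_diagonal(W, 0.0)
            th = Vt - gt / L

    margins = (Y * (W @ Xc.T - th[:, None])).min(axis=1)
    norms = np.linalg.norm(W, axis=1)
    margins = np.divide(margins, norms, out=np.zeros(N), where=norms > 0)
    from .network import SynapticState

    b = np.clip(th + f * W.sum(axis=1), 0.0, None)
    return SynapticState(u=W[:, :, None], I_inh=b), margins


def density_vs_load(
    N: int,
    f: float,
    z: int,
    load_fractions: np.ndarray | list[float],
    config: ConsolidationConfig | None = None,
    seed: int = 0,
    capacity: float | None = None,
    solver: str = "replay",
) -> pd.DataFrame:
    """Final connection density after consolidation at each load.

    ``load_fractions`` are expressed relative to the (numerically estimated)
    critical capacity. Runs that end with persistently unstable patterns are
    flagged ``converged=False``. Single-component (z = 1) networks bottom out
    near 50% density however high the load; multi-component networks are
    sparser, with density increasing with load.

    ``solver="replay"`` runs imprint -> stabilise -> consolidate;
    ``solver="direct"`` (z = 1 only) solves the equivalent nonnegative
    max-L2-margin problem with :func:`max_l2_margin_weights`, which reaches
    the converged density orders of magnitude faster at scale.
    """
    if capacity is None:
        capacity = estimate_capacity(N, f, seed=seed)
    config = config or ConsolidationConfig()
    rows = []
    rng = np.random.default_rng(seed)
    for frac in load_fractions:
        M = max(1, int(round(frac * capacity * N)))
        pats = generate_patterns(N, M, f, seed=int(rng.integers(2**31 - 1)))
        if solver == "direct":
            if z != 1:
                raise ValueError("the direct max-L2-margin solver applies to z = 1 only")
            state, margins_i = max_l2_margin_weights(pats, seed=seed)
            converged = bool(np.mean(margins_i > 0) >= 0.98)
            q = 2.0
        else:
            state0 = imprint_patterns(pats, z=z)
            stabilize_patterns(state0, pats)
            state, diag = consolidate(state0, pats, config)
            converged = bool(diag.n_mismatch[-1] == 0)
            q = 2.0 / z
        floor = config.prune_floor * state.w[state.w > 0].mean() if (state.w > 0).any() else 0.0
        rows.append(
            {
                "alpha": M / N,
                "alpha_over_alpha_c": (M / N) / capacity,
                "density": state.density(floor),
                "converged": converged,
                "mean_snr": float(np.mean(snr(state, pats, q))),
            }
        )
    return pd.DataFrame(rows)


def run_wake_sleep(spec: ExperimentSpec) -> dict:
    """Full wake -> sleep -> read-out experiment.

    Returns a bundle with the pattern set, pre/post states, consolidation
    diagnostics and the analysis tables; writes everything plus a manifest to
    ``spec.outdir`` when given. Deterministic given ``spec.seed``.
    """
    t0 = time.time()
    bundle: dict = {"spec": spec}
    manifest = sio.Manifest(run_id=f"wake_sleep_seed{spec.seed}", seed=spec.seed,
                            config=spec.__dict__.copy())

    pats = generate_patterns(spec.N, spec.M, spec.f, seed=spec.seed)
    state_pre = imprint_patterns(pats, z=spec.z)
    bundle["imprint_stable"] = bool(stability_report(state_pre, pats).all())
    if not bundle["imprint_stable"]:
        stabilize_patterns(state_pre, pats)  # error-correcting wake phase
    bundle["patterns"] = pats
    bundle["state_pre"] = state_pre
    manifest.add_timing("wake", time.time() - t0)

    t1 = time.time()
    cfg = ConsolidationConfig(**spec.consolidation) if spec.consolidation else ConsolidationConfig()
    state_post, diag = consolidate(state_pre, pats, cfg)
    bundle["state_post"] = state_post
    bundle["diagnostics"] = diag
    manifest.add_timing("sleep", time.time() - t1)

    t2 = time.time()
    floor = cfg.prune_floor * state_post.w[state_post.w > 0].mean()
    bundle["density_pre"] = state_pre.density(floor)
    bundle["density_post"] = state_post.density(floor)

    level_pre, _ = tolerated_noise(
        state_pre, pats, "synaptic", trials=spec.noise_trials, seed=spec.seed
    )
    level_post, _ = tolerated_noise(
        state_post, pats, "synaptic", trials=spec.noise_trials, seed=spec.seed
    )
    bundle["tolerated_synaptic_noise"] = {"pre": level_pre, "post": level_post}

    bundle["pruning"], bundle["pruning_slope"] = an.pruning_vs_weight(
        state_pre.w, state_post.w, floor=floor
    )
    bundle["response_correlation"] = an.response_correlation_connectivity(
        state_pre, state_post, pats, floor=floor
    )

    novel = generate_patterns(spec.N, spec.n_novel, spec.f, seed=spec.seed + 1)
    from .consolidation import margins as _margins

    temp = 0.5 * float(np.median(np.abs(_margins(state_post, pats))))
    bundle["sparseness_familiar"] = an.tuning_sparseness(
        an.graded_responses(state_post, pats, temperature=temp), axis=1
    )
    bundle["sparseness_novel"] = an.tuning_sparseness(
        an.graded_responses(state_post, novel, temperature=temp), axis=1
    )

    bundle["snr_change"], bundle["snr_change_slope"] = an.pattern_snr_change(
        state_pre, state_post, pats
    )
    manifest.add_timing("analysis", time.time() - t2)

    if spec.outdir:
        outdir = Path(spec.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_patterns(outdir / "patterns.tsv", pats)
        sio.write_state(outdir / "state_pre.tsv", state_pre)
        sio.write_state(outdir / "state_post.tsv", state_post)
        diag.to_frame().to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        bundle["pruning"].to_csv(outdir / "pruning_vs_weight.tsv", sep="\t", index=False)
        bundle["response_correlation"].to_csv(
            outdir / "response_correlation.tsv", sep="\t", index=False
        )
        bundle["snr_change"].to_csv(outdir / "pattern_snr_change.tsv", sep="\t", index=False)
        for name in (
            "patterns.tsv", "state_pre.tsv", "state_post.tsv", "diagnostics.tsv",
            "pruning_vs_weight.tsv", "response_correlation.tsv", "pattern_snr_change.tsv",
        ):
            manifest.add_file(outdir / name)
        manifest.write(outdir / "manifest.json")
    return bundle
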
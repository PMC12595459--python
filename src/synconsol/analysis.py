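"""Trajectory and network statistics: fluctuation scaling, norm stability,
pruning, response-correlation connectivity, tuning sparseness, per-pattern SNR.

These are the read-outs used to compare model behaviour with longitudinal
synaptic imaging and neural recordings. They operate on plain data structures
(:class:`~synconsol.synapse_sim.TrajectoryTable`, weight matrices, response
matrices), so any conforming table — simulated or experimental — can be fed
through them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .consolidation import margins, snr
from .network import SynapticState
from .patterns import PatternSet
from .synapse_sim import TrajectoryTable

__all__ = [
    "ScalingFit",
    "NormCVResult",
    "fluctuation_scaling",
    "norm_cv",
    "pruning_vs_weight",
    "graded_responses",
    "response_correlation_connectivity",
    "tuning_sparseness",
    "pattern_snr_change",
]


@dataclass
class ScalingFit:
    """Power-law exponent of fluctuation size versus strength for one branch.

    The model for |dw| ~ c * w**slope; ``slope`` is the log-log regression
    slope and ``slope_se`` its bootstrap standard error (resampling synapses,
    which respects within-synapse autocorrelation).
    """

    branch: str  # "potentiation" | "depression"
    slope: float
    intercept: float
    slope_se: float
    n_pairs: int
    window: int
    n_boot: int


@dataclass
class NormCVResult:
    """Stability of population q-norms over time.

    ``cv[i]`` is the coefficient of variation of ``(sum_j w_j(t)**q)**(1/q)``
    across time for ``q = q_grid[i]``; ``q_min`` is the exponent of the most
    stable norm. A population under multiplicative homeostatic scaling of
    z-factor synapses has its most stable norm at q = 2/z.
    """

    q_grid: np.ndarray
    cv: np.ndarray
    cv_rank: np.ndarray
    q_min: float
    q_min_se: float


def _pairs_from_table(
    table: TrajectoryTable, dt_lag: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (w(t), dw, synapse_id) pairs at the requested lag."""
    wide = table.pivot()  # time x synapse
    times = wide.index.to_numpy()
    dt = float(np.median(np.diff(times)))
    if dt_lag is None:
        dt_lag = dt
    lag_steps = int(round(dt_lag / dt))
    if lag_steps < 1 or not np.isclose(lag_steps * dt, dt_lag, rtol=1e-6):
        raise ValueError("dt_lag must be a positive multiple of the sampling interval")
    W = wide.to_numpy()
    ids = np.broadcast_to(wide.columns.to_numpy(), W[:-lag_steps].shape)
    w0 = W[:-lag_steps].ravel()
    dw = (W[lag_steps:] - W[:-lag_steps]).ravel()
    sid = ids.ravel()
    keep = w0 > 0  # a strength of zero has no log, and pruned synapses stay 0
    return w0[keep], dw[keep], sid[keep]


def _branch_slope(
    logw: np.ndarray, logdw: np.ndarray, window: int, method: str
) -> tuple[float, float]:
    """Slope/intercept of the log-log trend for one branch of pairs."""
    order = np.argsort(logw)
    x, yv = logw[order], logdw[order]
    if method == "raw":
        res = stats.linregress(x, yv)
        return float(res.slope), float(res.intercept)
    kernel = np.full(window, 1.0 / window)
    if method == "moving_average":
        xs = np.convolve(x, kernel, mode="valid")
        ys = np.convolve(yv, kernel, mode="valid")
    elif method == "rmsd":
        xs = np.convolve(x, kernel, mode="valid")
        ys = 0.5 * np.log10(np.convolve((10.0**yv) ** 2, kernel, mode="valid"))
    else:
        raise ValueError(f"unknown method {method!r}")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept)


def fluctuation_scaling(
    table: TrajectoryTable,
    dt_lag: float | None = None,
    n_boot: int = 100,
    window: int = 101,
    seed: int | None = None,
    method: str = "moving_average",
) -> dict[str, ScalingFit]:
    """Fluctuation-scaling exponents per branch: slope of log|dw| vs log w.

    Forms all (w(t), w(t + dt_lag) - w(t)) pairs, splits them into
    potentiation (dw > 0) and depression (dw < 0), sorts each branch by
    initial strength, smooths the log-log scatter with a centered moving
    average of ``window`` pairs, and fits a line to the smoothed trend by
    least squares. ``method="raw"`` regresses the raw pairs directly and
    ``method="rmsd"`` fits the moving root-mean-square deviation; all three
    give nearly identical exponents on power-law data. The standard error
    comes from ``n_boot`` bootstrap resamples over synapses.

    Branches with fewer than ``window`` pairs are skipped (absent from the
    returned dict) with a warning.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    w0, dw, sid = _pairs_from_table(table, dt_lag)
    rng = np.random.default_rng(seed)
    unique_ids = np.unique(sid)
    fits: dict[str, ScalingFit] = {}
    for branch, mask in (("potentiation", dw > 0), ("depression", dw < 0)):
        if mask.sum() < window:
            import warnings

            warnings.warn(
                f"{branch} branch has {int(mask.sum())} pairs < window={window}; skipped"
            )
            continue
        logw = np.log10(w0[mask])
        logdw = np.log10(np.abs(dw[mask]))
        bid = sid[mask]
        slope, intercept = _branch_slope(logw, logdw, window, method)

        # bootstrap over synapses
        by_id = {u: np.flatnonzero(bid == u) for u in unique_ids}
        boot_slopes = []
        for _ in range(n_boot):
            sample = rng.choice(unique_ids, size=unique_ids.size, replace=True)
            idx = np.concatenate([by_id[u] for u in sample if by_id[u].size])
            if idx.size < window:
                continue
            s, _ = _branch_slope(logw[idx], logdw[idx], window, method)
            boot_slopes.append(s)
        se = float(np.std(boot_slopes, ddof=1)) if len(boot_slopes) > 1 else float("nan")
        fits[branch] = ScalingFit(
            branch=branch,
            slope=slope,
            intercept=intercept,
            slope_se=se,
            n_pairs=int(mask.sum()),
            window=window,
            n_boot=n_boot,
        )
    return fits


def norm_cv(
    table: TrajectoryTable,
    q_grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> NormCVResult:
    """Coefficient of variation of the population q-norm across time.

    For each q in the grid, computes ``norm(t) = (sum_j w_j(t)**q)**(1/q)``
    over the common time grid (pruned synapses contribute zero), then
    ``cv(q) = std_t / mean_t``. ``q_min`` is the grid argmin; its bootstrap
    SE resamples synapses. The cv curve is also rank-normalised to [0, 1]
    for comparison across datasets with different absolute variability.
    """
    if q_grid is None:
        q_grid = np.arange(0.25, 3.01, 0.25)
    q_grid = np.asarray(q_grid, dtype=float)
    wide = table.pivot()
    if wide.shape[0] < 2:
        raise ValueError("need at least two time points")
    W = wide.to_numpy()  # (T, n)

    def cv_curve(Wq_stack: np.ndarray) -> np.ndarray:
        # Wq_stack: (nq, T) of sum_j w^q
        norms = Wq_stack ** (1.0 / q_grid[:, None])
        return norms.std(axis=1, ddof=0) / norms.mean(axis=1)

    Wq = np.stack([(W**q).sum(axis=1) for q in q_grid])  # (nq, T)
    cv = cv_curve(Wq)
    q_min = float(q_grid[np.argmin(cv)])

    rng = np.random.default_rng(seed)
    n = W.shape[1]
    Wq_syn = np.stack([W**q for q in q_grid])  # (nq, T, n)
    boot_qmin = np.empty(n_boot)
    for b in range(n_boot):
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
        stack = Wq_syn @ counts  # (nq, T)
        boot_qmin[b] = q_grid[np.argmin(cv_curve(stack))]
    q_min_se = float(boot_qmin.std(ddof=1)) if n_boot > 1 else float("nan")

    ranks = stats.rankdata(cv)
    cv_rank = (ranks - 1) / (len(ranks) - 1) if len(ranks) > 1 else np.zeros_like(ranks)
    return NormCVResult(q_grid=q_grid, cv=cv, cv_rank=cv_rank, q_min=q_min, q_min_se=q_min_se)


def pruning_vs_weight(
    before: np.ndarray,
    after: np.ndarray,
    bins: int = 10,
    floor: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Empirical pruning probability per weight bin plus a logistic slope.

    A connection counts as pruned if it was live before (``w > floor``) and
    is at or below the floor after. Weights are binned into ``bins`` quantile
    bins of log-weight; the returned slope is the coefficient of a logistic
    regression of the prune indicator on log10-weight (negative slope: strong
    connections survive preferentially). The default floor is 1e-3 times the
    mean initial live weight.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("weight matrices must have matching shapes")
    off = ~np.eye(before.shape[0], dtype=bool) if before.ndim == 2 else np.ones(before.shape, bool)
    if floor is None:
        live0 = before[off & (before > 0)]
        floor = 1e-3 * live0.mean() if live0.size else 0.0
    live = off & (before > floor)
    w = before[live]
    pruned = (after[live] <= floor).astype(float)

    logw = np.log10(w)
    edges = np.unique(np.quantile(logw, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.digitize(logw, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            rows.append((10.0 ** logw[m].mean(), pruned[m].mean(), int(m.sum())))
    table = pd.DataFrame(rows, columns=["weight", "prune_probability", "n"])

    if pruned.min() == pruned.max():
        import warnings

        warnings.warn("no variation in pruning outcome; logistic fit degenerate")
        return table, float("nan")
    import statsmodels.api as sm

    X = sm.add_constant(logw)
    fit = sm.Logit(pruned, X).fit(disp=0, maxiter=200)
    return table, float(fit.params[1])


def response_correlation_connectivity(
    syn_before: SynapticState,
    syn_after: SynapticState,
    patterns: PatternSet,
    bins: int = 6,
    floor: float | None = None,
) -> pd.DataFrame:
    """Survival probability and mean strength versus response correlation.

    Uses the total excitatory input current ``sum_j w_ij xi_j`` of the
    consolidated network during recall of each pattern as a graded response,
    computes the Pearson correlation of responses across patterns for every
    directed neuron pair, and reports — per correlation bin — the fraction of
    initially live connections that survive consolidation and the mean
    surviving strength (max-normalised). Neurons with constant responses are
    excluded from the correlation.
    """
    xi = patterns.xi.astype(float)
    resp = syn_after.w @ xi.T  # (N, M) graded recall responses
    variable = resp.std(axis=1) > 0
    w_b, w_a = syn_before.w, syn_after.w
    if floor is None:
        live0 = w_b[w_b > 0]
        floor = 1e-3 * live0.mean() if live0.size else 0.0

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(resp)
    off = ~np.eye(syn_before.N, dtype=bool)
    valid = off & variable[:, None] & variable[None, :] & (w_b > floor)
    c = corr[valid]
    survived = w_a[valid] > floor
    strength = w_a[valid]
    strength = strength / strength.max() if strength.max() > 0 else strength

    edges = np.linspace(c.min(), c.max(), bins + 1)
    idx = np.clip(np.digitize(c, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        m = idx == b
        if not m.any():
            continue
        surv = survived[m]
        mean_strength = strength[m][surv].mean() if surv.any() else np.nan
        rows.append((c[m].mean(), surv.mean(), mean_strength, int(m.sum())))
    return pd.DataFrame(
        rows, columns=["correlation", "connection_probability", "mean_strength", "n"]
    )


def graded_responses(
    syn: SynapticState,
    patterns: PatternSet,
    temperature: float | None = None,
) -> np.ndarray:
    """Soft (sigmoidal) neuron x stimulus response matrix for tuning analyses.

    ``r = 1 / (1 + exp(-I / T))`` of the input-current margins. The hard
    threshold makes responses to unstored stimuli identically zero, which
    leaves tuning curves degenerate; a sigmoid of finite temperature exposes
    how far below threshold a stimulus sits. ``T`` defaults to half the
    median absolute margin over the given patterns.
    """
    I = margins(syn, patterns)
    if temperature is None:
        med = float(np.median(np.abs(I)))
        temperature = 0.5 * med if med > 0 else 1.0
    return expit(I / temperature)


def tuning_sparseness(responses: np.ndarray, axis: int = 1) -> float:
    """Population/lifetime selectivity of nonnegative responses, in [0, 1].

    ``S = (1 - a) / (1 - 1/n)`` with ``a = (mean r)^2 / mean(r^2)`` computed
    along ``axis`` and averaged over the other axis; S = 0 for perfectly
    uniform responses and S -> 1 when a unit responds to a single stimulus.
    Rows (or columns) that are identically zero are excluded.
    """
    r = np.asarray(responses, dtype=float)
    if np.any(r < 0):
        raise ValueError("responses must be nonnegative")
    if r.shape[axis] < 2:
        raise ValueError("need at least 2 entries along the selectivity axis")
    n = r.shape[axis]
    mean_r = r.mean(axis=axis)
    mean_r2 = (r**2).mean(axis=axis)
    ok = mean_r2 > 0
    if not ok.any():
        raise ValueError("all response vectors are zero; sparseness undefined")
    a = mean_r[ok] ** 2 / mean_r2[ok]
    s = (1.0 - a) / (1.0 - 1.0 / n)
    return float(s.mean())


def pattern_snr_change(
    syn_start: SynapticState,
    syn_end: SynapticState,
    patterns: PatternSet,
    q: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-pattern SNR before/after consolidation and the gain-vs-start slope.

    A pattern's SNR is the minimum over neurons of its signed input-current
    margin ``(2 xi - 1) I`` divided by the neuron's noise scale
    ``sqrt(sum_j w_ij^q)``, evaluated with the same q at both ends (default:
    the structurally matched q = 2/z of the end state). Returns the table of
    (initial SNR, change) per pattern and the least-squares slope of change
    on initial SNR; a negative slope means initially weak memories gain the
    most.
    """
    if q is None:
        q = 2.0 / syn_end.z

    def per_pattern(syn: SynapticState) -> np.ndarray:
        I = margins(syn, patterns)  # (N, M)
        y = 2.0 * patterns.xi.T - 1.0
        signed = y * I
        w = syn.w
        noise = np.sqrt((np.where(w > 0, w, 0.0) ** q).sum(axis=1))
        ratio = np.divide(
            signed, noise[:, None], out=np.zeros_like(signed), where=noise[:, None] > 0
        )
        return ratio.min(axis=0)  # (M,)

    start = per_pattern(syn_start)
    end = per_pattern(syn_end)
    delta = end - start
    table = pd.DataFrame(
        {"pattern": np.arange(patterns.M), "snr_start": start, "snr_change": delta}
    )
    slope = float(stats.linregress(start, delta).slope) if patterns.M > 1 else float("nan")
    return table, slope
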
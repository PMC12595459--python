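"""Replay-driven consolidation: margin maximisation over subsynaptic factors.

Consolidation makes the imprinted attractors noise-robust. Each neuron
independently maximises the signal-to-noise ratio of its weakest stored
pattern,

    SNR_i = min_mu |I_i^mu| / sqrt(sum_j w_ij^q),

where ``I_i^mu = sum_j w_ij xi_j^mu - I_inh_i`` is the input-current margin of
pattern mu. Because plasticity acts on the multiplicative factors ``u_ijk``
while homeostatic scaling keeps each neuron's factor norm ``sum_jk u_ijk^2``
constant, running the algorithm with z factors implicitly maximises the
margin under an L_{2/z} constraint on the weights: z = 1 is the classic
nonnegative L2 (neural-noise-optimal, dense) solution, z = 2 the L1
(synaptic-noise-optimal, sparse) solution.

One replay cycle has three steps:

1. *Induction* — every pattern is reinstated as the network state; a signed
   gate weights a Hebbian plasticity signal
   ``delta_u_ijk = g_i xi_j w_ij / u_ijk`` that is accumulated across
   patterns. The gate is ``g_i = y exp(-beta_i y I)`` with
   ``y = 2 xi_i - 1`` the reinstated state's side of the threshold; while a
   pattern is a fixed point (the normal operating regime) this equals
   ``sign(I) exp(-beta_i |I|)``, and when a pattern is transiently unstable
   it is the error-correcting batch-perceptron direction, which is what lets
   replay recover stability instead of amplifying the error.
2. *Expression* — a per-neuron learning rate ``G_i = eta / sum_mu |g_i|``
   normalises total expression per cycle, so the combination ``G_i g_i`` is a
   softmax over ``-beta_i |I_i^mu|``: expression concentrates on the weakest
   pattern as the sharpness ``beta_i`` is annealed upward (a soft version of
   the batch perceptron's support-vector selection). The inhibitory current
   receives the bias-term analogue of the update.
3. *Homeostatic scaling* — every factor of neuron i is multiplied by a
   single lambda_i restoring the factor norm, a purely multiplicative
   regulation that preserves all weight ratios.

Negative factors are clipped to zero; for z >= 2 a weight that reaches zero
can never regrow (pruning is absorbing), which is the source of the sparse
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SynapticState
from .patterns import PatternSet

__all__ = [
    "ConsolidationConfig",
    "ConsolidationDiagnostics",
    "ConsolidationError",
    "PlasticitySignals",
    "gate",
    "margins",
    "replay_cycle",
    "learning_rate",
    "expression_weights",
    "express_and_scale",
    "consolidate",
    "snr",
    "factor_misalignment",
]


@dataclass
class ConsolidationConfig:
    """Hyperparameters of the replay/expression/scaling loop.

    Attributes
    ----------
    cycles
        Number of full replay cycles.
    eta
        Expression budget per neuron per cycle (total |Delta| of the gated
        signal); dimensionless relative to the unit factor norm.
    beta0
        Initial gating sharpness. ``None`` (default) sets it per neuron so
        that ``beta0 * median_mu |I_i^mu| = 1`` at cycle 0.
    beta_growth
        Multiplicative annealing of beta per cycle (>= 1); larger values
        sharpen the soft argmin toward hard weakest-pattern selection faster.
    norm_target
        Per-neuron factor-norm constant ``U0 = sum_jk u^2``; ``None`` freezes
        it from the state at cycle 0.
    prune_floor
        Relative weight (fraction of the mean surviving weight) below which a
        connection counts as pruned in the density diagnostics.
    max_unstable_cycles
        Abort if some pattern stays unstable for more than this many
        consecutive cycles. ``None`` (default) never aborts: transient
        instability early in a run is normal while margins are still smaller
        than the per-cycle expression wobble, and its duration depends on the
        schedule; set an explicit window to catch true divergence.
    snr_q
        Noise-scaling exponent used for the per-cycle SNR diagnostics;
        ``None`` uses the structurally matched q = 2/z.
    ei_balance
        Split inhibition into an excitation-tracking part ``f sum_j w`` plus
        a learned offset (default). Disable to apply the inhibitory update
        directly to ``I_inh``; the optimisation problem is identical but far
        worse conditioned for 0/1 patterns (see
        :func:`express_and_scale`).
    """

    cycles: int = 400
    eta: float = 0.01
    beta0: float | None = None
    beta_growth: float = 1.02
    norm_target: np.ndarray | None = None
    prune_floor: float = 1e-3
    max_unstable_cycles: int | None = None
    snr_q: float | None = None
    ei_balance: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.beta0 is not None and self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")
        if self.beta_growth < 1.0:
            raise ValueError("beta_growth must be >= 1")


class ConsolidationError(RuntimeError):
    """Raised when replay loses a pattern for too many consecutive cycles."""

    def __init__(self, message: str, diagnostics: "ConsolidationDiagnostics | None" = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class PlasticitySignals:
    """Accumulated plasticity of one replay cycle.

    ``I`` is the (N, M) margin matrix, ``g`` the raw gate values, and
    ``sum_abs_g``/``sum_g`` the per-neuron accumulators that set the learning
    rate and the inhibitory update. ``mismatch`` flags (neuron, pattern)
    entries where the reinstated response disagreed with the pattern.
    """

    I: np.ndarray
    g: np.ndarray
    sum_abs_g: np.ndarray
    sum_g: np.ndarray
    mismatch: np.ndarray

    def delta_u(self, syn: SynapticState, patterns: PatternSet) -> np.ndarray:
        """Materialise the accumulated per-factor increments ``sum_mu delta_u``.

        For component k the increment on connection j->i is
        ``(sum_mu g_i^mu xi_j^mu) * (w_ij / u_ijk)`` with the convention that
        the factor ratio is 1 for z = 1 (empty product) and 0 on pruned
        (w = 0) synapses for z >= 2.
        """
        A = self.g @ patterns.xi.astype(float)  # (N, N): sum_mu g_i^mu xi_j^mu
        np.fill_diagonal(A, 0.0)
        return A[:, :, None] * _factor_ratios(syn)


def _factor_ratios(syn: SynapticState) -> np.ndarray:
    """``w_ij / u_ijk`` per component, the gradient of w wrt each factor.

    z = 1: identically 1 off-diagonal (regrowth possible). z >= 2: 0 wherever
    the weight is pruned, making pruning absorbing.
    """
    N, z = syn.N, syn.z
    off = ~np.eye(N, dtype=bool)
    if z == 1:
        ratio = np.zeros((N, N, 1))
        ratio[off, 0] = 1.0
        return ratio
    w = syn.w
    ratio = np.zeros((N, N, z))
    for k in range(z):
        uk = syn.u[:, :, k]
        np.divide(w, uk, out=ratio[:, :, k], where=uk > 0)
    ratio[w == 0] = 0.0
    return ratio


def gate(I: np.ndarray | float, beta: np.ndarray | float) -> np.ndarray:
    """Signed plasticity gate ``g = sign(I) * exp(-beta |I|)``.

    ``sign(0) = -1``, consistent with the strict firing threshold (a neuron
    at threshold is silent, so plasticity pushes it further below). Strong
    margins gate toward zero: familiar, robust memories induce little
    plasticity.
    """
    I = np.asarray(I, dtype=float)
    sigma = np.where(I > 0, 1.0, -1.0)
    return sigma * np.exp(-np.asarray(beta, dtype=float) * np.abs(I))


def margins(syn: SynapticState, patterns: PatternSet) -> np.ndarray:
    """Input-current margins ``I_i^mu`` of every neuron under every pattern, (N, M)."""
    return syn.w @ patterns.xi.T.astype(float) - syn.I_inh[:, None]


def replay_cycle(
    syn: SynapticState, patterns: PatternSet, beta: np.ndarray | float
) -> PlasticitySignals:
    """Reinstate every pattern and accumulate the gated plasticity signals.

    The gate sign and exponent follow the reinstated pattern's stability
    margin ``y I`` (``y = 2 xi_i - 1``), which coincides with
    :func:`gate`'s ``sign(I) exp(-beta |I|)`` for every (neuron, pattern)
    pair that is on the correct side of the threshold — i.e. always, under
    the fixed-point precondition — and points in the error-correcting
    direction for pairs flagged in ``mismatch``.
    """
    I = margins(syn, patterns)
    beta_col = np.broadcast_to(np.asarray(beta, dtype=float), (syn.N,))[:, None]
    y = 2.0 * patterns.xi.T - 1.0  # (N, M)
    # clip the exponent: badly violated patterns at high sharpness would
    # overflow; they saturate instead (expression_weights is exact regardless)
    g = y * np.exp(np.minimum(-beta_col * (y * I), 500.0))
    mismatch = (I > 0) != (patterns.xi.T == 1)
    return PlasticitySignals(
        I=I,
        g=g,
        sum_abs_g=np.abs(g).sum(axis=1),
        sum_g=g.sum(axis=1),
        mismatch=mismatch,
    )


def learning_rate(sum_abs_g: np.ndarray, eta: float) -> np.ndarray:
    """Per-neuron rate ``G_i = eta / sum_mu |g_i|`` (0 if the sum underflows).

    Normalises expression so every neuron spends the same budget eta per
    cycle: ``sum_mu G_i |g_i^mu| = eta``.
    """
    sum_abs_g = np.asarray(sum_abs_g, dtype=float)
    G = np.zeros_like(sum_abs_g)
    np.divide(eta, sum_abs_g, out=G, where=sum_abs_g > 0)
    return G


def expression_weights(
    I: np.ndarray, xi: np.ndarray, beta: np.ndarray, eta: float
) -> np.ndarray:
    """Signed per-pattern expression ``E = G_i g_i^mu`` via a stable softmax.

    Mathematically identical to ``learning_rate(signals.sum_abs_g, eta) *
    signals.g``: ``E_i^mu = eta * y * softmax_mu(-beta_i * y * I_i^mu)`` with
    ``y = 2 xi_i^mu - 1``, which under the fixed-point precondition reads
    ``eta * sign(I) * softmax_mu(-beta_i |I_i^mu|)``. Computed with the usual
    max-shift so that arbitrarily large beta (hard argmin) neither under- nor
    overflows.
    """
    y = 2.0 * np.asarray(xi).T - 1.0  # (N, M)
    x = -np.asarray(beta, dtype=float)[:, None] * (y * I)
    x -= x.max(axis=1, keepdims=True)
    p = np.exp(x)
    p /= p.sum(axis=1, keepdims=True)
    return eta * y * p


def express_and_scale(
    syn: SynapticState,
    E: np.ndarray,
    patterns: PatternSet,
    norm_target: np.ndarray,
    balance_f: float | None = None,
    theta: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply the expressed plasticity and the homeostatic rescaling, in place.

    ``E`` is the signed (N, M) expression matrix ``G_i g_i^mu``. Updates:

    * ``u_ijk <- max(0, u_ijk + (E xi)_ij * w_ij / u_ijk)`` (clipping at zero
      implements nonnegativity and pruning),
    * the inhibitory current receives the bias-term analogue of the update.
      In the plain form (``balance_f=None``) this is
      ``I_inh_i <- max(0, I_inh_i - sum_mu E_i^mu)``. With
      ``balance_f = f`` given, inhibition is split into a component
      ``f * sum_j w_ij`` that tracks total excitatory drive (E/I balance)
      plus a learned offset ``theta`` that takes the gradient update
      ``theta_i <- theta_i - sum_mu E_i^mu``; the total
      ``I_inh = max(0, theta + f sum_j w)`` spans exactly the same bias
      values, but the balanced part cancels the large common-drive component
      that every Hebbian weight change of 0/1 patterns carries
      (``xi_mu . xi_nu ~ N f^2``), without which margins of order
      ``sqrt(N) f`` smaller would be washed out cycle after cycle,
    * every factor of neuron i multiplied by lambda_i so that
      ``sum_jk u_ijk^2 = norm_target_i`` again. Only the factors are scaled:
      the bias is free in the margin problem, and rescaling it along with the
      weights would shrink it geometrically (lambda < 1 whenever expression
      grows the norm) and bias the equilibrium away from the max-margin
      solution.

    Returns ``(dead, theta)``: the boolean mask of dead neurons (entire
    factor row pruned away; frozen as-is) and the updated inhibitory offset
    (``None`` in the plain form).
    """
    xi = patterns.xi.astype(float)
    B = E @ xi  # (N, N) accumulated signed expression per connection
    np.fill_diagonal(B, 0.0)
    ratio = _factor_ratios(syn)
    syn.u += B[:, :, None] * ratio
    np.clip(syn.u, 0.0, None, out=syn.u)

    sq = np.einsum("ijk,ijk->i", syn.u, syn.u)
    dead = sq <= 0
    lam = np.ones_like(sq)
    np.sqrt(np.divide(norm_target, sq, out=lam, where=~dead), out=lam, where=~dead)
    syn.u *= lam[:, None, None]
    syn.invalidate()

    if balance_f is None:
        syn.I_inh = np.clip(syn.I_inh - E.sum(axis=1), 0.0, None)
        return dead, None
    theta = (theta if theta is not None else np.zeros(syn.N)) - E.sum(axis=1)
    syn.I_inh = np.clip(theta + balance_f * syn.w.sum(axis=1), 0.0, None)
    return dead, theta


def snr(syn: SynapticState, patterns: PatternSet, q: float) -> np.ndarray:
    """Per-neuron SNR: weakest-pattern margin over the q-scaled noise term.

    ``SNR_i = min_mu |I_i^mu| / sqrt(sum_j w_ij^q)`` with q = 2 for neural
    noise and q = 2 - 2/z for structural (synaptic) noise on z-factor
    synapses. Dead neurons (zero denominator) report SNR 0.
    """
    if not 0 < q <= 2:
        raise ValueError("q must lie in (0, 2]")
    I = margins(syn, patterns)
    signal = np.abs(I).min(axis=1)
    w = syn.w
    noise = np.sqrt(np.where(w > 0, w, 0.0).__pow__(q).sum(axis=1))
    out = np.zeros(syn.N)
    np.divide(signal, noise, out=out, where=noise > 0)
    return out


def factor_misalignment(syn: SynapticState) -> tuple[float, float]:
    """Mean over live synapses of ``max_{k,k'} |u_k - u_k'|``, plus mean factor.

    Returns ``(misalignment, mean_factor)``; both are 0 for a network with no
    live synapses, and misalignment is identically 0 for z = 1.
    """
    w = syn.w
    live = w > 0
    if not live.any():
        return 0.0, 0.0
    u_live = syn.u[live]  # (n_live, z)
    spread = u_live.max(axis=1) - u_live.min(axis=1)
    return float(spread.mean()), float(u_live.mean())


@dataclass
class ConsolidationDiagnostics:
    """Per-cycle record of the consolidation run.

    All arrays have one row per recorded cycle; per-neuron quantities have a
    column per neuron. ``min_margin`` is ``min_mu |I_i^mu|`` (the SNR
    signal), ``snr`` the per-neuron SNR at the configured q.
    """

    cycle: np.ndarray
    beta_mean: np.ndarray
    min_margin: np.ndarray
    snr: np.ndarray
    density: np.ndarray
    misalignment: np.ndarray
    mean_factor: np.ndarray
    expression: np.ndarray
    n_mismatch: np.ndarray
    dead: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    aborted: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "beta_mean": self.beta_mean,
                "min_margin_mean": self.min_margin.mean(axis=1),
                "min_margin_min": self.min_margin.min(axis=1),
                "snr_mean": self.snr.mean(axis=1),
                "snr_min": self.snr.min(axis=1),
                "density": self.density,
                "misalignment": self.misalignment,
                "mean_factor": self.mean_factor,
                "expression": self.expression,
                "n_mismatch": self.n_mismatch,
            }
        )


def consolidate(
    syn: SynapticState,
    patterns: PatternSet,
    config: ConsolidationConfig | None = None,
) -> tuple[SynapticState, ConsolidationDiagnostics]:
    """Run the full replay -> expression -> homeostatic-scaling loop.

    The input state is not modified; a consolidated copy is returned together
    with per-cycle diagnostics. Raises :class:`ConsolidationError` if some
    pattern stays unstable for more than ``config.max_unstable_cycles``
    consecutive cycles.
    """
    config = config or ConsolidationConfig()
    state = syn.copy()
    xi = patterns.xi
    if patterns.N != state.N:
        raise ValueError("pattern and state dimensions disagree")
    z = state.z
    q_diag = config.snr_q if config.snr_q is not None else 2.0 / z

    # homeostatic set point: freeze the factor norm of the incoming state
    if config.norm_target is not None:
        norm_target = np.broadcast_to(
            np.asarray(config.norm_target, dtype=float), (state.N,)
        ).copy()
    else:
        norm_target = np.einsum("ijk,ijk->i", state.u, state.u)

    I0 = margins(state, patterns)
    if config.beta0 is None:
        med = np.median(np.abs(I0), axis=1)
        beta0 = np.where(med > 0, 1.0 / np.where(med > 0, med, 1.0), 1.0)
    else:
        beta0 = np.full(state.N, float(config.beta0))

    rec: dict[str, list] = {k: [] for k in (
        "cycle", "beta_mean", "min_margin", "snr", "density",
        "misalignment", "mean_factor", "expression", "n_mismatch",
    )}
    mean_w0 = state.w[state.w > 0].mean() if (state.w > 0).any() else 0.0
    floor = config.prune_floor * mean_w0
    consecutive_unstable = 0
    dead = np.zeros(state.N, dtype=bool)
    aborted = False
    balance_f = patterns.f if config.ei_balance else None
    theta = (
        state.I_inh - patterns.f * state.w.sum(axis=1) if config.ei_balance else None
    )

    for c in range(config.cycles):
        beta = beta0 * config.beta_growth**c
        I = margins(state, patterns)
        mismatch = (I > 0) != (xi.T == 1)
        mismatch[dead] = False
        n_mismatch = int(mismatch.sum())

        # record the pre-update snapshot of this cycle
        mis, mean_u = factor_misalignment(state)
        rec["cycle"].append(c)
        rec["beta_mean"].append(float(beta.mean()))
        rec["min_margin"].append(np.abs(I).min(axis=1))
        rec["snr"].append(snr(state, patterns, q_diag))
        rec["density"].append(state.density(floor))
        rec["misalignment"].append(mis)
        rec["mean_factor"].append(mean_u)
        rec["expression"].append(config.eta)
        rec["n_mismatch"].append(n_mismatch)

        E = expression_weights(I, xi, beta, config.eta)
        E[dead] = 0.0
        new_dead, theta = express_and_scale(
            state, E, patterns, norm_target, balance_f=balance_f, theta=theta
        )
        dead |= new_dead

        consecutive_unstable = consecutive_unstable + 1 if n_mismatch > 0 else 0
        if (
            config.max_unstable_cycles is not None
            and consecutive_unstable > config.max_unstable_cycles
        ):
            aborted = True
            break

    diag = ConsolidationDiagnostics(
        cycle=np.array(rec["cycle"]),
        beta_mean=np.array(rec["beta_mean"]),
        min_margin=np.array(rec["min_margin"]),
        snr=np.array(rec["snr"]),
        density=np.array(rec["density"]),
        misalignment=np.array(rec["misalignment"]),
        mean_factor=np.array(rec["mean_factor"]),
        expression=np.array(rec["expression"]),
        n_mismatch=np.array(rec["n_mismatch"], dtype=int),
        dead=dead,
        aborted=aborted,
    )
    if aborted:
        raise ConsolidationError(
            f"pattern instability persisted for more than "
            f"{config.max_unstable_cycles} consecutive cycles",
            diagnostics=diag,
        )
    return state, diag
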
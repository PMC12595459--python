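# Methods

## Model

The circuit is a recurrent network of N binary neurons with synchronous
(parallel) updates: s_i(t+1) = Θ(Σ_j w_ij s_j(t) − I_inh,i), with a strict
threshold (a neuron exactly at threshold stays silent), nonnegative weights,
no autapses, and inhibition summarised by one scalar current per neuron.
Each weight is a product of z nonnegative subsynaptic factors,
w_ij = Π_k u_ijk; component 1 is the volatile plasticity tag, the others
represent slower structural processes. Memories are M binary patterns with
i.i.d. Bernoulli(f) entries, f ≤ 0.5; storage load is α = M/N.

Memory robustness is the SNR of the weakest stored pattern per neuron,
SNR_i = min_μ |I_i^μ| / sqrt(Σ_j w_ij^q), with the noise exponent q set by
the perturbation type: q = 2 for neural noise (bit flips in the cue) and
q = 2 − 2/z for white noise on the volatile factor of a z-factor synapse
(first-order weight perturbation |Δw| ∝ w^{1−1/z} on aligned factors).

## Wake phase

`imprint_patterns` uses a clipped covariance rule,
w_ij = (c/N)[Σ_μ (ξ_i−f)(ξ_j−f)]₊, with the inhibitory threshold at the
midpoint between each neuron's weakest "on" drive and strongest "off" drive.
Factors start aligned (u = w^{1/z}) and each neuron's factor norm is scaled
to 1 — per-neuron rescaling of (w, I_inh) leaves the dynamics invariant, so
this only fixes the homeostatic set point. One-shot imprinting has limited
capacity; `stabilize_patterns` (Motzkin relaxation: per sweep, an exact
overcorrecting step along each neuron's most violated pattern) repairs the
remaining errors whenever the sign-constrained storage problem is feasible,
leaving a small margin cushion (2% of the mean drive by default) so that the
first consolidation cycles do not immediately knock patterns back out. Both
steps together constitute the wake phase; consolidation assumes every
pattern is a fixed point when it starts.

## Consolidation (sleep phase)

One cycle, in order:

1. **Replay / induction.** Each pattern is reinstated as the network state;
   the margin I_i^μ is computed and gated. The gate is
   g = y·exp(−β_i·y·I) with y = 2ξ_i − 1 the reinstated state's side of
   threshold. While a pattern is a fixed point this equals the response-signed
   form sign(I)e^{−β|I|}; when a pattern is transiently unstable it points in
   the error-correcting (batch perceptron) direction, which is what makes
   transient instability recoverable. The plasticity signal per factor is
   δu_ijk = g·ξ_j·w_ij/u_ijk — the gradient of the weight with respect to
   that factor. For z = 1 the factor ratio is the empty product (1), so a
   pruned single-component weight can regrow; for z ≥ 2 the ratio is 0 on
   pruned weights, so pruning is absorbing.
2. **Expression.** The learning rate G_i = η/Σ_μ|g| normalises the total
   expressed plasticity to η per neuron per cycle, making G·g an exact
   softmax over −β·(stability margins). It is computed with the standard
   max-shifted softmax so arbitrarily large β neither under- nor overflows.
   Updates are clipped at zero (nonnegativity). The inhibitory current is
   decomposed as I_inh = f·Σ_j w_ij + θ: the first part tracks total
   excitatory drive (E/I balance) and follows the weights automatically; the
   learned offset θ receives the bias-term update −Σ_μ G g. The balanced
   decomposition matters numerically: with 0/1 patterns every Hebbian update
   carries a common-drive component of order N f² that would otherwise swamp
   margins of order √N·f smaller, making convergence at realistic N
   impractically slow. The plain (unbalanced) rule is available via
   `ei_balance=False`; the two define the same optimisation problem.
3. **Homeostatic scaling.** Every factor of neuron i is multiplied by one
   λ_i restoring Σ_jk u² to its set point (frozen from the state at cycle 0).
   Only the factors are scaled — the bias is a free parameter of the margin
   problem, and rescaling it alongside the weights shrinks it geometrically
   whenever expression grows the norm, which demonstrably biases the
   equilibrium away from the max-margin solution.

The sharpness anneals as β_i(c) = β0_i·growth^c with β0_i = 1/median_μ|I_i^μ|
at cycle 0, taking the soft argmin toward hard support-vector selection.
With the factor norm held fixed, the fixed point of this loop is the
nonnegative max-margin solution under ‖w‖_{2/z}: verified on small instances
against an SLSQP quadratic program (z = 1, L2) and a HiGHS linear program
(z = 2, L1) to within 2% in margin.

### Schedules

η is the expression budget per cycle relative to the unit factor norm;
smaller η converges closer to the optimum but more slowly. Defaults
(cycles = 400, η = 0.01, growth = 1.02) suit quick desk runs; the tests use
η = 0.002–0.01 with growth 1.0005–1.002 and 2 500–16 000 cycles depending on
instance size. The z = 3 flow is stiffest (updates scale with w^{2/3}), so
pruning to convergence takes several times more cycles than z = 2. Early in
a run, patterns whose margins are still below the per-cycle expression wobble
flip transiently; this resolves itself and is why the abort window
(`max_unstable_cycles`) is off by default and opt-in.

### Direct solver

`max_l2_margin_weights` solves the z = 1 fixed point directly: squared-hinge
max-margin with continuation in the hinge stiffness, by accelerated projected
gradient (FISTA) over all neurons simultaneously, with the same E/I-balanced
bias parameterisation. It reaches the converged density orders of magnitude
faster than replay at N = 500 and is what the load sweeps and the density
benchmark use for z = 1; its agreement with the replay algorithm is covered
by the oracle-equivalence tests.

## Robustness measurement

Recall protocol: cue the network, run 10 synchronous steps, declare success
if the final overlap reaches 95% of the pattern's self-overlap (the
self-normalisation keeps exact retrieval at score 1 even when a pattern's
realised on-count fluctuates around N·f, which matters at low coding levels).
Neural noise flips cue bits independently; synaptic noise adds one quenched
Gaussian draw to the volatile factor per recall test (per-step redraws are
not modelled). `tolerated_noise` bisects on the noise level for the largest
level with ≥90% success.

## Synaptic volatility simulator

Each of n independent synapses holds z factors, initialised aligned with
log-normal strengths (median 0.35, log-SD 0.5 — heavy-tailed, as measured
spine-size distributions are). Per step of length dt: all factors relax
toward their common geometric mean at rate `relax` (capped at full
realignment per step) — consolidation between measurements redistributing
strength across components, a weight-preserving operation — and the volatile
tag then receives white noise of SD sigma·√dt. For z = 1 the tag reflects at
zero; for z ≥ 2 a tag reaching zero prunes the synapse permanently, matching
absorbing pruning in the network model. Defaults: n = 1000, dt = 0.5 h,
T = 24 h (dense longitudinal imaging cadence), sigma = 0.02 per √h,
relax = 2 /h. With these the measured fluctuation exponents recover 1 − 1/z
within two bootstrap SEs for z ∈ {1, 2, 3}; slower realignment (relax ≲ 0.5)
lets factor misalignment accumulate and attenuates the exponent, and larger
sigma inflates the z = 1 depression exponent through boundary reflections.
The homeostatic flag rescales all live strengths multiplicatively each step
so Σ_j w^{2/z} is conserved exactly, pinning the most stable q-norm at 2/z.

What the simulator does *not* emulate: activity-dependent (extrinsic)
plasticity, measurement noise, synapse turnover (new synapses appearing), or
inter-synapse correlations beyond the optional global homeostatic coupling.
Passing tests therefore show that the *analysis* recovers the exponents the
*model* predicts — not that real synapses obey them.

## Trajectory statistics

`fluctuation_scaling` forms all (w(t), Δw) pairs at one sampling lag, splits
by sign of Δw, sorts by strength, smooths (log w, log |Δw|) with a centered
101-pair moving average, and fits a line by least squares; raw-pair
regression and a moving-RMSD variant give nearly identical exponents (the
RMSD variant carries a small Jensen gap, ~0.002 on an exact power law).
Standard errors bootstrap over synapses (default 100 replicates), preserving
within-synapse autocorrelation. Zero-strength origins are excluded (no log).

`norm_cv` computes (Σ_j w_j(t)^q)^{1/q} on a common time grid (pruned
synapses contribute zero) for q ∈ {0.25, …, 3.0} (step 0.25, covering 2/z for
z ∈ {1, 2, 3} plus a flat tail), takes the CV across time, rank-normalises
the curve to [0, 1], and bootstraps q_min over synapses (default 1000
replicates). The q-grid pitch (0.25) bounds the resolution of q_min.

Pruning-vs-weight uses quantile bins of log-weight with a statsmodels
logistic regression of the prune indicator on log10 w (the reported slope's
sign is the statistic of interest). Response-correlation connectivity uses
the consolidated network's graded recall drive Σ_j w_ij ξ_j per pattern,
Pearson-correlates neuron pairs across patterns (constant responders
excluded), and reports survival fraction and max-normalised mean surviving
strength per correlation bin. Tuning sparseness is the Treves–Rolls-style
selectivity S = (1 − a)/(1 − 1/n), a = (mean r)²/mean(r²), computed along the
chosen axis and averaged over the other, with all-zero vectors excluded; for
tuning comparisons responses are sigmoidal in the margin with a temperature
of half the median familiar-pattern margin (a hard threshold would leave
novel-stimulus responses identically zero and the comparison degenerate).
Per-pattern SNR for the retention analysis is the minimum over neurons of the
signed margin over the neuron's noise term, at the same q before and after.

## Numerical choices and degenerate inputs

- Capacity is estimated by bisection over M on per-neuron LP feasibility
  (HiGHS) of sampled neurons; the per-neuron problems are exchangeable, so
  ~15–20 sampled neurons suffice at the resolution used (ΔM ≈ N/50).
- Tiny dense instances can be genuinely infeasible under nonnegativity (one
  pattern's active set containing another's with opposite target); oracles
  report these as infeasible and the equivalence tests select feasible draws.
- Dead neurons (entire factor row pruned) are frozen and flagged; neurons
  silent in every pattern have a degenerate (infinite-margin) storage problem
  and are excluded from margin comparisons.
- Serialisation is full-precision decimal (%.17g) TSV with round-trip float
  parsing, so states and tables survive write/read bit-exactly.
- The gating exponent in the raw replay signal is clipped at 500 to avoid
  overflow on badly violated patterns at extreme sharpness; the expression
  path uses the max-shifted softmax and is exact regardless.

## Known limitations

- Replay consolidation at N ≳ 500 near capacity converges slowly in margin;
  the direct FISTA solver covers that regime for z = 1. There is no direct
  solver for z ≥ 2 (the L_{2/z} problem is nonconvex for z > 2).
- The z = 3 density ordering (sparser than z = 2) emerges only when both are
  run to convergence; at moderate loads z = 3 prunes very slowly.
- Asynchronous updates, graded activity during recall, explicit inhibitory
  neurons, and cue clamping beyond a single initial condition per recall
  block are not modelled.
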
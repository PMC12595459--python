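# synconsol

Replay-driven synaptic consolidation in recurrent attractor networks with
multiplicative multi-component synapses.

## The scientific problem

Binary recurrent networks store memories as attractors: a pattern
ξ<sup>μ</sup> ∈ {0,1}<sup>N</sup> is stored when every neuron reproduces its
target state under the dynamics s<sub>i</sub>(t+1) = Θ(Σ<sub>j</sub>
w<sub>ij</sub> s<sub>j</sub>(t) − I<sub>inh,i</sub>) with nonnegative weights
and a per-neuron inhibitory current. Freshly imprinted memories are fragile:
any small perturbation of the cue (neural noise) or of the weights (intrinsic
synaptic noise) destroys recall. Consolidation — biologically, what happens
during sleep — should maximise the signal-to-noise ratio of the weakest
stored memory,

    SNR_i = min_mu |I_i^mu| / sqrt(Σ_j w_ij^q),

where q = 2 for neural noise and q = 2 − 2/z for intrinsic noise on synapses
composed of z multiplicative subsynaptic factors, w<sub>ij</sub> =
Π<sub>k</sub> u<sub>ijk</sub>.

This package implements the consolidation algorithm that performs that
maximisation with purely local, biologically styled operations:

1. **Replay** — each stored pattern is reinstated; a signed gate
   g = ±e<sup>−β|I|</sup> accumulates a Hebbian plasticity signal
   δu<sub>ijk</sub> = g ξ<sub>j</sub> w<sub>ij</sub>/u<sub>ijk</sub>
   (weak, near-threshold memories induce the most plasticity);
2. **Expression** — a per-neuron learning rate G = η/Σ|g| fixes the total
   expression per cycle, so G·g is a softmax over −β|I|: an annealed soft
   argmin that converges to the batch perceptron's support-vector selection;
3. **Homeostatic scaling** — all factors of a neuron are multiplied by one
   number restoring Σu² to its set point, a purely multiplicative
   normalisation that preserves weight ratios.

Running this with z factors implicitly solves the nonnegative max-margin
problem under an L<sub>2/z</sub> constraint: z = 1 gives the dense,
neural-noise-optimal L2 solution (never below ~50% connectivity); z = 2 gives
the sparse, synaptic-noise-optimal L1 solution — pruning, multiplicative
homeostasis and noise robustness from one rule. The package also ships a
stochastic simulator of intrinsic synaptic volatility and the trajectory
statistics used to look for multi-factor structure in longitudinal synapse
data: fluctuation-scaling exponents (⟨|Δw|⟩ ∝ w<sup>1−1/z</sup>) and the
most-stable-norm exponent (CV of ‖w‖<sub>q</sub> over time is minimal at
q<sub>min</sub> = 2/z).

Intended users: computational neuroscientists studying memory consolidation,
and experimentalists with longitudinal spine-size or synaptic-weight
trajectories who want the scaling analyses.

## Worked example

```python
from synconsol import (ConsolidationConfig, consolidate, generate_patterns,
                       imprint_patterns, stabilize_patterns, snr, tolerated_noise)

pats = generate_patterns(N=150, M=30, f=0.5, seed=11)       # 30 memories
pre = imprint_patterns(pats, z=2)                           # wake: one-shot imprint
stabilize_patterns(pre, pats)                               # wake: error-correcting repair
post, diag = consolidate(pre, pats,                         # sleep: margin maximisation
                         ConsolidationConfig(cycles=4000, eta=0.005,
                                             beta_growth=1.002))

floor = 1e-3 * post.w[post.w > 0].mean()
print(f"density  pre={pre.density(floor):.3f}  post={post.density(floor):.3f}")
print(f"mean SNR (q=1)  pre={snr(pre, pats, 1.0).mean():.4f}  "
      f"post={snr(post, pats, 1.0).mean():.4f}")
lv_pre, _ = tolerated_noise(pre, pats, "synaptic", trials=4, seed=3)
lv_post, _ = tolerated_noise(post, pats, "synaptic", trials=4, seed=3)
print(f"tolerated synaptic noise  pre={lv_pre:.4f}  post={lv_post:.4f}")
```

prints

```
density  pre=0.684  post=0.491
mean SNR (q=1)  pre=0.0086  post=0.0787
tolerated synaptic noise  pre=0.0042  post=0.0391
```

Consolidation pruned the network to 49% connectivity while raising the
weakest-memory SNR ninefold; the consolidated network survives quenched white
noise on its volatile synaptic components at a scale comparable to the mean
live factor itself (0.039 vs. a mean factor of 0.041), roughly ten times the
level that destroys recall in the merely stabilised network.

The same machinery is available from the shell:

```bash
synconsol generate-patterns --n 150 --m 30 --seed 11 --out pats.tsv
synconsol imprint --patterns pats.tsv --z 2 --state-out pre.tsv
synconsol consolidate --patterns pats.tsv --state-in pre.tsv --state-out post.tsv
synconsol simulate-synapses --n 1000 --z 2 --out traj.tsv
synconsol analyze-scaling --table traj.tsv --out slopes.tsv
```

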
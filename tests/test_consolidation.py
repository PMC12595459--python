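import numpy as np
import pytest

from synconsol import (
    ConsolidationConfig,
    consolidate,
    expression_weights,
    express_and_scale,
    factor_misalignment,
    gate,
    generate_patterns,
    imprint_patterns,
    learning_rate,
    margins,
    replay_cycle,
    snr,
)
from synconsol.consolidation import ConsolidationError


class TestGate:
    def test_half_decay_at_log_two(self):
        assert gate(np.log(2.0), 1.0) == pytest.approx(0.5)
        assert gate(-np.log(2.0), 1.0) == pytest.approx(-0.5)

    def test_silent_convention_at_zero_current(self):
        assert gate(0.0, 1.0) == -1.0

    def test_strong_memories_gate_to_zero(self):
        assert abs(gate(50.0, 2.0)) < 1e-40


class TestReplayCycle:
    def test_single_component_signal_is_gated_perceptron_direction(self, small_patterns):
        state = imprint_patterns(small_patterns, z=1)
        sig = replay_cycle(state, small_patterns, beta=1.0)
        delta = sig.delta_u(state, small_patterns)
        expected = sig.g @ small_patterns.xi.astype(float)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(delta[:, :, 0], expected)

    def test_two_aligned_components_scale_with_sqrt_weight(self, small_patterns, imprinted_z2):
        sig = replay_cycle(imprinted_z2, small_patterns, beta=1.0)
        delta = sig.delta_u(imprinted_z2, small_patterns)
        A = sig.g @ small_patterns.xi.astype(float)
        np.fill_diagonal(A, 0.0)
        expected = A * np.sqrt(imprinted_z2.w)
        for k in (0, 1):
            assert np.allclose(delta[:, :, k], expected, atol=1e-12)

    def test_silent_presynaptic_neuron_contributes_nothing(self, small_patterns, imprinted_z2):
        mu = 0
        silent = np.flatnonzero(small_patterns.xi[mu] == 0)
        single = generate_patterns(60, 1, 0.5, seed=0)
        single.xi[0] = small_patterns.xi[mu]
        sig = replay_cycle(imprinted_z2, single, beta=1.0)
        delta = sig.delta_u(imprinted_z2, single)
        assert np.all(delta[:, silent, :] == 0)

    def test_fixed_point_gates_match_response_sign_convention(
        self, small_patterns, imprinted_z2
    ):
        # with every pattern a fixed point, the stability gate equals sign(I)e^{-b|I|}
        sig = replay_cycle(imprinted_z2, small_patterns, beta=2.0)
        assert not sig.mismatch.any()
        assert np.allclose(sig.g, gate(sig.I, 2.0))


class TestLearningRate:
    def test_single_pattern_spends_full_budget(self):
        g = np.array([[0.3]])
        G = learning_rate(np.abs(g).sum(axis=1), eta=0.05)
        assert G[0] * abs(g[0, 0]) == pytest.approx(0.05)

    def test_equal_margins_split_budget_equally(self, small_patterns, imprinted_z2):
        sig = replay_cycle(imprinted_z2, small_patterns, beta=1.0)
        G = learning_rate(sig.sum_abs_g, eta=0.02)
        expressed = G[:, None] * np.abs(sig.g)
        assert np.allclose(expressed.sum(axis=1), 0.02)

    def test_underflowed_gates_give_zero_rate(self):
        assert learning_rate(np.array([0.0]), eta=0.1)[0] == 0.0

    def test_soft_argmin_identity_is_exact(self, small_patterns, imprinted_z2):
        # G * g == eta * softmax(-beta |I|) per pattern, to machine precision
        beta = 1.7
        sig = replay_cycle(imprinted_z2, small_patterns, beta=beta)
        G = learning_rate(sig.sum_abs_g, eta=0.03)
        lhs = G[:, None] * sig.g
        rhs = expression_weights(sig.I, small_patterns.xi, np.full(60, beta), eta=0.03)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-18)

    def test_sharp_gating_selects_weakest_pattern(self, small_patterns, imprinted_z2):
        I = margins(imprinted_z2, small_patterns)
        E = expression_weights(I, small_patterns.xi, np.full(60, 1e4), eta=1.0)
        # hard argmin: all expression lands on the weakest pattern(s); the
        # one-shot imprint has discrete margin levels, so exact ties occur
        # and the softmax splits the budget equally among them
        absI = np.abs(I)
        tied_min = np.isclose(absI, absI.min(axis=1, keepdims=True), rtol=1e-9)
        on_weakest = np.where(tied_min, np.abs(E), 0.0).sum(axis=1)
        assert np.allclose(on_weakest, 1.0)


class TestExpressAndScale:
    def test_factor_norm_restored_exactly(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        target = np.einsum("ijk,ijk->i", state.u, state.u)
        I = margins(state, small_patterns)
        E = expression_weights(I, small_patterns.xi, np.ones(60), eta=0.05)
        express_and_scale(state, E, small_patterns, target)
        after = np.einsum("ijk,ijk->i", state.u, state.u)
        assert np.allclose(after, target, rtol=1e-10)

    def test_scaling_preserves_weight_ratios(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        target = np.einsum("ijk,ijk->i", state.u, state.u)
        I = margins(state, small_patterns)
        E = expression_weights(I, small_patterns.xi, np.ones(60), eta=0.01)
        # capture weights right after expression but before scaling by
        # re-deriving them: scaling multiplies each row by a constant, so
        # ratios within a row of the scaled state must match the unscaled one
        unscaled = state.copy()
        xi = small_patterns.xi.astype(float)
        B = E @ xi
        np.fill_diagonal(B, 0.0)
        from synconsol.consolidation import _factor_ratios

        unscaled.u += B[:, :, None] * _factor_ratios(unscaled)
        np.clip(unscaled.u, 0.0, None, out=unscaled.u)
        unscaled.invalidate()
        express_and_scale(state, E, small_patterns, target)
        live = (state.w > 0) & (unscaled.w > 0)
        ratio = state.w[live] / unscaled.w[live]
        row_idx = np.nonzero(live)[0]
        for i in np.unique(row_idx):
            r = ratio[row_idx == i]
            assert np.allclose(r, r[0], rtol=1e-12)

    def test_pruned_synapse_never_regrows_multicomponent(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        state.u[3, 7, :] = 0.0
        state.invalidate()
        target = np.einsum("ijk,ijk->i", state.u, state.u)
        for _ in range(5):
            I = margins(state, small_patterns)
            E = expression_weights(I, small_patterns.xi, np.ones(60), eta=0.05)
            express_and_scale(state, E, small_patterns, target)
        assert state.w[3, 7] == 0.0

    def test_dead_neuron_flagged(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        state.u[5] = 0.0
        state.invalidate()
        target = np.einsum("ijk,ijk->i", state.u, state.u)
        I = margins(state, small_patterns)
        E = expression_weights(I, small_patterns.xi, np.ones(60), eta=0.0001)
        dead, _ = express_and_scale(state, E, small_patterns, target)
        assert dead[5]


class TestConsolidate:
    def test_norm_conserved_every_cycle_and_patterns_stay_stable(
        self, small_patterns, consolidated_z2, imprinted_z2
    ):
        state, diag = consolidated_z2
        target = np.einsum("ijk,ijk->i", imprinted_z2.u, imprinted_z2.u)
        after = np.einsum("ijk,ijk->i", state.u, state.u)
        assert np.allclose(after, target, rtol=1e-10)
        assert diag.n_mismatch[-1] == 0

    def test_snr_improves_at_matched_exponent(self, small_patterns, imprinted_z2, consolidated_z2):
        state, _ = consolidated_z2
        q = 2.0 / state.z
        assert np.all(
            snr(state, small_patterns, q) >= snr(imprinted_z2, small_patterns, q) - 1e-12
        )

    def test_min_snr_trend_nondecreasing_late(self, consolidated_z2):
        _, diag = consolidated_z2
        late = diag.snr.min(axis=1)[diag.snr.shape[0] // 2 :]
        # smooth over 100-cycle blocks; allow 1% wobble
        blocks = [late[i : i + 100].mean() for i in range(0, len(late) - 99, 100)]
        assert all(b2 >= b1 * 0.99 for b1, b2 in zip(blocks, blocks[1:]))

    def test_final_factors_aligned(self, consolidated_z2):
        state, _ = consolidated_z2
        mis, mean_u = factor_misalignment(state)
        assert mis < 0.01 * mean_u

    def test_weight_updates_are_multiplicative_for_two_factors(
        self, small_patterns, consolidated_z2
    ):
        # per-cycle weight changes of aligned two-factor synapses are
        # proportional to the momentary weight: w' = w (1 + B)^2 lambda^2,
        # where B is the expressed per-connection signal and lambda the
        # homeostatic rescale — verified exactly, plus the emergent log-log
        # magnitude scaling (|dw| grows ~linearly with w)
        from scipy import stats

        state, diag = consolidated_z2
        before = state.copy()
        beta = diag.beta_mean[-1]
        I = margins(before, small_patterns)
        E = expression_weights(I, small_patterns.xi, np.full(60, beta), eta=0.005)
        B = E @ small_patterns.xi.astype(float)
        np.fill_diagonal(B, 0.0)
        target = np.einsum("ijk,ijk->i", before.u, before.u)
        stepped = before.copy()
        express_and_scale(stepped, E, small_patterns, target, balance_f=0.5,
                          theta=np.zeros(60))
        u_pred = np.clip(before.u[:, :, 0] * (1.0 + B), 0.0, None)  # aligned factors
        sq = (2 * u_pred**2).sum(axis=1)
        lam = np.sqrt(target / sq)
        w_pred = (lam[:, None] * u_pred) ** 2
        assert np.allclose(stepped.w, w_pred, rtol=1e-8, atol=1e-14)

        # emergent magnitude scaling at moderate gating sharpness, where the
        # expressed signal is spread over several patterns
        after, _ = consolidate(
            state.copy(), small_patterns, ConsolidationConfig(cycles=1, eta=0.005)
        )
        live = (after.w > 0) & (state.w > 0)
        dw = np.abs(after.w[live] - state.w[live])
        w = state.w[live]
        keep = dw > 0
        res = stats.linregress(np.log10(w[keep]), np.log10(dw[keep]))
        assert res.rvalue**2 > 0.9
        assert 0.7 < res.slope < 1.1

    def test_density_decreases_with_component_count(self, small_patterns):
        # higher z implies a tighter implicit sparsity bias; the z = 3 flow
        # anneals more stiffly (updates scale with w^{2/3}), so it gets a
        # longer schedule to prune to convergence
        dens = {}
        for z, cycles in ((1, 6000), (2, 8000), (3, 16000)):
            state0 = imprint_patterns(small_patterns, z=z)
            cfg = ConsolidationConfig(cycles=cycles, eta=0.01, beta_growth=1.0005)
            state, diag = consolidate(state0, small_patterns, cfg)
            assert diag.n_mismatch[-1] == 0
            floor = 1e-3 * state.w[state.w > 0].mean()
            dens[z] = state.density(floor)
        assert dens[1] > dens[2] >= dens[3]

    def test_alignment_decays_from_misaligned_start(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 0.4, size=(60, 60))
        state.u[:, :, 0] *= np.exp(eps)
        state.u[:, :, 1] *= np.exp(-eps)
        state.invalidate()
        cfg = ConsolidationConfig(cycles=2000, eta=0.005, beta_growth=1.002)
        out, diag = consolidate(state, small_patterns, cfg)
        rel = diag.misalignment / np.maximum(diag.mean_factor, 1e-300)
        blocks = [rel[i : i + 400].mean() for i in range(0, 2000, 400)]
        assert all(b2 < b1 for b1, b2 in zip(blocks, blocks[1:]))

    def test_abort_on_persistent_instability(self, small_patterns, imprinted_z2):
        state = imprinted_z2.copy()
        state.I_inh = state.I_inh * 50.0  # silence everything: on-patterns unstable
        cfg = ConsolidationConfig(cycles=50, eta=1e-9, max_unstable_cycles=5)
        with pytest.raises(ConsolidationError) as exc:
            consolidate(state, small_patterns, cfg)
        assert exc.value.diagnostics is not None
        assert exc.value.diagnostics.aborted


class TestSnr:
    def test_single_synapse_arithmetic(self):
        from synconsol import PatternSet, SynapticState

        w = np.zeros((2, 2))
        w[0, 1] = 4.0
        state = SynapticState(u=w[:, :, None], I_inh=np.array([2.0, 0.0]))
        pats = PatternSet(xi=np.array([[1, 1]]), f=0.5)
        # margin |4 - 2| = 2; noise sqrt(4^1) = 2 at q=1
        assert snr(state, pats, q=1.0)[0] == pytest.approx(1.0)

    def test_homogeneity_in_weight_scale(self, small_patterns, imprinted_z2):
        lam = 2.5
        scaled = imprinted_z2.copy()
        scaled.u *= lam ** (1.0 / scaled.z)
        scaled.I_inh = scaled.I_inh * lam
        scaled.invalidate()
        for q in (0.5, 1.0, 2.0):
            s0 = snr(imprinted_z2, small_patterns, q)
            s1 = snr(scaled, small_patterns, q)
            assert np.allclose(s1, s0 * lam ** (1 - q / 2), rtol=1e-10)

    def test_invalid_exponent_rejected(self, small_patterns, imprinted_z2):
        with pytest.raises(ValueError):
            snr(imprinted_z2, small_patterns, q=2.5)
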
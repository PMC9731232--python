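import numpy as np
import pytest

from conftest import random_ensemble
from morphoinfer import (
    CellEnsembleState,
    GeneralizedState,
    NoiseParams,
    PrecisionConfig,
    RunConfig,
    SimulationDivergenceError,
    flow,
    free_energy,
    generalized_shift,
    generate_noise,
    initial_ensemble,
    integrate_step,
    sense,
    simulate,
)
from morphoinfer.inference_engine import _shift_orders


def make_prec(morph, **kw):
    base = PrecisionConfig.defaults(morph.n_slots, morph.n_slots)
    fields = dict(
        pi1_c=base.pi1_c,
        pi1_x=base.pi1_x,
        pi1_lambda=base.pi1_lambda,
        pi2=base.pi2,
        prior_mean=base.prior_mean,
    )
    fields.update(kw)
    return PrecisionConfig(**fields)


def finite_difference_gradients(ens, morph, prec, gains=None, h=1e-6):
    """Independent oracle: central differences of the free energy with
    respect to the lowest-order internal and active states, re-sensing
    the world (zero noise) after each perturbation."""

    def F_of(I0, A0):
        e = CellEnsembleState(
            internal=ens.internal.copy(),
            active=ens.active.copy(),
            sc=ens.sc,
            sx=ens.sx,
            s_lambda=ens.s_lambda,
        )
        e.internal[:, 0, :] = I0
        e.active[:, 0, :] = A0
        e = sense(e, morph, gains)
        return free_energy(e, morph, prec)

    I0 = ens.internal[:, 0, :].copy()
    A0 = ens.active[:, 0, :].copy()
    gI = np.zeros_like(I0)
    gA = np.zeros_like(A0)
    for idx in np.ndindex(I0.shape):
        p = I0.copy(); p[idx] += h
        m = I0.copy(); m[idx] -= h
        gI[idx] = (F_of(p, A0) - F_of(m, A0)) / (2 * h)
    for idx in np.ndindex(A0.shape):
        p = A0.copy(); p[idx] += h
        m = A0.copy(); m[idx] -= h
        gA[idx] = (F_of(I0, p) - F_of(I0, m)) / (2 * h)
    return gI, gA


class TestGeneralizedShift:
    def test_order_one_becomes_zero(self):
        g = GeneralizedState(orders=np.array([[1.0, 2.0, 3.0]]))
        assert np.all(generalized_shift(g).orders == 0.0)

    def test_shifts_levels_down(self):
        g = GeneralizedState(orders=np.array([[1.0, 2], [3, 4], [5, 6]]))
        out = generalized_shift(g)
        np.testing.assert_array_equal(out.orders, [[3, 4], [5, 6], [0, 0]])

    def test_nilpotent_after_order_count_applications(self):
        g = GeneralizedState(orders=np.arange(12.0).reshape(4, 3))
        for _ in range(g.order_count):
            g = generalized_shift(g)
        assert np.all(g.orders == 0.0)


class TestFreeEnergy:
    def test_zero_at_prior_mean_with_matched_sensation(self, tiny_morph, rng):
        prec = make_prec(tiny_morph)
        n, S, C = 3, 3, 4
        internal = np.zeros((n, 3, S))
        active = np.zeros((n, 3, 2 + C))
        ens = CellEnsembleState(
            internal=internal, active=active,
            sc=np.zeros((n, C)), sx=np.zeros((n, 2)), s_lambda=np.zeros((n, C)),
        )
        # overwrite sensations with the model's own predictions
        from morphoinfer.model_core import predict

        for i in range(n):
            g = predict(internal[i, 0], tiny_morph)
            ens.sc[i], ens.sx[i], ens.s_lambda[i] = g.sc, g.sx, g.s_lambda
        assert free_energy(ens, tiny_morph, prec) < 1e-20

    def test_sensory_term_scales_with_precision(self, tiny_morph, rng):
        ens = random_ensemble(tiny_morph, rng)
        base = make_prec(tiny_morph, pi2=np.full(3, 1e-300))
        doubled = make_prec(
            tiny_morph,
            pi1_c=base.pi1_c * 2,
            pi1_x=base.pi1_x * 2,
            pi1_lambda=base.pi1_lambda * 2,
            pi2=np.full(3, 1e-300),
        )
        np.testing.assert_allclose(
            free_energy(ens, tiny_morph, doubled),
            2 * free_energy(ens, tiny_morph, base),
            rtol=1e-12,
        )

    def test_matches_independent_quadratic_form(self, tiny_morph, rng):
        ens = random_ensemble(tiny_morph, rng)
        prec = make_prec(tiny_morph)
        from morphoinfer.model_core import prediction_error

        total = 0.0
        for i in range(3):
            eps = prediction_error(ens.sensory_triple(i), ens.beliefs[i], tiny_morph)
            total += 0.5 * (
                prec.pi1_c[i] * np.sum(eps.sc**2)
                + prec.pi1_x[i] * np.sum(eps.sx**2)
                + prec.pi1_lambda[i] * np.sum(eps.s_lambda**2)
                + prec.pi2[i] * np.sum(ens.beliefs[i] ** 2)
            )
        np.testing.assert_allclose(
            free_energy(ens, tiny_morph, prec), total, rtol=1e-12
        )


class TestFlow:
    def test_matches_negative_fd_gradient_plus_shift(self, tiny_morph, rng):
        prec = make_prec(tiny_morph)
        for _ in range(10):
            ens = random_ensemble(tiny_morph, rng)
            gains = rng.uniform(0.5, 1.5, 3)
            ens = sense(ens, tiny_morph, gains)  # stored sensations must
            # reflect the same gains the flow assumes
            dI, dA = flow(ens, tiny_morph, prec, gains)
            gI, gA = finite_difference_gradients(ens, tiny_morph, prec, gains)
            expI = _shift_orders(ens.internal, axis=1)
            expA = _shift_orders(ens.active, axis=1)
            expI[:, 0, :] -= gI
            expA[:, 0, :] -= gA
            scale = 1 + max(np.abs(expI).max(), np.abs(expA).max())
            assert np.abs(dI - expI).max() / scale < 1e-5
            assert np.abs(dA - expA).max() / scale < 1e-5

    def test_fixed_point_has_zero_flow(self, single_slot_morph):
        m = single_slot_morph
        prec = make_prec(m)
        internal = np.zeros((1, 3, 1))
        active = np.zeros((1, 3, 2 + m.n_channels))
        # cell at the slot, secreting the slot profile
        active[0, 0, :2] = m.ex_star[:, 0]
        active[0, 0, 2:] = m.ec_star[:, 0]
        ens = CellEnsembleState(
            internal=internal, active=active,
            sc=np.zeros((1, m.n_channels)), sx=np.zeros((1, 2)),
            s_lambda=np.zeros((1, m.n_channels)),
        )
        ens = sense(ens, m)
        dI, dA = flow(ens, m, prec)
        assert np.abs(dI).max() < 1e-12
        assert np.abs(dA).max() < 1e-12

    def test_negligible_sensory_precision_leaves_prior_decay(self, tiny_morph, rng):
        tiny = 1e-300
        prec = make_prec(
            tiny_morph,
            pi1_c=np.full(3, tiny),
            pi1_x=np.full(3, tiny),
            pi1_lambda=np.full(3, tiny),
        )
        ens = random_ensemble(tiny_morph, rng)
        dI, _ = flow(ens, tiny_morph, prec)
        expected = _shift_orders(ens.internal, axis=1)
        expected[:, 0, :] -= prec.pi2[:, None] * ens.beliefs
        np.testing.assert_allclose(dI, expected, rtol=1e-10, atol=1e-12)


class TestGenerateNoise:
    def test_zero_sd_gives_zeros(self):
        assert np.all(generate_noise(NoiseParams(sd=0.0), 100, 3) == 0)

    def test_white_noise_unit_variance(self):
        w = generate_noise(NoiseParams(sd=1.0, smoothness=0.0, seed=7), 10_000, 2)
        assert abs(w.var() - 1.0) < 0.05

    def test_smoothed_noise_is_correlated_with_right_sd(self):
        w = generate_noise(NoiseParams(sd=1.0, smoothness=2.0, seed=7), 20_000, 1)
        x = w[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 > 0.5
        assert abs(x.std() - 1.0) < 0.1

    def test_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            NoiseParams(sd=-0.1)


class TestIntegrateStep:
    def test_stationary_at_fixed_point(self, single_slot_morph):
        m = single_slot_morph
        prec = make_prec(m)
        internal = np.zeros((1, 3, 1))
        active = np.zeros((1, 3, 2 + m.n_channels))
        active[0, 0, :2] = m.ex_star[:, 0]
        active[0, 0, 2:] = m.ec_star[:, 0]
        ens = CellEnsembleState(
            internal=internal, active=active,
            sc=np.zeros((1, 4)), sx=np.zeros((1, 2)), s_lambda=np.zeros((1, 4)),
        )
        ens = sense(ens, m)
        out = integrate_step(ens, 0.1, None, m, prec)
        assert np.abs(out.internal - ens.internal).max() < 1e-10
        assert np.abs(out.active - ens.active).max() < 1e-10

    def test_small_step_decreases_free_energy(self, tiny_morph, rng):
        prec = make_prec(tiny_morph)
        ens = random_ensemble(tiny_morph, rng, spread=0.01)
        f0 = free_energy(ens, tiny_morph, prec)
        out = integrate_step(ens, 1e-3, None, tiny_morph, prec)
        assert free_energy(out, tiny_morph, prec) < f0

    def test_first_order_convergence_richardson(self, tiny_morph, rng):
        prec = make_prec(tiny_morph)
        ens = random_ensemble(tiny_morph, rng, spread=0.1)
        def halving_gap(dt):
            one = integrate_step(ens, dt, None, tiny_morph, prec)
            halfa = integrate_step(ens, dt / 2, None, tiny_morph, prec)
            half = integrate_step(halfa, dt / 2, None, tiny_morph, prec)
            return max(
                np.abs(one.internal - half.internal).max(),
                np.abs(one.active - half.active).max(),
            )

        # explicit Euler: the one-step vs two-half-steps gap is O(dt^2),
        # so halving dt shrinks it about fourfold
        g1 = halving_gap(1e-2)
        g2 = halving_gap(5e-3)
        assert 2.5 < g1 / g2 < 6.0

    def test_divergence_raises_with_context(self, tiny_morph, rng):
        prec = make_prec(tiny_morph)
        ens = random_ensemble(tiny_morph, rng)
        ens.internal[1, 0, :] = 1e7
        with pytest.raises(SimulationDivergenceError, match="cell"):
            integrate_step(ens, 0.1, None, tiny_morph, prec, divergence_bound=1e6)


class TestSimulate:
    def test_horizon_zero_returns_initial_state_only(self, morph):
        prec = make_prec(morph)
        traj = simulate(morph, prec, RunConfig(horizon=0, seed=3))
        assert len(traj) == 1

    def test_trajectory_length_and_free_energy_descent(self, morph):
        prec = make_prec(morph)
        traj = simulate(morph, prec, RunConfig(horizon=32, substeps=32, seed=0))
        assert len(traj) == 33
        assert traj.free_energy[-1] < traj.free_energy[0]

    def test_same_seed_bit_identical(self, morph):
        prec = make_prec(morph)
        run = RunConfig(horizon=4, substeps=32, seed=11)
        a = simulate(morph, prec, run)
        bt = simulate(morph, prec, run)
        for sa, sb in zip(a.snapshots, bt.snapshots):
            np.testing.assert_array_equal(sa.internal, sb.internal)
            np.testing.assert_array_equal(sa.active, sb.active)
            np.testing.assert_array_equal(sa.s_lambda, sb.s_lambda)

    def test_zero_noise_stationary_from_fixed_point(self, single_slot_morph):
        # at the single-slot fixed point the simulated collective stays put
        m = single_slot_morph
        prec = make_prec(m)
        run = RunConfig(
            horizon=16, substeps=32, seed=0,
            noise=NoiseParams(sd=0.0),
            init_position_sd=0.0, init_internal_sd=0.0,
        )
        traj = simulate(m, prec, run)
        # initial ensemble places the cell at the centroid (= the slot)
        # with zero secretion; relax secretion first then require
        # stationarity of the relaxed tail
        drift = np.abs(
            traj.snapshots[-1].positions - traj.snapshots[-2].positions
        ).max()
        assert drift < 1e-10

    def test_kernel_matches_reference_integrator(self, tiny_morph):
        prec = make_prec(tiny_morph)
        run = RunConfig(
            horizon=1, substeps=8, seed=5, noise=NoiseParams(sd=0.0)
        )
        traj = simulate(tiny_morph, prec, run)
        rng = np.random.default_rng(5)
        ens = initial_ensemble(tiny_morph, run, rng)
        for _ in range(8):
            ens = integrate_step(ens, 1 / 8, None, tiny_morph, prec)
        np.testing.assert_allclose(
            traj.final.beliefs, ens.beliefs, rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(
            traj.final.positions, ens.positions, rtol=1e-12, atol=1e-12
        )

    def test_long_format_export_round_trips(self, tiny_morph):
        prec = make_prec(tiny_morph)
        traj = simulate(tiny_morph, prec, RunConfig(horizon=2, substeps=8, seed=1))
        df = traj.to_long_frame()
        assert set(df.columns) == {"step", "cell", "block", "component", "value"}
        assert df["step"].nunique() == 3
        pos = df[(df.block == "position") & (df.step == 2)].pivot(
            index="cell", columns="component", values="value"
        )
        np.testing.assert_allclose(pos.to_numpy(), traj.final.positions)
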
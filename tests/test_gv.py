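"""Conductance extraction, Boltzmann fitting, shifts and group comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kvshift as kv
from kvshift.gv import boltzmann


def make_family(protocol, currents):
    return kv.CurrentTraceFamily(protocol, protocol.time_grid, currents)


class TestSteadyStateCurrent:
    def test_constant_sweep_returns_its_value(self, protocol):
        n_t = protocol.time_grid.size
        fam = make_family(protocol, np.full((14, n_t), 3.0))
        for _, i_ss in kv.steady_state_current(fam):
            assert i_ss == pytest.approx(3.0)

    def test_linear_ramp_gives_window_mean(self, protocol):
        # independent oracle: arithmetic mean of the ramp over window samples
        t = protocol.time_grid
        ramp = np.tile(0.02 * t, (14, 1))
        fam = make_family(protocol, ramp)
        window = t >= protocol.sweep_duration - protocol.steady_state_window
        expected = (0.02 * t[window]).mean()
        for _, i_ss in kv.steady_state_current(fam):
            assert i_ss == pytest.approx(expected, abs=1e-12)

    def test_window_outside_recording_rejected(self, protocol):
        n_t = protocol.time_grid.size
        fam = make_family(protocol, np.zeros((14, n_t)))
        fam.time_grid = fam.time_grid[: n_t // 4]
        fam.currents = fam.currents[:, : n_t // 4]
        with pytest.raises(ValueError, match="steady-state window"):
            kv.steady_state_current(fam)


class TestComputeConductance:
    @pytest.mark.parametrize(
        "v, i, vk, expected",
        [
            (-40.0, 0.0, -80.0, 0.0),
            (-40.0, 2.0, -80.0, 0.05),
            (0.0, 1.0, -80.0, 0.0125),
        ],
    )
    def test_ohmic_division(self, v, i, vk, expected):
        curve = kv.compute_conductance([(v, i)], vk)
        assert curve.conductance[0] == pytest.approx(expected)

    def test_points_at_reversal_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="reversal"):
            curve = kv.compute_conductance([(-80.0, 0.1), (-40.0, 2.0)], -80.0)
        assert curve.voltages.tolist() == [-40.0]

    def test_linear_in_current(self):
        pts = [(-40.0, 2.0), (0.0, 4.0), (40.0, 5.0)]
        scaled = [(v, 3.0 * i) for v, i in pts]
        g1 = kv.compute_conductance(pts, -80.0).conductance
        g2 = kv.compute_conductance(scaled, -80.0).conductance
        np.testing.assert_allclose(g2, 3.0 * g1)


class TestFitBoltzmann:
    def test_noiseless_round_trip(self):
        v = np.arange(-80.0, 51.0, 10.0)
        curve = kv.GVCurve(v, boltzmann(v, 1.0, -30.0, 10.0))
        fit = kv.fit_boltzmann(curve)
        assert fit.converged
        assert fit.G_MAX == pytest.approx(1.0, abs=1e-6)
        assert fit.V_half == pytest.approx(-30.0, abs=1e-6)
        assert fit.slope == pytest.approx(10.0, abs=1e-6)

    def test_midpoint_is_half_max(self):
        v = np.arange(-80.0, 51.0, 10.0)
        rng = np.random.default_rng(3)
        curve = kv.GVCurve(v, boltzmann(v, 2.0, -25.0, 8.0) + rng.normal(0, 0.02, v.size))
        fit = kv.fit_boltzmann(curve)
        assert fit.predict(fit.V_half) == pytest.approx(fit.G_MAX / 2.0, rel=1e-12)

    def test_grid_search_oracle_agrees(self):
        # brute-force lattice over (G_MAX, V_half, s) against the NLS optimum
        rng = np.random.default_rng(7)
        v = np.linspace(-70, 30, 9)
        g = boltzmann(v, 1.0, -30.0, 10.0) + rng.normal(0, 0.01, v.size)
        curve = kv.GVCurve(v, g)
        fit = kv.fit_boltzmann(curve)
        gm_grid = np.linspace(0.9, 1.1, 21)
        vh_grid = np.linspace(-35, -25, 41)
        s_grid = np.linspace(8, 12, 21)
        best, best_sse = None, np.inf
        for gm, vh, s in itertools.product(gm_grid, vh_grid, s_grid):
            sse = float(((g - boltzmann(v, gm, vh, s)) ** 2).sum())
            if sse < best_sse:
                best, best_sse = (gm, vh, s), sse
        assert fit.G_MAX == pytest.approx(best[0], abs=(gm_grid[1] - gm_grid[0]))
        assert fit.V_half == pytest.approx(best[1], abs=(vh_grid[1] - vh_grid[0]))
        assert fit.slope == pytest.approx(best[2], abs=(s_grid[1] - s_grid[0]))
        assert fit.residual_sum_of_squares <= best_sse + 1e-12

    def test_flat_curve_rejected(self):
        v = np.linspace(-60, 40, 6)
        with pytest.raises(ValueError, match="flat"):
            kv.fit_boltzmann(kv.GVCurve(v, np.ones_like(v)))

    def test_too_few_voltages_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            kv.fit_boltzmann(kv.GVCurve(np.array([-40.0, 0.0, 40.0]), np.array([0.1, 0.5, 0.9])))


class TestPipelineRecovery:
    def test_noiseless_generator_round_trip(self, protocol, noiseless_truth):
        """gen -> steady state -> conductance -> Boltzmann recovers the truth."""
        fam = kv.gen_current_family(protocol, noiseless_truth)
        with pytest.warns(UserWarning):
            curve = kv.compute_conductance(
                kv.steady_state_current(fam), protocol.reversal_potential
            )
        fit = kv.fit_boltzmann(curve)
        assert fit.V_half == pytest.approx(noiseless_truth.control_V_half, abs=0.1)
        assert abs(fit.G_MAX - noiseless_truth.control_G_MAX) < 0.01 * noiseless_truth.control_G_MAX
        assert abs(fit.slope - noiseless_truth.control_slope) < 0.01 * noiseless_truth.control_slope

    def test_rmse_shrinks_with_noise(self, protocol):
        def vhalf_rmse(noise_sd, reps=20):
            errs = []
            for rep in range(reps):
                truth = kv.GroundTruth(noise_sd=noise_sd, seed=100 + rep)
                fam = kv.gen_current_family(protocol, truth)
                with pytest.warns(UserWarning):
                    curve = kv.compute_conductance(
                        kv.steady_state_current(fam), protocol.reversal_potential
                    )
                errs.append(kv.fit_boltzmann(curve).V_half - truth.control_V_half)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert vhalf_rmse(1.0) < vhalf_rmse(10.0)


class TestGVShift:
    def test_identical_fits_zero_shift(self):
        fit = kv.BoltzmannFit(1.0, -30.0, 10.0)
        assert kv.gv_shift(fit, fit) == 0.0

    def test_sign_convention_matches_reported_example(self):
        control = kv.BoltzmannFit(1.0, -20.0, 10.0)
        compound = kv.BoltzmannFit(1.0, -60.7, 10.0)
        assert kv.gv_shift(control, compound) == pytest.approx(-40.7)

    def test_antisymmetric(self):
        a = kv.BoltzmannFit(1.0, -20.0, 10.0)
        b = kv.BoltzmannFit(1.0, -45.0, 10.0)
        assert kv.gv_shift(a, b) == -kv.gv_shift(b, a)

    def test_unconverged_input_rejected(self):
        good = kv.BoltzmannFit(1.0, -20.0, 10.0)
        bad = kv.BoltzmannFit(1.0, -20.0, 10.0, converged=False)
        with pytest.raises(ValueError, match="converge"):
            kv.gv_shift(good, bad)

    @settings(deadline=None, max_examples=25)
    @given(delta=st.floats(-50, 50, allow_nan=False))
    def test_translation_equivariance(self, delta):
        """Shifting every voltage of both datasets leaves the shift unchanged."""
        v = np.arange(-80.0, 51.0, 10.0)
        base = kv.fit_boltzmann(kv.GVCurve(v, boltzmann(v, 1.0, -30.0, 10.0)))
        comp = kv.fit_boltzmann(kv.GVCurve(v, boltzmann(v, 1.0, -45.0, 10.0)))
        moved_base = kv.fit_boltzmann(
            kv.GVCurve(v + delta, boltzmann(v, 1.0, -30.0, 10.0))
        )
        moved_comp = kv.fit_boltzmann(
            kv.GVCurve(v + delta, boltzmann(v, 1.0, -45.0, 10.0))
        )
        assert kv.gv_shift(moved_base, moved_comp) == pytest.approx(
            kv.gv_shift(base, comp), abs=1e-4
        )


class TestGmaxRatio:
    def test_equal_and_doubled(self):
        a = kv.BoltzmannFit(1.0, -30.0, 10.0)
        b = kv.BoltzmannFit(2.0, -30.0, 10.0)
        assert kv.gmax_ratio(a, a) == pytest.approx(1.0)
        assert kv.gmax_ratio(a, b) == pytest.approx(2.0)

    def test_ratio_maps_to_percent_reduction(self):
        # a ratio of 0.17 is an 83% reduction in maximal conductance
        control = kv.BoltzmannFit(1.0, -30.0, 10.0)
        compound = kv.BoltzmannFit(0.17, -30.0, 10.0)
        ratio = kv.gmax_ratio(control, compound)
        assert 100.0 * (1.0 - ratio) == pytest.approx(83.0)

    def test_nonpositive_control_rejected(self):
        bad = kv.BoltzmannFit(0.0, -30.0, 10.0)
        ok = kv.BoltzmannFit(1.0, -30.0, 10.0)
        with pytest.raises(ValueError, match="positive"):
            kv.gmax_ratio(bad, ok)


class TestCompareShifts:
    def test_identical_groups_t_zero_p_one(self):
        g = [-25.0, -26.0, -24.0, -25.5]
        t, p = kv.compare_shifts(g, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_welch_t(self):
        a = np.array([-25.5, -24.0, -27.0, -26.5])
        b = np.array([-40.0, -38.5, -42.0])
        t, _ = kv.compare_shifts(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert t == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_permutation_oracle_decision(self):
        # exhaustive label-permutation test on small, clearly separated groups
        import itertools as it

        a = [-25.5, -24.9, -26.1, -25.2]
        b = [-49.6, -48.8, -50.2, -49.1]
        pooled = np.array(a + b)
        obs = abs(np.mean(a) - np.mean(b))
        count = total = 0
        for idx in it.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += stat >= obs - 1e-12
            total += 1
        perm_p = count / total
        _, p = kv.compare_shifts(a, b)
        assert (p < 0.05) == (perm_p < 0.05)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            kv.compare_shifts([-25.0], [-40.0, -41.0])
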
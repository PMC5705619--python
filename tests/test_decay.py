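import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from terradose import (
    K40,
    TH232,
    U238,
    Radionuclide,
    approximation_error,
    build_interpolant,
    decay_approx,
    decay_exact,
    simulate_table,
)


class TestExactDecay:
    def test_half_life_definition(self):
        assert decay_exact(10.0, U238, 4e9) == pytest.approx(5.0)

    def test_t_zero_identity(self):
        assert decay_exact(8.65, K40, 0.0) == 8.65

    def test_century_decay_is_insignificant(self):
        a = decay_exact(8.65, U238, 100.0)
        assert 1.0 - a / 8.65 == pytest.approx(1.733e-8, rel=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_exact(1.0, U238, -1.0)

    def test_decay_constant_identity(self):
        for nuc in (U238, TH232, K40):
            assert nuc.decay_constant * nuc.half_life == pytest.approx(math.log(2))

    @given(
        t1=st.floats(0.0, 1e10),
        t2=st.floats(0.0, 1e10),
        a0=st.floats(0.01, 1e3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_semigroup_property(self, t1, t2, a0):
        stepwise = decay_exact(decay_exact(a0, K40, t1), K40, t2)
        direct = decay_exact(a0, K40, t1 + t2)
        assert stepwise == pytest.approx(direct, rel=1e-12)


class TestInterpolant:
    def test_power_coefficients_round_to_published(self):
        interp = build_interpolant()
        e, d, c, b, a = interp.power_coeffs
        assert round(a, 4) == 0.0067
        assert round(b, 4) == -0.0820
        assert round(c, 4) == 0.3993
        assert round(d, 4) == -0.9560
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_full_precision_leading_coefficient(self):
        # brute-force forward-difference table from e^0 ... e^-4
        y = [math.exp(-z) for z in range(5)]
        d4 = y[4] - 4 * y[3] + 6 * y[2] - 4 * y[1] + y[0]
        interp = build_interpolant()
        assert interp.power_coeffs[4] == pytest.approx(d4 / 24.0, rel=1e-12)
        assert d4 / 24.0 == pytest.approx(0.0066526, abs=5e-8)

    def test_exact_at_nodes(self):
        interp = build_interpolant()
        for z, y in zip(interp.nodes, interp.node_values):
            assert abs(interp(z) - y) < 1e-12
            assert abs(interp.evaluate_power(z) - y) < 1e-12

    def test_newton_and_power_forms_agree(self):
        interp = build_interpolant()
        z = np.linspace(0, 4, 1001)
        assert np.max(np.abs(interp(z) - interp.evaluate_power(z))) < 1e-9

    def test_unequal_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_interpolant([0.0, 1.0, 2.5, 3.0, 4.0])
        with pytest.raises(ValueError):
            build_interpolant([0.0, 1.0, 2.0, 3.0])


class TestApproxDecay:
    def test_t_zero_exact(self):
        assert decay_approx(8.65, U238, 0.0) == pytest.approx(8.65, rel=1e-12)

    def test_node_exactness_at_z_one(self):
        t = 1.0 / U238.decay_constant
        a = decay_approx(1.0, U238, t)
        assert abs(a - math.exp(-1.0)) < 1e-12

    def test_midpoint_value(self):
        interp = build_interpolant()
        assert interp(0.5) == pytest.approx(0.61197, abs=5e-6)
        assert interp(0.5) - math.exp(-0.5) == pytest.approx(0.00544, abs=5e-5)

    def test_extrapolation_refused_then_allowed(self):
        t = 5.0 / K40.decay_constant
        with pytest.raises(ValueError, match="span"):
            decay_approx(1.0, K40, t)
        assert decay_approx(1.0, K40, t, allow_extrapolation=True) > math.exp(-5.0)

    def test_low_z_bias_matches_linear_coefficient(self):
        interp = build_interpolant()
        z = 1e-4
        rel = abs(interp(z) - math.exp(-z)) / math.exp(-z)
        assert rel == pytest.approx(abs(interp.power_coeffs[1] + 1.0) * z, rel=1e-3)


class TestApproximationError:
    def test_default_interpolant_bound(self):
        err = approximation_error()
        assert err < 0.05
        assert err == pytest.approx(0.0062, abs=5e-4)

    def test_zero_at_nodes(self):
        interp = build_interpolant()
        for z in interp.nodes:
            assert abs(interp(z) - math.exp(-z)) < 1e-12

    def test_degree_exactness_on_quartic(self):
        # interpolating a quartic through 5 points reproduces it everywhere
        interp = build_interpolant()
        z = np.linspace(0, 4, 501)
        quartic = interp.evaluate_power(z)
        assert np.max(np.abs(interp(z) - quartic)) < 1e-9

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            approximation_error(grid_size=10)


class TestSimulateTable:
    INITIAL = {"U-238": 8.65, "Th-232": 12.5, "K-40": 214.0}

    def test_century_curves_flat(self):
        curves = simulate_table(self.INITIAL, horizon=100.0, n_points=11)
        for c in curves:
            rel_drop = 1.0 - c.exact_activity[-1] / c.initial_activity
            assert rel_drop < 1e-7

    def test_five_half_lives(self):
        nuc = Radionuclide("X", 2.0)
        curves = simulate_table({"X": 32.0}, [nuc], horizon=10.0, n_points=2)
        assert curves[0].exact_activity[-1] == pytest.approx(1.0)

    def test_k40_decays_fastest(self):
        curves = simulate_table(self.INITIAL, horizon=1e9, n_points=3)
        frac = {
            c.radionuclide.name: c.exact_activity[-1] / c.initial_activity
            for c in curves
        }
        assert frac["K-40"] < frac["U-238"] < frac["Th-232"]

    def test_frame_columns(self):
        (c, *_) = simulate_table(self.INITIAL, horizon=10.0, n_points=3)
        f = c.to_frame()
        assert list(f.columns) == [
            "nuclide", "time_y", "activity_exact", "activity_approx",
        ]
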
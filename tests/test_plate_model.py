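"""Unit and property tests for the plate-theory equations and domain types."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platesim import (
    ColumnSpec,
    FlowSpec,
    SeparationMethod,
    Solute,
    TimeGrid,
    concentration_exact,
    concentration_stirling,
    dead_time,
    k_from_solubilities,
    log_factorial_stirling,
    reduced_volume,
    retention_factor,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_column_from_dead_volume_round_trip(self):
        flow = FlowSpec(flow_mL_per_min=2.0)
        col = ColumnSpec.from_dead_volume(100, dead_volume_mL=6.0,
                                          phase_ratio=2.0, flow=flow)
        assert col.dead_time_min == pytest.approx(3.0, rel=1e-12)
        assert col.dead_volume_mL(flow) == pytest.approx(6.0, rel=1e-12)

    def test_per_plate_volumes_derive_from_dead_volume_and_phase_ratio(self):
        flow = FlowSpec(flow_mL_per_min=1.0)
        col = ColumnSpec(n_plates=100, dead_time_min=3.0, phase_ratio=2.0)
        assert col.plate_mobile_volume_mL(flow) == pytest.approx(0.03)
        assert col.plate_stationary_volume_mL(flow) == pytest.approx(0.015)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_plates=0, dead_time_min=3.0, phase_ratio=2.0),
            dict(n_plates=100, dead_time_min=0.0, phase_ratio=2.0),
            dict(n_plates=100, dead_time_min=3.0, phase_ratio=-1.0),
        ],
    )
    def test_invalid_column_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ColumnSpec(**kwargs)

    def test_solute_solubility_consistency_enforced(self):
        Solute(name="A", K=3.0, C0=1.0,
               solubility_stationary_g_per_L=0.6,
               solubility_mobile_g_per_L=0.2)
        with pytest.raises(ValueError, match="inconsistent"):
            Solute(name="A", K=2.0, C0=1.0,
                   solubility_stationary_g_per_L=0.6,
                   solubility_mobile_g_per_L=0.2)

    def test_unretained_solute_allowed_negative_K_rejected(self):
        assert Solute(name="U", K=0.0, C0=1.0).K == 0.0
        with pytest.raises(ValueError):
            Solute(name="X", K=-0.1, C0=1.0)

    def test_time_grid_uniform_spacing(self):
        g = TimeGrid(0.0, 10.0, 5)
        t = g.times()
        assert np.allclose(np.diff(t), g.spacing_min)
        assert g.spacing_min == pytest.approx(2.5)
        with pytest.raises(ValueError):
            TimeGrid(5.0, 5.0, 10)


# ---------------------------------------------------------------------------
# reduced volume
# ---------------------------------------------------------------------------


class TestReducedVolume:
    def test_worked_case_peak_coordinate(self, case1_method):
        # at the K=3 retention time 7.5 min the band sits at v = n = 100
        assert reduced_volume(7.5, case1_method, K=3.0) == pytest.approx(100.0)

    def test_zero_time_gives_zero(self, case1_method):
        assert reduced_volume(0.0, case1_method, K=5.0) == 0.0

    def test_unretained_solute_reaches_n_at_dead_time(self, case1_method):
        tm = case1_method.column.dead_time_min
        n = case1_method.column.n_plates
        assert reduced_volume(tm, case1_method, K=0.0) == pytest.approx(n)

    def test_negative_time_rejected(self, case1_method):
        with pytest.raises(ValueError):
            reduced_volume(-1.0, case1_method, K=1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.floats(0.01, 100.0),
        a=st.floats(0.1, 10.0),
        K=st.floats(0.0, 20.0),
    )
    def test_linear_in_time(self, t, a, K):
        method = SeparationMethod(
            column=ColumnSpec(50, 2.0, 1.5), flow=FlowSpec(1.0)
        )
        v1 = reduced_volume(t, method, K)
        v2 = reduced_volume(a * t, method, K)
        assert v2 == pytest.approx(a * v1, rel=1e-9)

    def test_strictly_decreasing_in_K(self, case1_method):
        vs = [reduced_volume(5.0, case1_method, K) for K in (0.0, 1.0, 3.0, 9.0)]
        assert all(a > b for a, b in zip(vs, vs[1:]))


# ---------------------------------------------------------------------------
# Stirling log-factorial
# ---------------------------------------------------------------------------


class TestLogFactorialStirling:
    def test_closed_form_at_one(self):
        assert log_factorial_stirling(1) == pytest.approx(
            0.5 * math.log(2 * math.pi) - 1.0
        )

    @pytest.mark.parametrize("n,tol", [(10, 0.01), (100, 0.001)])
    def test_relative_error_vs_exact_factorial(self, n, tol):
        # oracle: exact log-factorial as a sum of logs
        exact_log = sum(math.log(k) for k in range(1, n + 1))
        rel_err = abs(math.exp(log_factorial_stirling(n) - exact_log) - 1.0)
        assert rel_err < tol

    def test_error_shrinks_monotonically(self):
        errs = []
        for n in (5, 10, 20, 50, 100):
            exact_log = sum(math.log(k) for k in range(1, n + 1))
            errs.append(abs(math.exp(log_factorial_stirling(n) - exact_log) - 1.0))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            log_factorial_stirling(0)


# ---------------------------------------------------------------------------
# concentration models
# ---------------------------------------------------------------------------


class TestConcentrationExact:
    def test_single_plate_closed_form(self):
        # n=1, K=0, C0=1: C(v) = e^-v * v, so C(1) = e^-1
        assert concentration_exact(1.0, 1, 0.0, 1.0) == pytest.approx(
            math.exp(-1.0)
        )

    def test_zero_volume_gives_zero(self):
        for n in (1, 10, 1000):
            assert concentration_exact(0.0, n, 2.0, 1.0) == 0.0

    def test_argmax_at_v_equals_n(self):
        # oracle: brute-force scan of the band over a fine v grid
        v = np.linspace(0.0, 300.0, 30001)
        c = concentration_exact(v, 100, 3.0, 1.0)
        assert v[np.argmax(c)] == pytest.approx(100.0, abs=0.02)

    def test_matches_naive_formula_at_small_n(self):
        # log-space evaluation must agree with the literal formula where
        # integer factorials are representable
        rng = np.random.default_rng(7)
        for n in (1, 3, 7, 12, 20):
            vs = rng.uniform(0.0, 5.0 * n, size=20)
            naive = (
                1.0 / (1.0 + 2.0) * np.exp(-vs) * vs**n / math.factorial(n)
            )
            ours = concentration_exact(vs, n, 2.0, 1.0)
            assert np.allclose(ours, naive, rtol=1e-10)

    def test_no_overflow_at_huge_plate_count(self):
        n = 100_000
        c = concentration_exact(float(n), n, 0.0, 1.0)
        assert np.isfinite(c) and c > 0

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            concentration_exact(-0.5, 10, 0.0, 1.0)


class TestConcentrationStirling:
    def test_agrees_with_exact_near_peak(self):
        v = np.linspace(60.0, 140.0, 401)
        ex = concentration_exact(v, 100, 3.0, 1.0)
        stl = concentration_stirling(v, 100, 3.0, 1.0)
        assert np.max(np.abs(stl - ex) / ex) < 0.001

    def test_zero_volume_gives_zero(self):
        assert concentration_stirling(0.0, 50, 1.0, 2.0) == 0.0

    def test_convergence_to_exact_is_monotone_in_n(self):
        # relative error within +-4 sqrt(n) of the peak shrinks with n
        errs = []
        for n in (20, 50, 100, 500, 1000):
            half = 4.0 * math.sqrt(n)
            v = np.linspace(n - half, n + half, 801)
            ex = concentration_exact(v, n, 0.0, 1.0)
            stl = concentration_stirling(v, n, 0.0, 1.0)
            errs.append(float(np.max(np.abs(stl - ex) / ex)))
        assert all(a >= b for a, b in zip(errs, errs[1:]))
        assert errs[2] < 0.01  # under 1% from n=100 on

    def test_small_n_warns_but_computes(self):
        with pytest.warns(UserWarning, match="n > 10"):
            c = concentration_stirling(5.0, 5, 0.0, 1.0)
        assert c > 0

    @settings(derandomize=True, max_examples=40)
    @given(
        v=st.floats(1.0, 400.0),
        c0=st.floats(0.1, 10.0),
        scale=st.floats(0.5, 5.0),
    )
    def test_homogeneous_in_injected_concentration(self, v, c0, scale):
        base = concentration_stirling(v, 100, 2.0, c0)
        scaled = concentration_stirling(v, 100, 2.0, scale * c0)
        assert scaled == pytest.approx(scale * base, rel=1e-10)

    def test_monotone_suppression_in_K(self):
        cs = [concentration_exact(100.0, 100, K, 1.0) for K in (0.0, 1.0, 3.0, 9.0)]
        assert all(a > b for a, b in zip(cs, cs[1:]))


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------


class TestScalarHelpers:
    @pytest.mark.parametrize(
        "cs,cm,expected", [(0.6, 0.2, 3.0), (0.5, 0.5, 1.0), (0.2, 0.6, 1 / 3)]
    )
    def test_partition_coefficient_from_solubilities(self, cs, cm, expected):
        assert k_from_solubilities(cs, cm) == pytest.approx(expected)

    def test_non_positive_solubility_rejected(self):
        with pytest.raises(ValueError):
            k_from_solubilities(0.0, 0.2)
        with pytest.raises(ValueError):
            k_from_solubilities(0.6, -0.2)

    @pytest.mark.parametrize("vm,f,expected", [(3.0, 1.0, 3.0), (6.0, 2.0, 3.0)])
    def test_dead_time_from_dead_volume(self, vm, f, expected):
        assert dead_time(vm, FlowSpec(f)) == pytest.approx(expected)

    def test_dead_time_rejects_non_positive_volume(self):
        with pytest.raises(ValueError):
            dead_time(0.0, FlowSpec(1.0))

    @pytest.mark.parametrize(
        "K,beta,expected", [(3.0, 2.0, 1.5), (0.0, 2.0, 0.0), (9.0, 2.0, 4.5)]
    )
    def test_retention_factor(self, K, beta, expected):
        assert retention_factor(K, beta) == pytest.approx(expected)

    def test_retention_factor_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            retention_factor(3.0, 0.0)
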
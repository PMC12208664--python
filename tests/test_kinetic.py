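"""Unit and property tests for the kinetic core (steady state, indices, dynamics)."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6adyn import (
    CompartmentState,
    DegenerateStateError,
    ModelVariant,
    NoSteadyStateError,
    ParameterError,
    RateSet,
    apply_variant,
    derive_indices,
    simulate_dynamics,
    steady_state,
)

positive_rate = st.floats(0.05, 20.0, allow_nan=False)


def random_rateset(rng):
    a1, a2, b, g = rng.gamma(1.0, 1.0, 4) + 0.02
    return RateSet.baseline(a1, a2, b, g, S=10.0)


class TestSteadyState:
    def test_printed_closed_forms(self):
        ss = steady_state(RateSet(1, 1, 1, 1, 1, 10))
        assert (ss.nuc_A, ss.nuc_m6A, ss.cyt_A) == (1.0, 1.0, 1.0)
        assert ss.cyt_m6A == pytest.approx(0.1)

    def test_nuclear_decay_reduces_nuclear_pool(self):
        # Nuc = alpha/(beta+delta); Cyt = beta*Nuc/gamma
        ss = steady_state(RateSet(1, 0, 1, 1, 1, 1, delta=1))
        assert ss.nuc_A == pytest.approx(0.5)
        assert ss.cyt_A == pytest.approx(0.5)

    def test_no_methylated_production_empties_species(self):
        ss = steady_state(RateSet(1, 0, 1, 1, 1, 10))
        assert ss.nuc_m6A == 0 and ss.cyt_m6A == 0
        assert derive_indices(ss).m6a_level == 0

    def test_zero_export_without_nuclear_decay_has_no_steady_state(self):
        with pytest.raises(NoSteadyStateError):
            steady_state(RateSet(1, 1, 0, 0, 1, 10))

    def test_zero_export_with_nuclear_decay_is_fine(self):
        ss = steady_state(RateSet(1, 0, 0, 0, 1, 1, delta=2))
        assert ss.nuc_A == pytest.approx(0.5)
        assert ss.cyt_A == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            RateSet(1, 1, -1, 1, 1, 10)

    def test_matches_long_time_dynamics_on_random_rates(self, rng):
        # the analytic fixed point is the t->inf limit of the transient
        for _ in range(100):
            r = random_rateset(rng)
            ss = steady_state(r)
            t_end = 50.0 / min(
                r.alpha_A, r.alpha_m6A, r.beta_A, r.gamma_A, r.gamma_m6A
            )
            tc = simulate_dynamics(r, CompartmentState(0, 0, 0, 0), np.array([t_end]))
            got = tc.state(0).as_array()
            want = ss.as_array()
            assert np.allclose(got, want, rtol=1e-8, atol=1e-12)


class TestDerivedIndices:
    def test_reference_state_arithmetic(self):
        idx = derive_indices(CompartmentState(1, 1, 1, 0.1))
        assert idx.m6a_level == pytest.approx(1.1 / 3.1)
        assert idx.nuc_cyt_ratio == pytest.approx(2 / 1.1)
        assert idx.nuc_m6a_level == pytest.approx(0.5)
        assert idx.cyt_m6a_level == pytest.approx(0.1 / 1.1)
        assert idx.gene_level == pytest.approx(3.1)

    def test_symmetric_decay_gives_half_everywhere(self):
        ss = steady_state(RateSet(2, 2, 1, 1, 3, 3))
        idx = derive_indices(ss)
        assert idx.m6a_level == pytest.approx(0.5)
        assert idx.nuc_m6a_level == pytest.approx(0.5)
        assert idx.cyt_m6a_level == pytest.approx(0.5)

    def test_empty_cytoplasm_flags_undefined_not_nan(self):
        idx = derive_indices(CompartmentState(1, 1, 0, 0))
        assert idx.cyt_m6a_level is None
        assert idx.nuc_cyt_ratio is None
        assert idx.m6a_level == pytest.approx(0.5)

    def test_all_zero_state_is_degenerate(self):
        with pytest.raises(DegenerateStateError):
            derive_indices(CompartmentState(0, 0, 0, 0))

    def test_selective_decay_orders_compartments(self, rng):
        # gamma_m6A > gamma_A => nuclear level > whole-cell > cytoplasmic
        for _ in range(100):
            r = random_rateset(rng)
            idx = derive_indices(steady_state(r))
            assert idx.nuc_m6a_level > idx.m6a_level > idx.cyt_m6a_level


class TestDynamics:
    def test_single_exponential_nuclear_decay(self):
        r = RateSet(0, 0, 1, 1, 1, 1)
        tc = simulate_dynamics(r, CompartmentState(1, 0, 0, 0), np.array([np.log(2)]))
        assert tc.nuc_A[0] == pytest.approx(0.5)

    def test_two_exponential_cytoplasm(self):
        # alpha=0, beta=1, gamma=10, nuc0=1, cyt0=0.1
        r = RateSet(0, 0, 1, 1, 10, 10)
        tc = simulate_dynamics(r, CompartmentState(1, 0, 0.1, 0), np.array([1.0]))
        expected = (1 / 9) * (np.exp(-1) - np.exp(-10)) + 0.1 * np.exp(-10)
        assert tc.cyt_A[0] == pytest.approx(expected, rel=1e-12)

    def test_steady_state_is_fixed_point(self):
        r = RateSet.baseline(1.3, 0.7, 0.9, 1.1, S=10)
        ss = steady_state(r)
        tc = simulate_dynamics(r, ss, np.linspace(0.1, 20, 30))
        assert np.allclose(tc.nuc_A, ss.nuc_A, rtol=1e-12)
        assert np.allclose(tc.cyt_m6A, ss.cyt_m6A, rtol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        alpha=positive_rate,
        beta=positive_rate,
        gamma=positive_rate,
        n0=st.floats(0, 5),
        c0=st.floats(0, 5),
        t=st.floats(0.01, 10),
    )
    def test_closed_form_matches_adaptive_integration(self, alpha, beta, gamma, n0, c0, t):
        r = RateSet(alpha, alpha, beta, beta, gamma, gamma)
        init = CompartmentState(n0, 0, c0, 0)
        grid = np.array([t])
        cf = simulate_dynamics(r, init, grid)
        nu = simulate_dynamics(r, init, grid, method="numeric")
        scale = max(1e-9, nu.nuc_A[0], nu.cyt_A[0])
        assert abs(cf.nuc_A[0] - nu.nuc_A[0]) / scale < 1e-6
        assert abs(cf.cyt_A[0] - nu.cyt_A[0]) / scale < 1e-6

    def test_degenerate_equal_export_and_decay(self):
        # beta == gamma triggers the t*exp(-gamma t) limit branch
        r = RateSet(0, 0, 1.0, 1.0, 1.0, 1.0)
        init = CompartmentState(1, 0, 0.1, 0)
        t = np.array([0.5, 1.0, 2.0])
        cf = simulate_dynamics(r, init, t)
        nu = simulate_dynamics(r, init, t, method="numeric")
        assert np.allclose(cf.cyt_A, nu.cyt_A, rtol=1e-6)
        # analytic: cyt(t) = (c0 + n0*t) e^{-t}
        assert np.allclose(cf.cyt_A, (0.1 + t) * np.exp(-t), rtol=1e-9)

    def test_near_degenerate_no_cancellation(self):
        r = RateSet(0, 0, 1.0, 1.0, 1.0 + 1e-12, 1.0 + 1e-12)
        cf = simulate_dynamics(r, CompartmentState(1, 0, 0.1, 0), np.array([1.0]))
        assert cf.cyt_A[0] == pytest.approx((0.1 + 1.0) * np.exp(-1), rel=1e-6)

    def test_linearity_in_production(self, rng):
        # scaling both alphas scales pools, leaves every index unchanged
        r = random_rateset(rng)
        c = 3.7
        scaled = dataclasses.replace(r, alpha_A=c * r.alpha_A, alpha_m6A=c * r.alpha_m6A)
        s1, s2 = steady_state(r), steady_state(scaled)
        assert np.allclose(c * s1.as_array(), s2.as_array(), rtol=1e-12)
        i1, i2 = derive_indices(s1), derive_indices(s2)
        assert i1.m6a_level == pytest.approx(i2.m6a_level)
        assert i1.nuc_cyt_ratio == pytest.approx(i2.nuc_cyt_ratio)

    def test_decreasing_grid_rejected(self):
        r = RateSet(1, 1, 1, 1, 1, 10)
        with pytest.raises(ParameterError):
            simulate_dynamics(r, CompartmentState(0, 0, 0, 0), np.array([1.0, 0.5]))
        with pytest.raises(ParameterError):
            simulate_dynamics(r, CompartmentState(0, 0, 0, 0), np.array([-1.0, 0.5]))


class TestVariants:
    def test_ko_removes_selective_decay(self):
        base = RateSet.baseline(1, 1, 1, 1, S=10)
        ko = apply_variant(base, "ko")
        assert ko.gamma_m6A == ko.gamma_A
        assert base.gamma_m6A == 10.0  # base untouched

    def test_export_variants_scale_export(self):
        base = RateSet.baseline(1, 1, 2, 1, S=10)
        fac = apply_variant(base, "export_facilitated")
        inh = apply_variant(base, "export_inhibited")
        assert fac.beta_m6A == pytest.approx(10 * base.beta_A)
        assert inh.beta_m6A == pytest.approx(0.1 * base.beta_A)
        # alternative hypotheses: m6A acts on export, not on stability
        assert fac.gamma_m6A == fac.gamma_A
        assert inh.gamma_m6A == inh.gamma_A

    def test_baseline_reimposes_s_multiplier(self):
        r = RateSet(1, 1, 1, 5, 1, 3)
        out = apply_variant(r, ModelVariant("baseline", {"S": 10}))
        assert out.gamma_m6A == pytest.approx(10 * out.gamma_A)
        assert out.beta_m6A == out.beta_A

    def test_nuclear_decay_variant_sets_delta(self):
        out = apply_variant(RateSet.baseline(1, 1, 1, 1), ModelVariant("nuclear_decay", {"delta": 0.5}))
        assert out.delta == 0.5

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            ModelVariant("mystery")


def test_rateset_dict_roundtrip():
    r = RateSet.baseline(1.5, 0.5, 2.0, 0.8, S=10, delta=0.1)
    assert RateSet.from_dict(r.to_dict()) == r
    with pytest.raises(ParameterError):
        RateSet.from_dict({"alpha_A": 1, "bogus": 2})


def test_timecourse_tidy_frame():
    r = RateSet.baseline(1, 1, 1, 1, S=10)
    tc = simulate_dynamics(r, steady_state(r), np.array([0.0, 1.0, 2.0]))
    df = tc.to_frame()
    assert list(df.columns[:5]) == ["time", "nuc_A", "nuc_m6A", "cyt_A", "cyt_m6A"]
    assert "m6a_level" in df.columns and len(df) == 3
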
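"""Prony kernel, recursive viscoelastic update, and the quadrature oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from viscocann.qlv import (
    PronySet,
    convolution_oracle,
    prony_from_raw,
    prony_kernel,
    recursive_sensitivities,
    recursive_stress,
)

PSET = PronySet(0.4, ((0.3, 1.0), (0.3, 100.0)))


class TestPronySet:
    def test_partition_of_unity_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            PronySet(0.5, ((0.3, 1.0), (0.3, 100.0)))

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PronySet(0.4, ((0.3, -1.0), (0.3, 100.0)))

    def test_decreasing_taus_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            PronySet(0.4, ((0.3, 100.0), (0.3, 1.0)))

    def test_flat_parameter_vector(self):
        assert np.allclose(PSET.v, [0.4, 0.3, 1.0, 0.3, 100.0])


class TestKernel:
    def test_unity_at_zero(self):
        assert prony_kernel(PSET, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_derived_value_at_one_second(self):
        assert prony_kernel(PSET, 1.0) == pytest.approx(0.807379, abs=1e-6)

    def test_long_term_limit(self):
        assert prony_kernel(PSET, 1e6) == pytest.approx(0.4, abs=1e-12)

    def test_monotone_non_increasing(self):
        g = prony_kernel(PSET, np.linspace(0.0, 500.0, 2000))
        assert np.all(np.diff(g) <= 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            prony_kernel(PSET, -0.1)


class TestConstraintMapping:
    def test_midpoint_raw_outputs(self):
        ps = prony_from_raw([0.5, 0.5, 0.5, 0.5])
        g1, tau1 = ps.terms[0]
        g2, tau2 = ps.terms[1]
        assert g1 == pytest.approx(0.475)
        assert g2 == pytest.approx((1.0 - 0.475) * 0.475)
        assert ps.g0 == pytest.approx(1.0 - g1 - g2)
        assert tau1 == pytest.approx(10.0**-0.5, rel=1e-12)  # geometric midpoint of [0.01, 10]
        assert tau2 == pytest.approx(100.0, rel=1e-12)  # geometric midpoint of [10, 1000]

    def test_random_sweep_always_valid(self):
        rng = np.random.default_rng(42)
        for raw in rng.uniform(1e-9, 1.0 - 1e-9, size=(2000, 4)):
            ps = prony_from_raw(raw)  # PronySet.__post_init__ enforces invariants
            assert ps.g0 >= 0.0
            assert ps.terms[0][1] < ps.terms[1][1]

    def test_out_of_interval_rejected(self):
        with pytest.raises(ValueError, match="open interval"):
            prony_from_raw([0.0, 0.5, 0.5, 0.5])


class TestRecursiveStress:
    def test_elastic_limit_reproduces_p0(self):
        ps = PronySet(1.0, ((0.0, 1.0), (0.0, 100.0)))
        t = np.linspace(0.0, 10.0, 101)
        P0 = np.sin(t)
        hist = recursive_stress(t, P0, ps)
        assert np.allclose(hist.P, P0, atol=1e-14)
        assert np.allclose(hist.h, 0.0)

    def test_step_input_recovers_kernel(self):
        # near-Heaviside: unit stress arrives within 1e-9 s of t=0
        t = np.concatenate([[0.0, 1e-9], np.logspace(-2, np.log10(500.0), 400)])
        P0 = np.where(t > 0.0, 1.0, 0.0)
        hist = recursive_stress(t, P0, PSET)
        assert np.allclose(hist.P[1:], prony_kernel(PSET, t[1:]), atol=1e-6)

    def test_history_integrals_start_at_zero(self):
        t = np.linspace(0.0, 5.0, 50)
        hist = recursive_stress(t, np.cos(t), PSET)
        assert np.all(hist.h[:, 0] == 0.0)

    def test_decreasing_times_rejected_with_index(self):
        t = np.array([0.0, 1.0, 0.5, 2.0])
        with pytest.raises(ValueError, match="index 2"):
            recursive_stress(t, np.zeros(4), PSET)

    def test_triangular_ramp_matches_oracle(self):
        dt = 0.05  # tau1 / 20
        t = np.arange(0.0, 20.0 + dt / 2, dt)
        P0 = np.where(t < 10.0, t / 10.0, (20.0 - t) / 10.0)
        r = recursive_stress(t, P0, PSET).P
        c = convolution_oracle(t, P0, PSET).P
        assert np.max(np.abs(r - c)) / np.max(np.abs(r)) < 1e-3

    def test_nonuniform_grid_matches_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0.0, 20.0, 600))
        t = np.concatenate([[0.0], t[np.diff(t, prepend=-1.0) > 1e-4]])
        P0 = np.sin(np.pi * t / 20.0) ** 2
        r = recursive_stress(t, P0, PSET).P
        c = convolution_oracle(t, P0, PSET).P
        assert np.max(np.abs(r - c)) / np.max(np.abs(r)) < 1e-2

    def test_chained_history_reproduces_unsplit_series(self):
        """Splitting a protocol at an interior stamp and carrying the final
        history integrals forward reproduces the unsplit evaluation."""
        t = np.linspace(0.0, 20.0, 401)
        P0 = np.sin(t / 3.0)
        full = recursive_stress(t, P0, PSET)
        k = 200
        first = recursive_stress(t[: k + 1], P0[: k + 1], PSET)
        second = recursive_stress(t[k:], P0[k:], PSET, h0=first.h[:, -1])
        assert np.allclose(second.P, full.P[k:], atol=1e-12)

    def test_relaxation_hold_decays_to_long_term_fraction(self):
        # 5 s ramp to 1 kPa, then 600 s hold
        t = np.concatenate([np.linspace(0.0, 5.0, 51), 5.0 + np.logspace(-2, np.log10(600.0), 200)])
        P0 = np.minimum(t / 5.0, 1.0)
        P = recursive_stress(t, P0, PSET).P
        hold = P[51:]
        assert np.all(np.diff(hold) <= 1e-12)
        assert hold[-1] == pytest.approx(PSET.g0 * 1.0, abs=5e-3)


class TestConvolutionOracle:
    def test_constant_input_passes_long_term_share(self):
        t = np.linspace(0.0, 10.0, 100)
        P0 = np.full_like(t, 2.0)
        # constant P0 from t=0 carries only the long-term elastic share
        assert np.allclose(convolution_oracle(t, P0, PSET).P, PSET.g0 * 2.0, atol=1e-12)

    def test_grid_refinement_shrinks_disagreement(self):
        errs = []
        for dt in (0.1, 0.05, 0.025):
            t = np.arange(0.0, 20.0 + dt / 2, dt)
            P0 = np.sin(np.pi * t / 20.0) ** 2
            r = recursive_stress(t, P0, PSET).P
            c = convolution_oracle(t, P0, PSET).P
            errs.append(np.max(np.abs(r - c)) / np.max(np.abs(r)))
        assert errs[1] < 0.6 * errs[0]
        assert errs[2] < 0.6 * errs[1]


class TestSensitivities:
    def test_parameter_and_input_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 20.0, 120)
        P0 = np.cumsum(rng.normal(0.0, 0.05, t.size))
        theta = np.array([0.35, 0.2, 1.5, 80.0])
        w = rng.normal(size=t.size)  # arbitrary adjoint of P

        def scalar(th, p0):
            P, _, _ = recursive_sensitivities(t, p0, *th)
            return float(w @ P)

        P, dP, backprop = recursive_sensitivities(t, P0, *theta)
        grad_theta = w @ dP
        for k in range(4):
            eps = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            fd = (scalar(tp, P0) - scalar(tm, P0)) / (2 * eps)
            assert grad_theta[k] == pytest.approx(fd, rel=1e-5, abs=1e-9)
        P0bar = backprop(w)
        for idx in (0, 1, 37, 119):
            eps = 1e-6
            pp, pm = P0.copy(), P0.copy()
            pp[idx] += eps
            pm[idx] -= eps
            fd = (scalar(theta, pp) - scalar(theta, pm)) / (2 * eps)
            assert P0bar[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
    st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
    st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
    st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
)
def test_constraint_mapping_property(s1, s2, s3, s4):
    ps = prony_from_raw([s1, s2, s3, s4])
    assert abs(ps.g0 + ps.weights.sum() - 1.0) < 1e-12
    assert ps.g0 > 0.0
    assert 0.01 <= ps.terms[0][1] <= 10.0 < ps.terms[1][1] <= 1000.0
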
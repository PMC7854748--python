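"""Unit and property tests of the three-state master-equation core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pfefit as pf
from pfefit.kinetics import PURE_A1, Propagator, StateFractions

from conftest import rk4_propagate

rates_st = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


class TestGenerator:
    def test_all_zero_rates_give_zero_matrix(self):
        G = pf.build_generator(pf.RateConstants(0, 0, 0, 0))
        assert np.all(G == 0)

    def test_wild_type_diagonal(self, wt_rates):
        G = pf.build_generator(wt_rates)
        assert np.allclose(np.diag(G), [-0.061, -0.436, -0.17])
        # no direct A1 <-> H_inact edge
        assert G[0, 2] == 0 and G[2, 0] == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            pf.RateConstants(-0.1, 0, 0, 0)

    @given(k1=rates_st, kneg1=rates_st, ki=rates_st, kr=rates_st)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_columns_sum_to_zero_and_stable_spectrum(self, k1, kneg1, ki, kr):
        G = pf.build_generator(pf.RateConstants(k1, kneg1, ki, kr))
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-12)
        assert np.all(np.real(np.linalg.eigvals(G)) <= 1e-10)


class TestPropagate:
    def test_zero_time_is_identity(self, wt_rates):
        s = StateFractions(0.2, 0.3, 0.5)
        assert pf.propagate(s, wt_rates, 0.0) is s

    def test_symmetric_chain_equipartitions(self):
        rc = pf.RateConstants(1, 1, 1, 1)
        s = pf.propagate(PURE_A1, rc, 1e3)
        assert np.allclose(s.to_array(), 1 / 3, atol=1e-6)

    def test_matches_fixed_step_integration(self, wt_rates):
        got = pf.propagate(PURE_A1, wt_rates, 10.0).to_array()
        want = rk4_propagate(pf.build_generator(wt_rates), PURE_A1.to_array(), 10.0, 1e-3)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_negative_time_rejected(self, wt_rates):
        with pytest.raises(ValueError):
            pf.propagate(PURE_A1, wt_rates, -1.0)

    @given(
        k1=rates_st, kneg1=rates_st, ki=rates_st, kr=rates_st,
        dt=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        a1=st.floats(min_value=0.0, max_value=1.0),
        a2=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conserves_total_population(self, k1, kneg1, ki, kr, dt, a1, a2):
        rc = pf.RateConstants(k1, kneg1, ki, kr)
        frac = StateFractions.from_array(np.array([a1, a2, max(1e-12, 2 - a1 - a2)]))
        out = pf.propagate(frac, rc, dt)
        assert abs(out.a1 + out.a2 + out.h_inact - 1.0) < 1e-9
        assert min(out.a1, out.a2, out.h_inact) >= 0

    def test_degenerate_eigenvalues_fall_back_to_expm(self):
        # k1 = k_react, k_neg1 = k_inact = 0 gives a repeated eigenvalue
        rc = pf.RateConstants(1.0, 0.0, 0.0, 1.0)
        prop = Propagator(rc)
        out = prop.propagate(PURE_A1.to_array(), np.array([2.5]))[0]
        want = rk4_propagate(pf.build_generator(rc), PURE_A1.to_array(), 2.5, 1e-4)
        assert np.max(np.abs(out - want)) < 1e-7


class TestSteadyState:
    def test_all_rates_equal_equipartitions(self):
        s = pf.steady_state(pf.RateConstants(2, 2, 2, 2))
        assert np.allclose(s.to_array(), 1 / 3, atol=1e-12)

    def test_no_inactivation_detaches_third_state(self):
        rc = pf.RateConstants(0.3, 0.6, 0.0, 0.5)
        s = pf.steady_state(rc)
        assert s.h_inact == 0
        assert s.a1 / s.a2 == pytest.approx(0.6 / 0.3)

    def test_wild_type_ratios_and_long_time_limit(self, wt_rates):
        s = pf.steady_state(wt_rates)
        ratios = s.to_array() / s.a1
        assert np.allclose(ratios, [1.0, 3.8125, 9.419117647], rtol=1e-6)
        long = pf.propagate(PURE_A1, wt_rates, 1e4).to_array()
        assert np.max(np.abs(long - s.to_array())) < 1e-6

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            pf.steady_state(pf.RateConstants(0, 0, 0, 0))

    def test_absorbing_limit(self):
        # irreversible inactivation locks everything in H_inact
        s = pf.steady_state(pf.RateConstants(1.0, 0.5, 1.0, 0.0))
        assert s.h_inact == pytest.approx(1.0)

    def test_h_inact_monotone_in_rate_ratio(self, wt_rates):
        h_values = [
            pf.steady_state(wt_rates.with_k_react(kr)).h_inact for kr in (0.5, 0.2, 0.1)
        ]
        assert h_values == sorted(h_values)  # increasing as k_react drops
        base = pf.RateConstants(0.061, 0.016, 0.1, 0.17)
        h_up = [
            pf.steady_state(pf.RateConstants(0.061, 0.016, ki, 0.17)).h_inact
            for ki in (0.1, 0.4, 1.0)
        ]
        assert h_up == sorted(h_up)


class TestRelaxationRates:
    def test_decoupled_two_state_limit(self):
        rc = pf.RateConstants(0.3, 0.7, 0.0, 0.0)
        rates = pf.relaxation_rates(rc)
        assert min(rates) == pytest.approx(0.0, abs=1e-12)
        assert max(rates) == pytest.approx(1.0)

    def test_scaling_linearity(self, wt_rates):
        r1 = pf.relaxation_rates(wt_rates)
        r3 = pf.relaxation_rates(wt_rates.scaled(3.0))
        assert np.allclose(np.array(r3), 3.0 * np.array(r1))

    def test_wild_type_matches_characteristic_polynomial(self, wt_rates):
        # non-zero eigenvalues solve x^2 - (tr) x + (sum of 2x2 minors) = 0
        # for the generator restricted to its non-conserved subspace
        G = pf.build_generator(wt_rates)
        tr = np.trace(G)
        m = (
            np.linalg.det(G[np.ix_([0, 1], [0, 1])])
            + np.linalg.det(G[np.ix_([0, 2], [0, 2])])
            + np.linalg.det(G[np.ix_([1, 2], [1, 2])])
        )
        roots = np.roots([1.0, -tr, m])
        assert np.allclose(sorted(np.abs(roots)), pf.relaxation_rates(wt_rates), rtol=1e-10)


class TestTwoState:
    def test_zero_time_identity(self):
        assert pf.propagate_two_state(0.7, pf.TwoStateRateConstants(1, 2), 0.0) == 0.7

    def test_equal_rates_relax_to_half(self):
        out = pf.propagate_two_state(1.0, pf.TwoStateRateConstants(0.4, 0.4), 1e4)
        assert out == pytest.approx(0.5, abs=1e-12)

    def test_matches_numerical_integration(self):
        rc2 = pf.TwoStateRateConstants(0.9, 0.35)
        G = np.array([[-rc2.k_inact, rc2.k_react], [rc2.k_inact, -rc2.k_react]])
        want = rk4_propagate(G, np.array([0.8, 0.2]), 1.0, 1e-5)[0]
        got = pf.propagate_two_state(0.8, rc2, 1.0)
        assert abs(got - want) < 1e-10

    def test_pooled_limit_of_three_state_model(self, wt_rates):
        # with a very fast A1 <-> A2 pre-equilibrium (k1 = k_-1 = 1e3) the
        # weighted three-state activity matches the two-state solution with
        # the effective inactivation rate halved
        rc = pf.RateConstants(1e3, 1e3, wt_rates.k_inact, wt_rates.k_react)
        rc2 = pf.TwoStateRateConstants(wt_rates.k_inact / 2, wt_rates.k_react)
        w = pf.ActivityWeights(alpha2=0.5)
        state = pf.steady_state(pf.RateConstants(1e3, 1e3, 0, 1))  # active equipartition
        for dt in (0.5, 2.0, 10.0, 60.0):
            s3 = pf.propagate(state, rc, dt)
            act3 = s3.a1 * w.alpha1 + s3.a2 * w.alpha2
            act2 = pf.propagate_two_state(1.0, rc2, dt) * (w.alpha1 + w.alpha2) / 2
            assert act3 == pytest.approx(act2, rel=0.01)


class TestSimulateCurrent:
    def test_initial_current_is_amplitude(self, step_protocol, wt_truth):
        from pfefit.synthetic import rates_for_protocol

        rates = rates_for_protocol(step_protocol, wt_truth)
        tr = pf.simulate_current(step_protocol, rates, t_grid=np.array([0.0]))
        assert tr.current[0] == pytest.approx(1.0)

    def test_long_hold_reaches_weighted_steady_state(self):
        rc = pf.RateConstants(0.5, 0.1, 2.0, 0.05)  # k_react << k_inact
        protocol = pf.Protocol((pf.PotentialStep(-0.2, 500.0),))
        tr = pf.simulate_current(protocol, [rc], amplitudes={-0.2: 2.0})
        ss = pf.steady_state(rc)
        want = 2.0 * (ss.a1 + 0.5 * ss.a2)
        assert tr.current[-1] == pytest.approx(want, rel=1e-6)

    def test_step_relaxation_is_biexponential(self, step_protocol, wt_truth):
        from scipy.optimize import curve_fit
        from pfefit.synthetic import rates_for_protocol

        rates = rates_for_protocol(step_protocol, wt_truth)
        tr = pf.simulate_current(step_protocol, rates, t_grid=np.arange(0, 350, 0.1))
        # second step: first excursion to the oxidative potential
        seg = (tr.time >= 50.0) & (tr.time < 100.0)
        t = tr.time[seg] - 50.0
        y = tr.current[seg]

        def one_exp(t, a, k, c):
            return a * np.exp(-k * t) + c

        def two_exp(t, a1, k1, a2, k2, c):
            return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) + c

        p1, _ = curve_fit(one_exp, t, y, p0=[0.5, 0.5, 0.3], maxfev=20000)
        p2, _ = curve_fit(two_exp, t, y, p0=[0.3, 1.0, 0.3, 0.05, 0.3], maxfev=20000)
        ssr1 = np.sum((y - one_exp(t, *p1)) ** 2)
        ssr2 = np.sum((y - two_exp(t, *p2)) ** 2)
        assert ssr1 / ssr2 > 10

    def test_missing_amplitude_errors(self, step_protocol, wt_truth):
        from pfefit.synthetic import rates_for_protocol

        rates = rates_for_protocol(step_protocol, wt_truth)
        with pytest.raises(KeyError):
            pf.simulate_current(step_protocol, rates, amplitudes={-0.31: 1.0})

    def test_film_loss_decays_current(self, step_protocol, wt_truth):
        from pfefit.synthetic import rates_for_protocol

        rates = rates_for_protocol(step_protocol, wt_truth)
        t = np.arange(0, 350, 0.5)
        with_loss = pf.simulate_current(step_protocol, rates, t_grid=t, film_loss_tau=100.0)
        without = pf.simulate_current(step_protocol, rates, t_grid=t)
        assert np.all(with_loss.current <= without.current + 1e-12)
        assert with_loss.current[-1] < without.current[-1] * 0.1


class TestSimulateCV:
    sweep = {"E_start": -0.6, "E_vertex": 0.0, "scan_rate": 0.003}
    law = pf.KReactLaw(mode="exponential", k0=0.17, E_ref=-0.196, slope=23.0259)

    def test_no_inactivation_no_hysteresis(self, wt_rates):
        rc = pf.RateConstants(wt_rates.k1, wt_rates.k_neg1, 0.0, wt_rates.k_react)
        tr = pf.simulate_cv(self.sweep, self.law, rc)
        half = len(tr) // 2
        fwd = tr.current[: half + 1]
        bwd = tr.current[half:][::-1]
        n = min(len(fwd), len(bwd))
        # compare at equal potentials
        assert np.max(np.abs(fwd[:n] - bwd[:n])) < 1e-9

    def test_wild_type_peak_below_vertex(self, wt_rates):
        tr = pf.simulate_cv(self.sweep, self.law, wt_rates)
        half = len(tr) // 2
        i_peak = np.argmax(tr.current[: half + 1])
        assert tr.potential[i_peak] < self.sweep["E_vertex"] - 0.05

    def test_faster_scan_leaves_less_inactive(self, wt_rates):
        h_at_vertex = []
        for rate in (0.003, 0.006):
            sweep = dict(self.sweep, scan_rate=rate)
            tr = pf.simulate_cv(sweep, self.law, wt_rates)
            half = len(tr) // 2
            # infer inactive fraction from current suppression at the vertex
            shape = np.tanh(20.0 * (tr.potential[half] + 0.426))
            h_at_vertex.append(1.0 - tr.current[half] / shape)
        assert h_at_vertex[1] < h_at_vertex[0]
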
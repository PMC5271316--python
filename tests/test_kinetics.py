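"""Correlation estimators, reactive-flux rate fits, multi-exponential times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fieldhb as fh
from fieldhb.kinetics import pair_state_series, pair_states_from_hbonds
from oracles import enumerate_correlations, two_state_curves

import pandas as pd


def series_from_h(h, Hp=None, Q=None, pid=0, dt=1.0):
    h = np.asarray(h)
    Hp = np.maximum(h, 0) if Hp is None else np.asarray(Hp)
    Hp = np.maximum(Hp, h)
    return fh.PairStateSeries(pair_id=pid, t=np.arange(len(h)) * dt, h=h,
                              Hprime=Hp, Q=Q)


class TestPairStates:
    def test_always_bonded_pair(self):
        p = pair_state_series(0, np.arange(5.0), [1, 1, 1, 1, 1],
                              [3.0, 3.1, 2.9, 3.0, 3.1], cutoff=3.2)
        assert np.all(p.h == 1)
        assert np.all(p.Q == 0)
        assert p.Rmax is None

    def test_hand_built_six_frame_example(self):
        """r = (3.0, 3.0, 3.3, 3.1, 3.6, 3.0) under the PW criteria."""
        r = np.array([3.0, 3.0, 3.3, 3.1, 3.6, 3.0])
        h = (r <= 3.2).astype(int)           # angle assumed satisfied
        p = pair_state_series(0, np.arange(6.0), h, r, cutoff=3.2)
        np.testing.assert_array_equal(p.h, [1, 1, 0, 1, 0, 1])
        assert p.Rmax == pytest.approx(3.3)
        np.testing.assert_array_equal(p.Q, [0, 0, 1, 0, 0, 0])

    def test_gillespie_output_passes_through_unchanged(self):
        truth = fh.KineticGroundTruth(k1=0.4, k1p=0.05, k2=0.7, k2p=0.05,
                                      k_escape=0.02, n_pairs=5, t_total=20,
                                      dt=0.5, seed=2)
        pairs = fh.gen_hb_trajectories(truth)
        corr = fh.correlate(pairs, max_lag=10)   # accepts them directly
        assert corr.C[0] == 1.0

    def test_from_bond_table(self):
        r = {(0, 1, 2): np.array([3.0, 3.0, 3.3, 3.1, 3.6, 3.0])}
        tbl = pd.DataFrame({"frame": [0, 1, 3, 5], "donor_atom": 0,
                            "hydrogen_atom": 1, "acceptor_atom": 2})
        out = pair_states_from_hbonds(tbl, r, np.arange(6.0), cutoff=3.2)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].h, [1, 1, 0, 1, 0, 1])
        np.testing.assert_array_equal(out[0].Q, [0, 0, 1, 0, 0, 0])

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError, match="Hprime"):
            fh.PairStateSeries(0, np.arange(3.0), h=[1, 1, 1],
                               Hprime=[1, 0, 1])


class TestCorrelate:
    def test_single_pair_enumeration_example(self):
        """h = (1,1,0,1): C(1)=S(1)=1/2, C(2)=1/2, S(2)=0."""
        corr = fh.correlate([series_from_h([1, 1, 0, 1])])
        assert corr.C[1] == 0.5 and corr.S[1] == 0.5
        assert corr.C[2] == 0.5 and corr.S[2] == 0.0

    def test_single_pair_quasifree_example(self):
        """Same pair, H′ ≡ 1: N(1) = 1/2."""
        corr = fh.correlate([series_from_h([1, 1, 0, 1],
                                           Hp=[1, 1, 1, 1])])
        assert corr.N[1] == 0.5

    def test_all_bonded_ensemble(self):
        pairs = [series_from_h([1] * 20, pid=i) for i in range(4)]
        corr = fh.correlate(pairs)
        np.testing.assert_array_equal(corr.S, 1.0)
        np.testing.assert_array_equal(corr.C, 1.0)
        np.testing.assert_array_equal(corr.N, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_enumeration_bitwise(self, seed):
        """Vectorised estimator vs triple-loop oracle, exact equality."""
        rng = np.random.default_rng(seed)
        n_pairs, T = rng.integers(2, 11), rng.integers(10, 51)
        pairs = []
        for i in range(n_pairs):
            h = (rng.random(T) < 0.6).astype(int)
            hp = np.maximum(h, (rng.random(T) < 0.3).astype(int))
            q = ((1 - hp) * (rng.random(T) < 0.2)).astype(int)
            pairs.append(series_from_h(h, Hp=hp, Q=q, pid=i))
        if not any(p.h.any() for p in pairs):
            return
        L = T // 2
        corr = fh.correlate(pairs, max_lag=float(L))
        S, C, N, F, den = enumerate_correlations(pairs, L)
        ok = den > 0
        np.testing.assert_array_equal(corr.C[ok], C[ok])
        np.testing.assert_array_equal(corr.S[ok], S[ok])
        np.testing.assert_array_equal(corr.N[ok], N[ok])
        np.testing.assert_array_equal(corr.F[ok], F[ok])
        np.testing.assert_array_equal(corr.n_origins, den)

    def test_no_bonded_origins_is_an_error(self):
        with pytest.raises(ValueError, match="bonded"):
            fh.correlate([series_from_h([0, 0, 0, 0])])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_estimator_invariants_hold_on_random_inputs(self, seed):
        """S(0)=C(0)=1, 0 ≤ S ≤ C ≤ 1, S non-increasing, N(0)=F(0)=0."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(5, 40))
        pairs = []
        for i in range(int(rng.integers(1, 6))):
            h = (rng.random(T) < rng.uniform(0.2, 0.9)).astype(int)
            hp = np.maximum(h, (rng.random(T) < 0.4).astype(int))
            q = ((1 - hp) * (rng.random(T) < 0.3)).astype(int)
            pairs.append(series_from_h(h, Hp=hp, Q=q, pid=i))
        if not any(p.h.any() for p in pairs):
            return
        corr = fh.correlate(pairs)
        corr.validate()   # raises on any invariant violation


class TestReactiveFlux:
    def test_exponential_taylor_accuracy(self):
        t = np.arange(0, 5, 0.01)
        corr = fh.CorrelationSet(lags=t, S=np.exp(-t), C=np.exp(-t),
                                 N=np.zeros_like(t), F=np.zeros_like(t),
                                 n_origins=np.ones_like(t, dtype=int))
        k = fh.reactive_flux(corr)
        np.testing.assert_allclose(k[1:-1], np.exp(-t)[1:-1], rtol=1e-3)

    def test_constant_and_linear_curves(self):
        t = np.arange(0, 10.0)
        mk = lambda C: fh.CorrelationSet(lags=t, S=C, C=C,
                                         N=np.zeros_like(t),
                                         F=np.zeros_like(t),
                                         n_origins=np.ones_like(t, int))
        np.testing.assert_allclose(fh.reactive_flux(mk(np.full(10, 0.5))), 0)
        np.testing.assert_allclose(
            fh.reactive_flux(mk(1 - 0.05 * t)), 0.05, atol=1e-12)


def exact_two_state_corr(k1, k2, dt=0.02, t_max=40.0):
    lags = np.arange(0, t_max + 1e-9, dt)
    C, N = two_state_curves(k1, k2, lags)
    return fh.CorrelationSet(lags=lags, S=C.copy(), C=C, N=N,
                             F=np.zeros_like(C),
                             n_origins=np.ones_like(C, dtype=int))


class TestFitRates:
    def test_exact_two_state_recovery(self):
        """Rates recovered from analytic master-equation curves."""
        corr = exact_two_state_corr(0.4, 0.7)
        fit = fh.fit_rates(corr, model="LC")
        assert fit.k1 == pytest.approx(0.4, rel=1e-3)
        assert fit.k2 == pytest.approx(0.7, rel=1e-3)
        assert fit.lifetime == pytest.approx(2.5, rel=1e-3)

    def test_extended_nests_lc_when_f_vanishes(self):
        corr = exact_two_state_corr(0.4, 0.7)
        lc = fh.fit_rates(corr, model="LC")
        ext = fh.fit_rates(corr, model="extended")
        assert ext.k2p == pytest.approx(0.0, abs=1e-8)
        assert ext.k1 == pytest.approx(lc.k1, rel=1e-6)
        assert ext.k2 == pytest.approx(lc.k2, rel=1e-6)
        assert ext.rss <= lc.rss + 1e-15

    def test_singular_design_reports_condition_number(self):
        t = np.arange(0, 40, 0.5)
        C = np.exp(-0.3 * t)
        corr = fh.CorrelationSet(lags=t, S=C.copy(), C=C, N=0.5 * C,
                                 F=np.zeros_like(C),
                                 n_origins=np.ones_like(C, int))
        with pytest.raises(ValueError, match="condition"):
            fh.fit_rates(corr, model="extended")

    def test_gillespie_nesting_property(self, standard_truth):
        import dataclasses
        truth = dataclasses.replace(standard_truth, n_pairs=800)
        corr = fh.correlate(fh.gen_hb_trajectories(truth), max_lag=40.0)
        lc = fh.fit_rates(corr, model="LC")
        ext = fh.fit_rates(corr, model="extended")
        assert ext.rss <= lc.rss + 1e-15
        assert abs(ext.k1 - truth.k1_total) / truth.k1_total < 0.15


class TestMultiExp:
    def test_single_exponential_exact(self):
        t = np.arange(0, 50, 0.5)
        fit = fh.fit_multiexp(t, np.exp(-t / 5.0), n_terms=1)
        assert fit.taus[0] == pytest.approx(5.0, abs=1e-6)
        assert fit.tau_weighted == pytest.approx(5.0, abs=1e-6)

    def test_two_exponential_weighted_time(self):
        """0.7·exp(−t/2) + 0.3·exp(−t/20) → τ_w = 7.4 ps."""
        t = np.arange(0, 100, 0.25)
        y = 0.7 * np.exp(-t / 2) + 0.3 * np.exp(-t / 20)
        fit = fh.fit_multiexp(t, y, n_terms=2)
        assert fit.tau_weighted == pytest.approx(7.4, rel=1e-4)

    def test_overparameterised_fit_still_returns_tau(self):
        t = np.arange(0, 50, 0.5)
        fit = fh.fit_multiexp(t, np.exp(-t / 5.0), n_terms=2)
        assert fit.tau_weighted == pytest.approx(5.0, rel=0.01)

    def test_integral_weighting_flag(self):
        t = np.arange(0, 100, 0.25)
        y = 0.7 * np.exp(-t / 2) + 0.3 * np.exp(-t / 20)
        fit = fh.fit_multiexp(t, y, n_terms=2, weighting="integral")
        expect = (0.7 * 4 + 0.3 * 400) / (0.7 * 2 + 0.3 * 20)
        assert fit.tau_weighted == pytest.approx(expect, rel=1e-3)


class TestLifetimesReport:
    def test_lifetime_is_reciprocal_rate(self):
        table = fh.lifetimes_report([
            {"condition": "zero", "system": "PW", "k1": 0.25, "k2": 0.5,
             "k2p": 0.01, "tau_C": 30.0}])
        assert table["zeta_ps"].iloc[0] == pytest.approx(4.0)
        assert table["tau_C_ps"].iloc[0] == 30.0

    def test_zero_rate_gives_infinite_lifetime(self):
        table = fh.lifetimes_report([{"k1": 0.0}])
        assert np.isinf(table["zeta_ps"].iloc[0])
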
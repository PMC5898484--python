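"""K_D isotherm fitting, the k_off = K_D k_on identity, and the avidity
birth-death model against a Gillespie oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nupfret as nf
from nupfret.binding import AvidityModel, BindingIsotherm, TitrationSeries
from oracles import gillespie_first_passage


def _exact_series(kd, concs, n=2000):
    concs = np.asarray(concs, float)
    return TitrationSeries(concs, concs / (concs + kd), np.full(concs.size, n))


WT_CONCS = [5e-9, 1e-8, 2e-8, 4e-8, 8e-8, 1.5e-7, 3e-7, 5e-7]


class TestFitKd:
    @pytest.mark.parametrize("kd", [35e-9, 222e-9])
    def test_exact_isotherm_recovered(self, kd):
        res = nf.fit_kd(_exact_series(kd, np.array(WT_CONCS) * (kd / 35e-9)))
        assert res.kd == pytest.approx(kd, rel=1e-6)

    def test_midpoint_fraction(self):
        kd = 50e-9
        ser = _exact_series(kd, [5e-9, 2e-8, kd, 2e-7, 1e-6])
        i = list(ser.ntr_conc).index(kd)
        assert ser.fraction_bound[i] == pytest.approx(0.5)

    def test_round_trip_recovery_unbiased(self):
        """K_D from simulated titrations is unbiased within 3 SEM over 20 seeds."""
        est = np.array([
            nf.fit_kd(nf.simulate_titration(35e-9, WT_CONCS, 2000, seed=s)).kd
            for s in range(20)
        ])
        sem = est.std(ddof=1) / np.sqrt(20)
        assert abs(est.mean() - 35e-9) < 3 * sem + 0.005 * 35e-9

    def test_scale_equivariance(self):
        """Scaling concentrations and K_D together leaves the fit ratio fixed."""
        base = nf.fit_kd(_exact_series(35e-9, WT_CONCS)).kd
        lam = 7.3
        scaled = nf.fit_kd(_exact_series(35e-9 * lam, np.array(WT_CONCS) * lam)).kd
        assert scaled / base == pytest.approx(lam, rel=1e-6)

    def test_saturated_series_non_identifiable(self):
        concs = np.array([1e-6, 3e-6, 1e-5, 3e-5])
        ser = TitrationSeries(concs, np.array([0.999, 0.9995, 0.9999, 1.0]),
                              np.full(4, 2000))
        with pytest.raises(ValueError, match="identifiable"):
            BindingIsotherm(ser)

    def test_needs_a_decade_span(self):
        concs = np.array([1e-8, 2e-8, 3e-8, 4e-8])
        ser = TitrationSeries(concs, concs / (concs + 35e-9), np.full(4, 2000))
        with pytest.raises(ValueError, match="decade"):
            BindingIsotherm(ser)


class TestKoffFromKd:
    def test_naive_estimate(self):
        """100 nM at 1e7 1/(M s) gives the textbook 1 1/s dissociation rate."""
        assert nf.koff_from_kd(100e-9, 1e7) == pytest.approx(1.0)

    def test_zero_kd(self):
        assert nf.koff_from_kd(0.0, 1e7) == 0.0

    def test_round_trip_with_titration(self):
        k_on = 4e7
        kd = 35e-9
        fit = nf.fit_kd(nf.simulate_titration(kd, WT_CONCS, 2000, seed=3))
        assert nf.koff_from_kd(fit.kd, k_on) == pytest.approx(k_on * kd, rel=0.1)


class TestAvidityModel:
    def test_single_site_limit(self):
        m = AvidityModel(1, 1e7, 3.3, c_local=0.05)
        assert m.global_koff("single_bond") == pytest.approx(3.3, rel=1e-12)
        assert m.global_koff("quasi_stationary") == pytest.approx(3.3, rel=1e-9)

    def test_no_rebinding_limit(self):
        """c_local = 0: pure death chain, single-bond start leaves at k_off_ind."""
        m = AvidityModel(6, 1e7, 2.0, c_local=0.0)
        assert m.global_koff("single_bond") == pytest.approx(2.0, rel=1e-12)
        assert m.global_koff("quasi_stationary") == pytest.approx(2.0, rel=1e-9)

    def test_mfpt_matches_gillespie(self):
        """N = 5, balanced rates: MFPT within 3 SEM of 1e5 stochastic runs."""
        k = 1e6
        m = AvidityModel(5, 1.0, k, c_local=k)  # k_on_ind * c_local = k_off_ind
        t_mc = gillespie_first_passage(5, k, k, n_runs=100_000, start_state=1, seed=0)
        t_model = m.mean_first_passage_times()[0]
        sem = t_mc.std(ddof=1) / np.sqrt(t_mc.size)
        assert abs(t_mc.mean() - t_model) < 3 * sem

    @pytest.mark.parametrize("n", [2, 4, 8, 10])
    def test_mfpt_matches_gillespie_across_n(self, n):
        m = AvidityModel(n, 1.0, 1.0, c_local=0.5)
        t_mc = gillespie_first_passage(n, 0.5, 1.0, n_runs=20_000, start_state=1, seed=n)
        sem = t_mc.std(ddof=1) / np.sqrt(t_mc.size)
        assert abs(t_mc.mean() - m.mean_first_passage_times()[0]) < 3 * sem

    def test_monotone_in_koff_ind(self):
        base = AvidityModel(5, 1e6, 1e3, c_local=1e-3)
        rates = [base.with_koff_ind(k).global_koff() for k in [1e2, 1e3, 1e4, 1e5]]
        assert np.all(np.diff(rates) > 0)

    def test_monotone_decreasing_in_c_local_and_n(self):
        by_c = [AvidityModel(5, 1e6, 1e3, c_local=c).global_koff()
                for c in [1e-5, 1e-4, 1e-3, 1e-2]]
        assert np.all(np.diff(by_c) < 0)
        by_n = [AvidityModel(n, 1e6, 1e3, c_local=1e-3).global_koff()
                for n in [1, 2, 4, 8]]
        assert np.all(np.diff(by_n) < 0)

    def test_invert_identity_at_n1(self):
        m = AvidityModel(1, 1e7, 1.0)
        assert m.invert_koff_individual(8.7) == pytest.approx(8.7, rel=1e-6)

    def test_invert_round_trip_random_models(self):
        """invert(global(m)) returns k_off_ind for 100 random models."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            # keep the rebinding ratio <= 10 so the avidity amplification
            # stays inside the inverter's documented 1e12 search bracket
            m = AvidityModel(n, 10 ** rng.uniform(5, 7), 10 ** rng.uniform(4, 7),
                             c_local=10 ** rng.uniform(-4, -2))
            k_glob = m.global_koff()
            rec = m.invert_koff_individual(k_glob)
            assert rec == pytest.approx(m.k_off_ind, rel=1e-5)

    def test_receptor_scale_inversion_amplifies(self):
        """A multivalent complex dissociating globally at 8.7 1/s implies a
        per-motif rate orders of magnitude higher under strong rebinding."""
        m = AvidityModel(8, 1e8, 1.0, c_local=0.05)  # strong local rebinding
        k_ind = m.invert_koff_individual(8.7)
        assert k_ind > 100 * 8.7

    def test_quasi_stationary_slower_than_single_bond(self):
        # from the QSD most probability sits at high occupancy: slower exit
        m = AvidityModel(5, 1.0, 1e6, c_local=1e6)
        assert m.global_koff("quasi_stationary") < m.global_koff("single_bond")

    def test_log_domain_matches_linear(self):
        m = AvidityModel(4, 1e8, 1e5, c_local=0.05)
        assert m.global_koff(log_domain=True) == pytest.approx(m.global_koff(), rel=1e-6)


class TestKdIndividual:
    def test_half_occupancy(self):
        assert nf.kd_individual_from_fractions(0.5, 2e-4) == pytest.approx(2e-4)

    def test_brackets_submillimolar_range(self):
        """At c_eff = 0.2 mM, occupancies 0.22-0.67 map onto K_D 0.1-0.7 mM."""
        lo = nf.kd_individual_from_fractions(0.67, 2e-4)
        hi = nf.kd_individual_from_fractions(0.22, 2e-4)
        assert lo == pytest.approx(1e-4, rel=0.02)
        assert hi == pytest.approx(7.1e-4, rel=0.02)

    @given(st.floats(0.05, 0.95), st.floats(0.1, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_in_occupancy(self, f1, f2):
        c = 2e-4
        k1 = nf.kd_individual_from_fractions(f1, c)
        k2 = nf.kd_individual_from_fractions(f2, c)
        assert (f1 < f2) == (k1 > k2) or f1 == f2

    def test_boundary_fractions_rejected(self):
        with pytest.raises(ValueError):
            nf.kd_individual_from_fractions(0.0, 1e-4)
        with pytest.raises(ValueError):
            nf.kd_individual_from_fractions(1.0, 1e-4)
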
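"""Burst search, E/S computation, histograms and population splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nupfret as nf
from nupfret.bursts import DEFAULT_E_EDGES, ESPoints, find_bursts


class TestFindBursts:
    def test_empty_stream(self):
        assert len(find_bursts(np.array([]), np.array([]))) == 0

    def test_single_dense_cluster(self):
        """100 photons inside 1 ms and nothing else: exactly one 100-photon burst."""
        times = np.linspace(10.0, 11.0, 100)
        channels = np.zeros(100, int)
        bursts = find_bursts(times, channels, window_ms=0.5, min_rate=20, min_total=50)
        assert len(bursts) == 1
        assert bursts.totals[0] == 100

    def test_sparse_background_yields_nothing(self):
        """Uniform Poisson background far below min_rate triggers no bursts."""
        rng = np.random.default_rng(0)
        # 2 photons/ms over 1 s: P(>=20 in any 0.5 ms window) is astronomically small
        times = np.sort(rng.uniform(0, 1000.0, size=2000))
        bursts = find_bursts(times, np.zeros(2000, int))
        assert len(bursts) == 0

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            find_bursts(np.array([2.0, 1.0]), np.array([0, 0]))

    def test_channel_counts_partition_burst(self):
        times = np.linspace(0.0, 1.0, 90)
        channels = np.tile([0, 1, 2], 30)
        bursts = find_bursts(times, channels, min_total=50)
        assert len(bursts) == 1
        assert bursts.n_donor_dex[0] == bursts.n_acceptor_dex[0] == bursts.n_acceptor_aex[0] == 30


class TestComputeES:
    def test_raw_arithmetic(self):
        """60/40/100 photons with unit corrections give E = 0.6, S = 0.5."""
        burst = nf.PhotonBurst(n_donor_dex=40, n_acceptor_dex=60, n_acceptor_aex=100)
        pts = nf.compute_es(burst)
        assert pts.e[0] == pytest.approx(0.6)
        assert pts.s[0] == pytest.approx(0.5)

    def test_donor_only_stoichiometry(self):
        pts = nf.compute_es(nf.PhotonBurst(50, 5, 0))
        assert pts.s[0] == pytest.approx(1.0)

    def test_acceptor_only_stoichiometry(self):
        pts = nf.compute_es(nf.PhotonBurst(0, 1, 80))
        assert pts.s[0] == pytest.approx(1 / 81)

    def test_zero_denominator_flagged_not_dropped(self):
        pts = nf.compute_es(nf.PhotonBurst(0, 0, 80))
        assert len(pts) == 1
        assert not pts.valid[0]

    def test_corrections_recover_true_efficiency(self):
        """Generator + matching corrections invert to the true E on average."""
        corr = nf.CorrectionFactors(gamma=1.3, alpha=0.05, delta=0.04)
        species = [nf.FretSpecies(0.6, 1.0)]
        bursts = nf.simulate_bursts(
            species, nf.BurstGenConfig(n_bursts=4000, seed=2, corrections=corr))
        pts = nf.compute_es(bursts, corr)
        assert np.nanmean(pts.e[pts.valid]) == pytest.approx(0.6, abs=0.01)

    def test_raw_proximity_ratio_in_unit_interval(self, contaminated_mixture_bursts):
        pts = nf.compute_es(contaminated_mixture_bursts)
        sel = pts.selected()
        assert ((sel.e >= 0) & (sel.e <= 1)).all()
        assert ((sel.s >= 0) & (sel.s <= 1)).all()


class TestHistogramAndSelection:
    def test_histogram_conserves_points(self, contaminated_mixture_bursts):
        pts = nf.compute_es(contaminated_mixture_bursts)
        hist2d, e_edges, s_edges, _ = nf.build_es_histogram(pts)
        sel = pts.selected()
        in_range = (
            (sel.e >= e_edges[0]) & (sel.e <= e_edges[-1])
            & (sel.s >= s_edges[0]) & (sel.s <= s_edges[-1])
        ).sum()
        assert hist2d.sum() == in_range

    def test_identical_points_single_cell(self):
        pts = ESPoints(np.full(40, 0.45), np.full(40, 0.5), np.ones(40, bool))
        hist2d, *_ = nf.build_es_histogram(pts)
        assert hist2d.max() == 40
        assert (hist2d > 0).sum() == 1

    def test_two_modes_in_s_slice(self, clean_mixture_bursts):
        """The S ~ 0.5 slice resolves modes at the generator's efficiencies."""
        pts = nf.compute_es(clean_mixture_bursts)
        _, e_edges, _, marginal = nf.build_es_histogram(pts)
        centers = 0.5 * (e_edges[:-1] + e_edges[1:])
        lo = marginal.copy()
        lo[centers > 0.4] = 0
        hi = marginal.copy()
        hi[centers <= 0.4] = 0
        width = e_edges[1] - e_edges[0]
        assert abs(centers[np.argmax(lo)] - 0.2) <= 1.5 * width
        assert abs(centers[np.argmax(hi)] - 0.6) <= 1.5 * width

    def test_select_all_donor_only_empty(self):
        pts = ESPoints(np.zeros(50), np.full(50, 0.98), np.ones(50, bool))
        with pytest.warns(UserWarning, match="no bursts"):
            sel = nf.select_fret_species(pts)
        assert len(sel) == 0

    def test_select_window_identity(self, clean_mixture_bursts):
        pts = nf.compute_es(clean_mixture_bursts).selected()
        sel = nf.select_fret_species(pts, (0.0, 1.0))
        assert len(sel) == len(pts)

    def test_contaminant_rejection_rate(self):
        """20% donor-only + 80% double-labelled: ~80% survive the S window."""
        species = nf.two_state_species(fraction_bound=0.5, donor_only=0.2)
        bursts = nf.simulate_bursts(species, nf.BurstGenConfig(n_bursts=5000, seed=13))
        pts = nf.compute_es(bursts)
        sel = nf.select_fret_species(pts)
        assert len(sel) / len(pts) == pytest.approx(0.8, abs=0.03)


class TestSplitPopulations:
    def test_all_below_boundary(self):
        pts = ESPoints(np.full(30, 0.1), np.full(30, 0.5), np.ones(30, bool))
        assert nf.split_populations(pts).fraction_bound == 1.0

    @pytest.mark.parametrize("frac_bound", [0.3, 0.5])
    def test_generator_fraction_recovery(self, frac_bound):
        species = [nf.FretSpecies(0.6, 1 - frac_bound), nf.FretSpecies(0.2, frac_bound)]
        bursts = nf.simulate_bursts(species, nf.BurstGenConfig(n_bursts=5000, seed=21))
        sel = nf.select_fret_species(nf.compute_es(bursts))
        split = nf.split_populations(sel)
        sd = np.sqrt(frac_bound * (1 - frac_bound) / len(sel))
        assert abs(split.fraction_bound - frac_bound) < 3 * sd + 0.01

    def test_threshold_permutation_invariant(self, clean_mixture_bursts):
        pts = nf.select_fret_species(nf.compute_es(clean_mixture_bursts))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pts))
        shuffled = ESPoints(pts.e[perm], pts.s[perm], pts.valid[perm])
        assert (nf.split_populations(shuffled).fraction_bound
                == nf.split_populations(pts).fraction_bound)

    def test_two_gaussian_matches_threshold_on_resolved_mixture(self, clean_mixture_bursts):
        sel = nf.select_fret_species(nf.compute_es(clean_mixture_bursts))
        thr = nf.split_populations(sel, "threshold")
        gmm = nf.split_populations(sel, "two_gaussian")
        assert gmm.method == "two_gaussian"
        assert gmm.fraction_bound == pytest.approx(thr.fraction_bound, abs=0.03)
        assert gmm.components["mu_low"] == pytest.approx(0.2, abs=0.03)
        assert gmm.components["mu_high"] == pytest.approx(0.6, abs=0.03)

    def test_two_gaussian_degenerate_falls_back(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0.55, 0.05, 400)
        pts = ESPoints(e, np.full(400, 0.5), np.ones(400, bool))
        split = nf.split_populations(pts, "two_gaussian")
        assert split.method == "threshold"

    def test_too_few_points_rejected(self):
        pts = ESPoints(np.full(10, 0.5), np.full(10, 0.5), np.ones(10, bool))
        with pytest.raises(ValueError, match="20"):
            nf.split_populations(pts)


class TestUnbiasedFractionRecovery:
    def test_threshold_unbiased_across_seeds(self):
        """Recovered bound fraction is unbiased within Monte-Carlo error over 20 seeds."""
        truth = 0.3
        species = [nf.FretSpecies(0.6, 1 - truth), nf.FretSpecies(0.2, truth)]
        est = []
        for seed in range(20):
            bursts = nf.simulate_bursts(species, nf.BurstGenConfig(n_bursts=2000, seed=seed))
            sel = nf.select_fret_species(nf.compute_es(bursts))
            est.append(nf.split_populations(sel).fraction_bound)
        est = np.asarray(est)
        sem = est.std(ddof=1) / np.sqrt(len(est))
        # small positive bias ~ P(unbound burst below 0.4) is part of the method
        assert abs(est.mean() - truth) < 3 * sem + 0.01


@given(st.floats(0.05, 0.95), st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_raw_es_always_in_unit_interval(e_true, seed):
    """Uncorrected proximity ratio and stoichiometry never leave [0, 1]."""
    bursts = nf.simulate_bursts(
        [nf.FretSpecies(e_true, 1.0)], nf.BurstGenConfig(n_bursts=50, seed=seed))
    pts = nf.compute_es(bursts).selected()
    assert ((pts.e >= 0) & (pts.e <= 1)).all()
    assert ((pts.s >= 0) & (pts.s <= 1)).all()
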
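"""γH2Ax quantifications: binning, normalization, correlation, statistics."""

import numpy as np
import pytest
from scipy import stats

from contactddr.ddr import (
    asymmetry_index,
    bin_signal,
    call_domains,
    correlate_tracks,
    cross_border_fraction,
    fisher_overlap,
    normalize_to_dsb_bin,
    paired_t_test,
    subtraction_track,
)
from contactddr.genome import BinGrid, CoverageTrack, GenomicInterval
from contactddr.simulate import (
    GammaForwardModel,
    SimulationConfig,
    expected_contacts,
    generating_profile,
    sample_matrix,
    scenario_suite,
    simulate_gammax,
)


def track(values, bin_width=10_000, chrom="chrT", units="raw_count"):
    v = np.asarray(values, dtype=float)
    grid = BinGrid(chrom, 0, len(v) * bin_width, bin_width)
    return CoverageTrack(grid, v, units=units)


class TestBinSignal:
    def test_identity_at_source_width(self):
        t = track([1, 2, 3])
        np.testing.assert_array_equal(bin_signal(t, 10_000).values, t.values)

    def test_mean_of_constituents(self):
        t = track([2, 4, 6, 8])
        np.testing.assert_array_equal(bin_signal(t, 20_000).values, [3, 7])

    def test_truncated_final_bin_uses_available_bins(self):
        t = track([2, 4, 6])
        out = bin_signal(t, 20_000)
        np.testing.assert_array_equal(out.values, [3, 6])

    def test_non_multiple_width_rejected(self):
        with pytest.raises(ValueError):
            bin_signal(track([1, 2, 3]), 15_000)


class TestNormalizeToDsbBin:
    def test_division_and_unit_at_dsb(self):
        t = track([2, 4, 8])
        out = normalize_to_dsb_bin(t, GenomicInterval("chrT", 10_000, 20_000))
        np.testing.assert_allclose(out.values, [0.5, 1, 2])

    def test_constant_track_all_ones(self):
        t = track([5, 5, 5, 5])
        out = normalize_to_dsb_bin(t, GenomicInterval("chrT", 0, 10_000))
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_dsb_bin_rejected(self):
        t = track([0, 1, 2])
        with pytest.raises(ValueError):
            normalize_to_dsb_bin(t, GenomicInterval("chrT", 0, 10_000))


class TestCorrelateTracks:
    def test_self_correlation_one(self, rng):
        t = track(rng.poisson(20, size=30))
        assert correlate_tracks(t, t).r == pytest.approx(1.0)

    def test_anticorrelation_minus_one(self, rng):
        v = rng.poisson(20, size=30).astype(float)
        a = track(v)
        b = track(100 - v)
        assert correlate_tracks(a, b).r == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        v = rng.poisson(20, size=30).astype(float) + 1
        a, b = track(v), track(rng.poisson(20, size=30).astype(float) + 1)
        r1 = correlate_tracks(a, b).r
        r2 = correlate_tracks(track(3 * v + 7), b).r
        assert r1 == pytest.approx(r2)

    def test_simulated_gamma_vs_generating_v4c(self):
        cfg = SimulationConfig(scenario="dsb", dsb_position=2_000_000)
        m = sample_matrix(expected_contacts(cfg), 3)
        v = generating_profile(m, cfg.dsb_interval())
        noise_free = simulate_gammax(
            m, cfg.dsb_interval(), GammaForwardModel(background=0.0, noise_mode="none"), 0
        )
        assert correlate_tracks(noise_free, v).r == pytest.approx(1.0)
        noisy = simulate_gammax(
            m, cfg.dsb_interval(), GammaForwardModel(background=0.0), 4
        )
        assert correlate_tracks(noisy, v).r >= 0.9

    def test_rebin_over_interval(self):
        a = track([0, 0, 2, 4, 6, 8, 10, 13])
        b = track([0, 0, 4, 8, 12, 16, 20, 26])
        iv = GenomicInterval("chrT", 20_000, 80_000)
        res = correlate_tracks(a, b, iv, 20_000)
        assert res.n_bins == 3 and res.r == pytest.approx(1.0)

    def test_interval_with_too_few_target_bins_rejected(self):
        a = track([1, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError):
            correlate_tracks(a, a, GenomicInterval("chrT", 0, 40_000), 20_000)

    def test_too_few_bins_rejected(self):
        a = track([1, 2])
        with pytest.raises(ValueError):
            correlate_tracks(a, a)


class TestSubtraction:
    def test_identical_groups_zero(self, rng):
        t = track(rng.poisson(10, size=20))
        d = subtraction_track([t, t], [t])
        np.testing.assert_array_equal(d.values, 0.0)
        assert d.units == "delta"

    def test_single_track_groups_plain_difference(self):
        a, b = track([3, 5, 7]), track([1, 1, 1])
        np.testing.assert_array_equal(subtraction_track([a], [b]).values, [2, 4, 6])

    def test_group_means(self):
        a1, a2 = track([2, 4]), track([4, 8])
        b1, b2 = track([1, 1]), track([3, 3])
        np.testing.assert_array_equal(
            subtraction_track([a1, a2], [b1, b2]).values, [1, 4]
        )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtraction_track([track([1, 2])], [track([1, 2, 3])])


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.p == 1

    def test_constant_nonzero_difference_edge(self):
        res = paired_t_test([1, 2, 3], [2, 3, 4])
        assert res.p == 0 and res.statistic == float("-inf")

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([1.5, 2, 4, 5])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(d) - 1)
        res = paired_t_test(a, b)
        assert res.statistic == pytest.approx(t_hand)
        assert res.p == pytest.approx(p_hand)

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        hits = sum(
            paired_t_test(rng.normal(size=50), rng.normal(size=50)).p < 0.05
            for _ in range(1000)
        )
        assert 0.035 <= hits / 1000 <= 0.065


class TestCallDomains:
    def test_signal_equals_control_no_domains(self, rng):
        v = rng.poisson(30, size=100).astype(float)
        call = call_domains(track(v), track(v))
        assert call.intervals == []

    def test_planted_domain_recovered(self, rng):
        n = 200
        ctl = rng.poisson(20, size=n).astype(float)
        sig = rng.poisson(20, size=n).astype(float)
        sig[80:110] = rng.poisson(200, size=30)
        call = call_domains(track(sig), track(ctl))
        assert len(call.intervals) == 1
        iv = call.intervals[0]
        lo, hi = iv.start // 10_000, iv.end // 10_000
        covered = max(0, min(hi, 110) - max(lo, 80))
        assert covered >= 27  # >= 90% of the planted 30 bins
        assert call.fold[0] > 4 and call.p[0] < 1e-3

    def test_library_scale_invariance(self, rng):
        n = 150
        ctl = rng.poisson(20, size=n).astype(float)
        sig = rng.poisson(20, size=n).astype(float)
        sig[50:70] = rng.poisson(180, size=20)
        c1 = call_domains(track(sig), track(ctl))
        c2 = call_domains(track(sig * 2), track(ctl * 2))
        assert [iv.start for iv in c1.intervals] == [iv.start for iv in c2.intervals]
        assert [iv.end for iv in c1.intervals] == [iv.end for iv in c2.intervals]

    def test_all_zero_inputs_empty(self):
        z = track(np.zeros(50))
        assert call_domains(z, z).intervals == []


class TestFisherOverlap:
    def _ivs(self, bins, bin_width=10_000):
        return [
            GenomicInterval("chrT", b * bin_width, (b + 1) * bin_width) for b in bins
        ]

    def test_identical_half_grid_association(self):
        grid = BinGrid("chrT", 0, 400_000, 10_000)
        a = self._ivs(range(20))
        res = fisher_overlap(a, a, grid)
        assert res.p < 0.01

    def test_disjoint_covering_sets_odds_zero(self):
        grid = BinGrid("chrT", 0, 100_000, 10_000)
        a = self._ivs(range(5))
        b = self._ivs(range(5, 10))
        res = fisher_overlap(a, b, grid)
        assert res.statistic == 0.0

    def test_matches_scipy_on_random_tables(self, rng):
        # independent cross-check of the integer-combinatorics p against scipy
        from contactddr.ddr import fisher_exact_two_sided

        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            _, p_mine = fisher_exact_two_sided(a, b, c, d)
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert p_mine == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)

    def test_table_3113_matches_enumeration(self):
        grid = BinGrid("chrT", 0, 80_000, 10_000)
        a = self._ivs([0, 1, 2, 3])  # A = bins 0-3
        b = self._ivs([0, 1, 2, 4])  # B: 3 overlap, 1 only-B
        res = fisher_overlap(a, b, grid)
        # table [[3,1],[1,3]]: enumerate all tables with fixed margins
        p_exact = _exhaustive_fisher(3, 1, 1, 3)
        assert res.p == pytest.approx(p_exact, abs=1e-12)


def _exhaustive_fisher(a, b, c, d):
    """Two-sided Fisher p by brute-force enumeration with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {
        x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-10)))


class TestAsymmetryIndex:
    def test_mirror_symmetric_track_zero(self):
        v = np.array([0, 1, 3, 9, 3, 1, 0], dtype=float)
        t = track(v)
        res = asymmetry_index(t, GenomicInterval("chrT", 30_000, 40_000), 0.5)
        assert res.A == pytest.approx(0.0)

    def test_all_mass_downstream_is_one(self):
        v = np.array([0, 0, 5, 9, 8, 7, 6], dtype=float)
        t = track(v)
        res = asymmetry_index(t, GenomicInterval("chrT", 20_000, 30_000), 1.0)
        assert res.A == pytest.approx(1.0)
        assert res.mass_up == 0.0

    def test_flat_subthreshold_track_zero(self):
        t = track(np.full(9, 0.1))
        res = asymmetry_index(t, GenomicInterval("chrT", 40_000, 50_000), 1.0)
        assert res.A == 0.0 and res.mass_up == res.mass_down == 0.0

    def test_scenario_contrast_mid_vs_border_proximal(self):
        # mid-TAD break: balanced spread; near-border break: skewed spread
        for seed in (0, 1, 2):
            suite = scenario_suite(seed=seed)
            mid = suite["mid_tad_dsb"]
            prox = suite["border_proximal_dsb"]
            bg_m = float(np.median(mid.controls["hic"].values))
            bg_p = float(np.median(prox.controls["hic"].values))
            a_mid = asymmetry_index(mid.gammax["hic"], mid.config.dsb_interval(), bg_m)
            a_prox = asymmetry_index(
                prox.gammax["hic"], prox.config.dsb_interval(), bg_p
            )
            assert abs(a_mid.A) <= 0.2
            assert abs(a_prox.A) > abs(a_mid.A) + 0.2


class TestCrossBorderFraction:
    def test_confined_track_fraction_one(self):
        v = np.zeros(10)
        v[2:4] = 5
        t = track(v)
        tads = [
            GenomicInterval("chrT", 0, 50_000),
            GenomicInterval("chrT", 50_000, 100_000),
        ]
        fr = cross_border_fraction(
            t, GenomicInterval("chrT", 20_000, 30_000), tads, 0.0
        )
        assert fr == pytest.approx([1.0, 0.0])

    def test_fractions_sum_to_one_when_tads_tile(self, rng):
        v = rng.poisson(10, size=10).astype(float)
        t = track(v)
        tads = [
            GenomicInterval("chrT", 0, 30_000),
            GenomicInterval("chrT", 30_000, 100_000),
        ]
        fr = cross_border_fraction(t, GenomicInterval("chrT", 0, 10_000), tads, 1.0)
        assert sum(fr) == pytest.approx(1.0)

    def test_zero_mass_all_zero(self):
        t = track(np.zeros(10))
        tads = [GenomicInterval("chrT", 0, 100_000)]
        fr = cross_border_fraction(t, GenomicInterval("chrT", 0, 10_000), tads, 1.0)
        assert fr == [0.0]

    def test_border_dsb_spreads_into_both_tads(self):
        for seed in (0, 1, 2):
            suite = scenario_suite(seed=seed)
            sc = suite["border_dsb"]
            cfg = sc.config
            grid = cfg.grid
            tads = [
                GenomicInterval(cfg.chrom, grid.bin_start(sl.start),
                                grid.bin_end(sl.stop - 1))
                for sl in cfg.tad_slices()
            ]
            bg = float(np.median(sc.controls["hic"].values))
            fr = cross_border_fraction(sc.gammax["hic"], cfg.dsb_interval(), tads, bg)
            ti = sc.truth["tad_index"]
            assert fr[ti] >= 0.25 and fr[ti - 1] >= 0.25


class TestEndToEndContrasts:
    def test_ctcf_deletion_recovery(self):
        # planted intra-TAD contact reduction surfaces as significant γ loss
        # in the targeted TAD and nothing in the neighbor
        rej_in, rej_nb = 0, 0
        for seed in range(6):
            suite = scenario_suite(seed=seed)
            sc = suite["ctcf_deletion"]
            dsb = sc.config.dsb_interval()
            wt = normalize_to_dsb_bin(sc.gammax["wt"], dsb)
            ko = normalize_to_dsb_bin(sc.gammax["ko"], dsb)
            sls = sc.config.tad_slices()
            ti, nb = sc.truth["reduced_tad"], sc.truth["neighbor_tad"]
            p_in = paired_t_test(wt.values[sls[ti]], ko.values[sls[ti]]).p
            p_nb = paired_t_test(wt.values[sls[nb]], ko.values[sls[nb]]).p
            rej_in += p_in < 0.05
            rej_nb += p_nb < 0.05
            # direction: WT carries more γ than KO in the reduced TAD
            assert wt.values[sls[ti]].mean() > ko.values[sls[ti]].mean()
        assert rej_in == 6
        assert rej_nb <= 1

    def test_border_vs_promoter_within_tad_profiles_near_identical(self):
        # the two breaks sit one bin apart; within the shared TAD their
        # normalized profiles are near-identical (the real-data claim), while
        # the neighbor TAD separates them sharply. A raw paired t-test can
        # detect the one-bin discretization offset, so similarity is asserted
        # directly.
        rej_nb = 0
        for seed in range(6):
            suite = scenario_suite(seed=seed)
            gb = normalize_to_dsb_bin(
                suite["border_dsb"].gammax["hic"],
                suite["border_dsb"].config.dsb_interval(),
            )
            gp = normalize_to_dsb_bin(
                suite["border_proximal_dsb"].gammax["hic"],
                suite["border_proximal_dsb"].config.dsb_interval(),
            )
            sls = suite["border_dsb"].config.tad_slices()
            ti = suite["border_dsb"].truth["tad_index"]
            # within-TAD profiles compared at equal distance from each break
            # (the real breaks are sub-bin apart; aligning on the break undoes
            # the one-bin discretization offset): near-identical shape + level
            bb = suite["border_dsb"].truth["dsb_bin"]
            pb = suite["border_proximal_dsb"].truth["dsb_bin"]
            k = sls[ti].stop - pb - 1
            a = gb.values[bb + 1 : bb + 1 + k]
            b = gp.values[pb + 1 : pb + 1 + k]
            assert np.corrcoef(a, b)[0, 1] > 0.98
            assert abs(a.mean() - b.mean()) / b.mean() < 0.15
            p_nb = paired_t_test(gb.values[sls[ti - 1]], gp.values[sls[ti - 1]]).p
            rej_nb += p_nb < 0.05
        assert rej_nb == 6
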
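"""Ground-truth generators: determinism, analytic expectations, recovery."""

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from fretkit import (
    FlimCellSpec,
    ImageCellSpec,
    MaturationScenario,
    area_normalize,
    expected_decay_counts,
    flim_fret_efficiency,
    gen_cohort_timeseries,
    gen_emission_scan,
    gen_flim_stack,
    gen_spectrum,
    gen_tcspc_decay,
    gen_two_channel_image,
    linear_unmix,
    spectral_fret_efficiency,
    sum_roi_decay,
    tail_fit,
    tandem_scenario,
)


class TestGenSpectrum:
    def test_symmetric_when_unskewed(self):
        s = gen_spectrum(550, 10, skew=0.0)
        peak_idx = np.argmax(s.values)
        left = s.values[:peak_idx][::-1]
        right = s.values[peak_idx + 1 :]
        m = min(left.size, right.size)
        np.testing.assert_allclose(left[:m], right[:m], rtol=1e-9)

    @pytest.mark.parametrize("skew", [-4.0, 0.0, 4.0])
    def test_peak_lands_on_requested_wavelength(self, skew):
        s = gen_spectrum(593, 18, skew=skew)
        assert abs(s.peak_wavelength_nm - 593) <= 1.0

    def test_area_normalizes_cleanly(self):
        s = area_normalize(gen_spectrum(517, 15, skew=3))
        assert abs(s.integral() - 1.0) < 1e-9

    def test_deterministic(self):
        a = gen_spectrum(517, 15, skew=3)
        b = gen_spectrum(517, 15, skew=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestGenEmissionScan:
    def test_zero_efficiency_pure_donor(self, donor_emission, acceptor_emission):
        scan = gen_emission_scan(0.0, donor_emission, acceptor_emission, 0.8, 0.54)
        # no intensity in the far-red acceptor region
        assert scan.intensities[scan.wavelengths_nm > 680].max() < 1e-9

    def test_roundtrip_recovers_thirty_percent(
        self, donor_emission, acceptor_emission, donor_ref, acceptor_ref
    ):
        scan = gen_emission_scan(0.30, donor_emission, acceptor_emission, 0.8, 0.54)
        res = linear_unmix(scan, donor_ref, acceptor_ref)
        assert spectral_fret_efficiency(res, 0.8, 0.54) == pytest.approx(30.0, abs=1e-9)

    def test_direct_excitation_biases_upward(
        self, donor_emission, acceptor_emission, donor_ref, acceptor_ref
    ):
        def recovered(direct):
            scan = gen_emission_scan(
                0.30, donor_emission, acceptor_emission, 0.8, 0.54,
                direct_excitation_fraction=direct,
            )
            return spectral_fret_efficiency(
                linear_unmix(scan, donor_ref, acceptor_ref), 0.8, 0.54
            )

        assert recovered(0.1) > recovered(0.0) + 1.0


class TestGenTcspcDecay:
    def test_expected_counts_match_closed_form(self):
        bins, rng_ns, tau = 64, 12.5, 3.05
        t, counts = expected_decay_counts((tau,), (1.0,), 1e5, bins, rng_ns)
        edges = np.linspace(0, rng_ns, bins + 1)
        raw = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        oracle = 1e5 * raw / (1 - np.exp(-rng_ns / tau))
        np.testing.assert_allclose(counts, oracle, rtol=1e-12)
        assert counts.sum() == pytest.approx(1e5, rel=1e-12)

    def test_total_counts_match_budget_on_average(self):
        totals = [
            gen_tcspc_decay((3.0,), (1.0,), 5000, seed=s).total_counts
            for s in range(200)
        ]
        assert np.mean(totals) == pytest.approx(5000, rel=0.01)

    def test_huge_budget_end_to_end_recovery(self):
        d = gen_tcspc_decay((2.5,), (1.0,), 5e6, seed=1)
        fit = tail_fit(d)
        assert fit.tau_ns == pytest.approx(2.5, rel=0.005)

    def test_invalid_amplitude_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            gen_tcspc_decay((3.0, 1.0), (0.7, 0.6), 1e4, seed=0)

    def test_deterministic_given_seed(self):
        a = gen_tcspc_decay((3.0,), (1.0,), 1e4, seed=9)
        b = gen_tcspc_decay((3.0,), (1.0,), 1e4, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_background_fills_tail(self):
        d = gen_tcspc_decay((0.5,), (1.0,), 1e6, background_fraction=0.2, seed=2)
        tail = d.counts[-32:]
        assert tail.mean() > 0.5 * (0.2 * 1e6 / 256)


class TestGenFlimStack:
    def test_dark_cell_recovers_donor_lifetime(self, ruby_scenario):
        spec = FlimCellSpec((5.5, 5.5), (4.0, 4.0), 0.0, ruby_scenario)
        stack, truth = gen_flim_stack((12, 12), [spec], 2000, seed=3)
        decay = sum_roi_decay(stack, stack.intensity_image > 0, 0)
        fit = tail_fit(decay)
        assert fit.tau_ns == pytest.approx(3.05, rel=0.02)
        assert truth["E_app_expected_percent"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_mature_cell_recovers_roi_efficiency(self, ruby_scenario):
        spec = FlimCellSpec((5.5, 5.5), (4.0, 4.0), 1.0, ruby_scenario)
        stack, _ = gen_flim_stack((12, 12), [spec], 4000, seed=4)
        decay = sum_roi_decay(stack, stack.intensity_image > 0, 0)
        fit = tail_fit(decay)
        e = flim_fret_efficiency(fit.tau_ns, 3.05)
        assert e == pytest.approx(27.0, abs=2.5)

    def test_zero_cells_empty_stack(self):
        stack, truth = gen_flim_stack((8, 8), [], 1000, seed=0)
        assert stack.cube.sum() == 0
        assert truth.empty

    def test_overlapping_cells_rejected(self, ruby_scenario):
        specs = [
            FlimCellSpec((5.0, 5.0), (4.0, 4.0), 0.0, ruby_scenario),
            FlimCellSpec((6.0, 6.0), (4.0, 4.0), 1.0, ruby_scenario),
        ]
        with pytest.raises(ValueError, match="overlaps"):
            gen_flim_stack((12, 12), specs, 1000, seed=0)

    def test_bit_reproducible(self, ruby_scenario):
        spec = FlimCellSpec((5.5, 5.5), (4.0, 4.0), 0.5, ruby_scenario)
        s1, _ = gen_flim_stack((12, 12), [spec], 1000, seed=8)
        s2, _ = gen_flim_stack((12, 12), [spec], 1000, seed=8)
        np.testing.assert_array_equal(s1.cube, s2.cube)


class TestGenTwoChannelImage:
    def test_dark_acceptor_cohort_slopes_cluster_at_zero(self):
        specs = [
            ImageCellSpec((10, 10 + 16 * i), (5, 5), 300.0, 0.0, 0.27)
            for i in range(3)
        ]
        img, truth = gen_two_channel_image((20, 60), specs, background=5, seed=5)
        assert np.all(truth["true_slope"] == 0.0)

    def test_identical_cells_unimodal_near_true_slope(self):
        from fretkit import background_subtract, cell_intensity_slope, segment_cells

        specs = [
            ImageCellSpec((10, 10 + 16 * i), (5, 5), 100.0 + 150 * i, 1.0, 0.27)
            for i in range(4)
        ]
        img, truth = gen_two_channel_image((20, 76), specs, background=5, seed=6)
        labels = segment_cells(img, threshold=15, min_area=30)
        bg = background_subtract(img, labels)
        slopes = [
            cell_intensity_slope(bg, labels == c, min_pixels=30).slope
            for c in np.unique(labels[labels > 0])
        ]
        assert np.median(slopes) == pytest.approx(
            truth["true_slope"].iloc[0], rel=0.10
        )

    def test_cohort_contrast_distinguishable(self, rng):
        def cohort_slopes(alpha, beta, seed):
            r = np.random.default_rng(seed)
            fs = r.beta(alpha, beta, 6)
            specs = [
                ImageCellSpec((10, 10 + 14 * i), (5, 5), 300.0, f, 0.27)
                for i, f in enumerate(fs)
            ]
            _, truth = gen_two_channel_image((20, 100), specs, seed=seed)
            return truth["true_slope"].to_numpy()

        dark = cohort_slopes(0.5, 2.0, 1)
        mature = cohort_slopes(5.0, 1.0, 2)
        assert wasserstein_distance(dark, mature) > 0


class TestGenCohortTimeseries:
    def test_day_zero_all_unmatured(self, ruby_scenario):
        cohort = gen_cohort_timeseries(
            [0], ruby_scenario, cells_per_day=2, shape=(24, 24),
            cell_radius=(3.5, 3.5), per_pixel_photons=200, seed=1,
        )
        _, _, truth = cohort[0]
        assert np.all(truth["f"] == 0.0)
        assert truth["E_app_expected_percent"].abs().max() < 1e-6

    def test_increasing_days_increase_mean_apparent_efficiency(self):
        # effective in-cell maturation on the days scale
        slow = MaturationScenario(t_half_min=2880.0, E_true=0.27, tau_D_ns=3.05)
        cohort = gen_cohort_timeseries(
            [1, 3, 5], slow, cells_per_day=4, shape=(24, 24),
            cell_radius=(3.5, 3.5), per_pixel_photons=200, seed=2,
        )
        means = [truth["E_app_expected_percent"].mean() for _, _, truth in cohort]
        assert means[0] < means[1] < means[2]

    def test_same_seed_identical_cohort(self, ruby_scenario):
        kw = dict(
            cells_per_day=2, shape=(24, 24), cell_radius=(3.5, 3.5),
            per_pixel_photons=200, seed=7,
        )
        c1 = gen_cohort_timeseries([1, 2], ruby_scenario, **kw)
        c2 = gen_cohort_timeseries([1, 2], ruby_scenario, **kw)
        for (_, s1, t1), (_, s2, t2) in zip(c1, c2):
            np.testing.assert_array_equal(s1.cube, s2.cube)
            np.testing.assert_array_equal(t1["f"].to_numpy(), t2["f"].to_numpy())

    def test_scenario_lookup_by_acceptor(self):
        sc = tandem_scenario("mRuby3")
        assert sc.t_half_min == 136.5
        assert sc.tau_D_ns == 3.05
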
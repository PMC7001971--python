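"""TCSPC decay aggregation, tail fitting, and lifetime-ratio efficiency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretkit import (
    DecayCurve,
    FlimStack,
    expected_decay_counts,
    flim_fret_efficiency,
    framewise_lifetimes,
    gen_tcspc_decay,
    lifetime_map,
    model_select,
    photobleach_compare,
    read_decay,
    read_flim_stack,
    sum_roi_decay,
    tail_fit,
    write_decay,
    write_flim_stack,
)


class TestDecayCurve:
    def test_nonuniform_bins_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            DecayCurve(np.array([0.0, 1.0, 3.0]), np.ones(3))

    def test_fractional_counts_rejected_by_default(self):
        with pytest.raises(ValueError, match="integer"):
            DecayCurve(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.5, 0.0]))

    def test_csv_roundtrip(self, tmp_path):
        d = gen_tcspc_decay((3.05,), (1.0,), 1e4, seed=0)
        p = tmp_path / "d.csv"
        write_decay(d, p)
        back = read_decay(p)
        np.testing.assert_array_equal(back.counts, d.counts)


class TestSumRoiDecay:
    def _stack(self, rng, shape=(4, 5), bins=16):
        cube = rng.integers(0, 20, size=(*shape, bins))
        return FlimStack(cube, np.arange(bins) * 0.05 + 0.025)

    def test_single_pixel_identity(self, rng):
        stack = self._stack(rng)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[2, 3] = True
        out = sum_roi_decay(stack, mask, 0)
        np.testing.assert_array_equal(out.counts, stack.cube[2, 3])

    def test_two_identical_pixels_double(self):
        cube = np.zeros((2, 2, 8), dtype=int)
        cube[0, 0] = cube[1, 1] = np.arange(8)
        stack = FlimStack(cube, np.arange(8) * 0.1 + 0.05)
        mask = np.ones((2, 2), dtype=bool)
        out = sum_roi_decay(stack, mask, 0)
        np.testing.assert_array_equal(out.counts, 2 * np.arange(8))

    def test_matches_brute_force_loop(self, rng):
        """Element-wise triple loop over (y, x, t) as an independent oracle."""
        stack = self._stack(rng)
        mask = rng.random(stack.shape) > 0.4
        thr = 100.0
        expected = np.zeros(stack.cube.shape[2])
        for y in range(stack.shape[0]):
            for x in range(stack.shape[1]):
                if mask[y, x] and stack.cube[y, x].sum() > thr:
                    for t in range(stack.cube.shape[2]):
                        expected[t] += stack.cube[y, x, t]
        if expected.sum() == 0:
            pytest.skip("degenerate draw: nothing above threshold")
        out = sum_roi_decay(stack, mask, thr)
        np.testing.assert_array_equal(out.counts, expected)

    def test_photon_conservation(self, rng):
        stack = self._stack(rng)
        mask = np.ones(stack.shape, dtype=bool)
        thr = 50.0
        out = sum_roi_decay(stack, mask, thr)
        qual = stack.intensity_image > thr
        assert out.total_counts == stack.intensity_image[qual].sum()

    def test_empty_selection_rejected(self, rng):
        stack = self._stack(rng)
        with pytest.raises(ValueError, match="no pixels"):
            sum_roi_decay(stack, np.ones(stack.shape, bool), 1e9)


class TestTailFit:
    def test_noiseless_monoexponential_exact(self):
        t = np.arange(256) * (12.5 / 256) + 12.5 / 512
        counts = 5000.0 * np.exp(-t / 3.05)
        d = DecayCurve(t, np.round(counts * 1e6) / 1e6, require_integer=False)
        fit = tail_fit(d, min_total_counts=1)
        assert fit.success
        assert fit.tau_ns == pytest.approx(3.05, abs=1e-6)

    def test_poisson_recovery_per_fit_within_5pct(self):
        taus = []
        for seed in range(20):
            d = gen_tcspc_decay((2.5,), (1.0,), 1e5, seed=seed)
            fit = tail_fit(d)
            assert fit.success
            assert fit.tau_ns == pytest.approx(2.5, rel=0.05)
            taus.append(fit.tau_ns)
        assert np.mean(taus) == pytest.approx(2.5, rel=0.01)

    def test_mono_fit_of_biexponential_brackets_components(self):
        d = gen_tcspc_decay((3.05, 1.5), (0.5, 0.5), 1e6, seed=3)
        fit = tail_fit(d, n_components=1)
        assert 1.5 < fit.tau_ns < 3.05

    def test_biexponential_recovery(self):
        d = gen_tcspc_decay((3.0, 0.8), (0.5, 0.5), 1e6, seed=11)
        fit = tail_fit(d, n_components=2)
        assert fit.success
        assert fit.lifetimes_ns[0] == pytest.approx(3.0, rel=0.1)
        assert fit.lifetimes_ns[1] == pytest.approx(0.8, rel=0.15)

    def test_low_counts_rejected(self):
        d = gen_tcspc_decay((3.0,), (1.0,), 500, seed=0)
        with pytest.raises(ValueError, match="minimum"):
            tail_fit(d)

    def test_window_before_peak_rejected(self):
        # decay with a rising edge: peak at bin 8, exponential fall after
        t = np.arange(128) * 0.1 + 0.05
        counts = np.round(
            5000 * np.exp(-np.abs(t - t[8]) / np.where(t < t[8], 0.2, 3.0))
        )
        d = DecayCurve(t, counts)
        with pytest.raises(ValueError, match="peak"):
            tail_fit(d, fit_window=(0, d.counts.size - 1))

    def test_too_short_window_rejected(self):
        d = gen_tcspc_decay((3.0,), (1.0,), 1e5, seed=0)
        peak = int(np.argmax(d.counts))
        with pytest.raises(ValueError, match="shorter"):
            tail_fit(d, fit_window=(peak + 2, peak + 6))


class TestModelSelect:
    def test_clean_monoexponential_prefers_one(self):
        d = gen_tcspc_decay((3.05,), (1.0,), 1e6, seed=5)
        assert model_select(d) == 1

    def test_strong_biexponential_prefers_two(self):
        d = gen_tcspc_decay((3.0, 0.8), (0.5, 0.5), 1e6, seed=6)
        assert model_select(d) == 2

    def test_infinite_threshold_always_one(self):
        d = gen_tcspc_decay((3.0, 0.8), (0.5, 0.5), 1e6, seed=6)
        assert model_select(d, chi2_improvement_threshold=np.inf) == 1


class TestFlimEfficiency:
    @pytest.mark.parametrize(
        "tau_da,tau_d,expected_pct",
        [(2.22, 3.05, 27), (2.92, 3.05, 4), (2.41, 3.05, 21), (2.81, 3.11, 10)],
    )
    def test_published_lifetime_pairs(self, tau_da, tau_d, expected_pct):
        assert round(flim_fret_efficiency(tau_da, tau_d)) == expected_pct

    def test_equal_lifetimes_zero(self):
        assert flim_fret_efficiency(3.05, 3.05) == 0.0

    def test_negative_efficiency_reported(self):
        assert flim_fret_efficiency(3.2, 3.05) < 0

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            flim_fret_efficiency(0.0, 3.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, tau_da, tau_d, c):
        e1 = flim_fret_efficiency(tau_da, tau_d)
        e2 = flim_fret_efficiency(c * tau_da, c * tau_d)
        assert e1 == pytest.approx(e2, rel=1e-9, abs=1e-9)


class TestLifetimeMap:
    def test_uniform_stack_uniform_map(self, ruby_scenario):
        from fretkit import FlimCellSpec, gen_flim_stack

        spec = FlimCellSpec((5.5, 5.5), (4.5, 4.5), 0.0, ruby_scenario)
        stack, _ = gen_flim_stack((12, 12), [spec], per_pixel_photons=2e4, seed=9)
        m = lifetime_map(stack, min_photons_per_pixel=1000)
        vals = m[np.isfinite(m)]
        assert vals.size > 30
        assert np.mean(vals) == pytest.approx(3.05, rel=0.03)

    def test_all_dark_stack_all_absent(self):
        stack = FlimStack(np.zeros((4, 4, 32), int), np.arange(32) * 0.1 + 0.05)
        m = lifetime_map(stack)
        assert np.all(np.isnan(m))

    def test_two_region_stack_separates(self, ruby_scenario):
        from fretkit import FlimCellSpec, gen_flim_stack

        specs = [
            FlimCellSpec((5.5, 5.5), (4.5, 4.5), 0.0, ruby_scenario),
            FlimCellSpec((5.5, 18.5), (4.5, 4.5), 1.0, ruby_scenario),
        ]
        stack, _ = gen_flim_stack((12, 24), specs, per_pixel_photons=2e4, seed=10)
        m = lifetime_map(stack, min_photons_per_pixel=1000)
        left = m[:, :12][np.isfinite(m[:, :12])]
        right = m[:, 12:][np.isfinite(m[:, 12:])]
        sep = abs(left.mean() - right.mean())
        pooled_sem = np.sqrt(left.var() / left.size + right.var() / right.size)
        assert sep > 5 * pooled_sem


class TestPhotobleachAndFramewise:
    def test_full_bleach_restores_zero_efficiency(self):
        pre = tail_fit(gen_tcspc_decay((2.2,), (1.0,), 1e5, seed=1))
        post = tail_fit(gen_tcspc_decay((3.05,), (1.0,), 1e5, seed=2))
        cmp = photobleach_compare(pre, post, tau_D_ns=3.05)
        assert cmp.E_post == pytest.approx(0.0, abs=2.0)
        assert cmp.E_pre > cmp.E_post

    def test_identical_fits_zero_delta(self):
        fit = tail_fit(gen_tcspc_decay((2.5,), (1.0,), 1e5, seed=3))
        cmp = photobleach_compare(fit, fit, tau_D_ns=3.05)
        assert cmp.delta_E == 0.0

    def test_mixture_prebleach_lower_lifetime(self, ruby_scenario):
        pre_decay = gen_tcspc_decay(
            (3.05, ruby_scenario.tau_DA_ns), (0.2, 0.8), 1e5, seed=4
        )
        post_decay = gen_tcspc_decay((3.05,), (1.0,), 1e5, seed=5)
        cmp = photobleach_compare(
            tail_fit(pre_decay), tail_fit(post_decay), tau_D_ns=3.05
        )
        assert cmp.E_post < cmp.E_pre

    def test_identical_blocks_identical_lifetimes(self):
        d = gen_tcspc_decay((3.0,), (1.0,), 1e5, seed=8)
        table = framewise_lifetimes([d, d, d])
        assert table.shape[0] == 3
        assert table["tau_ns"].nunique() == 1

    def test_single_block_single_row(self):
        d = gen_tcspc_decay((3.0,), (1.0,), 1e5, seed=8)
        assert framewise_lifetimes([d]).shape[0] == 1

    def test_bleaching_reduces_intensity_not_lifetime(self):
        # 20% intensity loss per block at constant lifetime
        blocks = [
            gen_tcspc_decay((3.0,), (1.0,), 1e5 * 0.8**i, seed=20 + i)
            for i in range(4)
        ]
        table = framewise_lifetimes(blocks)
        assert np.all(np.diff(table["total_counts"]) < 0)
        assert np.allclose(table["tau_ns"], 3.0, rtol=0.03)


class TestFlimStackIO:
    def test_tiff_sidecar_roundtrip(self, tmp_path, rng):
        cube = rng.integers(0, 50, size=(6, 7, 16))
        stack = FlimStack(cube, np.arange(16) * 0.05 + 0.025)
        p = tmp_path / "stack.tif"
        write_flim_stack(stack, p)
        back = read_flim_stack(p)
        np.testing.assert_array_equal(back.cube, stack.cube)
        np.testing.assert_allclose(back.bin_times_ns, stack.bin_times_ns)
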
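import numpy as np
import pytest

from dimple.errors import MaskError, ParameterError
from dimple.msi_io import Mask, MSIGrid, PixelSpectrum
from dimple.preprocess import (
    HyperspectralImage,
    PreprocessParams,
    PseudobulkSpectrum,
    assign_pixel_peaks,
    auto_mask,
    build_pseudobulk,
    filter_background,
    find_consensus_peaks,
    remove_sparse_channels,
    run_preprocess,
    smooth_pseudobulk,
    suppress_hot_pixels,
)
from dimple.synthetic import generate_root_msi

from _oracles import (
    brute_consensus_peaks,
    brute_hot_pixel_rescale,
    brute_running_median,
    brute_sparse_channel_removed,
)
from conftest import make_grid


def uniform_grid(rows, cols, tic=10.0):
    entries = {
        (r, c): ([100.0], [tic]) for r in range(rows) for c in range(cols)
    }
    return make_grid(entries, rows, cols)


class TestHotPixels:
    def test_uniform_tic_grid_unchanged(self):
        grid = uniform_grid(4, 4)
        assert suppress_hot_pixels(grid, k=5.0, enabled=True) == grid

    def test_disabled_is_identity(self):
        grid, _ = generate_root_msi(rows=20, cols=8, n_per_pattern=1, seed=2)
        assert suppress_hot_pixels(grid, enabled=False) is grid

    def test_outlier_rescaled_to_neighborhood_median(self):
        grid = uniform_grid(5, 5, tic=10.0)
        grid[2, 2] = PixelSpectrum([100.0, 200.0], [600.0, 400.0])  # TIC 1000
        out = suppress_hot_pixels(grid, k=5.0, enabled=True)
        expected_tic = brute_hot_pixel_rescale(grid.tic_image(), k=5.0)
        assert np.allclose(out.tic_image(), expected_tic)
        # relative intensities within the pixel preserved
        assert np.allclose(out[2, 2].intensity, [6.0, 4.0])

    def test_matches_brute_force_on_random_grid(self):
        rng = np.random.default_rng(0)
        entries = {
            (r, c): ([100.0], [float(rng.integers(1, 30))])
            for r in range(6)
            for c in range(6)
        }
        entries[(1, 4)] = ([100.0], [5000.0])
        entries[(5, 0)] = ([100.0], [4000.0])  # corner pixel
        grid = make_grid(entries, 6, 6)
        out = suppress_hot_pixels(grid, k=5.0, enabled=True)
        assert np.allclose(out.tic_image(), brute_hot_pixel_rescale(grid.tic_image(), 5.0))

    def test_synthetic_hot_pixels_are_flagged(self):
        grid, gt = generate_root_msi(
            rows=30, cols=10, n_per_pattern=2, patterns=("uniform",),
            n_background_only=0, n_sparse=0, n_hot_pixels=2,
            noise_sigma=0.05, seed=4,
        )
        out = suppress_hot_pixels(grid, k=5.0, enabled=True)
        tic_in, tic_out = grid.tic_image(), out.tic_image()
        for r, c in gt.hot_pixels:
            assert tic_out[r, c] < tic_in[r, c] / 10


class TestAutoMask:
    def test_recovers_ground_truth_mask(self):
        grid, gt = generate_root_msi(
            rows=30, cols=12, n_per_pattern=2, patterns=("uniform",),
            n_background_only=0, n_sparse=0, noise_rate=0,
            noise_sigma=0.05, fold_range=(10.0, 10.0), seed=5,
        )
        assert np.array_equal(auto_mask(grid).grid, gt.mask.grid)

    def test_constant_tic_rejected(self):
        with pytest.raises(MaskError):
            auto_mask(uniform_grid(4, 4))

    def test_all_zero_tic_rejected(self):
        with pytest.raises(MaskError):
            auto_mask(MSIGrid.empty(3, 3))

    def test_supplied_mask_bypasses_auto(self):
        """run_preprocess with an explicit mask must not invoke auto-masking
        (a constant-TIC grid would make auto_mask fail)."""
        entries = {(r, c): ([100.0], [10.0]) for r in range(6) for c in range(6)}
        for r in range(2, 5):
            for c in range(2, 5):
                entries[(r, c)] = ([100.0, 100.001], [10.0, 50.0])
        grid = make_grid(entries, 6, 6)
        mask = np.zeros((6, 6), bool)
        mask[2:5, 2:5] = True
        hsi, _ = run_preprocess(grid, Mask(mask))
        assert np.array_equal(hsi.mask.grid, mask)


class TestPseudobulk:
    def test_single_pixel_region_verbatim(self):
        grid = make_grid({(0, 0): ([100.0, 200.0], [1.0, 2.0])}, 2, 2)
        region = np.zeros((2, 2), bool)
        region[0, 0] = True
        pb = build_pseudobulk(grid, Mask(region))
        assert np.array_equal(pb.mz, [100.0, 200.0])
        assert np.array_equal(pb.intensity, [1.0, 2.0])
        assert pb.n_pixels == 1

    def test_identical_mz_entries_sum(self):
        grid = make_grid(
            {(0, 0): ([100.0], [5.0]), (0, 1): ([100.0], [5.0])}, 1, 2
        )
        pb = build_pseudobulk(grid, Mask(np.ones((1, 2), bool)))
        assert np.array_equal(pb.mz, [100.0])
        assert np.array_equal(pb.intensity, [10.0])

    def test_total_intensity_matches_generator_bookkeeping(self):
        grid, gt = generate_root_msi(
            rows=20, cols=8, n_per_pattern=1, patterns=("uniform",),
            n_background_only=0, n_sparse=0, noise_rate=0, seed=6,
        )
        pb = build_pseudobulk(grid, gt.mask)
        total = sum(grid[r, c].tic for r, c in np.argwhere(gt.mask.grid))
        assert np.isclose(pb.intensity.sum(), total)

    def test_empty_region_rejected(self):
        with pytest.raises(MaskError):
            build_pseudobulk(MSIGrid.empty(2, 2), Mask(np.zeros((2, 2), bool)))


class TestSmoothPseudobulk:
    def test_width_one_is_identity(self):
        pb = PseudobulkSpectrum([1.0, 2.0, 3.0], [5.0, 1.0, 9.0], 1)
        out = smooth_pseudobulk(pb, 1)
        assert np.array_equal(out.intensity, pb.intensity)

    def test_isolated_spike_removed(self):
        pb = PseudobulkSpectrum(np.arange(5) + 1.0, [0, 0, 100, 0, 0], 1)
        out = smooth_pseudobulk(pb, 3)
        assert np.array_equal(out.intensity, np.zeros(5))
        assert np.array_equal(out.mz, pb.mz)

    def test_constant_unchanged(self):
        pb = PseudobulkSpectrum(np.arange(7) + 1.0, np.full(7, 4.0), 1)
        assert np.array_equal(smooth_pseudobulk(pb, 3).intensity, pb.intensity)

    def test_even_width_rejected(self):
        pb = PseudobulkSpectrum([1.0], [1.0], 1)
        with pytest.raises(ParameterError):
            smooth_pseudobulk(pb, 4)

    @pytest.mark.parametrize("width", [1, 3, 5, 7])
    def test_matches_naive_sliding_median(self, width):
        rng = np.random.default_rng(width)
        inten = rng.exponential(size=200)
        pb = PseudobulkSpectrum(np.sort(rng.random(200)) + 100, inten, 3)
        out = smooth_pseudobulk(pb, width)
        assert np.allclose(out.intensity, brute_running_median(inten, width))


class TestConsensusPeaks:
    def test_empty_spectrum(self):
        pb = PseudobulkSpectrum(np.empty(0), np.empty(0), 1)
        assert find_consensus_peaks(pb) == []

    def test_close_pair_keeps_only_maximum(self):
        pb = PseudobulkSpectrum([100.00000, 100.00010], [10.0, 5.0], 1)
        assert find_consensus_peaks(pb, 2.5) == [(100.0, 10.0)]

    def test_distant_pair_keeps_both(self):
        pb = PseudobulkSpectrum([100.0000, 100.0010], [10.0, 10.0], 1)
        centers = find_consensus_peaks(pb, 2.5)
        assert [c for c, _ in centers] == [100.0, 100.001]

    def test_equal_intensity_tie_goes_to_lower_mz(self):
        pb = PseudobulkSpectrum([100.00000, 100.00010], [7.0, 7.0], 1)
        assert find_consensus_peaks(pb, 2.5) == [(100.0, 7.0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        # clustered values to exercise window overlaps, plus intensity ties
        base = rng.uniform(100, 500, 40)
        mz = np.sort(
            np.concatenate([b * (1 + rng.normal(0, 2e-6, 5)) for b in base])
        )
        inten = np.round(rng.exponential(size=mz.size), 1)  # ties likely
        pb = PseudobulkSpectrum(mz, inten, 1)
        assert find_consensus_peaks(pb, 2.5) == brute_consensus_peaks(mz, inten, 2.5)

    def test_centers_separated_by_more_than_window(self, default_fixture):
        grid, gt = default_fixture
        pb = build_pseudobulk(grid, gt.mask)
        centers = np.array([c for c, _ in find_consensus_peaks(pb, 2.5)])
        gaps_ppm = np.diff(centers) / centers[:-1] * 1e6
        assert np.all(gaps_ppm > 2.5)


class TestBackgroundFilter:
    def _pb(self, mz, inten, n):
        return PseudobulkSpectrum(np.atleast_1d(mz), np.atleast_1d(inten), n)

    def test_zero_background_kept_with_infinite_fold(self):
        ps = filter_background(
            [(100.0, 4.0)], self._pb(100.0, 4.0, 1), self._pb(500.0, 1.0, 1)
        )
        (peak,) = ps.peaks
        assert peak.kept and np.isinf(peak.fold_enrichment)

    def test_exact_threshold_removed_by_strict_inequality(self):
        ps = filter_background(
            [(100.0, 3.0)], self._pb(100.0, 3.0, 1), self._pb(100.0, 2.0, 1),
            min_fold=1.5,
        )
        assert not ps.peaks[0].kept  # 3.0 > 1.5 * 2.0 is false

    def test_just_above_threshold_kept(self):
        ps = filter_background(
            [(100.0, 3.1)], self._pb(100.0, 3.1, 1), self._pb(100.0, 2.0, 1),
            min_fold=1.5,
        )
        assert ps.peaks[0].kept
        assert np.isclose(ps.peaks[0].fold_enrichment, 1.55)

    def test_per_pixel_means_remove_area_bias(self):
        # same per-pixel level both sides (fold 1) but 4x more sample pixels:
        # raw sums would report fold 4 and keep the peak; per-pixel means do not
        sample = self._pb(100.0, 40.0, 4)
        background = self._pb(100.0, 10.0, 1)
        per_pixel = filter_background([(100.0, 40.0)], sample, background)
        raw_sum = filter_background(
            [(100.0, 40.0)], sample, background, normalize="sum"
        )
        assert not per_pixel.peaks[0].kept
        assert raw_sum.peaks[0].kept

    def test_zero_pixel_regions_rejected(self):
        with pytest.raises(Exception):
            filter_background(
                [(100.0, 1.0)], self._pb(100.0, 1.0, 1),
                PseudobulkSpectrum([100.0], [1.0], 0),
            )


class TestAssignment:
    def _peakset(self, centers, ppm=2.5):
        return filter_background(
            [(c, 1.0) for c in centers],
            PseudobulkSpectrum(np.asarray(centers, float), np.ones(len(centers)), 1),
            PseudobulkSpectrum([1000.0], [1.0], 1),
            window_ppm=ppm,
        )

    def test_empty_pixel_gives_zero_vector(self):
        grid = MSIGrid.empty(2, 2)
        hsi = assign_pixel_peaks(grid, self._peakset([100.0]), Mask(np.ones((2, 2), bool)))
        assert not hsi.cube.any()

    def test_entry_assigned_to_nearer_center(self):
        grid = make_grid({(0, 0): ([100.00010], [7.0])}, 1, 1)
        hsi = assign_pixel_peaks(
            grid, self._peakset([100.00000, 100.00050]), Mask(np.ones((1, 1), bool))
        )
        assert hsi.cube[0, 0, 0] == 7.0  # nearer center, 1.0 ppm away
        assert hsi.cube[1, 0, 0] == 0.0

    def test_two_entries_in_one_window_sum(self):
        grid = make_grid({(0, 0): ([99.99990, 100.00010], [2.0, 3.0])}, 1, 1)
        hsi = assign_pixel_peaks(grid, self._peakset([100.0]), Mask(np.ones((1, 1), bool)))
        assert hsi.cube[0, 0, 0] == 5.0

    def test_out_of_window_entries_dropped(self):
        grid = make_grid({(0, 0): ([100.01], [9.0])}, 1, 1)  # 100 ppm away
        hsi = assign_pixel_peaks(grid, self._peakset([100.0]), Mask(np.ones((1, 1), bool)))
        assert not hsi.cube.any()

    def test_background_pixels_zero(self):
        grid = make_grid({(0, 0): ([100.0], [1.0]), (0, 1): ([100.0], [1.0])}, 1, 2)
        mask = Mask(np.array([[True, False]]))
        hsi = assign_pixel_peaks(grid, self._peakset([100.0]), mask)
        assert hsi.cube[0, 0, 1] == 0.0

    def test_conservation_of_in_window_intensity(self, default_processed):
        """Assignment neither creates nor loses in-window signal: per pixel,
        the channel sums equal the total intensity of entries inside any
        kept window."""
        grid, gt, hsi, peakset = default_processed
        centers = peakset.kept_centers
        half = centers * 2.5e-6
        rng = np.random.default_rng(0)
        pix = np.argwhere(gt.mask.grid)
        full = assign_pixel_peaks(grid, peakset, gt.mask)
        for r, c in pix[rng.choice(len(pix), 40, replace=False)]:
            spec = grid[r, c]
            in_window = np.zeros(len(spec), bool)
            for k, center in enumerate(centers):
                in_window |= np.abs(spec.mz - center) <= half[k]
            assert np.isclose(full.cube[:, r, c].sum(), spec.intensity[in_window].sum())


class TestSparsityFilter:
    def _hsi(self, channels):
        cube = np.stack(channels).astype(float)
        return HyperspectralImage(
            channel_mz=100.0 + np.arange(cube.shape[0]),
            cube=cube,
            mask=Mask(np.ones(cube.shape[1:], bool)),
        )

    def test_isolated_pixel_removed(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = remove_sparse_channels(self._hsi([img]))
        assert out.n_channels == 0 and len(out.removed_mz) == 1

    def test_solid_block_kept(self):
        img = np.zeros((5, 5))
        img[1:4, 1:4] = 1.0  # erosion retains the block center
        out = remove_sparse_channels(self._hsi([img]))
        assert out.n_channels == 1 and len(out.removed_mz) == 0

    def test_checkerboard_removed(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        out = remove_sparse_channels(self._hsi([img.astype(float)]))
        assert out.n_channels == 0

    def test_border_only_channel_removed(self):
        img = np.ones((4, 4))
        img[1:3, 1:3] = 0.0  # borders count as zero-padded
        out = remove_sparse_channels(self._hsi([img]))
        assert out.n_channels == 0

    def test_removed_channels_stay_exportable(self):
        img = np.zeros((5, 5))
        img[2, 2] = 7.0
        out = remove_sparse_channels(self._hsi([img]))
        assert out.removed_cube[0, 2, 2] == 7.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_neighborhood_check(self, seed):
        rng = np.random.default_rng(seed)
        channels = [(rng.random((8, 8)) < p).astype(float) for p in (0.2, 0.5, 0.8)]
        out = remove_sparse_channels(self._hsi(channels))
        for i, img in enumerate(channels):
            removed = brute_sparse_channel_removed(img)
            assert (100.0 + i in out.removed_mz) == removed


class TestRunPreprocess:
    def test_recovers_exactly_the_planted_channels(self, default_processed):
        grid, gt, hsi, peakset = default_processed
        planted = np.array(sorted(ch.true_mz for ch in gt.foreground_channels))
        assert hsi.n_channels == len(planted) == 20
        for mz in planted:
            err_ppm = np.min(np.abs(hsi.channel_mz - mz)) / mz * 1e6
            assert err_ppm <= 2.5

    def test_background_only_and_sparse_channels_excluded(self, default_processed):
        _, gt, hsi, _ = default_processed
        for ch in gt.channels:
            if ch.background_only or ch.sparse:
                err_ppm = np.min(np.abs(hsi.channel_mz - ch.true_mz)) / ch.true_mz * 1e6
                assert err_ppm > 2.5

    def test_unreachable_min_fold_keeps_nothing(self, default_fixture):
        grid, gt = default_fixture
        hsi, peakset = run_preprocess(
            grid, gt.mask, PreprocessParams(min_fold=1e9)
        )
        assert hsi.n_channels == 0

    def test_widened_window_merges_close_pair(self):
        """Two planted peaks 4 ppm apart resolve at 2.5 ppm but merge at 5 ppm."""
        mz_a = 200.0
        mz_b = 200.0 * (1 + 4e-6)
        entries = {}
        for r in range(8):
            for c in range(8):
                if 2 <= r <= 5 and 2 <= c <= 5:
                    entries[(r, c)] = ([mz_a, mz_b], [10.0, 8.0])
        grid = make_grid(entries, 8, 8)
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        narrow, _ = run_preprocess(grid, Mask(mask), PreprocessParams(window_ppm=2.5))
        wide, _ = run_preprocess(grid, Mask(mask), PreprocessParams(window_ppm=5.0))
        assert narrow.n_channels - wide.n_channels == 1

    def test_kept_count_monotone_in_min_fold(self, default_fixture):
        grid, gt = default_fixture
        counts = []
        for fold in (1.1, 1.5, 3.0, 5.0, 8.0):
            hsi, _ = run_preprocess(grid, gt.mask, PreprocessParams(min_fold=fold))
            counts.append(hsi.n_channels)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_center_count_monotone_in_window(self, default_fixture):
        grid, gt = default_fixture
        pb = build_pseudobulk(grid, gt.mask)
        counts = [
            len(find_consensus_peaks(pb, ppm)) for ppm in (1.0, 2.5, 5.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_keep_sparse_retains_more_channels(self, default_fixture):
        grid, gt = default_fixture
        with_filter, _ = run_preprocess(grid, gt.mask)
        without, _ = run_preprocess(
            grid, gt.mask, PreprocessParams(remove_sparse=False)
        )
        assert without.n_channels > with_filter.n_channels
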
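"""Voxelwise feature computations: Kendall's W / ReHo, ALFF / fALFF,
z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from pdprog.core import BrainMask, Image3D, Image4D
from pdprog.features import (
    ReHoParams,
    SpectralParams,
    compute_alff_falff,
    compute_reho,
    kendall_w,
    zscore_map,
)

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def brute_force_kendall_w(block: np.ndarray) -> float:
    """Independent oracle: explicit rank sums, no shared code path."""
    k, n = block.shape
    ranks = np.empty_like(block, dtype=float)
    for i in range(k):
        ranks[i] = rankdata(block[i])
    s = 0.0
    rank_sums = [float(ranks[:, t].sum()) for t in range(n)]
    mean_sum = sum(rank_sums) / n
    for t in range(n):
        s += (rank_sums[t] - mean_sum) ** 2
    return 12.0 * s / (k * k * (n**3 - n))


class TestKendallW:
    def test_identical_increasing_series_give_perfect_concordance(self):
        block = np.tile(np.arange(20.0), (27, 1))
        assert kendall_w(block) == pytest.approx(1.0, abs=1e-12)

    def test_two_reversed_rankings_give_zero(self):
        block = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
        assert kendall_w(block) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_block(self):
        rng = np.random.default_rng(42)
        block = rng.standard_normal((27, 20))
        assert kendall_w(block) == pytest.approx(brute_force_kendall_w(block), abs=1e-12)

    def test_all_constant_block_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-constant"):
            assert kendall_w(np.ones((5, 8)), "midrank_tie_correction") == 0.0

    def test_tie_correction_raises_w_for_tied_data(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(6, 12)).astype(float)
        assert kendall_w(block, "midrank_tie_correction") >= kendall_w(block)

    def test_rejects_degenerate_shapes(self):
        with pytest.raises(ValueError):
            kendall_w(np.ones((1, 10)))
        with pytest.raises(ValueError):
            kendall_w(np.ones(10))

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_and_invariant_under_common_monotone_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        block = rng.standard_normal((8, 15))
        w = kendall_w(block)
        assert 0.0 <= w <= 1.0
        transformed = np.exp(a * block + b)  # strictly increasing map
        assert kendall_w(transformed) == pytest.approx(w, abs=1e-12)


class TestComputeReho:
    def test_shared_timeseries_gives_unit_map(self):
        series = np.sin(np.arange(20))
        data = np.broadcast_to(series, (6, 6, 6, 20)).copy()
        img = Image4D(data, AFFINE, 2.4)
        mask = BrainMask(np.ones((6, 6, 6)), AFFINE)
        reho = compute_reho(img, mask)
        assert np.allclose(reho.data, 1.0)

    def test_matches_voxelwise_oracle_on_masked_fixture(self):
        """Map equals brute-force Kendall's W over explicitly gathered in-mask
        neighbourhoods, voxel by voxel, to 1e-12."""
        rng = np.random.default_rng(7)
        shape = (6, 6, 6)
        data = rng.standard_normal((*shape, 20))
        mask_arr = rng.random(shape) < 0.85
        mask_arr[3, 3, 3] = True
        img = Image4D(data, AFFINE, 2.4)
        params = ReHoParams()
        reho = compute_reho(img, BrainMask(mask_arr, AFFINE), params)

        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask_arr[x, y, z]:
                        assert reho.data[x, y, z] == 0.0
                        continue
                    block = []
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                i, j, k = x + dx, y + dy, z + dz
                                if (
                                    0 <= i < shape[0]
                                    and 0 <= j < shape[1]
                                    and 0 <= k < shape[2]
                                    and mask_arr[i, j, k]
                                ):
                                    block.append(data[i, j, k])
                    if len(block) - 1 < params.min_neighbors:
                        assert reho.data[x, y, z] == 0.0
                    else:
                        expected = brute_force_kendall_w(np.array(block))
                        assert reho.data[x, y, z] == pytest.approx(expected, abs=1e-12)

    def test_white_noise_interior_mean_near_chance_level(self):
        """Independent voxels: E[W] = 1/K; checked on a stride-3 subsample of
        interior voxels (disjoint neighbourhoods, hence independent W)."""
        rng = np.random.default_rng(3)
        g = 16
        img = Image4D(rng.standard_normal((g, g, g, 100)), AFFINE, 2.4)
        mask = BrainMask(np.ones((g, g, g)), AFFINE)
        reho = compute_reho(img, mask)
        sample = reho.data[1:-1:3, 1:-1:3, 1:-1:3].ravel()
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - 1 / 27) < 3 * se

    def test_corner_voxel_uses_truncated_neighbourhood(self):
        rng = np.random.default_rng(5)
        shape = (4, 4, 4)
        data = rng.standard_normal((*shape, 30))
        img = Image4D(data, AFFINE, 2.4)
        reho = compute_reho(img, BrainMask(np.ones(shape), AFFINE))
        corner_block = data[:2, :2, :2].reshape(8, 30)
        assert reho.data[0, 0, 0] == pytest.approx(
            brute_force_kendall_w(corner_block), abs=1e-12
        )

    def test_too_few_timepoints_rejected(self):
        img = Image4D(np.zeros((4, 4, 4, 3)), AFFINE, 2.4)
        with pytest.raises(ValueError, match="4 timepoints"):
            compute_reho(img, BrainMask(np.ones((4, 4, 4)), AFFINE))


class TestAlffFalff:
    def _volume(self, series: np.ndarray, tr: float = 2.4) -> tuple[Image4D, BrainMask]:
        data = np.broadcast_to(series, (3, 3, 3, series.size)).copy()
        return Image4D(data, AFFINE, tr), BrainMask(np.ones((3, 3, 3)), AFFINE)

    def test_pure_inband_sinusoid_has_unit_falff(self):
        t = np.arange(200) * 2.4
        img, mask = self._volume(np.sin(2 * np.pi * 0.05 * t))
        _, falff = compute_alff_falff(img, mask)
        assert falff.data[1, 1, 1] == pytest.approx(1.0, abs=0.02)

    def test_out_of_band_sinusoid_has_zero_falff(self):
        t = np.arange(200) * 2.4
        img, mask = self._volume(np.sin(2 * np.pi * 0.18 * t))
        _, falff = compute_alff_falff(img, mask)
        assert falff.data[1, 1, 1] == pytest.approx(0.0, abs=0.02)

    def test_equal_power_mixture_gives_sqrt_half(self):
        t = np.arange(200) * 2.4
        series = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.15 * t)
        img, mask = self._volume(series)
        _, falff = compute_alff_falff(img, mask)
        assert falff.data[1, 1, 1] == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_falff_squared_equals_fft_inband_power_fraction(self):
        """Parseval identity: with the ideal filter, fALFF^2 is the in-band
        power fraction of the detrended series."""
        rng = np.random.default_rng(11)
        n, tr = 200, 2.4
        raw = rng.standard_normal((100, n)).cumsum(axis=1)  # non-trivial spectra
        data = raw.reshape(100, 1, 1, n)
        img = Image4D(data, AFFINE, tr)
        mask = BrainMask(np.ones((100, 1, 1)), AFFINE)
        _, falff = compute_alff_falff(img, mask)

        freqs = np.fft.rfftfreq(n, tr)
        inband = (freqs >= 0.01) & (freqs <= 0.1)
        from scipy.signal import detrend

        x = detrend(raw, axis=1)
        spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
        weights = np.full(spec.shape[1], 2.0)
        weights[0] = 1.0
        if n % 2 == 0:
            weights[-1] = 1.0
        power = spec * weights
        frac = power[:, inband].sum(axis=1) / power[:, 1:].sum(axis=1)
        assert np.max(np.abs(falff.data[:, 0, 0] ** 2 - frac)) < 0.03

    def test_alff_nonnegative_and_falff_bounded(self):
        rng = np.random.default_rng(2)
        img = Image4D(rng.standard_normal((4, 4, 4, 64)), AFFINE, 2.4)
        mask = BrainMask(np.ones((4, 4, 4)), AFFINE)
        alff, falff = compute_alff_falff(img, mask)
        assert (alff.data >= 0).all()
        assert (falff.data <= 1.05).all() and (falff.data >= 0).all()

    def test_butterworth_variant_close_to_ideal_filter(self):
        t = np.arange(256) * 2.4
        img, mask = self._volume(np.sin(2 * np.pi * 0.05 * t))
        _, falff = compute_alff_falff(img, mask, SpectralParams(filter="butterworth"))
        assert falff.data[1, 1, 1] == pytest.approx(1.0, abs=0.05)

    def test_band_beyond_nyquist_rejected(self):
        img = Image4D(np.zeros((3, 3, 3, 32)), AFFINE, 10.0)  # Nyquist 0.05 Hz
        mask = BrainMask(np.ones((3, 3, 3)), AFFINE)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_alff_falff(img, mask)

    def test_constant_voxel_flagged_and_zeroed(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 3, 3, 64))
        data[0, 0, 0] = 5.0  # constant series
        img = Image4D(data, AFFINE, 2.4)
        mask = BrainMask(np.ones((3, 3, 3)), AFFINE)
        with pytest.warns(UserWarning, match="constant"):
            _, falff = compute_alff_falff(img, mask)
        assert falff.data[0, 0, 0] == 0.0


class TestZscoreMap:
    def test_hand_computed_values_population_sd(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = BrainMask(np.ones((3, 1, 1)), AFFINE)
        z = zscore_map(Image3D(data, AFFINE), mask)
        expected = np.array([-1.2247, 0.0, 1.2247])
        assert np.allclose(z.data[:, 0, 0], expected, atol=1e-4)

    def test_idempotent_on_standardised_map_and_shift_scale_invariant(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((5, 5, 5))
        mask = BrainMask(np.ones((5, 5, 5)), AFFINE)
        z1 = zscore_map(Image3D(data, AFFINE), mask)
        z2 = zscore_map(z1, mask)
        assert np.allclose(z1.data, z2.data, atol=1e-10)
        shifted = zscore_map(Image3D(3.5 * data - 7.0, AFFINE), mask)
        assert np.allclose(shifted.data, z1.data, atol=1e-10)

    def test_output_moments_within_mask(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((6, 6, 6)) * 4 + 2
        mask = BrainMask(rng.random((6, 6, 6)) < 0.7, AFFINE)
        z = zscore_map(Image3D(data, AFFINE), mask)
        vals = z.data[mask.data]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std() - 1.0) < 1e-10
        assert np.all(z.data[~mask.data] == 0.0)

    def test_constant_map_rejected(self):
        mask = BrainMask(np.ones((3, 3, 3)), AFFINE)
        with pytest.raises(ValueError, match="constant"):
            zscore_map(Image3D(np.full((3, 3, 3), 2.0), AFFINE), mask)
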
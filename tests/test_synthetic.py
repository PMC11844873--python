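"""Synthetic data generators: spectral/coherence ground truth, motion,
cohort generative model."""

import numpy as np
import pandas as pd
import pytest

from pdprog.cohort import add_total_scores
from pdprog.confounds import framewise_displacement
from pdprog.core import BrainMask, Image4D
from pdprog.features import compute_alff_falff, compute_reho
from pdprog.synthetic import (
    CohortSynthConfig,
    FMRISynthConfig,
    generate_cohort,
    generate_fmri,
    generate_motion,
    make_block_atlas,
    simulate_study,
    split_atlas,
    step_sd_for_mean_fd,
)


def _config(**kw) -> FMRISynthConfig:
    base = dict(grid_shape=(8, 8, 8), n_timepoints=200, repetition_time=2.4, seed=0)
    base.update(kw)
    return FMRISynthConfig(**base)


class TestGenerateFmri:
    def test_deterministic_given_seed(self):
        atlas = make_block_atlas((8, 8, 8), n_regions=2)
        img1, _, _ = generate_fmri(_config(seed=5), atlas)
        img2, _, _ = generate_fmri(_config(seed=5), atlas)
        assert np.array_equal(img1.data, img2.data)
        img3, _, _ = generate_fmri(_config(seed=6), atlas)
        assert not np.array_equal(img1.data, img3.data)

    def test_perfect_coherence_gives_identical_series_and_unit_reho(self):
        atlas = make_block_atlas((8, 8, 8), n_regions=1)
        cfg = _config(coherence_by_region={1: 1.0}, inband_fraction_by_region={1: 0.5})
        img, mask, truth = generate_fmri(cfg, atlas)
        voxels = img.data[atlas.data == 1]
        assert np.allclose(voxels - voxels[0], 0.0, atol=1e-12)
        reho = compute_reho(img, mask)
        inner = reho.data[2:-2, 2:-2, 2:-2]
        assert np.allclose(inner[inner > 0], 1.0)
        assert truth.coherence_map[4, 4, 4] == 1.0

    def test_zero_coherence_gives_chance_level_reho(self):
        atlas = make_block_atlas((14, 14, 14), n_regions=1)
        cfg = _config(grid_shape=(14, 14, 14), n_timepoints=100,
                      coherence_by_region={1: 0.0})
        img, mask, _ = generate_fmri(cfg, atlas)
        reho = compute_reho(img, mask)
        sample = reho.data[2:-2:3, 2:-2:3, 2:-2:3].ravel()
        sample = sample[sample > 0]
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - 1 / 27) < 4 * se

    def test_spectral_control_of_inband_fraction(self):
        """FFT in-band power fraction of the generated series tracks phi."""
        atlas = make_block_atlas((8, 8, 8), n_regions=2)
        for phi in (0.2, 0.5, 0.8):
            cfg = _config(
                coherence_by_region={1: 1.0, 2: 0.0},
                inband_fraction_by_region={1: phi, 2: phi},
                seed=11,
            )
            img, _, _ = generate_fmri(cfg, atlas)
            series = img.data[atlas.data == 1][0]
            freqs = np.fft.rfftfreq(200, 2.4)
            power = np.abs(np.fft.rfft(series - series.mean())) ** 2
            inband = (freqs >= 0.01) & (freqs <= 0.1)
            frac = power[inband].sum() / power[1:].sum()
            assert abs(frac - phi) < 0.03

    def test_full_inband_power_gives_unit_falff(self):
        atlas = make_block_atlas((8, 8, 8), n_regions=1)
        cfg = _config(inband_fraction_by_region={1: 1.0}, coherence_by_region={1: 0.3})
        img, mask, _ = generate_fmri(cfg, atlas)
        _, falff = compute_alff_falff(img, mask)
        region = falff.data[atlas.data == 1]
        assert region.mean() > 0.97

    def test_falff_monotone_in_phi(self):
        atlas = make_block_atlas((8, 8, 8), n_regions=1)
        means = []
        for phi in (0.2, 0.5, 0.8):
            cfg = _config(inband_fraction_by_region={1: phi}, seed=13)
            img, mask, _ = generate_fmri(cfg, atlas)
            _, falff = compute_alff_falff(img, mask)
            means.append(falff.data[atlas.data == 1].mean())
        assert means[0] < means[1] < means[2]

    def test_grid_mismatch_rejected(self):
        atlas = make_block_atlas((10, 10, 10), n_regions=2)
        with pytest.raises(ValueError, match="grid"):
            generate_fmri(_config(), atlas)

    def test_band_without_fft_bin_rejected(self):
        atlas = make_block_atlas((8, 8, 8), n_regions=1)
        cfg = _config(n_timepoints=16, repetition_time=0.1,
                      inband_fraction_by_region={1: 0.5})
        with pytest.raises(ValueError, match="too small"):
            generate_fmri(cfg, atlas)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            _config(coherence_by_region={1: 1.5})
        with pytest.raises(ValueError):
            _config(inband_fraction_by_region={1: -0.1})


class TestGenerateMotion:
    def test_zero_step_gives_zero_fd(self):
        motion = generate_motion(20, 0.0, seed=0)
        fd = framewise_displacement(motion)
        assert np.all(fd.values == 0.0)

    def test_single_translation_step(self):
        motion = generate_motion(2, (0.1, 0.0), seed=1)
        trace = np.zeros((2, 6))
        trace[1, 0] = 0.1
        motion.trace = trace  # constructed single-step case
        fd = framewise_displacement(motion)
        assert fd.values == pytest.approx([0.1])

    def test_calibrated_step_sd_reaches_target_mean_fd(self):
        """Fixture realism: steps tuned for a mean FD near 0.258 mm."""
        step = step_sd_for_mean_fd(0.258)
        means = [
            framewise_displacement(generate_motion(500, step, seed=s)).mean
            for s in range(10)
        ]
        assert np.mean(means) == pytest.approx(0.258, rel=0.05)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            generate_motion(10, -0.1, seed=0)


def _regional(n, p=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"reho_r{j}" for j in range(p)]
    )


class TestGenerateCohort:
    def test_attrition_row_counts(self):
        config = CohortSynthConfig(n_baseline=50, retention=(0.6, 0.5, 0.3), seed=0)
        cohort, _ = generate_cohort(config, _regional(50))
        counts = cohort["EVENT_ID"].value_counts()
        assert counts["BL"] == 50
        assert counts["V04"] == 30 and counts["V06"] == 25 and counts["V10"] == 15

    def test_increasing_retention_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CohortSynthConfig(retention=(0.5, 0.6, 0.4))

    def test_total_reconstructed_from_parts_with_np4_rule(self):
        config = CohortSynthConfig(n_baseline=40, np4_missing_prob=0.5, seed=1)
        cohort, _ = generate_cohort(config, _regional(40))
        scored = add_total_scores(cohort)
        base = scored[scored["EVENT_ID"] == "BL"]
        assert (base["UPDRS_TOT"] == base["BASELINE_UPDRS"]).all()
        missing_frac = cohort["NP4TOT"].isna().mean()
        assert 0.3 < missing_frac < 0.7

    def test_visit_dates_fall_inside_matching_windows(self):
        config = CohortSynthConfig(n_baseline=30, seed=2)
        cohort, _ = generate_cohort(config, _regional(30))
        dates = pd.to_datetime(cohort["INFODT"])
        base = dates[cohort["EVENT_ID"] == "BL"].iloc[0]
        for event, target in (("V04", 365), ("V06", 730), ("V10", 1460)):
            offsets = (dates[cohort["EVENT_ID"] == event] - base).dt.days
            assert ((offsets - target).abs() <= 60).all()

    def test_target_r2_calibration_is_exact_in_truth(self):
        config = CohortSynthConfig(
            n_baseline=60,
            beta_imaging={"reho_r0": 3.0, "reho_r1": -2.0},
            target_r2=0.5,
            seed=3,
        )
        _, truth = generate_cohort(config, _regional(60, seed=3))
        assert truth.theoretical_r2["baseline"] == pytest.approx(0.5, abs=1e-9)

    def test_vanishing_noise_gives_unit_theoretical_r2(self):
        config = CohortSynthConfig(
            n_baseline=30, beta_imaging={"reho_r0": 3.0}, noise_sd=1e-9, seed=4
        )
        _, truth = generate_cohort(config, _regional(30))
        assert truth.theoretical_r2["baseline"] == pytest.approx(1.0, abs=1e-6)

    def test_theoretical_r2_matches_monte_carlo_regression(self):
        """Variance decomposition over 10,000 simulated subjects: an OLS fit
        of the observed totals on the generating features recovers the
        recorded theoretical R2 within +/- 0.02 (rounding and clipping are
        the only deviations from the linear model)."""
        n = 10_000
        config = CohortSynthConfig(
            n_baseline=n,
            beta_clinical={"MOCA": -2.0, "GDS": 1.5, "AGE": 1.0},
            beta_imaging={"reho_r0": 3.0, "reho_r1": -2.0},
            target_r2=0.5,
            seed=5,
        )
        regional = _regional(n, seed=5)
        cohort, truth = generate_cohort(config, regional)
        base = cohort[cohort["EVENT_ID"] == "BL"]
        y = base["BASELINE_UPDRS"].to_numpy(dtype=float)
        x = np.column_stack(
            [
                base["MOCA"],
                base["GDS"],
                base["AGE"],
                regional.iloc[:n]["reho_r0"],
                regional.iloc[:n]["reho_r1"],
                np.ones(n),
            ]
        ).astype(float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r2 = 1 - ((y - x @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert abs(r2 - truth.theoretical_r2["baseline"]) < 0.02

    def test_unknown_beta_name_rejected(self):
        config = CohortSynthConfig(n_baseline=10, beta_imaging={"nope": 1.0})
        with pytest.raises(ValueError, match="nope"):
            generate_cohort(config, _regional(10))

    def test_deterministic_given_seed(self):
        config = CohortSynthConfig(n_baseline=20, seed=9)
        a, _ = generate_cohort(config, _regional(20))
        b, _ = generate_cohort(config, _regional(20))
        pd.testing.assert_frame_equal(a, b)


class TestAtlases:
    def test_block_atlas_covers_interior_with_contiguous_labels(self):
        atlas = make_block_atlas((12, 12, 12), n_regions=6)
        assert atlas.label_ids == [1, 2, 3, 4, 5, 6]
        assert (atlas.data[0] == 0).all() and (atlas.data[-1] == 0).all()
        interior = atlas.data[1:-1, 1:-1, 1:-1]
        assert (interior > 0).all()

    def test_split_atlas_children_partition_parents(self):
        atlas = make_block_atlas((12, 12, 12), n_regions=4)
        fine = split_atlas(atlas)
        assert fine.n_labels == 8
        for lab in atlas.label_ids:
            parent = atlas.data == lab
            children = np.isin(fine.data, [2 * lab - 1, 2 * lab])
            assert np.array_equal(parent, children)


class TestSimulateStudy:
    def test_small_study_is_deterministic_and_self_consistent(self):
        a = simulate_study(n_participants=6, seed=3, grid_shape=(8, 8, 8),
                           n_timepoints=48, n_regions=3)
        b = simulate_study(n_participants=6, seed=3, grid_shape=(8, 8, 8),
                           n_timepoints=48, n_regions=3)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        for name in a.imaging:
            pd.testing.assert_frame_equal(a.imaging[name], b.imaging[name])
        assert a.ground_truth.theoretical_r2["baseline"] == pytest.approx(0.5, abs=1e-9)
        img, mask = a.fmri_for("P0000")
        assert img.shape == (8, 8, 8, 48)
        assert mask.n_voxels == int((a.atlas.data > 0).sum())
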
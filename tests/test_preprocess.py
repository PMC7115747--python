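"""Averaging, truncation, Goldindec baselining and vector normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramanchemo as rc
from ramanchemo.errors import (
    AlignmentError,
    EmptyRangeError,
    InputError,
    NormalizationError,
)
from ramanchemo.preprocess import polynomial_ols_baseline, smooth_intensities


GRID = np.arange(400.0, 1801.0, 2.0)


def _spec(y, grid=GRID):
    return rc.Spectrum(grid, y)


class TestAverageScans:
    def test_idempotent_on_identical_scans(self):
        s = _spec(np.linspace(0, 1, GRID.size))
        out = rc.average_scans([s] * 20)
        assert np.allclose(out.intensities, s.intensities)

    def test_arithmetic_mean(self):
        a = rc.Spectrum([400.0, 410.0], [0.0, 2.0])
        b = rc.Spectrum([400.0, 410.0], [2.0, 0.0])
        out = rc.average_scans([a, b])
        assert np.array_equal(out.intensities, [1.0, 1.0])

    def test_mismatched_grids_rejected(self):
        a = rc.Spectrum([400.0, 410.0], [0.0, 2.0])
        b = rc.Spectrum([400.0, 412.0], [2.0, 0.0])
        with pytest.raises(AlignmentError):
            rc.average_scans([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            rc.average_scans([])


class TestTruncate:
    def test_closed_interval_count(self):
        grid = np.arange(200.0, 2001.0, 100.0)
        out = rc.truncate(_spec(np.ones(grid.size), grid), 400, 1800)
        assert len(out) == 15

    def test_boundaries_included(self):
        grid = np.array([390.0, 400.0, 1800.0, 1810.0])
        out = rc.truncate(_spec(np.arange(4.0), grid), 400, 1800)
        assert np.array_equal(out.shifts, [400.0, 1800.0])

    def test_empty_range_error(self):
        with pytest.raises(EmptyRangeError):
            rc.truncate(_spec(np.ones(GRID.size)), 1900, 2000)


class TestGoldindec:
    def test_zero_spectrum_fixed_point(self):
        bl, corr = rc.goldindec_baseline(_spec(np.zeros(GRID.size)))
        assert np.allclose(bl.intensities, 0)
        assert np.allclose(corr.intensities, 0)

    def test_collapses_to_ols_on_pure_polynomial(self):
        k = np.arange(GRID.size, dtype=float)
        y = 5.0 + 0.01 * k + 1e-6 * k**2 - 2e-9 * k**3
        bl, corr = rc.goldindec_baseline(_spec(y))
        ols = polynomial_ols_baseline(_spec(y))
        scale = np.ptp(y)
        assert np.max(np.abs(bl.intensities - ols.intensities)) < 1e-6 * scale
        assert np.max(np.abs(corr.intensities)) < 1e-2 * scale

    def test_recovers_baseline_under_peaks(self):
        # random cubic + peaks + noise, truth from the generator
        cfg = rc.SynthConfig(seed=11, n_scans=1)
        X, gt = rc.generate_dataset(cfg)
        max_amp = max(p.amplitude for p in cfg.peaks)
        rmses = []
        for i in range(20):
            s = X.spectrum(i)
            bl, _ = rc.goldindec_baseline(s)
            true = gt.baselines[s.meta.sample]
            rmses.append(np.sqrt(np.mean((bl.intensities - true) ** 2)))
        assert max(rmses) < 0.05 * max_amp

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        y = np.exp(-0.5 * ((GRID - 1005) / 8) ** 2) + 0.01 * rng.normal(size=GRID.size)
        bl0, corr0 = rc.goldindec_baseline(_spec(y))
        bl1, corr1 = rc.goldindec_baseline(_spec(y + 7.5))
        assert np.allclose(bl1.intensities - bl0.intensities, 7.5, atol=1e-8)
        assert np.allclose(corr1.intensities, corr0.intensities, atol=1e-8)

    def test_too_short_input_rejected(self):
        with pytest.raises(InputError):
            rc.goldindec_baseline(rc.Spectrum([1.0, 2, 3, 4], np.ones(4)))

    def test_smoother_preserves_cubics(self):
        x = np.linspace(-1, 1, 101)
        y = 1 - 2 * x + 0.5 * x**2 + 3 * x**3
        assert np.allclose(smooth_intensities(y, 5, 3), y, atol=1e-12)


class TestVectorNormalize:
    def test_three_four_five(self):
        out = rc.vector_normalize(rc.Spectrum([400.0, 410.0], [3.0, 4.0]))
        assert np.allclose(out.intensities, [0.6, 0.8])

    def test_unit_norm_forced(self):
        out = rc.vector_normalize(rc.Spectrum([1.0, 2, 3, 4], np.ones(4)))
        assert np.allclose(out.intensities, 0.5)

    def test_zero_rejected(self):
        with pytest.raises(NormalizationError):
            rc.vector_normalize(rc.Spectrum([400.0, 410.0], [0.0, 0.0]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_output_norm_is_one(self, vals):
        y = np.asarray(vals)
        if np.linalg.norm(y) < 1e-9:
            return
        out = rc.vector_normalize(rc.Spectrum(np.arange(y.size, dtype=float), y))
        assert out.norm() == pytest.approx(1.0, abs=1e-9)


class TestPipeline:
    def test_counts_and_unit_norm(self, tiny_cfg):
        X, _ = rc.generate_dataset(tiny_cfg)
        proc = rc.preprocess_pipeline(X)
        n_samples = (len(tiny_cfg.concentrations) * tiny_cfg.n_bio_reps
                     * tiny_cfg.n_samples_per_rep)
        assert len(proc) == n_samples
        assert np.allclose(np.linalg.norm(proc.intensities, axis=1), 1.0, atol=1e-9)

    def test_twelve_samples_from_4x3x20(self):
        cfg = rc.SynthConfig(seed=5, grid_step=8.0, n_samples_per_rep=1, n_scans=20)
        X, _ = rc.generate_dataset(cfg)
        proc = rc.preprocess_pipeline(X)
        assert len(proc) == 12

    def test_sample_permutation_equivariance(self, tiny_cfg):
        X, _ = rc.generate_dataset(tiny_cfg)
        proc1 = rc.preprocess_pipeline(X)
        # permute whole samples (keep scans of a sample contiguous)
        samples = list(dict.fromkeys(X.samples))
        rng = np.random.default_rng(0)
        perm_samples = [samples[i] for i in rng.permutation(len(samples))]
        order = np.concatenate([np.flatnonzero(X.samples == s) for s in perm_samples])
        proc2 = rc.preprocess_pipeline(X.select(order))
        m1 = {s: proc1.intensities[i] for i, s in enumerate(proc1.samples)}
        for i, s in enumerate(proc2.samples):
            assert np.array_equal(proc2.intensities[i], m1[s])

    def test_zero_sample_names_culprit(self):
        cfg = rc.SynthConfig(seed=5, grid_step=8.0, n_samples_per_rep=1,
                             n_bio_reps=1, n_scans=2, noise_sd=0.0,
                             baseline_scale=0.0)
        X, _ = rc.generate_dataset(cfg)
        bad = X.samples[0]
        X.intensities[np.flatnonzero(X.samples == bad)] = 0.0
        with pytest.raises(NormalizationError, match=str(bad)):
            rc.preprocess_pipeline(X)
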
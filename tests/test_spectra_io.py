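"""Spectrum parsing, writing, grid alignment and dataset loading."""

import numpy as np
import pandas as pd
import pytest

import ramanchemo as rc
from ramanchemo.errors import (
    AlignmentError,
    ExtrapolationError,
    FormatError,
    InputError,
    MissingFileError,
)
from ramanchemo.io import load_dataset, validate_manifest


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSpectrum:
    def test_plain_pairs(self, tmp_path):
        p = _write(tmp_path, "a.csv", "400,1.0\n500,2.0\n")
        s = rc.read_spectrum(p)
        assert np.array_equal(s.shifts, [400, 500])
        assert np.array_equal(s.intensities, [1.0, 2.0])

    def test_descending_rows_are_sorted(self, tmp_path):
        p = _write(tmp_path, "a.csv", "500,2.0\n400,1.0\n450,9\n")
        s = rc.read_spectrum(p)
        assert np.array_equal(s.shifts, [400, 450, 500])
        assert np.array_equal(s.intensities, [1.0, 9.0, 2.0])

    def test_bad_value_names_line(self, tmp_path):
        p = _write(tmp_path, "a.csv", "400,abc\n500,2.0\n")
        with pytest.raises(FormatError, match="line 1"):
            rc.read_spectrum(p)

    def test_header_line_tolerated(self, tmp_path):
        p = _write(tmp_path, "a.csv", "shift_cm1,intensity\n400,1\n500,2\n")
        s = rc.read_spectrum(p)
        assert len(s) == 2

    def test_too_few_points(self, tmp_path):
        p = _write(tmp_path, "a.csv", "400,1.0\n")
        with pytest.raises(InputError):
            rc.read_spectrum(p)

    def test_duplicate_shift_rejected(self, tmp_path):
        p = _write(tmp_path, "a.csv", "400,1\n400,2\n500,3\n")
        with pytest.raises(FormatError):
            rc.read_spectrum(p)

    def test_jcamp_subset(self, tmp_path):
        text = (
            "##TITLE=demo\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n"
            "##XYDATA=(XY..XY)\n400, 1.0\n410 2.0\n420, 3.0\n##END=\n"
        )
        p = _write(tmp_path, "a.jdx", text)
        s = rc.read_spectrum(p, dialect="jcamp-dx")
        assert np.array_equal(s.shifts, [400, 410, 420])
        assert np.array_equal(s.intensities, [1, 2, 3])

    def test_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        s = rc.Spectrum(np.sort(rng.uniform(400, 1800, 50)), rng.normal(size=50))
        p = tmp_path / "rt.csv"
        rc.write_spectrum(p, s)
        back = rc.read_spectrum(p)
        assert np.array_equal(back.shifts, s.shifts)
        assert np.array_equal(back.intensities, s.intensities)


class TestResample:
    def test_linear_midpoint(self):
        s = rc.Spectrum([400.0, 402.0], [0.0, 2.0])
        out = rc.resample_to_grid(s, [400.0, 401.0, 402.0])
        assert out.intensities[1] == pytest.approx(1.0)

    def test_identity_grid(self):
        s = rc.Spectrum([400.0, 410, 420], [1.0, 5.0, 2.0])
        out = rc.resample_to_grid(s, s.shifts)
        assert np.array_equal(out.intensities, s.intensities)

    def test_exact_on_source_nodes(self):
        rng = np.random.default_rng(1)
        grid = np.sort(rng.uniform(400, 1800, 40))
        s = rc.Spectrum(grid, rng.normal(size=40))
        sub = grid[::3]
        out = rc.resample_to_grid(s, sub)
        assert np.array_equal(out.intensities, s.intensities[::3])

    def test_extrapolation_error(self):
        s = rc.Spectrum([400.0, 402.0], [0.0, 2.0])
        with pytest.raises(ExtrapolationError):
            rc.resample_to_grid(s, [399.0, 401.0])


class TestSpectrumInvariants:
    def test_nonincreasing_shifts_rejected(self):
        with pytest.raises(InputError):
            rc.Spectrum([400.0, 400.0, 410.0], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            rc.Spectrum([400.0, 410.0], [1.0])


def _study_on_disk(tmp_path, cfg):
    return rc.write_study(tmp_path / "study", cfg)


class TestLoadDataset:
    def test_identical_grids_pass_through(self, tmp_path):
        grid = "400,1\n500,2\n600,3\n"
        _write(tmp_path, "a.csv", grid)
        _write(tmp_path, "b.csv", "400,9\n500,8\n600,7\n")
        mf = pd.DataFrame(
            {
                "file": ["a.csv", "b.csv"],
                "sample": ["s1", "s2"],
                "condition": ["c", "c"],
                "concentration_mM": [0.0, 0.0],
                "replicate": ["r1", "r1"],
                "scan": [1, 1],
            }
        )
        ds = load_dataset(mf, base_dir=tmp_path)
        assert len(ds) == 2
        assert np.array_equal(ds.grid, [400, 500, 600])

    def test_disjoint_grids_intersection_error(self, tmp_path):
        _write(tmp_path, "a.csv", "400,1\n402,2\n404,3\n")
        _write(tmp_path, "b.csv", "401,1\n403,2\n405,3\n")
        mf = pd.DataFrame(
            {
                "file": ["a.csv", "b.csv"],
                "sample": ["s1", "s2"],
                "condition": ["c", "c"],
                "concentration_mM": [0.0, 0.0],
                "replicate": ["r1", "r1"],
                "scan": [1, 1],
            }
        )
        with pytest.raises(AlignmentError):
            load_dataset(mf, base_dir=tmp_path, grid_policy="intersection")

    def test_missing_file_error(self, tmp_path):
        mf = pd.DataFrame(
            {
                "file": ["nope.csv", "also.csv"],
                "sample": ["s1", "s2"],
                "condition": ["c", "c"],
                "concentration_mM": [0.0, 0.0],
                "replicate": ["r1", "r1"],
                "scan": [1, 1],
            }
        )
        with pytest.raises(MissingFileError):
            load_dataset(mf, base_dir=tmp_path)

    def test_synthetic_study_roundtrip_240_scans(self, tmp_path):
        # 4 classes x 3 bio reps x 1 sample x 20 scans = 240 files
        cfg = rc.SynthConfig(seed=3, grid_step=8.0, n_samples_per_rep=1, n_scans=20)
        paths = _study_on_disk(tmp_path, cfg)
        mf = rc.read_manifest(paths["manifest"])
        assert len(mf) == 240
        ds = load_dataset(mf, base_dir=tmp_path / "study")
        assert len(ds) == 240
        assert set(ds.labels) == {"0 mM", "7.5 mM", "15 mM", "30 mM"}

    def test_manifest_permutation_permutes_spectra(self, tmp_path):
        cfg = rc.SynthConfig(seed=3, grid_step=8.0, n_samples_per_rep=1,
                             n_bio_reps=1, n_scans=3)
        paths = _study_on_disk(tmp_path, cfg)
        mf = rc.read_manifest(paths["manifest"])
        perm = np.random.default_rng(5).permutation(len(mf))
        ds1 = load_dataset(mf, base_dir=tmp_path / "study")
        ds2 = load_dataset(mf.iloc[perm], base_dir=tmp_path / "study")
        assert np.array_equal(ds2.intensities, ds1.intensities[perm])
        assert list(ds2.samples) == list(np.asarray(ds1.samples)[perm])

    def test_duplicate_manifest_file_rejected(self):
        mf = pd.DataFrame(
            {
                "file": ["a.csv", "a.csv"],
                "sample": ["s1", "s2"],
                "condition": ["c", "c"],
                "concentration_mM": [0.0, 0.0],
                "replicate": ["r1", "r1"],
                "scan": [1, 2],
            }
        )
        with pytest.raises(InputError):
            validate_manifest(mf)
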
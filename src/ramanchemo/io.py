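"""Reading and writing spectra, manifests, and grid alignment.

Supported spectrum file dialects:

``two-column-csv``
    Plain text, one ``shift, intensity`` pair per line.  Comma, semicolon
    or whitespace separated; a single non-numeric header line and ``#``
    comment lines are tolerated.  This is the documented exchange format
    (columns ``shift_cm1, intensity``).

``jcamp-dx``
    A minimal JCAMP-DX subset: ``##``-prefixed label lines are treated as
    metadata and ignored except ``##XYDATA`` / ``##XYPOINTS``, after which
    numeric ``x y`` pairs are read until ``##END``.  Only the ``(XY..XY)``
    pair layout is supported — enough for instrument exports of point
    spectra, not the compressed ``(X++(Y..Y))`` forms.

A manifest is a CSV with columns
``file, sample, condition, concentration_mM, replicate, scan`` mapping
scan files to their sample annotations.
"""

from __future__ import annotations

import os
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    InputError,
    MissingFileError,
)
from .spectra import Spectrum, SpectrumMeta, SpectraSet, resample_to_grid

MANIFEST_COLUMNS = ["file", "sample", "condition", "concentration_mM", "replicate", "scan"]

_SPLIT = re.compile(r"[,;\s]+")


def _parse_pair(line: str):
    parts = [p for p in _SPLIT.split(line.strip()) if p]
    if len(parts) < 2:
        raise ValueError("fewer than two fields")
    return float(parts[0]), float(parts[1])


def _any_numeric(line: str) -> bool:
    for part in _SPLIT.split(line.strip()):
        if not part:
            continue
        try:
            float(part)
            return True
        except ValueError:
            pass
    return False


def _read_two_column(text: str, path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    seen_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            x, y = _parse_pair(line)
        except ValueError:
            if not seen_data and not _any_numeric(line):
                # a purely textual header line (e.g. "shift_cm1,intensity")
                # is allowed before the first data row
                seen_data = True
                continue
            raise FormatError(f"{path}: unparseable line {lineno}: {raw!r}") from None
        seen_data = True
        xs.append(x)
        ys.append(y)
    return np.asarray(xs), np.asarray(ys)


def _read_jcamp(text: str, path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label = line[2:].split("=", 1)[0].strip().upper().replace(" ", "")
            if label in ("XYDATA", "XYPOINTS"):
                in_data = True
            elif label == "END":
                in_data = False
            continue
        if not in_data:
            continue
        try:
            x, y = _parse_pair(line)
        except ValueError:
            raise FormatError(f"{path}: unparseable line {lineno}: {raw!r}") from None
        xs.append(x)
        ys.append(y)
    return np.asarray(xs), np.asarray(ys)


def read_spectrum(path, dialect: str = "two-column-csv") -> Spectrum:
    """Read one spectrum from a text file.

    Rows may appear in any shift order; the result is sorted ascending.
    Metadata is left unset (it comes from the manifest).

    Raises
    ------
    FormatError
        On an unparseable line (the message names the line number) or a
        duplicated shift value.
    InputError
        If fewer than 2 points were read.
    """
    if dialect not in ("two-column-csv", "jcamp-dx"):
        raise InputError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "two-column-csv":
        x, y = _read_two_column(text, path)
    else:
        x, y = _read_jcamp(text, path)
    if x.size < 2:
        raise InputError(f"{path}: a spectrum needs at least 2 points, got {x.size}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        raise FormatError(f"{path}: duplicate shift values")
    return Spectrum(x, y)


def write_spectrum(path, s: Spectrum) -> None:
    """Write a spectrum as two-column CSV (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("shift_cm1,intensity\n")
        for x, y in zip(s.shifts, s.intensities):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(path)
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    if df["file"].duplicated().any():
        dup = df.loc[df["file"].duplicated(), "file"].iloc[0]
        raise InputError(f"manifest has duplicate file path: {dup}")
    if (df["concentration_mM"].astype(float) < 0).any():
        raise InputError("manifest concentrations must be non-negative")
    return df.reset_index(drop=True)


def write_manifest(path, df: pd.DataFrame) -> None:
    validate_manifest(df).to_csv(path, index=False)


def _common_grid(grids: Sequence[np.ndarray]) -> np.ndarray:
    common = grids[0]
    for g in grids[1:]:
        common = np.intersect1d(common, g)
        if common.size == 0:
            break
    if common.size < 2:
        raise AlignmentError(
            "intersection grid policy produced an empty (or single-point) grid"
        )
    return common


def load_dataset(
    manifest: pd.DataFrame,
    base_dir=None,
    grid_policy: str = "reference-grid",
    dialect: str = "two-column-csv",
) -> SpectraSet:
    """Read every manifest row and align all spectra onto one grid.

    ``grid_policy``:

    * ``reference-grid`` (default) — the grid of the first manifest entry;
      other spectra are linearly interpolated onto it.
    * ``intersection`` — the exact set-intersection of all grids (no
      interpolation; errors if empty).

    Manifest order is preserved, so permuting manifest rows permutes the
    resulting spectra identically.
    """
    if grid_policy not in ("reference-grid", "intersection"):
        raise InputError(f"unknown grid policy {grid_policy!r}")
    manifest = validate_manifest(manifest)
    if len(manifest) == 0:
        raise InputError("manifest is empty")

    spectra = []
    for row in manifest.itertuples(index=False):
        fpath = row.file if base_dir is None else os.path.join(base_dir, row.file)
        if not os.path.exists(fpath):
            raise MissingFileError(f"manifest row points to missing file: {fpath}")
        s = read_spectrum(fpath, dialect=dialect)
        scan = None if pd.isna(row.scan) else int(row.scan)
        meta = SpectrumMeta(
            sample=str(row.sample),
            condition=str(row.condition),
            concentration_mM=float(row.concentration_mM),
            replicate=str(row.replicate),
            scan=scan,
        )
        spectra.append(Spectrum(s.shifts, s.intensities, meta))

    if grid_policy == "reference-grid":
        grid = spectra[0].shifts
    else:
        grid = _common_grid([s.shifts for s in spectra])
    aligned = [resample_to_grid(s, grid) for s in spectra]
    return SpectraSet.from_spectra(aligned)
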
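"""Band-intensity extraction and correlation with analyte measurements.

A band assignment is a published Raman shift (e.g. 1005 cm⁻¹ for the
phenylalanine ring-breathing mode, 1157/1520 cm⁻¹ for carotenoid C–C/C=C
stretches) plus a half-window; the band intensity of a processed
spectrum is the mean normalized intensity over the grid points inside
``center ± half_window`` (nearest grid point when the half-window is 0).

``correlate_bands`` compares these readouts with analyte levels measured
by reference chemistry (UPLC amino acids, GC-FID fatty-acid methyl
esters): band intensities and analyte levels are averaged per condition
× biological replicate and each mapped (analyte, band) pair is scored by
its Pearson R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import BandRangeError, InputError
from .spectra import Spectrum, SpectraSet
from .stats import pearson

DEFAULT_HALF_WINDOW = 6.0  # cm⁻¹, about half the ~13 cm⁻¹ spectral resolution


@dataclass(frozen=True)
class BandAssignment:
    """One assigned Raman band: center, window, and the biomolecule."""

    center_cm1: float
    halfwindow_cm1: float = DEFAULT_HALF_WINDOW
    biomolecule: str = ""
    note: str = ""

    def __post_init__(self):
        if self.halfwindow_cm1 < 0:
            raise InputError("half-window must be >= 0")


def read_bands(path) -> list[BandAssignment]:
    """Read a band table CSV (center_cm1, halfwindow_cm1, biomolecule)."""
    df = pd.read_csv(path)
    for col in ("center_cm1", "halfwindow_cm1", "biomolecule"):
        if col not in df.columns:
            raise InputError(f"band table missing column {col!r}")
    return [
        BandAssignment(
            center_cm1=float(r.center_cm1),
            halfwindow_cm1=float(r.halfwindow_cm1),
            biomolecule=str(r.biomolecule),
        )
        for r in df.itertuples(index=False)
    ]


def write_bands(path, bands) -> None:
    pd.DataFrame(
        {
            "center_cm1": [b.center_cm1 for b in bands],
            "halfwindow_cm1": [b.halfwindow_cm1 for b in bands],
            "biomolecule": [b.biomolecule for b in bands],
        }
    ).to_csv(path, index=False)


#: Analyte tables are plain DataFrames with columns
#: ``condition, replicate, analyte, level, unit`` (one row per
#: condition × replicate × analyte measurement).
ANALYTE_COLUMNS = ["condition", "replicate", "analyte", "level", "unit"]


def validate_analytes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANALYTE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"analyte table missing columns: {missing}")
    if (df["level"].astype(float) < 0).any():
        raise InputError("analyte levels must be non-negative")
    return df.reset_index(drop=True)


def read_analytes(path) -> pd.DataFrame:
    return validate_analytes(pd.read_csv(path))


def band_intensity(s: Spectrum, band: BandAssignment) -> float:
    """Mean intensity over the grid points inside the band window.

    With ``halfwindow_cm1 == 0`` (or a window narrower than the grid
    step) the nearest grid point to the center is used.
    """
    lo = band.center_cm1 - band.halfwindow_cm1
    hi = band.center_cm1 + band.halfwindow_cm1
    if hi < s.shifts[0] or lo > s.shifts[-1]:
        raise BandRangeError(
            f"band {band.center_cm1:g}±{band.halfwindow_cm1:g} cm⁻¹ does not "
            f"overlap the grid [{s.shifts[0]:g}, {s.shifts[-1]:g}]"
        )
    mask = (s.shifts >= lo) & (s.shifts <= hi)
    if not mask.any():
        idx = int(np.argmin(np.abs(s.shifts - band.center_cm1)))
        return float(s.intensities[idx])
    return float(s.intensities[mask].mean())


def correlate_bands(
    X: SpectraSet,
    bands,
    analytes: pd.DataFrame,
    mapping: Mapping[str, BandAssignment],
) -> pd.DataFrame:
    """Pearson R between mapped band intensities and analyte levels.

    For every ``analyte -> band`` pair in ``mapping``, band intensities
    of the processed spectra and the analyte levels are both averaged
    per (condition, replicate) cell shared by the two datasets, and the
    two vectors are correlated.  At least 3 shared conditions are
    required.

    Returns a table with columns
    ``analyte, band_center_cm1, biomolecule, R, n_points``.
    """
    analytes = validate_analytes(analytes)
    cond_x = set(X.labels.tolist())
    cond_a = set(analytes["condition"].astype(str))
    shared = cond_x & cond_a
    if len(shared) < 3:
        raise InputError(
            f"need at least 3 shared conditions, got {len(shared)}"
        )

    meta = X.meta.copy()
    rows = []
    for analyte, band in mapping.items():
        sub = analytes[analytes["analyte"] == analyte]
        if sub.empty:
            raise InputError(f"analyte {analyte!r} absent from the table")
        meta["_band"] = [band_intensity(X.spectrum(i), band) for i in range(len(X))]
        band_cell = (
            meta[meta["condition"].isin(shared)]
            .groupby(["condition", "replicate"])["_band"]
            .mean()
        )
        lvl_cell = (
            sub[sub["condition"].astype(str).isin(shared)]
            .assign(replicate=lambda d: d["replicate"].astype(str))
            .groupby(["condition", "replicate"])["level"]
            .mean()
        )
        band_cell.index = pd.MultiIndex.from_tuples(
            [(str(c), str(r)) for c, r in band_cell.index]
        )
        common = band_cell.index.intersection(lvl_cell.index)
        if len(common) < 3:
            raise InputError(
                f"analyte {analyte!r}: fewer than 3 shared condition/replicate cells"
            )
        r = pearson(band_cell.loc[common].to_numpy(), lvl_cell.loc[common].to_numpy())
        rows.append(
            {
                "analyte": analyte,
                "band_center_cm1": band.center_cm1,
                "biomolecule": band.biomolecule,
                "R": r,
                "n_points": len(common),
            }
        )
    return pd.DataFrame(rows)
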
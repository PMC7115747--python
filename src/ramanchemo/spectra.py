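"""Core in-memory containers: a single scan and an aligned collection.

A :class:`Spectrum` is one point scan — a strictly increasing Raman-shift
grid (cm⁻¹) with matching intensities (a.u.) and sample metadata.  A
:class:`SpectraSet` holds many spectra on one shared grid together with a
pandas metadata table (sample id, condition label, concentration,
biological replicate, scan index), which is the container every modelling
stage operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ExtrapolationError, InputError

#: Metadata columns carried by :class:`SpectraSet`.
META_COLUMNS = ["sample", "condition", "concentration_mM", "replicate", "scan"]


@dataclass(frozen=True)
class SpectrumMeta:
    """Sample annotations for one scan. All fields optional on raw reads."""

    sample: Optional[str] = None
    condition: Optional[str] = None
    concentration_mM: Optional[float] = None
    replicate: Optional[str] = None
    scan: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "condition": self.condition,
            "concentration_mM": self.concentration_mM,
            "replicate": self.replicate,
            "scan": self.scan,
        }


@dataclass
class Spectrum:
    """One Raman scan on a strictly increasing shift grid.

    Parameters
    ----------
    shifts : array-like
        Raman shifts in cm⁻¹, strictly increasing, length ≥ 2.
    intensities : array-like
        Intensities (arbitrary units), same length as ``shifts``.  May be
        negative after baseline correction.
    meta : SpectrumMeta
        Sample annotations.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise InputError("shifts and intensities must be 1-D")
        if self.shifts.size != self.intensities.size:
            raise InputError(
                f"length mismatch: {self.shifts.size} shifts vs "
                f"{self.intensities.size} intensities"
            )
        if self.shifts.size < 2:
            raise InputError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.shifts) > 0):
            raise InputError("shifts must be strictly increasing")

    def __len__(self) -> int:
        return self.shifts.size

    def with_intensities(self, intensities, **meta_updates) -> "Spectrum":
        """Copy with new intensities (same grid) and optional meta updates."""
        meta = replace(self.meta, **meta_updates) if meta_updates else self.meta
        return Spectrum(self.shifts.copy(), np.asarray(intensities, float), meta)

    def norm(self) -> float:
        """Euclidean norm of the intensity vector."""
        return float(np.linalg.norm(self.intensities))


def resample_to_grid(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Exact on points that already belong to the source grid.

    Raises
    ------
    ExtrapolationError
        If any grid point falls outside ``[min(s.shifts), max(s.shifts)]``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.shifts[0] or grid.max() > s.shifts[-1]:
        raise ExtrapolationError(
            f"target grid [{grid.min():g}, {grid.max():g}] extends outside the "
            f"source range [{s.shifts[0]:g}, {s.shifts[-1]:g}]"
        )
    vals = np.interp(grid, s.shifts, s.intensities)
    # np.interp is exact at source nodes, so identity grids round-trip.
    return Spectrum(grid, vals, s.meta)


class SpectraSet:
    """Aligned spectra on one shared grid, with per-spectrum metadata.

    Attributes
    ----------
    grid : ndarray, shape (p,)
        Shared Raman-shift grid in cm⁻¹.
    intensities : ndarray, shape (n, p)
        One row per spectrum.
    meta : pandas.DataFrame
        Columns ``sample, condition, concentration_mM, replicate, scan``,
        one row per spectrum, positionally aligned with ``intensities``.
    """

    def __init__(self, grid, intensities, meta: pd.DataFrame):
        self.grid = np.asarray(grid, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if not np.all(np.diff(self.grid) > 0):
            raise InputError("grid must be strictly increasing")
        if self.intensities.shape[1] != self.grid.size:
            raise AlignmentError(
                f"intensity matrix has {self.intensities.shape[1]} columns, "
                f"grid has {self.grid.size} points"
            )
        meta = meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        if len(meta) != self.intensities.shape[0]:
            raise InputError("metadata rows must match spectra count")
        if meta["condition"].isna().any():
            raise InputError("every spectrum needs a condition label")
        self.meta = meta

    # -- construction -------------------------------------------------

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        """Stack spectra that already share an identical grid."""
        if not spectra:
            raise InputError("empty spectra list")
        grid = spectra[0].shifts
        for s in spectra[1:]:
            if s.shifts.size != grid.size or not np.array_equal(s.shifts, grid):
                raise AlignmentError("spectra are not on a common grid")
        meta = pd.DataFrame([s.meta.as_dict() for s in spectra])
        X = np.vstack([s.intensities for s in spectra])
        return cls(grid, X, meta)

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Condition label per spectrum."""
        return self.meta["condition"].to_numpy()

    @property
    def concentrations(self) -> np.ndarray:
        return self.meta["concentration_mM"].to_numpy(dtype=float)

    @property
    def samples(self) -> np.ndarray:
        return self.meta["sample"].to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        scan = row["scan"]
        meta = SpectrumMeta(
            sample=row["sample"],
            condition=row["condition"],
            concentration_mM=row["concentration_mM"],
            replicate=row["replicate"],
            scan=None if pd.isna(scan) else int(scan),
        )
        return Spectrum(self.grid.copy(), self.intensities[i].copy(), meta)

    def spectra(self) -> Iterable[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectraSet(self.grid, self.intensities[idx], self.meta.iloc[idx])
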
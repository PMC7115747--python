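"""Scan averaging, Goldindec baseline correction, truncation, normalization.

The processing chain applied to every sample, in this fixed order:

1. arithmetic averaging of its repeated scans (``average_scans``),
2. truncation to the biological fingerprint range, 400–1800 cm⁻¹
   (``truncate``),
3. polynomial baseline removal with the Goldindec iterative scheme
   (``goldindec_baseline``, defaults: polynomial order 3, estimated peak
   ratio 0.5, smoothing window 5 points),
4. scaling to unit euclidean norm (``vector_normalize``).

Goldindec here is an iteratively reweighted polynomial fit with an
asymmetric truncated-quadratic cost: points whose residual above the
current baseline exceeds a threshold are treated as peak points and
carry zero weight, while points at or below the baseline always keep
full quadratic weight.  The threshold is driven by the *estimated peak
ratio* — it is taken as the ``(1 − peak_ratio)`` quantile of the current
residuals (floored at zero), so roughly a ``peak_ratio`` fraction of the
spectrum is allowed to sit above the fitted background.  A
Savitzky–Golay filter of ``smooth_window`` points (local polynomial of
the baseline degree) is applied before fitting — it suppresses
high-frequency noise while reproducing any polynomial of the baseline
degree exactly, edges included — and the fitted baseline is subtracted
from the *unsmoothed* signal.  On a peakless polynomial input the scheme
therefore collapses to the ordinary least-squares polynomial fit in one
iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.signal import savgol_filter

from .errors import (
    AlignmentError,
    ConvergenceError,
    EmptyRangeError,
    InputError,
    NormalizationError,
    ParameterError,
)
from .spectra import Spectrum, SpectraSet, SpectrumMeta

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    Attributes
    ----------
    poly_order : int
        Baseline polynomial degree (default 3).
    peak_ratio : float
        Estimated fraction of the spectrum occupied by peaks, in (0, 1)
        (default 0.5); drives the asymmetric-cost threshold.
    smooth_window : int
        Savitzky–Golay smoothing width in grid points, odd, ≥ 3
        (default 5).
    range_lo, range_hi : float
        Truncation bounds in cm⁻¹ (defaults 400, 1800), closed interval.
    norm : str
        Normalization mode; only ``"unit-euclidean"`` is defined.
    """

    poly_order: int = 3
    peak_ratio: float = 0.5
    smooth_window: int = 5
    range_lo: float = 400.0
    range_hi: float = 1800.0
    norm: str = "unit-euclidean"

    def __post_init__(self):
        if self.poly_order < 1:
            raise ParameterError("poly_order must be >= 1")
        if not (0.0 < self.peak_ratio < 1.0):
            raise ParameterError("peak_ratio must be in (0, 1)")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be odd and >= 3")
        if not self.range_lo < self.range_hi:
            raise ParameterError("range_lo must be < range_hi")
        if self.norm != "unit-euclidean":
            raise ParameterError(f"unsupported norm {self.norm!r}")

    def to_dict(self) -> dict:
        return {
            "poly_order": self.poly_order,
            "peak_ratio": self.peak_ratio,
            "smooth_window": self.smooth_window,
            "range_lo": self.range_lo,
            "range_hi": self.range_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        known = {k: d[k] for k in ("poly_order", "peak_ratio", "smooth_window", "range_lo", "range_hi") if k in d}
        return cls(**known)


def average_scans(scans: Sequence[Spectrum], sample: str | None = None) -> Spectrum:
    """Pointwise arithmetic mean of repeated scans on one grid.

    Metadata is inherited from the first scan (scan index cleared);
    ``sample`` overrides the sample id if given.
    """
    if len(scans) == 0:
        raise InputError("average_scans needs at least one scan")
    grid = scans[0].shifts
    for s in scans[1:]:
        if s.shifts.size != grid.size or not np.array_equal(s.shifts, grid):
            raise AlignmentError("scans are not on a common grid")
    mean = np.mean([s.intensities for s in scans], axis=0)
    m = scans[0].meta
    meta = SpectrumMeta(
        sample=sample if sample is not None else m.sample,
        condition=m.condition,
        concentration_mM=m.concentration_mM,
        replicate=m.replicate,
        scan=None,
    )
    return Spectrum(grid.copy(), mean, meta)


def truncate(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep exactly the grid points with ``lo <= shift <= hi`` (closed)."""
    mask = (s.shifts >= lo) & (s.shifts <= hi)
    if mask.sum() < 2:
        raise EmptyRangeError(
            f"truncation to [{lo:g}, {hi:g}] leaves {int(mask.sum())} point(s)"
        )
    return Spectrum(s.shifts[mask], s.intensities[mask], s.meta)


def smooth_intensities(y: np.ndarray, window: int, poly_order: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing of ``window`` points.

    The local polynomial degree is capped at ``min(poly_order,
    window − 2)`` so the filter reproduces any polynomial of the baseline
    degree exactly (interior and edges).
    """
    y = np.asarray(y, float)
    deg = min(poly_order, window - 2)
    if window > y.size:
        return y.copy()
    return savgol_filter(y, window_length=window, polyorder=deg)


def _weighted_polyfit(V: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    idx = w > 0
    coef, *_ = np.linalg.lstsq(V[idx], y[idx], rcond=None)
    return coef


def goldindec_baseline(
    s: Spectrum,
    cfg: PreprocessConfig | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[Spectrum, Spectrum]:
    """Fit and subtract a polynomial background with the Goldindec scheme.

    Returns ``(baseline, corrected)`` where ``corrected = s − baseline``.
    Iteration stops when the relative change of the coefficient vector
    drops below ``tol``, or when the peak/background partition revisits a
    previous state (the coefficients are a deterministic function of the
    partition, so a revisit means the iteration has settled into
    threshold flapping at or below working precision).

    Raises
    ------
    ConvergenceError
        If neither happens within ``max_iter`` iterations; the exception
        carries the last baseline iterate.
    """
    cfg = cfg if cfg is not None else PreprocessConfig()
    deg = cfg.poly_order
    n = len(s)
    if n < deg + 2:
        raise InputError(f"need at least poly_order + 2 = {deg + 2} points, got {n}")

    y_raw = s.intensities
    y = smooth_intensities(y_raw, cfg.smooth_window, cfg.poly_order)

    # shifts scaled to [-1, 1] for numerical conditioning
    lo, hi = s.shifts[0], s.shifts[-1]
    x = (2.0 * s.shifts - (lo + hi)) / (hi - lo)
    V = P.polyvander(x, deg)

    coef = _weighted_polyfit(V, y, np.ones(n))
    scale = max(float(np.linalg.norm(coef)), 1e-300)
    seen: set[bytes] = set()
    converged = False
    for _ in range(max_iter):
        b = V @ coef
        r = y - b
        thr = max(float(np.quantile(r, 1.0 - cfg.peak_ratio)), 0.0)
        w = (r <= thr).astype(float)
        if w.sum() < deg + 2:
            # keep the lowest-residual points so the fit stays determined
            keep = np.argsort(r)[: deg + 2]
            w[:] = 0.0
            w[keep] = 1.0
        key = w.tobytes()
        if key in seen:
            converged = True
            break
        seen.add(key)
        new = _weighted_polyfit(V, y, w)
        delta = float(np.linalg.norm(new - coef)) / max(float(np.linalg.norm(coef)), 1e-12 * scale, 1e-300)
        coef = new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Goldindec did not converge in {max_iter} iterations",
            last_baseline=V @ coef,
        )

    baseline_vals = V @ coef
    baseline = s.with_intensities(baseline_vals)
    corrected = s.with_intensities(y_raw - baseline_vals)
    return baseline, corrected


def polynomial_ols_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Plain least-squares polynomial background of the smoothed signal.

    Reference fit used for comparison and testing: same smoothing and
    scaling as :func:`goldindec_baseline` but no peak reweighting.
    """
    cfg = cfg if cfg is not None else PreprocessConfig()
    y = smooth_intensities(s.intensities, cfg.smooth_window, cfg.poly_order)
    lo, hi = s.shifts[0], s.shifts[-1]
    x = (2.0 * s.shifts - (lo + hi)) / (hi - lo)
    V = P.polyvander(x, cfg.poly_order)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    return s.with_intensities(V @ coef)


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit euclidean norm."""
    nrm = s.norm()
    if nrm <= 0.0 or not np.isfinite(nrm):
        raise NormalizationError(
            f"zero-norm spectrum cannot be normalized (sample {s.meta.sample!r})"
        )
    return s.with_intensities(s.intensities / nrm)


def preprocess_pipeline(raw: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Average scans per sample, truncate, baseline, and normalize.

    Returns one unit-norm spectrum per sample, in order of each sample's
    first appearance.  Stage errors are re-raised annotated with the
    sample id.
    """
    cfg = cfg if cfg is not None else PreprocessConfig()
    sample_order = raw.meta["sample"].drop_duplicates().tolist()
    out = []
    for sample in sample_order:
        idx = np.flatnonzero(raw.samples == sample)
        scans = [raw.spectrum(i) for i in idx]
        try:
            avg = average_scans(scans, sample=sample)
            trunc = truncate(avg, cfg.range_lo, cfg.range_hi)
            _, corrected = goldindec_baseline(trunc, cfg)
            out.append(vector_normalize(corrected))
        except NormalizationError:
            raise NormalizationError(
                f"sample {sample!r} has zero norm after baseline correction"
            ) from None
    return SpectraSet.from_spectra(out)
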
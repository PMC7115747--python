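"""L1-form distance statistics of spectra against a reference.

Three distances condense a spectrum's relation to a chosen reference
into one number, all with the same per-term form
``Σ_i sqrt((v_x,i − v_ref,i)²) = Σ_i |v_x,i − v_ref,i|`` — i.e. an L1
(city-block) sum, NOT a euclidean norm (the square root applies to each
term separately):

TPD
    Total Principal-component Distance — over the first five PC scores
    (or all available when fewer than five exist).
TSD
    Total Spectral Distance — over the normalized intensities at every
    Raman shift.
TCD
    Total Canonical Distance — over the first five canonical variates of
    the DAPC model (truncated to the ``n_classes − 1`` that exist).

The reference is either a named sample's processed spectrum or the
centroid of a condition group (the usual choice: the control medium).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import DAPCModel, PCAModel
from .errors import InputError, MissingReferenceError
from .spectra import Spectrum, SpectraSet

log = logging.getLogger(__name__)

N_DISTANCE_COMPONENTS = 5


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(np.abs(np.asarray(a, float) - np.asarray(b, float))))


def tpd(scores_x, scores_ref) -> float:
    """Total Principal-component Distance: L1 sum over PC scores.

    Both vectors must have equal length (the caller passes the first
    five scores, or all of them when the dataset has fewer than 5 PCs).
    """
    a = np.asarray(scores_x, float)
    b = np.asarray(scores_ref, float)
    if a.shape != b.shape:
        raise InputError(f"score length mismatch: {a.shape} vs {b.shape}")
    return _l1(a, b)


def tsd(sx: Spectrum, sref: Spectrum) -> float:
    """Total Spectral Distance: L1 sum of normalized intensities.

    Both spectra must share the grid and are expected to be unit-norm
    (the distance is defined on vector-normalized spectra).
    """
    if sx.shifts.size != sref.shifts.size or not np.array_equal(sx.shifts, sref.shifts):
        raise InputError("spectra are not on a common grid")
    return _l1(sx.intensities, sref.intensities)


def tcd(cx, cref, model: DAPCModel | None = None) -> float:
    """Total Canonical Distance: L1 sum over the first five canonicals.

    When the model has fewer than five canonical variates (C − 1 for C
    classes), all of them are used.
    """
    a = np.asarray(cx, float)
    b = np.asarray(cref, float)
    if a.shape != b.shape:
        raise InputError(f"canonical length mismatch: {a.shape} vs {b.shape}")
    if model is not None and a.size != model.n_canonical:
        raise InputError(
            f"expected {model.n_canonical} canonical coordinates, got {a.size}"
        )
    k = min(N_DISTANCE_COMPONENTS, a.size)
    return _l1(a[:k], b[:k])


@dataclass(frozen=True)
class ReferenceSpec:
    """Which spectrum the distances are measured from.

    ``mode`` is ``"named-spectrum"`` (``target`` = a sample id) or
    ``"group-centroid"`` (``target`` = a condition label).
    """

    mode: str
    target: str

    def __post_init__(self):
        if self.mode not in ("named-spectrum", "group-centroid"):
            raise InputError(f"unknown reference mode {self.mode!r}")


@dataclass
class DistanceTable:
    """Per-spectrum TPD/TSD/TCD rows plus per-condition means."""

    rows: pd.DataFrame         # columns: sample, condition, TPD, TSD, TCD
    group_means: pd.DataFrame  # columns: condition, TPD, TSD, TCD
    reference: ReferenceSpec

    def write(self, raw_path, mean_path) -> None:
        self.rows.to_csv(raw_path, index=False)
        self.group_means.to_csv(mean_path, index=False)


def distance_table(
    X: SpectraSet,
    pca: PCAModel,
    dapc: DAPCModel,
    ref: ReferenceSpec,
) -> DistanceTable:
    """Compute TPD/TSD/TCD for every spectrum against the reference.

    The reference vectors (PC scores, intensities, canonical scores) are
    those of the named sample, or the arithmetic centroid of the target
    condition group.  Group means are plain arithmetic means of the raw
    rows per condition.
    """
    scores = pca.transform(X.intensities)
    k = min(N_DISTANCE_COMPONENTS, scores.shape[1])
    if k < N_DISTANCE_COMPONENTS:
        log.warning("dataset yields only %d PCs; TPD uses all of them", k)
    covered = float(np.sum(pca.explained_fraction[:k])) * 100.0
    log.info("TPD over first %d PCs covering %.1f%% of dataset variance", k, covered)
    canon = np.atleast_2d(dapc.transform(scores))

    if ref.mode == "named-spectrum":
        sel = np.flatnonzero(X.samples == ref.target)
        if sel.size == 0:
            raise MissingReferenceError(f"no sample named {ref.target!r}")
    else:
        sel = np.flatnonzero(X.labels == ref.target)
        if sel.size == 0:
            raise MissingReferenceError(f"no condition named {ref.target!r}")
    ref_scores = scores[sel, :k].mean(axis=0)
    ref_int = X.intensities[sel].mean(axis=0)
    ref_canon = canon[sel].mean(axis=0)

    kc = min(N_DISTANCE_COMPONENTS, canon.shape[1])
    rows = pd.DataFrame(
        {
            "sample": X.samples,
            "condition": X.labels,
            "TPD": [_l1(scores[i, :k], ref_scores) for i in range(len(X))],
            "TSD": [_l1(X.intensities[i], ref_int) for i in range(len(X))],
            "TCD": [_l1(canon[i, :kc], ref_canon[:kc]) for i in range(len(X))],
        }
    )
    group_means = (
        rows.groupby("condition", sort=False)[["TPD", "TSD", "TCD"]]
        .mean()
        .reset_index()
    )
    return DistanceTable(rows=rows, group_means=group_means, reference=ref)
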
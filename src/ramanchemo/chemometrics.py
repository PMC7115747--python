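"""PCA with outlier screening, and DAPC model fitting/classification.

DAPC (discriminant analysis of principal components) is linear
discriminant analysis carried out on the scores of a spectrum set's
first ``n_pcs`` principal components, with equal class priors.  The
canonical variates are the generalized eigenvectors of the between-class
scatter against the pooled within-class scatter of those PC scores,
ordered by decreasing between/within variance ratio and scaled so the
pooled within-class variance along each variate is 1; classification
assigns the class whose centroid is nearest in that canonical space.
At most ``min(n_classes − 1, n_pcs)`` canonical variates exist.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA as _SkPCA

from .errors import InputError, ParameterError
from .spectra import SpectraSet

log = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Mean-centered principal component model of a spectrum set.

    ``mean + scores @ loadings`` reconstructs the training intensities.
    """

    mean: np.ndarray                  # (p,)
    loadings: np.ndarray              # (k, p), orthonormal rows
    scores: np.ndarray                # (n, k) training scores
    explained_fraction: np.ndarray    # (k,), non-increasing, sums to 1
    grid: np.ndarray                  # (p,) Raman shifts

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, intensities: np.ndarray) -> np.ndarray:
        """Project intensities (``(p,)`` or ``(n, p)``) onto the PC basis."""
        X = np.atleast_2d(np.asarray(intensities, float))
        if X.shape[1] != self.mean.size:
            raise InputError(
                f"expected {self.mean.size} intensity values, got {X.shape[1]}"
            )
        S = (X - self.mean) @ self.loadings.T
        return S[0] if np.asarray(intensities).ndim == 1 else S

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.asarray(scores) @ self.loadings


def fit_pca(X: SpectraSet) -> PCAModel:
    """Full mean-centered PCA of a spectrum set (all components kept)."""
    if len(X) < 2:
        raise InputError("PCA needs at least 2 spectra")
    pca = _SkPCA(n_components=None, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(X.intensities)
        frac = pca.explained_variance_ratio_
    # identical spectra: no variance to apportion
    frac = np.nan_to_num(frac, nan=0.0)
    return PCAModel(
        mean=pca.mean_,
        loadings=pca.components_,
        scores=scores,
        explained_fraction=frac,
        grid=X.grid.copy(),
    )


def choose_n_pcs(explained_fraction: np.ndarray, target: float = 0.99) -> int:
    """Smallest number of leading PCs whose cumulative variance ≥ target."""
    cum = np.cumsum(explained_fraction)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


@dataclass
class OutlierReport:
    """Per-spectrum outlier statistic and the spectra it excludes."""

    statistic: np.ndarray     # max |z| over the screened PCs, per spectrum
    threshold: float
    excluded: np.ndarray      # integer indices into the dataset
    excluded_ids: list = field(default_factory=list)
    rule: str = "score-zscore"

    @property
    def kept(self) -> np.ndarray:
        n = self.statistic.size
        mask = np.ones(n, dtype=bool)
        mask[self.excluded] = False
        return np.flatnonzero(mask)


def detect_outliers(
    pca: PCAModel,
    k_pcs: int = 5,
    rule: str = "score-zscore",
    z_threshold: float = 3.0,
    ids=None,
) -> OutlierReport:
    """Flag spectra with an extreme score on any of the first ``k_pcs`` PCs.

    A spectrum is excluded when ``|score| > z_threshold × SD`` of that
    component's training scores.  Components with (numerically) zero
    variance are skipped.
    """
    if rule != "score-zscore":
        raise ParameterError(f"unknown outlier rule {rule!r}")
    if z_threshold <= 0:
        raise ParameterError("z_threshold must be positive")
    k = min(int(k_pcs), pca.n_components)
    if k < 1:
        raise ParameterError("k_pcs must be >= 1")
    S = pca.scores[:, :k]
    sd = S.std(axis=0, ddof=1)
    tiny = 1e-12 * max(float(sd.max()), 1.0)
    live = sd > tiny
    n = S.shape[0]
    if not live.any():
        stat = np.zeros(n)
    else:
        stat = np.max(np.abs(S[:, live]) / sd[live], axis=1)
    excluded = np.flatnonzero(stat > z_threshold)
    ids = list(ids) if ids is not None else []
    return OutlierReport(
        statistic=stat,
        threshold=float(z_threshold),
        excluded=excluded,
        excluded_ids=[ids[i] for i in excluded] if ids else [],
        rule=rule,
    )


@dataclass
class DAPCModel:
    """LDA on retained PC scores: canonical map, centroids, class labels."""

    n_pcs: int
    coef: np.ndarray          # (n_pcs, m) PC scores -> canonical variates
    centroids: np.ndarray     # (C, m) class centroids in canonical space
    classes: list             # sorted class labels
    eigenvalues: np.ndarray   # (m,) between/within variance ratios, decreasing
    priors: np.ndarray        # (C,), equal

    @property
    def n_canonical(self) -> int:
        return self.coef.shape[1]

    def transform(self, pc_scores: np.ndarray) -> np.ndarray:
        """Map PC scores (first ``n_pcs`` used) to canonical coordinates."""
        S = np.atleast_2d(np.asarray(pc_scores, float))
        if S.shape[1] < self.n_pcs:
            raise InputError(
                f"need at least {self.n_pcs} PC scores, got {S.shape[1]}"
            )
        Z = S[:, : self.n_pcs] @ self.coef
        return Z[0] if np.asarray(pc_scores).ndim == 1 else Z


def fit_dapc(pca: PCAModel, labels, n_pcs: int | None = None) -> DAPCModel:
    """Fit a DAPC model on the first ``n_pcs`` PC scores.

    ``n_pcs`` defaults to the smallest count reaching 99% cumulative
    variance.  Each canonical variate's sign is oriented so the first
    (lexicographically) class's centroid coordinate is ≤ 0.

    Raises
    ------
    InputError
        With < 2 classes, a class of < 2 spectra, or ``n_pcs`` exceeding
        the number of PCs with nonzero variance.
    """
    labels = np.asarray(labels)
    if labels.size != pca.scores.shape[0]:
        raise InputError("one label per spectrum required")
    classes = sorted(set(labels.tolist()))
    C = len(classes)
    if C < 2:
        raise InputError("DAPC needs at least 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise InputError(f"classes with < 2 spectra: {small}")

    var = pca.scores.var(axis=0, ddof=1)
    n_nonzero = int(np.sum(var > 1e-12 * max(float(var.max()), 1.0)))
    if n_pcs is None:
        n_pcs = min(choose_n_pcs(pca.explained_fraction), n_nonzero)
    n_pcs = int(n_pcs)
    if n_pcs < 1 or n_pcs > n_nonzero:
        raise InputError(
            f"n_pcs={n_pcs} exceeds the {n_nonzero} PCs with nonzero variance"
        )

    S = pca.scores[:, :n_pcs]
    n = S.shape[0]
    mu = S.mean(axis=0)
    Sw = np.zeros((n_pcs, n_pcs))
    Sb = np.zeros((n_pcs, n_pcs))
    means = np.empty((C, n_pcs))
    for ci, c in enumerate(classes):
        Sc = S[labels == c]
        mc = Sc.mean(axis=0)
        means[ci] = mc
        D = Sc - mc
        Sw += D.T @ D
        d = (mc - mu)[:, None]
        Sb += Sc.shape[0] * (d @ d.T)
    Sw /= n - C          # pooled within-class covariance
    Sb /= max(C - 1, 1)

    # regularize a singular within-class scatter
    try:
        evals_w = scipy.linalg.eigvalsh(Sw)
        singular = evals_w.min() <= 1e-10 * max(evals_w.max(), 1e-300)
    except scipy.linalg.LinAlgError:
        singular = True
    if singular:
        ridge = 1e-8 * max(float(np.trace(Sw)) / n_pcs, 1e-12)
        Sw = Sw + ridge * np.eye(n_pcs)
        warnings.warn(
            "singular pooled within-class scatter; ridge regularization applied",
            RuntimeWarning,
            stacklevel=2,
        )
        log.warning("DAPC: within-class scatter singular, ridge %.3g applied", ridge)

    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)   # B-orthonormal: v' Sw v = 1
    except scipy.linalg.LinAlgError:
        ridge = 1e-8 * max(float(np.trace(Sw)) / n_pcs, 1e-12)
        Sw = Sw + ridge * np.eye(n_pcs)
        log.warning("DAPC: generalized eigensolve failed, ridge %.3g applied", ridge)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    m = min(C - 1, n_pcs)
    order = np.argsort(evals)[::-1][:m]
    V = evecs[:, order]
    lam = np.clip(evals[order], 0.0, None)

    # sign convention: first class centroid coordinate <= 0 on each variate
    first = means[0] @ V
    flip = first > 0
    V[:, flip] *= -1.0

    return DAPCModel(
        n_pcs=n_pcs,
        coef=V,
        centroids=means @ V,
        classes=list(classes),
        eigenvalues=lam,
        priors=np.full(C, 1.0 / C),
    )


def classify(model: DAPCModel, pc_scores: np.ndarray) -> tuple:
    """Assign the class with the nearest centroid in canonical space.

    Returns ``(label, canonical_scores)``.  Exact distance ties break to
    the lexicographically first class label.
    """
    z = model.transform(np.asarray(pc_scores, float))
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    d = np.linalg.norm(Z[:, None, :] - model.centroids[None, :, :], axis=2)
    pred_idx = np.argmin(d, axis=1)  # first minimum -> lexicographic tie-break
    labels = [model.classes[i] for i in pred_idx]
    if single:
        return labels[0], z
    return labels, Z


def models_to_json(pca: PCAModel, dapc: DAPCModel) -> str:
    """Serialize a fitted PCA + DAPC pair to a JSON document."""
    doc = {
        "pca": {
            "mean": pca.mean.tolist(),
            "loadings": pca.loadings.tolist(),
            "explained_fraction": pca.explained_fraction.tolist(),
            "grid": pca.grid.tolist(),
        },
        "dapc": {
            "n_pcs": dapc.n_pcs,
            "coef": dapc.coef.tolist(),
            "centroids": dapc.centroids.tolist(),
            "classes": dapc.classes,
            "eigenvalues": dapc.eigenvalues.tolist(),
        },
    }
    return json.dumps(doc)


def models_from_json(text: str) -> tuple[PCAModel, DAPCModel]:
    """Inverse of :func:`models_to_json` (training scores are not stored)."""
    doc = json.loads(text)
    p, d = doc["pca"], doc["dapc"]
    loadings = np.asarray(p["loadings"], float)
    pca = PCAModel(
        mean=np.asarray(p["mean"], float),
        loadings=loadings,
        scores=np.zeros((0, loadings.shape[0])),
        explained_fraction=np.asarray(p["explained_fraction"], float),
        grid=np.asarray(p["grid"], float),
    )
    C = len(d["classes"])
    dapc = DAPCModel(
        n_pcs=int(d["n_pcs"]),
        coef=np.asarray(d["coef"], float),
        centroids=np.asarray(d["centroids"], float),
        classes=list(d["classes"]),
        eigenvalues=np.asarray(d["eigenvalues"], float),
        priors=np.full(C, 1.0 / C),
    )
    return pca, dapc
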
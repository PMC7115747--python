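"""PCA, outlier screening, DAPC fitting and classification."""

import numpy as np
import pandas as pd
import pytest

import ramanchemo as rc
from ramanchemo.chemometrics import models_from_json, models_to_json
from ramanchemo.errors import InputError, ParameterError
from ramanchemo.spectra import SpectraSet


def _set_from_matrix(X, labels=None):
    n, p = X.shape
    labels = labels if labels is not None else ["c"] * n
    meta = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "condition": labels,
            "concentration_mM": 0.0,
            "replicate": "r1",
            "scan": 1,
        }
    )
    return SpectraSet(np.arange(p, dtype=float) + 400.0, X, meta)


class TestPCA:
    def test_rank_two_set_explained_by_two_pcs(self, rng):
        p = 40
        basis = rng.normal(size=(2, p))
        coeffs = rng.normal(size=(12, 2))
        X = coeffs @ basis + rng.normal(size=p)  # fixed offset = mean pattern
        pca = rc.fit_pca(_set_from_matrix(X))
        assert pca.explained_fraction[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_spectrum_maps_to_zero_scores(self, rng):
        X = rng.normal(size=(10, 25))
        pca = rc.fit_pca(_set_from_matrix(X))
        assert np.allclose(pca.transform(X.mean(axis=0)), 0.0, atol=1e-10)

    def test_variance_conserved(self, rng):
        X = rng.normal(size=(15, 30))
        pca = rc.fit_pca(_set_from_matrix(X))
        assert pca.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.explained_fraction) <= 1e-12)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(12, 20))
        pca = rc.fit_pca(_set_from_matrix(X))
        recon = pca.reconstruct(pca.scores)
        assert np.max(np.abs(recon - X)) < 1e-8 * np.ptp(X)

    def test_needs_two_spectra(self, rng):
        with pytest.raises(InputError):
            rc.fit_pca(_set_from_matrix(rng.normal(size=(1, 10))))


class TestOutliers:
    def test_constructed_outlier_flagged(self, rng):
        base = np.exp(-0.5 * ((np.arange(50) - 25) / 4.0) ** 2)
        X = base + 0.01 * rng.normal(size=(20, 50))
        X[7] = 10 * base  # one spectrum with 10x the marker amplitude
        pca = rc.fit_pca(_set_from_matrix(X))
        rep = rc.detect_outliers(pca, k_pcs=5, z_threshold=3.0)
        assert list(rep.excluded) == [7]

    def test_identical_spectra_none_flagged(self):
        X = np.ones((8, 30))
        pca = rc.fit_pca(_set_from_matrix(X))
        rep = rc.detect_outliers(pca, k_pcs=5, z_threshold=3.0)
        assert rep.excluded.size == 0

    def test_zero_threshold_rejected(self, rng):
        pca = rc.fit_pca(_set_from_matrix(rng.normal(size=(5, 10))))
        with pytest.raises(ParameterError):
            rc.detect_outliers(pca, z_threshold=0.0)


def _blobs(rng, centers, n_per, p=30, spread=0.05):
    """Well-separated class blobs embedded in p dims."""
    X, labels = [], []
    directions = rng.normal(size=(len(centers), p))
    for k, (c, d) in enumerate(zip(centers, directions)):
        X.append(c * d / np.linalg.norm(d) + spread * rng.normal(size=(n_per, p)))
        labels += [f"class{k}"] * n_per
    return np.vstack(X), labels


class TestDAPC:
    def test_two_classes_one_canonical_opposite_signs(self, rng):
        X, labels = _blobs(rng, [10.0, -10.0], 6)
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        dapc = rc.fit_dapc(pca, labels, n_pcs=2)
        assert dapc.n_canonical == 1
        assert dapc.centroids[0, 0] * dapc.centroids[1, 0] < 0

    def test_four_classes_three_canonicals(self, rng):
        X, labels = _blobs(rng, [5.0, 10.0, 15.0, 20.0], 5)
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        dapc = rc.fit_dapc(pca, labels, n_pcs=6)
        assert dapc.n_canonical == 3

    def test_label_permutation_drops_separation(self, rng):
        X, labels = _blobs(rng, [5.0, 10.0, 15.0, 20.0], 6)
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        true = rc.fit_dapc(pca, labels, n_pcs=5)
        perm = rc.fit_dapc(pca, rng.permutation(labels), n_pcs=5)
        assert perm.eigenvalues[0] < true.eigenvalues[0]

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        labels = ["a", "a", "a", "a", "b"]
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        with pytest.raises(InputError):
            rc.fit_dapc(pca, labels, n_pcs=2)

    def test_classify_at_centroid(self, rng):
        X, labels = _blobs(rng, [5.0, 12.0, 20.0], 5)
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        dapc = rc.fit_dapc(pca, labels, n_pcs=4)
        # synthesize PC scores whose canonical image is exactly a centroid
        coef = dapc.coef
        target = dapc.centroids[2]
        scores, *_ = np.linalg.lstsq(coef.T, target, rcond=None)
        label, _ = rc.classify(dapc, scores)
        assert label == "class2"

    def test_midway_tie_breaks_lexicographically(self):
        dapc = rc.DAPCModel(
            n_pcs=1,
            coef=np.array([[1.0]]),
            centroids=np.array([[-1.0], [1.0]]),
            classes=["a", "b"],
            eigenvalues=np.array([1.0]),
            priors=np.array([0.5, 0.5]),
        )
        label, _ = rc.classify(dapc, np.array([0.0]))
        assert label == "a"

    def test_training_self_classification_perfect(self, default_study):
        pca, dapc = default_study["pca"], default_study["dapc"]
        labels, _ = rc.classify(dapc, pca.scores)
        assert list(labels) == list(default_study["proc"].labels)

    def test_centroid_separation_dwarfs_within_spread(self, default_study):
        pca, dapc, proc = (default_study[k] for k in ("pca", "dapc", "proc"))
        Z = dapc.transform(pca.scores)
        spreads = []
        for c in dapc.classes:
            Zc = Z[proc.labels == c]
            spreads.append(Zc.std(axis=0, ddof=1).mean())  # per-axis spread
        dmin = min(
            np.linalg.norm(dapc.centroids[i] - dapc.centroids[j])
            for i in range(len(dapc.classes))
            for j in range(i + 1, len(dapc.classes))
        )
        assert dmin / max(spreads) > 10

    def test_accuracy_nondecreasing_in_n_pcs(self, default_study):
        pca, proc = default_study["pca"], default_study["proc"]
        accs = []
        for n_pcs in (2, 5, 10, 15):
            dapc = rc.fit_dapc(pca, proc.labels, n_pcs=n_pcs)
            labels, _ = rc.classify(dapc, pca.scores)
            accs.append(np.mean(np.asarray(labels) == proc.labels))
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_invariant_to_orthogonal_rotation(self, rng):
        X, labels = _blobs(rng, [4.0, 8.0, 12.0], 5, p=12)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        pca1 = rc.fit_pca(_set_from_matrix(X, labels))
        pca2 = rc.fit_pca(_set_from_matrix(X @ Q, labels))
        d1 = rc.fit_dapc(pca1, labels, n_pcs=4)
        d2 = rc.fit_dapc(pca2, labels, n_pcs=4)
        Z1 = d1.transform(pca1.scores)
        Z2 = d2.transform(pca2.scores)
        assert np.allclose(np.abs(Z1), np.abs(Z2), atol=1e-6)

    def test_agrees_with_reference_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, labels = _blobs(rng, [2.0, 3.5, 5.0], 8, spread=0.8)
        pca = rc.fit_pca(_set_from_matrix(X, labels))
        n_pcs = 5
        dapc = rc.fit_dapc(pca, labels, n_pcs=n_pcs)
        ours, _ = rc.classify(dapc, pca.scores)
        lda = LinearDiscriminantAnalysis(priors=np.full(3, 1 / 3))
        theirs = lda.fit(pca.scores[:, :n_pcs], labels).predict(pca.scores[:, :n_pcs])
        assert np.mean(np.asarray(ours) == theirs) == 1.0

    def test_json_roundtrip(self, default_study):
        pca, dapc = default_study["pca"], default_study["dapc"]
        pca2, dapc2 = models_from_json(models_to_json(pca, dapc))
        s = default_study["proc"].intensities[5]
        z1 = dapc.transform(pca.transform(s))
        z2 = dapc2.transform(pca2.transform(s))
        assert np.allclose(z1, z2, atol=1e-12)
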
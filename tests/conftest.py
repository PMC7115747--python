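import numpy as np
import pytest

import ramanchemo as rc


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study (4 classes x 3 reps x 3 samples x 20 scans),
    processed and modelled once for the whole session."""
    cfg = rc.SynthConfig(seed=1)
    X, gt = rc.generate_dataset(cfg)
    proc = rc.preprocess_pipeline(X)
    pca = rc.fit_pca(proc)
    n_pcs = rc.choose_n_pcs(pca.explained_fraction)
    dapc = rc.fit_dapc(pca, proc.labels, n_pcs=n_pcs)
    return {
        "cfg": cfg,
        "raw": X,
        "gt": gt,
        "proc": proc,
        "pca": pca,
        "n_pcs": n_pcs,
        "dapc": dapc,
    }


@pytest.fixture()
def tiny_cfg():
    """Small, fast study: coarse grid, few scans, still 4 separable classes."""
    return rc.SynthConfig(seed=7, grid_step=8.0, n_scans=4, n_samples_per_rep=3,
                          n_bio_reps=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
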
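"""End-to-end orchestration: config file → all pipeline artifacts.

``run_pipeline`` executes load → preprocess → PCA (+ outlier exclusion)
→ DAPC → leave-one-out metrics → distance statistics → ANOVA / Tukey /
regression → band–analyte correlations, and writes every result table
as CSV plus the fitted models as JSON, with a run log capturing the
package version, seed and parameters.

The YAML/JSON config layout::

    manifest: path/to/manifest.csv
    bands: path/to/bands.csv          # optional
    analytes: path/to/analytes.csv    # optional
    output_dir: results/
    preprocess: {poly_order: 3, peak_ratio: 0.5, smooth_window: 5,
                 range_lo: 400, range_hi: 1800}
    n_pcs: auto          # integer, or "auto" = 99% cumulative variance
    outliers: {k_pcs: 5, z_threshold: 3.0}
    reference: {mode: group-centroid, target: "0 mM"}   # optional
    seed: 0
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import read_bands, read_analytes, correlate_bands
from .chemometrics import (
    choose_n_pcs,
    detect_outliers,
    fit_dapc,
    fit_pca,
    models_to_json,
)
from .distances import ReferenceSpec, distance_table
from .errors import ConfigError, RamanChemoError
from .io import load_dataset, read_manifest
from .preprocess import PreprocessConfig, preprocess_pipeline
from .stats import linear_regression, one_way_anova, tukey_hsd
from .validation import all_class_metrics, loo_dapc

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str
    output_dir: str
    bands: Optional[str] = None
    analytes: Optional[str] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_pcs: object = "auto"
    outlier_k_pcs: int = 5
    outlier_z: float = 3.0
    reference_mode: str = "group-centroid"
    reference_target: Optional[str] = None  # default: lowest-concentration condition
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)  # YAML superset also parses JSON
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(doc, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def from_dict(cls, doc: dict, base_dir: str = ".") -> "PipelineConfig":
        if "manifest" not in doc:
            raise ConfigError("config is missing the 'manifest' path")
        if "output_dir" not in doc:
            raise ConfigError("config is missing 'output_dir'")

        def _path(key):
            val = doc.get(key)
            if val is None:
                return None
            return val if os.path.isabs(val) else os.path.join(base_dir, val)

        out = _path("output_dir")
        cfg = cls(
            manifest=_path("manifest"),
            output_dir=out,
            bands=_path("bands"),
            analytes=_path("analytes"),
            preprocess=PreprocessConfig.from_dict(doc.get("preprocess", {}) or {}),
            n_pcs=doc.get("n_pcs", "auto"),
            outlier_k_pcs=int((doc.get("outliers") or {}).get("k_pcs", 5)),
            outlier_z=float((doc.get("outliers") or {}).get("z_threshold", 3.0)),
            reference_mode=(doc.get("reference") or {}).get("mode", "group-centroid"),
            reference_target=(doc.get("reference") or {}).get("target"),
            seed=int(doc.get("seed", 0)),
        )
        for key, p in (("manifest", cfg.manifest), ("bands", cfg.bands), ("analytes", cfg.analytes)):
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"config {key} path does not exist: {p}")
        return cfg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the artifact files.

    Returns a dict of artifact paths and headline numbers.  On a stage
    failure the partial outputs are kept and a ``FAILED`` marker file
    names the stage; the error is re-raised.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    run_log = os.path.join(cfg.output_dir, "run.log")
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ramanchemo")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "load"
    try:
        log.info("ramanchemo %s, seed %d", __version__, cfg.seed)
        log.info("preprocess parameters: %s", cfg.preprocess.to_dict())
        manifest = read_manifest(cfg.manifest)
        raw = load_dataset(manifest, base_dir=os.path.dirname(os.path.abspath(cfg.manifest)))
        log.info("loaded %d scans on %d grid points", len(raw), raw.grid.size)

        stage = "preprocess"
        processed = preprocess_pipeline(raw, cfg.preprocess)
        log.info("preprocessed to %d sample spectra", len(processed))

        stage = "pca"
        pca = fit_pca(processed)
        report = detect_outliers(
            pca, k_pcs=cfg.outlier_k_pcs, z_threshold=cfg.outlier_z, ids=processed.samples
        )
        if report.excluded.size:
            log.info("excluding %d outlier spectra: %s", report.excluded.size, report.excluded_ids)
            processed = processed.select(report.kept)
            pca = fit_pca(processed)

        stage = "dapc"
        n_pcs = (
            choose_n_pcs(pca.explained_fraction)
            if cfg.n_pcs in ("auto", None)
            else int(cfg.n_pcs)
        )
        n_pcs = min(n_pcs, len(processed) - 1)
        dapc = fit_dapc(pca, processed.labels, n_pcs=n_pcs)
        log.info(
            "DAPC with %d PCs (%.1f%% cumulative variance), %d canonical variates",
            n_pcs, 100 * float(np.sum(pca.explained_fraction[:n_pcs])), dapc.n_canonical,
        )
        with open(os.path.join(cfg.output_dir, "model.json"), "w", encoding="utf-8") as fh:
            fh.write(models_to_json(pca, dapc))

        stage = "validation"
        cm = loo_dapc(processed, n_pcs=n_pcs)
        metrics = all_class_metrics(cm)
        cm.to_frame().to_csv(os.path.join(cfg.output_dir, "confusion_matrix.csv"))
        metrics.to_csv(os.path.join(cfg.output_dir, "metrics.csv"), index=False)
        log.info("LOO accuracy %.1f%%", cm.accuracy_pct)

        stage = "distances"
        target = cfg.reference_target
        if target is None:
            # default reference: the condition with the lowest concentration
            # (the unmodified-medium control in a dose study)
            idx = int(np.nanargmin(processed.concentrations))
            target = str(processed.labels[idx])
        ref = ReferenceSpec(mode=cfg.reference_mode, target=target)
        dt = distance_table(processed, pca, dapc, ref)
        dt.write(
            os.path.join(cfg.output_dir, "raw_distances.csv"),
            os.path.join(cfg.output_dir, "mean_distances.csv"),
        )

        stage = "stats"
        stat_rows, pair_frames = [], []
        for col in ("TPD", "TSD", "TCD"):
            an = one_way_anova(dt.rows[col], dt.rows["condition"], factor=col)
            stat_rows.append(
                {
                    "test": f"anova_{col}", "statistic": an.F,
                    "df_between": an.df_between, "df_within": an.df_within, "p": an.p,
                }
            )
            hsd = tukey_hsd(dt.rows[col], dt.rows["condition"])
            pair_frames.append(hsd.table.assign(metric=col))
        conc_by_cond = (
            dt.rows.assign(conc=processed.concentrations)
            .groupby("condition")["conc"].first()
        )
        if conc_by_cond.nunique() >= 3:
            for col in ("TPD", "TCD"):
                means = dt.group_means.set_index("condition")[col]
                reg = linear_regression(conc_by_cond.loc[means.index], means)
                stat_rows.append(
                    {
                        "test": f"regression_{col}_vs_concentration",
                        "statistic": reg.slope, "df_between": 1,
                        "df_within": len(means) - 2, "p": reg.p,
                        "r_squared": reg.r_squared,
                    }
                )
        pd.DataFrame(stat_rows).to_csv(os.path.join(cfg.output_dir, "stats_report.csv"), index=False)
        pd.concat(pair_frames).to_csv(os.path.join(cfg.output_dir, "pairwise_report.csv"), index=False)

        stage = "bands"
        corr_path = None
        if cfg.bands and cfg.analytes:
            band_list = read_bands(cfg.bands)
            analytes = read_analytes(cfg.analytes)
            by_center = {b.center_cm1: b for b in band_list}
            from .synthetic import DEFAULT_ANALYTE_MODEL

            mapping = {
                name: by_center[center]
                for name, (center, _, _) in DEFAULT_ANALYTE_MODEL.items()
                if center in by_center and name in set(analytes["analyte"])
            }
            if mapping:
                corr = correlate_bands(processed, band_list, analytes, mapping)
                corr_path = os.path.join(cfg.output_dir, "correlations.csv")
                corr.to_csv(corr_path, index=False)

        return {
            "output_dir": cfg.output_dir,
            "n_spectra": len(processed),
            "n_pcs": n_pcs,
            "loo_accuracy_pct": cm.accuracy_pct,
            "reference": target,
            "correlations": corr_path,
        }
    except RamanChemoError as exc:
        marker = os.path.join(cfg.output_dir, "FAILED")
        with open(marker, "w", encoding="utf-8") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def write_pipeline_config(path, doc: dict) -> None:
    """Write a pipeline config as YAML (JSON-compatible mapping)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def pipeline_summary_json(result: dict) -> str:
    return json.dumps(result, indent=1, default=str)
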
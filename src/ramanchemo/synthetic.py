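"""Synthetic Raman study generator with known ground truth.

Emulates the structure of a dried-spot cyanobacterial phenotyping
experiment: a small number of condition classes (dose levels of one
stimulus added to the growth medium), biological triplicate, three
dried-spot samples per replicate, and 20 point scans per sample on a
785 nm-style instrument (400–1800 cm⁻¹ grid, ~13 cm⁻¹ effective
resolution).  Each scan is

``Σ_k a_k · g_k(ν) + cubic baseline (per sample) + i.i.d. gaussian noise``

where the ``g_k`` are unit-height Gaussian/Lorentzian line shapes at
typical cell-biomass band positions.  A *marker* subset of bands
(phenylalanine-like 1005, carotenoid-like 1157/1520, lipid CH₂-like
1445 cm⁻¹) carries a linear dose response: its amplitudes are scaled by
``1 + slope × concentration``.  Biological-replicate variability is
multiplicative lognormal jitter on all peak amplitudes.  Matched analyte
tables (amino-acid/fatty-acid style measurements) are generated as
affine functions of the true marker amplitudes with a configurable
noise CV, so every downstream stage has a known recovery target.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so a given ``(config, seed)`` reproduces the study
bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandAssignment
from .errors import ParameterError
from .io import write_manifest, write_spectrum
from .spectra import SpectraSet, SpectrumMeta, Spectrum


@dataclass(frozen=True)
class Peak:
    """One spectral line: center (cm⁻¹), base amplitude (a.u.), FWHM, shape."""

    center: float
    amplitude: float
    fwhm: float
    shape: str = "gaussian"

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-amplitude line shape evaluated on the grid."""
        if self.shape == "gaussian":
            sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return np.exp(-0.5 * ((grid - self.center) / sigma) ** 2)
        if self.shape == "lorentzian":
            hwhm = self.fwhm / 2.0
            return hwhm**2 / ((grid - self.center) ** 2 + hwhm**2)
        raise ParameterError(f"unknown peak shape {self.shape!r}")


#: Base peak set: typical biomass band positions with FWHM ≥ the 13 cm⁻¹
#: instrument resolution.  Amplitudes in arbitrary units.
DEFAULT_PEAKS: tuple[Peak, ...] = (
    Peak(480.0, 0.35, 24.0),               # polysaccharide skeletal
    Peak(620.0, 0.20, 18.0),               # aromatic ring deformation
    Peak(785.0, 0.45, 20.0),               # nucleic acid backbone
    Peak(1005.0, 0.50, 14.0),              # phenylalanine ring breathing (marker)
    Peak(1095.0, 0.30, 22.0),              # DNA PO2⁻
    Peak(1157.0, 0.80, 18.0),              # carotenoid C–C (marker)
    Peak(1260.0, 0.35, 28.0),              # amide III
    Peak(1340.0, 0.30, 26.0),              # CH deformation
    Peak(1445.0, 0.45, 24.0),              # lipid CH₂ scissoring (marker)
    Peak(1520.0, 1.00, 18.0),              # carotenoid C=C (marker)
    Peak(1660.0, 0.55, 30.0, "lorentzian"),  # amide I
)

#: Dose-response slopes per marker center (fraction of base amplitude per
#: mM).  Signs differ on purpose: the stimulus raises protein- and
#: lipid-associated bands while depleting the carotenoid bands, so the
#: *composition* (what a vector-normalized spectrum measures) changes
#: strongly in both directions instead of a uniform intensity scale-up
#: that normalization would largely cancel.
DEFAULT_MARKER_SLOPES: Mapping[float, float] = {
    1005.0: 0.04,
    1157.0: -0.025,
    1445.0: 0.04,
    1520.0: -0.03,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study design and noise model for the generator.

    Defaults mirror the emulated experiment: 4 dose classes
    (0/7.5/15/30 mM), biological triplicate, 3 dried-spot samples per
    replicate, 20 scans per sample, 2 cm⁻¹ grid over 400–1800 cm⁻¹,
    additive noise SD of 2% of the largest base peak amplitude, and 5%
    lognormal replicate jitter on peak amplitudes.
    """

    grid_lo: float = 400.0
    grid_hi: float = 1800.0
    grid_step: float = 2.0
    peaks: tuple[Peak, ...] = DEFAULT_PEAKS
    marker_slopes: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SLOPES)
    )
    concentrations: Sequence[float] = (0.0, 7.5, 15.0, 30.0)
    baseline_scale: float = 1.5     # cubic-baseline magnitude, × max peak amplitude
    noise_sd: float = 0.02          # additive noise SD, × max peak amplitude
    rep_jitter_sigma: float = 0.05  # lognormal sigma of replicate amplitude jitter
    n_bio_reps: int = 3
    n_samples_per_rep: int = 3
    n_scans: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.grid_step <= 0 or self.grid_lo >= self.grid_hi:
            raise ParameterError("invalid grid specification")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ParameterError("concentrations must be distinct")
        for p in self.peaks:
            if p.amplitude <= 0:
                raise ParameterError("peak amplitudes must be positive")
            if p.fwhm < self.grid_step:
                raise ParameterError("peak FWHM must be >= grid step")
        cmax = max(self.concentrations)
        for c, slope in self.marker_slopes.items():
            if not any(pk.center == c for pk in self.peaks):
                raise ParameterError(f"marker center {c} has no matching peak")
            if 1.0 + slope * cmax <= 0:
                raise ParameterError(
                    f"marker {c}: slope {slope} drives the amplitude non-positive "
                    f"at {cmax} mM"
                )
        if self.noise_sd < 0 or self.rep_jitter_sigma < 0 or self.baseline_scale < 0:
            raise ParameterError("noise/jitter/baseline scales must be >= 0")
        if min(self.n_bio_reps, self.n_samples_per_rep, self.n_scans) < 1:
            raise ParameterError("replicate/sample/scan counts must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + 0.5 * self.grid_step, self.grid_step)

    def condition_label(self, conc: float) -> str:
        return f"{conc:g} mM"

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator actually drew, keyed for later recovery checks.

    ``sample_table`` has one row per dried-spot sample (sample id,
    condition, concentration, replicate) plus one ``amp_<center>``
    column per peak with the true amplitude used for that sample's
    scans, and one ``rel_<center>`` column per *marker* band holding the
    noiseless normalized band intensity (mean of the unit-norm clean
    peak signal over center ± 6 cm⁻¹) — the composition-like quantity a
    per-milligram reference measurement tracks.  ``baselines`` maps
    sample id → the true cubic baseline on the full grid.
    ``marker_centers`` lists the dose-responsive bands.
    """

    sample_table: pd.DataFrame
    baselines: dict
    marker_centers: list
    config: SynthConfig

    def marker_amplitudes(self) -> pd.DataFrame:
        """Mean true marker amplitude per (condition, replicate) cell."""
        cols = [f"amp_{c:g}" for c in self.marker_centers]
        return (
            self.sample_table.groupby(["condition", "replicate"], sort=False)[cols]
            .mean()
            .reset_index()
        )

    def marker_relative_intensities(self) -> pd.DataFrame:
        """Mean noiseless normalized marker intensity per (condition,
        replicate) cell."""
        cols = [f"rel_{c:g}" for c in self.marker_centers]
        return (
            self.sample_table.groupby(["condition", "replicate"], sort=False)[cols]
            .mean()
            .reset_index()
        )


def generate_dataset(cfg: SynthConfig | None = None, seed: int | None = None):
    """Draw a full synthetic study.

    Returns ``(raw: SpectraSet, gt: GroundTruth)`` with
    ``len(concentrations) × n_bio_reps × n_samples_per_rep × n_scans``
    scans (720 under the defaults).  ``seed`` overrides ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grid = cfg.grid
    p = grid.size
    profiles = np.vstack([pk.profile(grid) for pk in cfg.peaks])  # (K, p)
    base_amps = np.array([pk.amplitude for pk in cfg.peaks])
    slopes = np.array([cfg.marker_slopes.get(pk.center, 0.0) for pk in cfg.peaks])
    max_amp = float(base_amps.max())
    x01 = (2.0 * grid - (grid[0] + grid[-1])) / (grid[-1] - grid[0])  # [-1, 1]

    spectra_rows = []
    meta_rows = []
    gt_rows = []
    baselines = {}
    for conc in cfg.concentrations:
        label = cfg.condition_label(conc)
        dose = 1.0 + slopes * conc
        for rep in range(1, cfg.n_bio_reps + 1):
            jitter = rng.lognormal(mean=0.0, sigma=cfg.rep_jitter_sigma, size=len(cfg.peaks))
            amps = base_amps * dose * jitter
            clean_peaks = amps @ profiles
            unit_clean = clean_peaks / np.linalg.norm(clean_peaks)
            rel = {}
            for c in sorted(cfg.marker_slopes):
                win = np.abs(grid - c) <= 6.0
                rel[f"rel_{c:g}"] = float(unit_clean[win].mean())
            for samp in range(1, cfg.n_samples_per_rep + 1):
                sample_id = f"{conc:g}mM_r{rep}_s{samp}"
                c0 = rng.uniform(0.5, 1.5) * cfg.baseline_scale * max_amp
                c123 = rng.uniform(-0.5, 0.5, size=3) * cfg.baseline_scale * max_amp
                baseline = c0 + c123[0] * x01 + c123[1] * x01**2 + c123[2] * x01**3
                baselines[sample_id] = baseline
                signal = clean_peaks + baseline
                noise = rng.normal(0.0, cfg.noise_sd * max_amp, size=(cfg.n_scans, p))
                spectra_rows.append(signal[None, :] + noise)
                for scan in range(1, cfg.n_scans + 1):
                    meta_rows.append(
                        {
                            "sample": sample_id,
                            "condition": label,
                            "concentration_mM": conc,
                            "replicate": f"r{rep}",
                            "scan": scan,
                        }
                    )
                row = {
                    "sample": sample_id,
                    "condition": label,
                    "concentration_mM": conc,
                    "replicate": f"r{rep}",
                }
                row.update({f"amp_{pk.center:g}": amps[k] for k, pk in enumerate(cfg.peaks)})
                row.update(rel)
                gt_rows.append(row)

    X = SpectraSet(grid, np.vstack(spectra_rows), pd.DataFrame(meta_rows))
    gt = GroundTruth(
        sample_table=pd.DataFrame(gt_rows),
        baselines=baselines,
        marker_centers=sorted(cfg.marker_slopes),
        config=cfg,
    )
    return X, gt


#: Analyte names for the default marker bands, in the style of the
#: reference-chemistry tables (amino acid by UPLC, fatty acids by GC-FID).
#: Purely synthetic labels; the affine coefficients (offset, slope, unit)
#: set each analyte's scale on top of the normalized band intensity.
DEFAULT_ANALYTE_MODEL: Mapping[str, tuple[float, tuple[float, float], str]] = {
    "Phe": (1005.0, (2.0, 300.0), "nmol/mg DW"),
    "C16:0": (1445.0, (5.0, 200.0), "ug/mg DW"),
    "carotenoid": (1520.0, (0.5, 50.0), "ug/mg DW"),
}


def default_band_table() -> list[BandAssignment]:
    """Small example band-assignment table (synthetic fixture)."""
    return [
        BandAssignment(1005.0, 6.0, "phenylalanine", "ring breathing"),
        BandAssignment(1157.0, 6.0, "carotenoid", "C-C stretch"),
        BandAssignment(1445.0, 6.0, "lipid CH2", "scissoring"),
        BandAssignment(1520.0, 6.0, "carotenoid", "C=C stretch"),
    ]


def default_band_mapping() -> dict:
    """Default analyte → band mapping matching the generator's markers."""
    bands = {b.center_cm1: b for b in default_band_table()}
    return {name: bands[center] for name, (center, _, _) in DEFAULT_ANALYTE_MODEL.items()}


def generate_analytes(
    gt: GroundTruth,
    cv: float = 0.1,
    rng: np.random.Generator | None = None,
    model: Mapping[str, tuple[float, tuple[float, float], str]] | None = None,
) -> pd.DataFrame:
    """Analyte levels as affine functions of the true marker composition.

    One measurement per (condition, replicate, analyte):
    ``level = offset + slope × rel × (1 + ε)``, ``ε ~ N(0, cv²)``,
    clamped at zero, where ``rel`` is the noiseless normalized marker
    band intensity of that cell — a per-unit-biomass composition, the
    quantity a per-milligram-dry-weight chromatography measurement is
    proportional to.  ``cv = 0`` gives levels exactly affine in the true
    composition.
    """
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(gt.config.seed + 1)
    model = model if model is not None else DEFAULT_ANALYTE_MODEL
    amp = gt.marker_relative_intensities()
    rows = []
    for name, (center, (off, slope), unit) in model.items():
        col = f"rel_{center:g}"
        if col not in amp.columns:
            raise ParameterError(f"analyte {name!r} maps to non-marker band {center}")
        for r in amp.itertuples(index=False):
            a = getattr(r, col)
            noise = 1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0)
            rows.append(
                {
                    "condition": r.condition,
                    "replicate": r.replicate,
                    "analyte": name,
                    "level": max(0.0, off + slope * a * noise),
                    "unit": unit,
                }
            )
    return pd.DataFrame(rows)


def random_analytes(
    gt: GroundTruth,
    rng: np.random.Generator,
    name: str = "null_analyte",
) -> pd.DataFrame:
    """A null analyte with i.i.d. normal levels, unrelated to any band."""
    amp = gt.marker_amplitudes()
    levels = np.abs(rng.normal(10.0, 3.0, size=len(amp)))
    return pd.DataFrame(
        {
            "condition": amp["condition"],
            "replicate": amp["replicate"],
            "analyte": name,
            "level": levels,
            "unit": "a.u.",
        }
    )


def write_study(outdir, cfg: SynthConfig | None = None, seed: int | None = None) -> dict:
    """Materialize a synthetic study on disk for the file-based pipeline.

    Writes one two-column CSV per scan plus ``manifest.csv``,
    ``bands.csv``, ``analytes.csv`` and ``ground_truth.json``; returns
    the paths.
    """
    from .bands import write_bands

    cfg = cfg if cfg is not None else SynthConfig()
    X, gt = generate_dataset(cfg, seed=seed)
    os.makedirs(outdir, exist_ok=True)
    scandir = os.path.join(outdir, "scans")
    os.makedirs(scandir, exist_ok=True)

    manifest_rows = []
    for i in range(len(X)):
        row = X.meta.iloc[i]
        fname = os.path.join("scans", f"{row['sample']}_scan{int(row['scan']):02d}.csv")
        write_spectrum(
            os.path.join(outdir, fname),
            Spectrum(X.grid, X.intensities[i], SpectrumMeta()),
        )
        manifest_rows.append(
            {
                "file": fname,
                "sample": row["sample"],
                "condition": row["condition"],
                "concentration_mM": row["concentration_mM"],
                "replicate": row["replicate"],
                "scan": int(row["scan"]),
            }
        )
    paths = {
        "manifest": os.path.join(outdir, "manifest.csv"),
        "bands": os.path.join(outdir, "bands.csv"),
        "analytes": os.path.join(outdir, "analytes.csv"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_manifest(paths["manifest"], pd.DataFrame(manifest_rows))
    write_bands(paths["bands"], default_band_table())
    generate_analytes(gt).to_csv(paths["analytes"], index=False)
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": cfg.seed if seed is None else seed,
                "marker_centers": gt.marker_centers,
                "sample_table": gt.sample_table.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )
    return paths
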
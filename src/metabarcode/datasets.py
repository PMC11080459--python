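"""Labeled synthetic datasets of averaged metapixel spectra.

Each dataset item is what the measurement pipeline delivers for one frame: the
set of 49 averaged metapixel reflectance spectra on the model grid, labeled
cis or trans by the membrane state that generated it.  The default
("direct") generator synthesizes spectra at the averaged level, with additive
noise scaled by 1/sqrt(n_pixels) to match what block averaging of a full cube
would give (an equivalence the test suite checks); the "cube" route runs the
full simulate -> extract -> average chain per item.

Class contrast comes from the molecular model: the cis membrane adds the
1511 cm^-1 N=N band and carries ~17% lower lipid density (larger footprint).
A null configuration makes both classes draw from the identical distribution,
emulating measurements on the bare substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode import build_target_barcode, double_and_randomize
from .cube import NoiseModel, simulate_cube
from .extraction import average_doubled, extract_metapixel_spectra
from .grid import SpectralGrid, model_grid
from .kinetics import MembraneState
from .molecular import (AbsorptionBand, MediumConfig, MolecularModel,
                        d2o_background, make_molecular_model, molecular_loss)
from .resonance import R_BG_DEFAULT, RADIATIVE_FRACTION_DEFAULT

__all__ = [
    "ContrastConfig", "default_contrast", "null_contrast",
    "band_only_contrast", "LabeledDataset", "generate_labeled_dataset",
    "trajectory_spectra", "save_dataset", "load_dataset",
]

LABELS = ("trans", "cis")  # class index 0 = trans, 1 = cis


@dataclass(frozen=True)
class ContrastConfig:
    """Generative class contrast: molecular model plus state distributions."""

    molecular: MolecularModel
    cis_fraction_cis: float = 0.9    # mean cis fraction of cis-labeled items
    cis_fraction_trans: float = 0.1
    cis_fraction_sd: float = 0.03
    coverage_mean: float = 0.9
    coverage_sd: float = 0.03


def default_contrast() -> ContrastConfig:
    """AzoPC default: cis-only 1511 band plus reduced cis lipid density."""
    return ContrastConfig(molecular=make_molecular_model("azopc_default"))


def null_contrast() -> ContrastConfig:
    """Zero class contrast: identical band sets and density for both classes,
    so the loss channel is independent of the cis fraction (bare-substrate
    analogue; labels carry no spectral information)."""
    model = make_molecular_model(
        trans_bands=(), cis_bands=(), density_scale_cis=1.0)
    return ContrastConfig(molecular=model)


def band_only_contrast(center: float = 1742.0, strength: float = 1.0,
                       fwhm: float = 15.0) -> ContrastConfig:
    """Contrast confined to a single band: both classes share the base AzoPC
    bands at equal density, and only the cis class adds a band at ``center``
    (default the 1742 cm^-1 anhydrous-ester C=O stretch)."""
    base = make_molecular_model("azopc_default").trans_bands
    model = make_molecular_model(
        trans_bands=base,
        cis_bands=base + (AbsorptionBand(center, fwhm, strength),),
        density_scale_cis=1.0)
    return ContrastConfig(molecular=model)


@dataclass
class LabeledDataset:
    """Spectra ``X`` (n_items, n_metapixels, n_wavenumbers), labels ``y``
    (0 = trans, 1 = cis), with the generating grid and design resonances."""

    X: np.ndarray
    y: np.ndarray
    grid: SpectralGrid
    nu0s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_metapixels(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.grid, self.nu0s,
                              dict(self.meta))


def _draw_states(n_per_class: int, contrast: ContrastConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cis fractions and coverages for trans items then cis items."""
    c_trans = rng.normal(contrast.cis_fraction_trans, contrast.cis_fraction_sd,
                         n_per_class)
    c_cis = rng.normal(contrast.cis_fraction_cis, contrast.cis_fraction_sd,
                       n_per_class)
    c = np.clip(np.concatenate([c_trans, c_cis]), 0.0, 1.0)
    cov = np.clip(rng.normal(contrast.coverage_mean, contrast.coverage_sd,
                             2 * n_per_class), 0.0, 1.0)
    return c, cov


def generate_labeled_dataset(n_per_class: int = 247,
                             contrast: ContrastConfig | None = None,
                             noise: NoiseModel | None = None,
                             seed: int = 0,
                             grid: SpectralGrid | None = None,
                             n_metapixels: int = 49,
                             resonance_range: tuple[float, float] = (1400.0, 1800.0),
                             Q: float = 100.0,
                             amplitude: float = 0.6,
                             block_px: int = 16,
                             medium: MediumConfig | None = None,
                             mode: str = "direct") -> LabeledDataset:
    """Balanced labeled dataset of averaged metapixel spectra.

    The default sizes reproduce the study conditions: 247 items per class
    (494 total), 49 metapixels on the 251-point model grid.  ``mode='direct'``
    synthesizes averaged spectra with effective noise sigma/sqrt(2*block_px^2);
    ``mode='cube'`` runs the full cube -> extract -> average chain per item.
    Labels follow the generating state (cis_fraction >= 0.5 -> cis = 1).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    contrast = default_contrast() if contrast is None else contrast
    noise = NoiseModel() if noise is None else noise
    grid = model_grid() if grid is None else grid
    medium = MediumConfig() if medium is None else medium
    rng = np.random.default_rng(seed)

    barcode = build_target_barcode(n_metapixels, resonance_range, Q, amplitude)
    layout = double_and_randomize(barcode, seed=seed)
    nu0s = np.array([d.nu0 for d in barcode.designs])

    cis_frac, coverage = _draw_states(n_per_class, contrast, rng)
    n = 2 * n_per_class
    y = (cis_frac >= 0.5).astype(np.int64)
    drift = 1.0 + rng.normal(0.0, noise.drift_amplitude, n) \
        if noise.drift_amplitude > 0 else np.ones(n)

    if mode == "cube":
        X = np.empty((n, n_metapixels, len(grid)), dtype=np.float32)
        for i in range(n):
            state = MembraneState(float(cis_frac[i]), float(coverage[i]))
            cube = simulate_cube(layout, state, contrast.molecular, noise,
                                 grid, rng, block_px=block_px, medium=medium,
                                 drift_value=float(drift[i]))
            spectra = average_doubled(extract_metapixel_spectra(cube, layout),
                                      layout)
            X[i] = np.stack([s.values for s in spectra])
    elif mode == "direct":
        X = _direct_spectra(cis_frac, coverage, drift, contrast.molecular,
                            barcode.designs, grid, medium, noise, block_px, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    perm = rng.permutation(n)
    meta = {"seed": seed, "mode": mode, "n_per_class": n_per_class,
            "block_px": block_px}
    return LabeledDataset(X=X[perm], y=y[perm], grid=grid, nu0s=nu0s, meta=meta)


def _direct_spectra(cis_frac, coverage, drift, molecular, designs, grid,
                    medium, noise, block_px, rng) -> np.ndarray:
    """Vectorized averaged-level synthesis (statistically equivalent to the
    cube route: additive noise scaled by 1/sqrt(pixels averaged per design)."""
    nu = grid.values
    bg = d2o_background(grid, medium)
    nu0s = np.array([d.nu0 for d in designs])
    gam = nu0s / (2.0 * np.array([d.Q for d in designs]))
    gam_r = RADIATIVE_FRACTION_DEFAULT * gam
    amp = np.array([d.amplitude for d in designs])
    n = len(cis_frac)
    n_px = 2 * block_px**2  # two doubled blocks averaged per design
    sigma_eff = noise.additive_sigma / np.sqrt(n_px)
    X = np.empty((n, len(designs), len(nu)), dtype=np.float32)
    for lo in range(0, n, 64):
        hi = min(lo + 64, n)
        loss = np.stack([
            molecular_loss(molecular, MembraneState(float(c), float(cov)), grid)
            for c, cov in zip(cis_frac[lo:hi], coverage[lo:hi])])
        denom = (1j * (nu[None, None, :] - nu0s[None, :, None])
                 + gam[None, :, None] + loss[:, None, :])
        r = R_BG_DEFAULT + amp[None, :, None] * gam_r[None, :, None] / denom
        R = bg[None, None, :] * np.abs(r) ** 2
        R *= drift[lo:hi, None, None]
        if sigma_eff > 0:
            R += rng.normal(0.0, sigma_eff, size=R.shape)
        X[lo:hi] = np.clip(R, 0.0, None)
    return X


def trajectory_spectra(protocol, kinetics, initial: MembraneState,
                       contrast: ContrastConfig | None = None,
                       noise: NoiseModel | None = None,
                       t_end_s: float | None = None,
                       seed: int = 0,
                       grid: SpectralGrid | None = None,
                       n_metapixels: int = 49,
                       block_px: int = 16,
                       medium: MediumConfig | None = None):
    """Averaged metapixel spectra of every frame of a switching trajectory.

    Returns ``(times_s, states, X)`` with ``X`` of shape
    (n_frames, n_metapixels, n_wavenumbers); the frame-to-frame drift follows
    the Ornstein-Uhlenbeck path of the noise model.
    """
    from .cube import drift_path
    from .kinetics import switching_trajectory

    contrast = default_contrast() if contrast is None else contrast
    noise = NoiseModel() if noise is None else noise
    grid = model_grid() if grid is None else grid
    medium = MediumConfig() if medium is None else medium
    if t_end_s is None:
        t_end_s = protocol.events[-1].end_s + 900.0
    times, states = switching_trajectory(protocol, kinetics, initial, t_end_s)
    rng = np.random.default_rng(seed)
    barcode = build_target_barcode(n_metapixels)
    drift = drift_path(len(times), protocol.frame_period_s, noise, rng)
    cis_frac = np.array([s.cis_fraction for s in states])
    coverage = np.array([s.coverage for s in states])
    X = _direct_spectra(cis_frac, coverage, drift, contrast.molecular,
                        barcode.designs, grid, medium, noise, block_px, rng)
    return times, states, X


def save_dataset(ds: LabeledDataset, spectra_path: str | Path,
                 labels_path: str | Path) -> None:
    """Wide CSV: one row per (item, metapixel), columns = wavenumbers."""
    n, m, w = ds.X.shape
    cols = [f"{v:.0f}" for v in ds.grid.values]
    df = pd.DataFrame(ds.X.reshape(n * m, w), columns=cols)
    df.insert(0, "metapixel", np.tile(np.arange(m), n))
    df.insert(0, "item", np.repeat(np.arange(n), m))
    df.to_csv(spectra_path, index=False)
    pd.DataFrame({"item": np.arange(n), "label": [LABELS[c] for c in ds.y]}) \
        .to_csv(labels_path, index=False)


def load_dataset(spectra_path: str | Path, labels_path: str | Path,
                 nu0s: np.ndarray | None = None) -> LabeledDataset:
    df = pd.read_csv(spectra_path)
    labels = pd.read_csv(labels_path)
    wn_cols = [c for c in df.columns if c not in ("item", "metapixel")]
    wn = np.array([float(c) for c in wn_cols])
    n = df["item"].nunique()
    m = df["metapixel"].nunique()
    X = df[wn_cols].to_numpy(dtype=np.float32).reshape(n, m, len(wn))
    y = np.array([LABELS.index(s) for s in labels["label"]])
    grid = SpectralGrid(wn[0], wn[-1], wn[1] - wn[0])
    if nu0s is None:
        nu0s = np.linspace(1400.0, 1800.0, m)
    return LabeledDataset(X=X, y=y, grid=grid, nu0s=nu0s)
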
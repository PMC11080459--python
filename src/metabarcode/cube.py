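"""Hyperspectral reflectance cubes: forward simulation, noise, drift, HDF5 I/O.

One cube is a single acquisition frame: reflectance over (x, y, wavenumber).
Each physical barcode slot occupies a contiguous square block of imaging
pixels (default 16x16, a desk-scale stand-in for the instrument's 480x480
field of view).  Measurement imperfections are additive Gaussian pixel noise
plus a slow multiplicative drift shared by all pixels of a frame, modelling
illumination and evaporation drifts; across frames the drift follows an
Ornstein-Uhlenbeck process around 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .barcode import PhysicalLayout
from .grid import SpectralGrid
from .kinetics import MembraneState
from .molecular import MediumConfig, MolecularModel, d2o_background, molecular_loss
from .resonance import reflectance_values

__all__ = ["NoiseModel", "HyperspectralCube", "simulate_cube",
           "layout_reflectance", "drift_path", "save_cube", "load_cube"]

#: Reflectance values are clipped into this range after noise (detector range).
R_MAX = 1.5


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: per-pixel additive sigma and shared drift OU process."""

    additive_sigma: float = 5e-3
    drift_amplitude: float = 0.02
    drift_timescale_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class HyperspectralCube:
    """Reflectance over (x, y, wavenumber) for one time frame."""

    grid: SpectralGrid
    values: np.ndarray  # shape (nx, ny, n_wavenumbers)
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3 or vals.shape[2] != len(self.grid):
            raise ValueError(f"cube shape {vals.shape} inconsistent with grid "
                             f"length {len(self.grid)}")
        if np.any(vals < 0):
            raise ValueError("reflectance must be nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]


def layout_reflectance(layout: PhysicalLayout, state: MembraneState,
                       molecular: MolecularModel, grid: SpectralGrid,
                       medium: MediumConfig | None = None) -> np.ndarray:
    """Noise-free reflectance of every design in the layout, keyed by slot.

    Returns an array of shape (n_slots, n_wavenumbers) in slot order.
    """
    loss = molecular_loss(molecular, state, grid)
    bg = d2o_background(grid, medium)
    per_design = {did: reflectance_values(d, grid, loss=loss, background=bg)
                  for did, d in layout.designs.items()}
    return np.stack([per_design[did] for did in layout.slots])


def drift_path(n_frames: int, frame_period_s: float, noise: NoiseModel,
               rng: np.random.Generator) -> np.ndarray:
    """Multiplicative drift factors per frame: OU process around 1.

    Stationary standard deviation = drift_amplitude; correlation time =
    drift_timescale_s.  With drift_amplitude 0 the path is identically 1.
    """
    if noise.drift_amplitude == 0:
        return np.ones(n_frames)
    theta = 1.0 / noise.drift_timescale_s
    rho = np.exp(-theta * frame_period_s)
    x = np.empty(n_frames)
    x[0] = rng.normal(0.0, noise.drift_amplitude)
    innov_sd = noise.drift_amplitude * np.sqrt(1.0 - rho**2)
    for i in range(1, n_frames):
        x[i] = rho * x[i - 1] + rng.normal(0.0, innov_sd)
    return 1.0 + x


def simulate_cube(layout: PhysicalLayout, state: MembraneState,
                  molecular: MolecularModel, noise: NoiseModel,
                  grid: SpectralGrid, seed: int | np.random.Generator,
                  block_px: int = 16, medium: MediumConfig | None = None,
                  drift_value: float | None = None,
                  timestamp_s: float = 0.0) -> HyperspectralCube:
    """Simulate one acquisition frame of the full barcode.

    Every imaging pixel of a slot's ``block_px`` x ``block_px`` block carries
    that design's spectrum, multiplied by a frame-wide drift factor, plus
    i.i.d. additive Gaussian noise.  Bit-reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    slot_spectra = layout_reflectance(layout, state, molecular, grid, medium)
    if drift_value is None:
        drift_value = 1.0 if noise.drift_amplitude == 0 else \
            float(1.0 + rng.normal(0.0, noise.drift_amplitude))
    nrow, ncol = layout.shape
    nx, ny = nrow * block_px, ncol * block_px
    nw = len(grid)
    values = np.empty((nx, ny, nw), dtype=np.float64)
    for slot, spec in enumerate(slot_spectra):
        r, c = layout.slot_position(slot)
        values[r * block_px:(r + 1) * block_px,
               c * block_px:(c + 1) * block_px, :] = spec * drift_value
    if noise.additive_sigma > 0:
        values += rng.normal(0.0, noise.additive_sigma, size=values.shape)
    np.clip(values, 0.0, R_MAX, out=values)
    return HyperspectralCube(grid=grid, values=values, timestamp_s=timestamp_s)


def save_cube(cube: HyperspectralCube, path: str | Path,
              attrs: dict | None = None) -> None:
    """Write a cube to HDF5 (datasets /reflectance, /wavenumbers, /timestamp)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.values.astype(np.float32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("wavenumbers", data=cube.grid.values)
        f.create_dataset("timestamp", data=cube.timestamp_s)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_cube(path: str | Path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        wn = f["wavenumbers"][()]
        vals = f["reflectance"][()].astype(np.float64)
        ts = float(f["timestamp"][()])
    grid = SpectralGrid(float(wn[0]), float(wn[-1]), float(wn[1] - wn[0]))
    return HyperspectralCube(grid=grid, values=vals, timestamp_s=ts)
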
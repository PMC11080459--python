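"""Per-metapixel 1D spectra on a fixed wavenumber grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .grid import SpectralGrid

__all__ = ["ReflectanceSpectrum", "AbsorbanceSpectrum"]


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance versus wavenumber for one metapixel."""

    grid: SpectralGrid
    values: np.ndarray
    design_id: int
    role: Literal["sample", "reference"] = "sample"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (len(self.grid),):
            raise ValueError(f"values shape {vals.shape} does not match grid "
                             f"length {len(self.grid)}")
        if np.any(vals < 0):
            raise ValueError("reflectance must be nonnegative")
        object.__setattr__(self, "values", vals)

    def at(self, nu: float) -> float:
        """Reflectance at the grid point nearest ``nu``."""
        return float(self.values[self.grid.index_of(nu)])


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Base-10 absorbance, either one value per averaged metapixel resonance
    (``provenance='per_pixel'``, ``positions`` = the 49 resonance wavenumbers)
    or a dense reconstruction on a grid (``provenance='reconstructed'``)."""

    positions: np.ndarray
    values: np.ndarray
    provenance: Literal["per_pixel", "reconstructed"] = "per_pixel"
    design_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        vals = np.asarray(self.values, dtype=np.float64)
        if pos.shape != vals.shape:
            raise ValueError("positions and values must have equal shape")
        if not np.all(np.isfinite(vals)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", vals)
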
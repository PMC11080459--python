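"""Wavenumber grids for hyperspectral reflectance data.

All spectra in the package live on a :class:`SpectralGrid`, an evenly spaced,
strictly increasing wavenumber axis in cm^-1.  Two standard grids are used
throughout: the instrument acquisition range (948-1800 cm^-1) and the model
grid used for classification and absorbance reconstruction (1300-1800 cm^-1),
both at 2 cm^-1 resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralGrid", "model_grid", "instrument_grid"]


@dataclass(frozen=True)
class SpectralGrid:
    """Evenly spaced wavenumber axis.

    Parameters
    ----------
    start, stop : float
        First and last wavenumber (cm^-1).  ``stop`` is included when
        ``stop - start`` is an integer multiple of ``step``.
    step : float
        Grid spacing (cm^-1), > 0.
    """

    start: float
    stop: float
    step: float
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        vals = self.start + self.step * np.arange(n, dtype=np.float64)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, nu: float) -> int:
        """Index of the grid point nearest to ``nu`` (snapping)."""
        i = int(np.round((nu - self.start) / self.step))
        if i < 0 or i >= len(self):
            raise ValueError(f"{nu} cm^-1 outside grid [{self.start}, {self.values[-1]}]")
        return i

    def snap(self, nu: float) -> float:
        """Wavenumber of the grid point nearest to ``nu``."""
        return float(self.values[self.index_of(nu)])


def model_grid() -> SpectralGrid:
    """Classifier / reconstruction grid: 1300-1800 cm^-1, 2 cm^-1 (251 points)."""
    return SpectralGrid(1300.0, 1800.0, 2.0)


def instrument_grid() -> SpectralGrid:
    """Acquisition grid of the IR microscope: 948-1800 cm^-1, 2 cm^-1."""
    return SpectralGrid(948.0, 1800.0, 2.0)
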
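"""Single-mode coupled-mode (Fano) lineshape of a high-Q metapixel resonance.

Each metapixel is modelled as one resonant mode of frequency nu0 with
radiative decay rate gamma_r and intrinsic (non-radiative) rate gamma_nr,
interfering with a direct background reflection r_bg:

    R(nu) = bg(nu) * | r_bg + a * gamma_r / (i (nu - nu0) + gamma_tot + loss(nu)) |^2

where gamma_tot = gamma_r + gamma_nr = nu0 / (2 Q) is the half width at half
maximum, loss(nu) >= 0 is the molecular loss channel of the membrane, and
bg(nu) is the multiplicative D2O medium attenuation.  With a real, nonnegative
r_bg the noise-free lineshape is an exact symmetric Lorentzian peak, and any
added loss strictly attenuates the resonance -- the weak-coupling regime in
which molecular absorption imprints on the spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .designs import MetapixelDesign
from .grid import SpectralGrid
from .spectra import ReflectanceSpectrum

__all__ = ["metapixel_reflectance", "reflectance_values", "fit_lorentzian"]

#: Default direct (non-resonant) background reflection amplitude.
R_BG_DEFAULT = 0.1
#: Default radiative fraction gamma_r / gamma_tot of the total decay rate.
RADIATIVE_FRACTION_DEFAULT = 0.85


def reflectance_values(design: MetapixelDesign, grid: SpectralGrid,
                       loss: np.ndarray | float = 0.0,
                       background: np.ndarray | float = 1.0,
                       r_bg: float = R_BG_DEFAULT,
                       radiative_fraction: float = RADIATIVE_FRACTION_DEFAULT,
                       ) -> np.ndarray:
    """Reflectance array for one design on ``grid`` (no container wrapping)."""
    if design.Q <= 0:
        raise ValueError("Q must be > 0")
    if not 0.0 < radiative_fraction <= 1.0:
        raise ValueError("radiative_fraction must lie in (0, 1]")
    loss = np.asarray(loss, dtype=np.float64)
    if np.any(loss < 0):
        raise ValueError("loss channel must be nonnegative")
    nu = grid.values
    gamma_tot = design.nu0 / (2.0 * design.Q)
    gamma_r = radiative_fraction * gamma_tot
    denom = 1j * (nu - design.nu0) + gamma_tot + loss
    r = r_bg + design.amplitude * gamma_r / denom
    return np.asarray(background, dtype=np.float64) * np.abs(r) ** 2


def metapixel_reflectance(design: MetapixelDesign,
                          loss: np.ndarray | float = 0.0,
                          background: np.ndarray | float = 1.0,
                          grid: SpectralGrid | None = None,
                          r_bg: float = R_BG_DEFAULT,
                          radiative_fraction: float = RADIATIVE_FRACTION_DEFAULT,
                          ) -> ReflectanceSpectrum:
    """Noise-free reflectance spectrum of one metapixel.

    ``loss`` is the molecular loss channel (cm^-1, from
    :func:`metabarcode.molecular.molecular_loss`) and ``background`` the
    medium attenuation (from :func:`metabarcode.molecular.d2o_background`).
    """
    if grid is None:
        raise ValueError("grid is required")
    vals = reflectance_values(design, grid, loss, background, r_bg,
                              radiative_fraction)
    return ReflectanceSpectrum(grid=grid, values=vals, design_id=design.design_id)


def _lorentz_peak(nu, c0, area, nu0, hwhm):
    return c0 + area * hwhm**2 / ((nu - nu0) ** 2 + hwhm**2)


def fit_lorentzian(grid: SpectralGrid, values: np.ndarray
                   ) -> dict[str, float]:
    """Fit a constant-plus-Lorentzian peak; returns nu0, fwhm, Q, height.

    Independent oracle for the generator: a noise-free coupled-mode resonance
    with real r_bg is an exact Lorentzian, so the fit recovers nu0 and Q.
    """
    nu = grid.values
    v = np.asarray(values, dtype=np.float64)
    i0 = int(np.argmax(v))
    c0_guess = float(np.min(v))
    p0 = [c0_guess, float(v[i0] - c0_guess), float(nu[i0]), 5.0]
    popt, _ = curve_fit(_lorentz_peak, nu, v, p0=p0, maxfev=20000)
    c0, area, nu0, hwhm = popt
    hwhm = abs(hwhm)
    return {"nu0": float(nu0), "fwhm": float(2 * hwhm),
            "Q": float(nu0 / (2 * hwhm)), "height": float(area),
            "offset": float(c0)}
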
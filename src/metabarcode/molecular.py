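"""Molecular absorption of the photolipid membrane and the D2O medium.

The AzoPC photolipid carries four mid-IR marker bands: CH2 scissoring at
1470 cm^-1, azobenzene ring breathing at 1496 cm^-1, the N=N stretch at
1511 cm^-1 (present only in the cis photoisomer), and the ester C=O stretch
around 1735 cm^-1.  Photoisomerization to cis enlarges the lipid footprint by
roughly 20%, lowering the areal lipid density; this is modelled by scaling all
cis band strengths by ``density_scale_cis`` (default 1/1.2 ~ 0.83).

Band absorption enters the optical model as an added loss channel (cm^-1 of
extra linewidth) in the resonator denominator -- the weak-coupling regime in
which molecular vibrations attenuate the metapixel resonances rather than
split them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import SpectralGrid
from .kinetics import MembraneState

__all__ = [
    "AbsorptionBand", "MolecularModel", "make_molecular_model",
    "molecular_loss", "d2o_background", "MediumConfig",
]


@dataclass(frozen=True)
class AbsorptionBand:
    """One Lorentzian vibrational band.

    ``strength`` is the peak loss the fully covered membrane adds to the
    resonator linewidth at the band centre (cm^-1).
    """

    center: float
    fwhm: float
    strength: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.strength < 0:
            raise ValueError(f"strength must be >= 0, got {self.strength}")

    def profile(self, nu: np.ndarray) -> np.ndarray:
        """Unit-peak Lorentzian evaluated on ``nu``, times strength."""
        hwhm = 0.5 * self.fwhm
        return self.strength * hwhm**2 / ((nu - self.center) ** 2 + hwhm**2)


@dataclass(frozen=True)
class MolecularModel:
    """Band sets of the two photoisomers.

    ``density_scale_cis`` multiplies every cis band strength, expressing the
    reduced areal lipid density of the expanded cis membrane.
    """

    trans_bands: tuple[AbsorptionBand, ...]
    cis_bands: tuple[AbsorptionBand, ...]
    density_scale_cis: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.density_scale_cis <= 1.0:
            raise ValueError("density_scale_cis must lie in (0, 1]")


# Default band strengths (cm^-1 of added linewidth at full coverage) chosen so
# retrieved absorbances fall in the 1e-2..1e-1 range typical of SEIRA.
_AZOPC_TRANS = (
    AbsorptionBand(1470.0, 15.0, 0.8),    # CH2 scissoring
    AbsorptionBand(1496.0, 15.0, 0.6),    # azobenzene ring breathing
    AbsorptionBand(1735.0, 15.0, 1.5),    # ester C=O stretch
)
_AZOPC_CIS_EXTRA = (
    AbsorptionBand(1511.0, 15.0, 1.0),    # N=N stretch, cis only
)


def make_molecular_model(state_config: str | None = "azopc_default",
                         trans_bands: Sequence[AbsorptionBand] | None = None,
                         cis_bands: Sequence[AbsorptionBand] | None = None,
                         density_scale_cis: float | None = None) -> MolecularModel:
    """Build a :class:`MolecularModel` from a preset or explicit band lists.

    ``state_config="azopc_default"`` gives trans bands at {1470, 1496, 1735}
    cm^-1 and cis bands at {1470, 1496, 1511, 1735} cm^-1 with the cis
    strengths scaled by ``density_scale_cis`` (default 0.83).
    """
    if trans_bands is not None or cis_bands is not None:
        if trans_bands is None or cis_bands is None:
            raise ValueError("supply both trans_bands and cis_bands, or neither")
        scale = 1.0 if density_scale_cis is None else density_scale_cis
        return MolecularModel(tuple(trans_bands), tuple(cis_bands), scale)
    if state_config != "azopc_default":
        raise ValueError(f"unknown preset {state_config!r}")
    scale = 1.0 / 1.2 if density_scale_cis is None else density_scale_cis
    return MolecularModel(_AZOPC_TRANS, _AZOPC_TRANS + _AZOPC_CIS_EXTRA, scale)


def _band_sum(bands: Sequence[AbsorptionBand], nu: np.ndarray) -> np.ndarray:
    total = np.zeros_like(nu, dtype=np.float64)
    for b in bands:
        total += b.profile(nu)
    return total


def molecular_loss(model: MolecularModel, state: MembraneState,
                   grid: SpectralGrid) -> np.ndarray:
    """Per-wavenumber loss channel (cm^-1 linewidth contribution).

    loss(nu) = coverage * [(1 - c) * L_trans(nu) + c * d_cis * L_cis(nu)]
    where c is the cis fraction and d_cis the cis density scale.  Nonnegative
    everywhere; identically zero at zero coverage.
    """
    nu = grid.values
    c = state.cis_fraction
    loss = (1.0 - c) * _band_sum(model.trans_bands, nu)
    loss += c * model.density_scale_cis * _band_sum(model.cis_bands, nu)
    return state.coverage * loss


@dataclass(frozen=True)
class MediumConfig:
    """Smooth D2O medium attenuation, modelled via Beer-Lambert.

    The attenuation is 10**(-A_med(nu)) with A_med a broad Lorentzian wing
    centred below the measurement window (the D2O bending mode region) plus a
    small constant; ``enabled=False`` switches the medium off (attenuation 1).
    """

    enabled: bool = True
    amplitude: float = 0.25
    center: float = 1210.0
    fwhm: float = 180.0
    constant: float = 0.02

    def absorbance(self, nu: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return np.zeros_like(nu)
        hwhm = 0.5 * self.fwhm
        return self.amplitude * hwhm**2 / ((nu - self.center) ** 2 + hwhm**2) \
            + self.constant


def d2o_background(grid: SpectralGrid,
                   medium: MediumConfig | None = None) -> np.ndarray:
    """Multiplicative medium attenuation factor in (0, 1] on the grid."""
    medium = MediumConfig() if medium is None else medium
    return 10.0 ** (-medium.absorbance(grid.values))
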
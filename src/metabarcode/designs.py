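"""Metapixel unit-cell designs.

A metapixel is a periodic array of identical tilted-ellipse-pair unit cells
whose in-plane scale factor S sets the resonance wavenumber.  The geometry is
carried as metadata only; spectra are produced by the phenomenological
coupled-mode lineshape in :mod:`metabarcode.resonance`, never from geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Geometry", "MetapixelDesign", "BASE_GEOMETRY", "design_for"]


@dataclass(frozen=True)
class Geometry:
    """Unit-cell dimensions (nm / degrees), metadata only."""

    A_nm: float = 2000.0
    B_nm: float = 480.0
    Px_nm: float = 2100.0
    Py_nm: float = 2050.0
    theta_deg: float = 20.0
    thickness_nm: float = 700.0

    def scaled(self, S: float) -> "Geometry":
        """Lateral scaling by S (thickness and tilt unchanged)."""
        return Geometry(self.A_nm * S, self.B_nm * S, self.Px_nm * S,
                        self.Py_nm * S, self.theta_deg, self.thickness_nm)


BASE_GEOMETRY = Geometry()

# Reference wavenumber assigned to scale S = 1; resonance scales as 1/S.
_NU_REF = 1600.0


@dataclass(frozen=True)
class MetapixelDesign:
    """One metapixel design: resonance position, Q-factor and amplitude.

    Parameters
    ----------
    design_id : int
        Stable identifier; target-barcode designs are numbered 0..48 in order
        of increasing resonance.
    nu0 : float
        Resonance wavenumber (cm^-1), > 0.
    Q : float
        Quality factor nu0 / FWHM, > 0.
    amplitude : float
        Peak amplitude coefficient of the resonant pathway, in [0, 1].
    scale_S : float
        Lateral geometric scale factor (metadata).
    geometry : Geometry
        Unit-cell dimensions (metadata; never enters spectral computation).
    """

    design_id: int
    nu0: float
    Q: float
    amplitude: float
    scale_S: float = field(default=1.0)
    geometry: Geometry = field(default=BASE_GEOMETRY)

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError(f"Q must be > 0, got {self.Q}")
        if self.nu0 <= 0:
            raise ValueError(f"nu0 must be > 0, got {self.nu0}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must lie in [0, 1], got {self.amplitude}")

    @property
    def fwhm(self) -> float:
        """Resonance full width at half maximum, nu0 / Q (cm^-1)."""
        return self.nu0 / self.Q


def design_for(design_id: int, nu0: float, Q: float = 100.0,
               amplitude: float = 0.6) -> MetapixelDesign:
    """Construct a design with geometry metadata scaled to its resonance."""
    S = _NU_REF / nu0
    return MetapixelDesign(design_id=design_id, nu0=nu0, Q=Q,
                           amplitude=amplitude, scale_S=S,
                           geometry=BASE_GEOMETRY.scaled(S))
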
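"""From hyperspectral cubes to metapixel spectra, absorbance, and barcode maps.

The extraction chain mirrors the measurement post-processing: spatially
average each slot block into one reflectance spectrum per physical pixel,
average the doubled pixels of each design (98 -> 49 spectra; the two extras
are excluded from the averaged set), compute the base-10 absorbance

    A = -log10(R_sample / R_D2O)

at each design's resonance position against a D2O reference, reconstruct a
dense absorbance spectrum by linear interpolation plus a third-order
Savitzky-Golay filter, and render the 49 per-pixel absorbances as a 7x7
molecular barcode map in target-design order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .barcode import PhysicalLayout, design_index
from .cube import HyperspectralCube
from .grid import SpectralGrid
from .kinetics import SwitchProtocol
from .spectra import AbsorbanceSpectrum, ReflectanceSpectrum

__all__ = [
    "extract_metapixel_spectra", "average_doubled", "absorbance_at_resonance",
    "per_pixel_absorbance", "reconstruct_absorbance_spectrum",
    "render_barcode_map", "timeseries_absorbance", "exclusion_flags",
]


def extract_metapixel_spectra(cube: HyperspectralCube, layout: PhysicalLayout,
                              block_px: int | None = None
                              ) -> list[ReflectanceSpectrum]:
    """Arithmetic block mean per slot: one spectrum per physical pixel.

    Returns ``layout.n_slots`` spectra in slot order.  ``block_px`` defaults
    to the cube extent divided by the layout shape.
    """
    nrow, ncol = layout.shape
    if block_px is None:
        if cube.nx % nrow or cube.ny % ncol:
            raise ValueError("cube extent not divisible by layout shape")
        block_px = cube.nx // nrow
    if nrow * block_px > cube.nx or ncol * block_px > cube.ny:
        raise ValueError("layout blocks extend beyond the cube")
    out = []
    for slot, did in enumerate(layout.slots):
        r, c = layout.slot_position(slot)
        block = cube.values[r * block_px:(r + 1) * block_px,
                            c * block_px:(c + 1) * block_px, :]
        out.append(ReflectanceSpectrum(grid=cube.grid,
                                       values=block.mean(axis=(0, 1)),
                                       design_id=did))
    return out


def average_doubled(spectra: list[ReflectanceSpectrum],
                    layout: PhysicalLayout) -> list[ReflectanceSpectrum]:
    """Average the two duplicates of each doubled design; drop the extras.

    Returns exactly one spectrum per target design, ordered by design_id.
    """
    index = design_index(layout)
    by_slot = {slot: s for slot, s in enumerate(spectra)}
    out = []
    for did, slots in index.items():
        if did in layout.extras:
            continue
        if len(slots) != 2:
            raise ValueError(f"design {did} has {len(slots)} slots, expected 2")
        vals = np.mean([by_slot[s].values for s in slots], axis=0)
        out.append(ReflectanceSpectrum(grid=spectra[0].grid, values=vals,
                                       design_id=did))
    return sorted(out, key=lambda s: s.design_id)


def absorbance_at_resonance(sample: ReflectanceSpectrum,
                            reference: ReflectanceSpectrum,
                            nu0: float) -> float:
    """A = -log10(R_sample / R_ref) at the grid point nearest ``nu0``."""
    r_s = sample.at(nu0)
    r_r = reference.at(nu0)
    if r_s <= 0 or r_r <= 0:
        raise ValueError(f"nonpositive reflectance at {nu0} cm^-1: "
                         f"sample={r_s}, reference={r_r}")
    return float(-np.log10(r_s / r_r))


def per_pixel_absorbance(samples: list[ReflectanceSpectrum],
                         references: list[ReflectanceSpectrum],
                         layout: PhysicalLayout) -> AbsorbanceSpectrum:
    """Absorbance of each averaged design at its own resonance position."""
    ref_by_id = {s.design_id: s for s in references}
    pos, vals, ids = [], [], []
    for s in samples:
        nu0 = layout.designs[s.design_id].nu0
        pos.append(s.grid.snap(nu0))
        vals.append(absorbance_at_resonance(s, ref_by_id[s.design_id], nu0))
        ids.append(s.design_id)
    return AbsorbanceSpectrum(positions=np.array(pos), values=np.array(vals),
                              provenance="per_pixel",
                              design_ids=np.array(ids))


def reconstruct_absorbance_spectrum(per_pixel: AbsorbanceSpectrum,
                                    grid: SpectralGrid,
                                    window: int = 11,
                                    polyorder: int = 3) -> AbsorbanceSpectrum:
    """Linear interpolation onto ``grid`` followed by one Savitzky-Golay pass.

    Edge windows are handled by a polynomial fit (``mode='interp'``), so an
    order-3 filter reproduces cubic signals exactly.
    """
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if len(per_pixel.positions) < polyorder + 1:
        raise ValueError("need at least polyorder + 1 scattered points")
    order = np.argsort(per_pixel.positions)
    dense = np.interp(grid.values, per_pixel.positions[order],
                      per_pixel.values[order])
    smooth = savgol_filter(dense, window_length=window, polyorder=polyorder,
                           mode="interp")
    return AbsorbanceSpectrum(positions=grid.values.copy(), values=smooth,
                              provenance="reconstructed")


def render_barcode_map(per_pixel: AbsorbanceSpectrum,
                       shape: tuple[int, int] = (7, 7)) -> np.ndarray:
    """Place the 49 per-pixel absorbances into the 7x7 target-barcode pattern.

    Values are ordered by design (target-barcode order), not by the randomized
    physical position; row-major reshape, so ``map.ravel()`` round-trips.
    """
    vals = np.asarray(per_pixel.values)
    if per_pixel.design_ids is not None:
        vals = vals[np.argsort(per_pixel.design_ids)]
    if vals.size != shape[0] * shape[1]:
        raise ValueError(f"expected {shape[0] * shape[1]} values, got {vals.size}")
    return vals.reshape(shape)


def exclusion_flags(times_s: np.ndarray, protocol: SwitchProtocol,
                    pre_window_s: float = 14 * 60.0) -> np.ndarray:
    """True for frames to exclude: LED on, or within 14 min before the first
    LED event (membrane still equilibrating)."""
    times_s = np.asarray(times_s, dtype=float)
    flags = protocol.led_on(times_s)
    if protocol.events:
        t0 = protocol.events[0].start_s
        flags |= (times_s >= t0 - pre_window_s) & (times_s < t0)
    return flags


def timeseries_absorbance(cubes: list[HyperspectralCube],
                          layout: PhysicalLayout,
                          reference_frames: list[int],
                          design_id: int,
                          protocol: SwitchProtocol | None = None
                          ) -> pd.DataFrame:
    """Per-frame absorbance of one design at its resonance position.

    The reference spectrum is the mean of that design's averaged spectrum over
    the D2O-only ``reference_frames`` (which must precede the analyte frames).
    Returns a tidy frame (time_s, absorbance, excluded) with exclusion flags
    from the LED protocol when given.
    """
    if not reference_frames:
        raise ValueError("reference frame set must not be empty")
    times = np.array([c.timestamp_s for c in cubes])
    if max(reference_frames) >= len(cubes):
        raise ValueError("reference frame index out of range")
    nu0 = layout.designs[design_id].nu0

    def design_spectrum(cube: HyperspectralCube) -> ReflectanceSpectrum:
        spectra = extract_metapixel_spectra(cube, layout)
        averaged = average_doubled(spectra, layout)
        return next(s for s in averaged if s.design_id == design_id)

    per_frame = [design_spectrum(c) for c in cubes]
    ref_vals = np.mean([per_frame[i].values for i in reference_frames], axis=0)
    reference = ReflectanceSpectrum(grid=cubes[0].grid, values=ref_vals,
                                    design_id=design_id, role="reference")
    absorb = [absorbance_at_resonance(s, reference, nu0) for s in per_frame]
    excluded = exclusion_flags(times, protocol) if protocol is not None \
        else np.zeros(len(cubes), dtype=bool)
    return pd.DataFrame({"time_s": times, "absorbance": absorb,
                         "excluded": excluded})
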
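"""Barcode design: 49-pixel target barcode, pixel doubling, randomization.

The target barcode is a 7x7 pattern of metapixels with resonance positions
spaced linearly over 1400-1800 cm^-1.  For fabrication robustness every
target pixel is duplicated ("pixel doubling") and two extra metapixels are
added, giving 100 physical pixels that are placed in a seeded uniform-random
order on a 10x10 grid -- the randomization removes any systematic spatial
bias from the linear resonance scaling, while the design -> resonance mapping
stays injective so spectral and spatial information map unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .designs import Geometry, MetapixelDesign, design_for

__all__ = [
    "TargetBarcode", "PhysicalLayout", "build_target_barcode",
    "default_extra_designs", "double_and_randomize", "design_index",
    "save_layout", "load_layout",
]


@dataclass(frozen=True)
class TargetBarcode:
    """Ordered target designs with linearly increasing resonance positions."""

    designs: tuple[MetapixelDesign, ...]
    grid_shape: tuple[int, int] = (7, 7)
    resonance_range: tuple[float, float] = (1400.0, 1800.0)

    def __post_init__(self) -> None:
        nu = np.array([d.nu0 for d in self.designs])
        if np.any(np.diff(nu) <= 0):
            raise ValueError("design resonances must be strictly increasing")

    def __len__(self) -> int:
        return len(self.designs)


@dataclass(frozen=True)
class PhysicalLayout:
    """Random 10x10 placement of the doubled barcode plus two extras.

    ``slots`` is a row-major tuple of design_ids (index = row*ncols + col);
    ``designs`` maps design_id to the design, including the two extras.
    """

    slots: tuple[int, ...]
    designs: dict[int, MetapixelDesign]
    extras: tuple[int, int]
    seed: int
    shape: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if len(self.slots) != self.shape[0] * self.shape[1]:
            raise ValueError("slot count must match layout shape")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    def slot_position(self, slot: int) -> tuple[int, int]:
        """(row, col) of a slot, row-major, origin at top-left."""
        return divmod(slot, self.shape[1])


def build_target_barcode(n_pixels: int = 49,
                         resonance_range: tuple[float, float] = (1400.0, 1800.0),
                         Q: float = 100.0,
                         amplitude: float = 0.6) -> TargetBarcode:
    """Target barcode with ``n_pixels`` linearly spaced resonances.

    nu0_i = start + i * (stop - start) / (n_pixels - 1), i = 0..n_pixels-1.
    """
    lo, hi = resonance_range
    if hi <= lo:
        raise ValueError("resonance_range must be increasing")
    if n_pixels < 2:
        raise ValueError("n_pixels must be >= 2")
    nus = lo + (hi - lo) * np.arange(n_pixels) / (n_pixels - 1)
    designs = tuple(design_for(i, float(nu), Q=Q, amplitude=amplitude)
                    for i, nu in enumerate(nus))
    side = int(np.round(np.sqrt(n_pixels)))
    shape = (side, side) if side * side == n_pixels else (1, n_pixels)
    return TargetBarcode(designs=designs, grid_shape=shape,
                         resonance_range=(lo, hi))


def default_extra_designs(barcode: TargetBarcode) -> tuple[MetapixelDesign, MetapixelDesign]:
    """Two extra designs at the midpoints of the two central inter-pixel gaps,
    densifying the resonance sampling mid-range."""
    n = len(barcode)
    nus = [d.nu0 for d in barcode.designs]
    mid = n // 2
    e1 = 0.5 * (nus[mid - 1] + nus[mid])
    e2 = 0.5 * (nus[mid] + nus[mid + 1])
    d0 = barcode.designs[0]
    return (design_for(n, e1, Q=d0.Q, amplitude=d0.amplitude),
            design_for(n + 1, e2, Q=d0.Q, amplitude=d0.amplitude))


def double_and_randomize(barcode: TargetBarcode,
                         extra_designs: Sequence[MetapixelDesign] | None = None,
                         seed: int = 0) -> PhysicalLayout:
    """Pixel doubling plus extras, shuffled uniformly at random under ``seed``.

    Every target design appears exactly twice and each of the two extras once,
    for 2n + 2 physical pixels (100 for the 49-pixel target barcode).
    """
    if extra_designs is None:
        extra_designs = default_extra_designs(barcode)
    if len(extra_designs) != 2:
        raise ValueError(f"exactly 2 extra designs required, got {len(extra_designs)}")
    ids = [d.design_id for d in barcode.designs]
    extra_ids = tuple(d.design_id for d in extra_designs)
    if set(extra_ids) & set(ids):
        raise ValueError("extra design_ids collide with barcode design_ids")
    pool = np.array(ids + ids + list(extra_ids))
    rng = np.random.default_rng(seed)
    slots = tuple(int(i) for i in rng.permutation(pool))
    n_side = int(np.round(np.sqrt(len(pool))))
    shape = (n_side, n_side) if n_side * n_side == len(pool) else (1, len(pool))
    designs = {d.design_id: d for d in list(barcode.designs) + list(extra_designs)}
    return PhysicalLayout(slots=slots, designs=designs, extras=extra_ids,
                          seed=seed, shape=shape)


def design_index(layout: PhysicalLayout) -> dict[int, list[int]]:
    """Inverse mapping design_id -> sorted list of slot indices."""
    index: dict[int, list[int]] = {}
    for slot, did in enumerate(layout.slots):
        index.setdefault(did, []).append(slot)
    return {k: sorted(v) for k, v in sorted(index.items())}


def _design_to_dict(d: MetapixelDesign) -> dict:
    return {"design_id": d.design_id, "nu0": d.nu0, "Q": d.Q,
            "amplitude": d.amplitude, "scale_S": d.scale_S,
            "geometry": vars(d.geometry).copy()}


def _design_from_dict(rec: dict) -> MetapixelDesign:
    return MetapixelDesign(design_id=rec["design_id"], nu0=rec["nu0"],
                           Q=rec["Q"], amplitude=rec["amplitude"],
                           scale_S=rec["scale_S"],
                           geometry=Geometry(**rec["geometry"]))


def save_layout(layout: PhysicalLayout, path: str | Path) -> None:
    """Lossless JSON round-trip of a physical layout."""
    doc = {
        "seed": layout.seed,
        "shape": list(layout.shape),
        "slots": list(layout.slots),
        "extras": list(layout.extras),
        "designs": [_design_to_dict(d) for _, d in sorted(layout.designs.items())],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_layout(path: str | Path) -> PhysicalLayout:
    doc = json.loads(Path(path).read_text())
    designs = {rec["design_id"]: _design_from_dict(rec) for rec in doc["designs"]}
    return PhysicalLayout(slots=tuple(doc["slots"]), designs=designs,
                          extras=tuple(doc["extras"]), seed=doc["seed"],
                          shape=tuple(doc["shape"]))
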
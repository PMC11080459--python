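"""Photoisomerization kinetics and LED switching protocols.

AzoPC switches trans -> cis under 365 nm ("UV") light and cis -> trans under
465 nm ("VIS") light.  Under constant illumination the cis fraction c relaxes
first-order toward the photostationary state of that wavelength:

    dc/dt = k * (pss - c)

with rate k (s^-1) and photostationary cis fraction pss.  In the dark the
membrane state is held constant (thermal relaxation of AzoPC is hours-slow
against the minutes-long experiment).  The solution per illumination event is
an exact exponential, so trajectories are evaluated analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MembraneState", "LedEvent", "SwitchProtocol", "KineticsParams",
    "switching_trajectory", "default_protocol",
]


@dataclass(frozen=True)
class MembraneState:
    """Membrane composition: cis fraction and surface coverage, both in [0, 1]."""

    cis_fraction: float
    coverage: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cis_fraction", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def label(self) -> str:
        """State label by majority isomer: cis when cis_fraction >= 0.5."""
        return "cis" if self.cis_fraction >= 0.5 else "trans"


@dataclass(frozen=True)
class LedEvent:
    led: Literal["UV", "VIS"]
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.led not in ("UV", "VIS"):
            raise ValueError(f"led must be 'UV' or 'VIS', got {self.led!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SwitchProtocol:
    """Ordered, non-overlapping LED illumination events plus the frame period."""

    events: tuple[LedEvent, ...]
    frame_period_s: float = 64.0

    def __post_init__(self) -> None:
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be > 0")
        for a, b in zip(self.events, self.events[1:]):
            if b.start_s < a.end_s:
                raise ValueError("events must be time-ordered and non-overlapping")

    def frame_times(self, t_end_s: float) -> np.ndarray:
        return np.arange(0.0, t_end_s + 1e-9, self.frame_period_s)

    def led_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: is any LED on at time t (start inclusive, end exclusive)."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for ev in self.events:
            on |= (t >= ev.start_s) & (t < ev.end_s)
        return on


@dataclass(frozen=True)
class KineticsParams:
    """First-order photoswitching rates and photostationary cis fractions."""

    k_uv: float = 0.03
    k_vis: float = 0.03
    pss_uv: float = 0.9
    pss_vis: float = 0.1

    def __post_init__(self) -> None:
        if self.k_uv < 0 or self.k_vis < 0:
            raise ValueError("rates must be >= 0")
        for name in ("pss_uv", "pss_vis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pss_uv <= self.pss_vis:
            raise ValueError("pss_uv must exceed pss_vis")


def default_protocol(lead_in_s: float = 4200.0, n_cycles: int = 3,
                     on_s: float = 270.0, off_s: float = 900.0,
                     frame_period_s: float = 64.0,
                     first_led: str = "UV") -> SwitchProtocol:
    """Alternating UV/VIS protocol: LED on for 4 min 30 s, off for 15 min.

    One cycle is a UV step followed by a VIS step (each on/off pair); the
    default repeats three cycles after a lead-in with both LEDs dark.
    """
    events = []
    t = lead_in_s
    leds = ("UV", "VIS") if first_led == "UV" else ("VIS", "UV")
    for _ in range(n_cycles):
        for led in leds:
            events.append(LedEvent(led, t, on_s))
            t += on_s + off_s
    return SwitchProtocol(tuple(events), frame_period_s)


def _cis_at(t: float, protocol: SwitchProtocol, kin: KineticsParams,
            c0: float) -> float:
    """Exact piecewise-exponential cis fraction at time t (t >= 0)."""
    c = c0
    for ev in protocol.events:
        if t <= ev.start_s:
            return c
        k = kin.k_uv if ev.led == "UV" else kin.k_vis
        pss = kin.pss_uv if ev.led == "UV" else kin.pss_vis
        dt = min(t, ev.end_s) - ev.start_s
        c = pss + (c - pss) * np.exp(-k * dt)
        if t <= ev.end_s:
            return c
    return c


def switching_trajectory(protocol: SwitchProtocol, kinetics: KineticsParams,
                         initial: MembraneState,
                         t_end_s: float) -> tuple[np.ndarray, list[MembraneState]]:
    """Membrane state sampled every frame period up to ``t_end_s``.

    Returns ``(times, states)``.  During a UV (VIS) event the cis fraction
    relaxes exponentially toward ``pss_uv`` (``pss_vis``); it is constant in
    the dark.  Coverage is carried through unchanged.
    """
    if protocol.events and t_end_s < protocol.events[-1].end_s:
        raise ValueError("t_end_s must reach the end of the last event")
    times = protocol.frame_times(t_end_s)
    states = [
        MembraneState(float(np.clip(_cis_at(float(t), protocol, kinetics,
                                            initial.cis_fraction), 0.0, 1.0)),
                      initial.coverage)
        for t in times
    ]
    return times, states
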
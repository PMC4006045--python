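"""Functional parameters of the percussive task, per strike.

The task constraints of conchoidal flake removal are satisfied through the
energy delivered at the hammer's working point. Three quantities summarize
each strike:

* ``Ek_max = 1/2 m v_max^2`` — maximal kinetic energy, with ``v_max`` the
  peak working-point speed over the strike segment (central differences,
  no filtering);
* ``Ep = m g h`` — gravitational potential energy at movement start, with
  ``h`` the vertical distance from the working point at the start frame
  down to the core striking surface (``g = 9.81 m/s^2``);
* their ratio ``Ek_max / Ep`` — values above 1 indicate muscular work added
  beyond what gravity supplies, values near 1 a gravity-harnessing strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .events import StrikeSegment, _vertical_distance_to_plane, estimate_speed
from .reconstruction import ReconstructedTrial

GRAVITY = 9.81  # m/s^2


@dataclass
class EnergyMeasures:
    """Per-strike functional parameters (J; ratio dimensionless)."""

    hammer_mass: float
    v_max: float
    ek_max: float
    start_height: float  # h, m above the striking surface
    ep: float
    ratio: Optional[float]  # None when Ep <= 0 (flagged, excluded from summaries)
    start_below_surface: bool = False


def kinetic_energy_max(
    segment: StrikeSegment,
    working_point: np.ndarray,
    fs: float,
    hammer_mass: float,
) -> tuple[float, float]:
    """``(Ek_max, v_max)`` over the strike segment.

    The speed series is differentiated on the full trace (so the segment
    interior uses true central differences) and maximized over
    ``[start, end]`` — the apex-to-impact window is the natural maximal
    window for "maximal kinetic energy".
    """
    if hammer_mass <= 0:
        raise ValueError("hammer mass must be > 0")
    speed = estimate_speed(working_point, fs)
    v_max = float(np.max(speed[segment.frames]))
    return 0.5 * hammer_mass * v_max**2, v_max


def potential_energy(
    segment: StrikeSegment,
    recon: ReconstructedTrial,
    hammer_mass: float,
) -> tuple[float, float, bool]:
    """``(Ep, h, start_below_surface)`` at the strike's start frame.

    ``h`` is measured along gravity (vertical axis), not along the surface
    normal: Ep is gravitational. A start below the surface gives Ep <= 0,
    which is flagged rather than raised.
    """
    if hammer_mass <= 0:
        raise ValueError("hammer mass must be > 0")
    h = float(
        _vertical_distance_to_plane(
            recon.working_point[segment.start_idx : segment.start_idx + 1], recon.surface
        )[0]
    )
    return hammer_mass * GRAVITY * h, h, h < 0


def energy_ratio(ek_max: float, ep: float) -> Optional[float]:
    """``Ek_max / Ep``; undefined (None) when Ep <= 0."""
    if ep <= 0:
        return None
    return ek_max / ep


def strike_energies(
    segment: StrikeSegment, recon: ReconstructedTrial, hammer_mass: float
) -> EnergyMeasures:
    """All functional parameters for one detected strike."""
    ek, v_max = kinetic_energy_max(segment, recon.working_point, recon.fs, hammer_mass)
    ep, h, below = potential_energy(segment, recon, hammer_mass)
    return EnergyMeasures(
        hammer_mass=hammer_mass,
        v_max=v_max,
        ek_max=ek,
        start_height=h,
        ep=ep,
        ratio=energy_ratio(ek, ep),
        start_below_surface=below,
    )
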
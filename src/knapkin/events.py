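"""Strike segmentation and outcome matching.

A striking movement starts at the hand sensor's highest vertical position
prior to the strike and ends when the sensor reaches its lowest point or
first slows below the configured speed threshold (default 4.17e-3 m/s, the
240 Hz frame interval read as a speed — kept as conventionally printed,
overridable). Candidate impacts are local minima of the vertical hand-sensor
trace whose hammer working point approaches the registered striking-surface
plane within a gate distance; the rules presuppose knowing a strike
occurred, and the gate operationalizes that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .io import OutcomeRecord, RunConfig
from .reconstruction import ReconstructedTrial


def estimate_speed(positions: np.ndarray, fs: float) -> np.ndarray:
    """Speed series (m/s) from a position trace: central differences in the
    interior, one-sided at the boundaries, no smoothing."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if len(positions) < 3:
        raise ValueError("speed estimation needs at least 3 frames")
    vel = np.gradient(positions, 1.0 / fs, axis=0)
    return np.linalg.norm(vel, axis=1)


@dataclass
class StrikeSegment:
    """One detected striking movement with its outcome link."""

    start_idx: int
    end_idx: int
    impact_idx: int  # the gated local minimum
    apex_height: float  # m, hand-sensor vertical at start
    impact_height: float  # m, hand-sensor vertical at end
    flake_produced: Optional[bool] = None
    flake_mass_g: Optional[float] = None
    protocol_violation: bool = False

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ValueError("strike segment requires start < end")

    @property
    def frames(self) -> slice:
        return slice(self.start_idx, self.end_idx + 1)


def _vertical_distance_to_plane(points: np.ndarray, plane) -> np.ndarray:
    """Signed vertical (gravity-axis) distance from points to the plane."""
    n = plane.normal
    if abs(n[2]) < 1e-9:
        raise ValueError("striking surface is vertical; vertical distance undefined")
    z_plane = plane.point[2] - (
        n[0] * (points[:, 0] - plane.point[0]) + n[1] * (points[:, 1] - plane.point[1])
    ) / n[2]
    return points[:, 2] - z_plane


def segment_strikes(
    recon: ReconstructedTrial,
    config: Optional[RunConfig] = None,
) -> list[StrikeSegment]:
    """Detect striking movements on a reconstructed trial.

    Candidates: local minima of the vertical hand-sensor position whose
    working point lies within ``surface_gate_m`` of the striking surface.
    Start = last local maximum of the vertical trace before the impact;
    end = the earlier of the segment's lowest point and the first post-start
    frame slower than the speed threshold. Overlapping candidates are merged
    keeping the deeper minimum. No candidate -> empty list (not an error).
    """
    config = config or RunConfig()
    z = recon.hand_sensor_pos[:, 2]
    n = len(z)
    if n < 3:
        return []
    signal = (
        recon.hand_sensor_pos if config.speed_signal == "hand_sensor" else recon.working_point
    )
    speed = estimate_speed(signal, recon.fs)
    wp_dist = np.abs(_vertical_distance_to_plane(recon.working_point, recon.surface))

    minima = argrelextrema(z, np.less_equal, order=2)[0]
    minima = minima[(minima > 0) & (minima < n - 1)]
    candidates = [int(i) for i in minima if wp_dist[i] <= config.surface_gate_m]
    # collapse plateau runs to their deepest sample
    collapsed: list[int] = []
    for idx in candidates:
        if collapsed and idx - collapsed[-1] <= 2:
            if z[idx] < z[collapsed[-1]]:
                collapsed[-1] = idx
        else:
            collapsed.append(idx)

    segments: list[StrikeSegment] = []
    prev_end = -1
    for impact in collapsed:
        # start: the sensor's highest vertical position prior to the strike,
        # searched after the previous movement ended
        lo = prev_end + 1
        if lo >= impact:
            continue
        start = lo + int(np.argmax(z[lo:impact]))
        if start >= impact:
            continue
        # a striking movement must actually descend; this rejects micro
        # minima while the hammer hovers near the surface after a strike
        if z[start] - z[impact] < config.min_strike_drop_m:
            continue
        lowest = start + int(np.argmin(z[start : impact + 1]))
        # "slowed below threshold" presupposes having been fast: the
        # crossing only counts after the movement's speed peak (at the apex
        # itself the sensor is momentarily at rest and noise dips would
        # otherwise end the segment immediately)
        seg_speed = speed[start : impact + 1]
        peak = int(np.argmax(seg_speed))
        end = lowest
        slow = np.nonzero(seg_speed[peak:] < config.speed_threshold_m_per_s)[0]
        if len(slow):
            end = min(lowest, start + peak + int(slow[0]))
        if end <= start:
            continue
        seg = StrikeSegment(
            start_idx=start,
            end_idx=int(end),
            impact_idx=impact,
            apex_height=float(z[start]),
            impact_height=float(z[end]),
        )
        if segments and seg.start_idx <= segments[-1].end_idx:
            # overlapping candidates: keep the deeper minimum
            if z[impact] < z[segments[-1].impact_idx]:
                segments[-1] = seg
            continue
        segments.append(seg)
        prev_end = int(end)
    return segments


def attach_outcomes(
    segments: list[StrikeSegment],
    outcome_records: list[OutcomeRecord],
    max_strikes: int = 3,
) -> list[StrikeSegment]:
    """One-to-one ordered matching of detected strikes to outcome records
    for a single trial. A mismatch in counts is a reconciliation error;
    trials exceeding ``max_strikes`` strikes per flake attempt are flagged
    as protocol violations (not dropped)."""
    records = sorted(outcome_records, key=lambda r: r.strike_index)
    if len(records) > len(segments):
        raise ValueError(
            f"reconciliation error: {len(records)} outcome records but only "
            f"{len(segments)} detected strikes"
        )
    violation = len(segments) > max_strikes
    for seg, rec in zip(segments, records):
        seg.flake_produced = rec.flake_produced
        seg.flake_mass_g = rec.flake_mass_g
        seg.protocol_violation = violation
    return segments


def segments_table(segments: list[StrikeSegment], subject: str = "", trial: int = 0):
    rows = [
        {
            "subject": subject,
            "trial": trial,
            "strike": i + 1,
            "start": s.start_idx,
            "end": s.end_idx,
            "apex_height": s.apex_height,
            "flake_produced": s.flake_produced,
            "flake_mass_g": s.flake_mass_g,
        }
        for i, s in enumerate(segments)
    ]
    return pd.DataFrame(rows)
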
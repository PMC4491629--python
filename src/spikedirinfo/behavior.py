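"""Rotational asymmetry from tracked movement.

A unilateral dopamine lesion biases locomotion toward the lesioned
(ipsilateral) side. Heading samples are unwrapped along the shortest angular
path; positive (clockwise in overhead-camera image coordinates, i.e.
rightward) increments integrate into theta_R and negative ones into theta_L.
Ipsilateral rotation preference is 100% x theta_R / (theta_L + theta_R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_io import BehaviorTrack

#: samples separated by more than this gap are not connected when unwrapping
MAX_GAP_S = 0.5


@dataclass(frozen=True)
class RotationSummary:
    """Total degrees turned right/left and the resulting preference."""

    theta_R: float
    theta_L: float

    @property
    def preference_pct(self) -> float:
        return ipsilateral_preference(self)


def integrate_rotations(track: BehaviorTrack) -> RotationSummary:
    """Integrate total degrees rotated right (theta_R) and left (theta_L).

    Single-step heading jumps larger than 180 degrees are interpreted via
    the shortest angular path; steps across time gaps longer than
    ``MAX_GAP_S`` are skipped rather than interpolated.
    """
    if track.t.size < 2:
        raise ValueError("need at least 2 behavior samples")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("behavior sample times must be strictly increasing")
    dh = np.diff(track.heading)
    dh = (dh + 180.0) % 360.0 - 180.0  # shortest angular path
    dh = dh[dt <= MAX_GAP_S]
    theta_R = float(dh[dh > 0].sum())
    theta_L = float(-dh[dh < 0].sum())
    return RotationSummary(theta_R=theta_R, theta_L=theta_L)


def ipsilateral_preference(summary: RotationSummary) -> float:
    """100% x theta_R / (theta_L + theta_R); errors if the rat never turned."""
    total = summary.theta_L + summary.theta_R
    if total <= 0:
        raise ValueError("no rotation recorded; preference undefined")
    return 100.0 * summary.theta_R / total


def classify_amphetamine(ipsi_rpm: float, contra_rpm: float) -> str:
    """Classify an amphetamine-rotation session from rotations per minute.

    At least 10 more ipsilateral than contralateral rotations/min indicates
    the hemiparkinsonian state ('hPD'); at most 6 more indicates stimulation-
    alleviated symptoms ('alleviated'); the gap between is 'indeterminate'.
    """
    if ipsi_rpm < 0 or contra_rpm < 0:
        raise ValueError("rotation rates must be non-negative")
    d = ipsi_rpm - contra_rpm
    if d >= 10:
        return "hPD"
    if d <= 6:
        return "alleviated"
    return "indeterminate"
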
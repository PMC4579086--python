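"""In-memory containers for multi-electrode recording sessions.

A :class:`RecordingSession` holds trial-resolved band-limited field signals
(LFP) and nonnegative firing-rate envelopes (MUA) for a small grid of
electrodes, together with the grid geometry, sampling rate and the
piecewise-constant stimulus "scene" labels used for sensory-information
analyses.  Synthetic sessions additionally carry a :class:`GroundTruth`
describing the planted coupling graph and wave kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RecordingSession", "GroundTruth", "CouplingEdge"]


@dataclass(frozen=True)
class CouplingEdge:
    """A directed phase->rate coupling from one electrode to another.

    Parameters
    ----------
    sender, receiver:
        Electrode indices (flat, row-major over the grid).
    gain:
        Nonnegative coupling gain (dimensionless drive amplitude).
    lag_ms:
        Conduction delay from sender phase to receiver rate, in ms (>= one
        sample).
    preferred_phase:
        Phase (radians) of the sender oscillation that maximally drives the
        receiver.
    """

    sender: int
    receiver: int
    gain: float
    lag_ms: float = 10.0
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("coupling gain must be >= 0")
        if self.sender == self.receiver:
            raise ValueError("self-edges are not allowed")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session."""

    coupling_edges: list[CouplingEdge]
    wave_vector: np.ndarray          # (n_time, 2), rad/mm, piecewise constant
    scene_direction: np.ndarray      # (n_scenes, 2) unit (or zero) vectors
    speed_m_per_s: float
    seed: int


@dataclass
class RecordingSession:
    """Trial x electrode x time arrays plus geometry and stimulus structure.

    Attributes
    ----------
    lfp:
        Band-limited field signal, shape (n_trials, n_electrodes, n_time).
    rate:
        Nonnegative firing-rate envelope, same shape as ``lfp``.
    positions_mm:
        Electrode coordinates in mm, shape (n_electrodes, 2).
    fs_hz:
        Sampling rate in Hz.
    scene_labels:
        Integer scene id per sample, shape (n_time,).
    provenance:
        Free-form metadata (config dict, seed, package version).
    ground_truth:
        Present only for synthetic sessions.
    """

    lfp: np.ndarray
    rate: np.ndarray
    positions_mm: np.ndarray
    fs_hz: float
    scene_labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.scene_labels = np.asarray(self.scene_labels)
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be (n_trials, n_electrodes, n_time)")
        if self.lfp.shape != self.rate.shape:
            raise ValueError("lfp and rate shapes differ")
        if self.positions_mm.shape != (self.lfp.shape[1], 2):
            raise ValueError("positions_mm must be (n_electrodes, 2)")
        if len(np.unique(self.positions_mm, axis=0)) != len(self.positions_mm):
            raise ValueError("electrode positions must be unique")
        if self.scene_labels.shape != (self.lfp.shape[2],):
            raise ValueError("scene_labels must cover every sample")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_time(self) -> int:
        return self.lfp.shape[2]

    @property
    def n_scenes(self) -> int:
        return int(self.scene_labels.max()) + 1
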
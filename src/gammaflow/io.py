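"""Session container I/O (HDF5, with NPZ accepted for small fixtures).

Layout of the HDF5 container (schema "gammaflow-session", version 1):
datasets ``lfp``, ``rate`` (trial x electrode x time), ``positions_mm``,
``scene_labels``; root attributes ``fs_hz``, ``schema``, ``schema_version``
and a JSON ``provenance`` string.  Synthetic ground truth, when present,
lives under a ``ground_truth`` group.  Phases are stored in radians,
positions in mm, times in ms.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .session import CouplingEdge, GroundTruth, RecordingSession

__all__ = ["write_session", "read_session", "SessionFormatError"]

SCHEMA = "gammaflow-session"
SCHEMA_VERSION = 1


class SessionFormatError(RuntimeError):
    """The file is not a readable session container of a known version."""


def _edges_array(edges: list[CouplingEdge]) -> np.ndarray:
    return np.array([[e.sender, e.receiver, e.gain, e.lag_ms,
                      e.preferred_phase] for e in edges], dtype=float
                    ).reshape(-1, 5)


def _edges_from_array(arr: np.ndarray) -> list[CouplingEdge]:
    return [CouplingEdge(sender=int(r[0]), receiver=int(r[1]), gain=r[2],
                         lag_ms=r[3], preferred_phase=r[4]) for r in arr]


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session container; lossless including provenance."""
    path = Path(path)
    if path.suffix == ".npz":
        _write_npz(session, path)
        return
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs_hz"] = float(session.fs_hz)
        f.attrs["provenance"] = json.dumps(session.provenance)
        f.create_dataset("lfp", data=session.lfp)
        f.create_dataset("rate", data=session.rate)
        f.create_dataset("positions_mm", data=session.positions_mm)
        f.create_dataset("scene_labels", data=session.scene_labels)
        gt = session.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            g.attrs["speed_m_per_s"] = gt.speed_m_per_s
            g.attrs["seed"] = gt.seed
            g.create_dataset("wave_vector", data=gt.wave_vector)
            g.create_dataset("scene_direction", data=gt.scene_direction)
            g.create_dataset("coupling_edges",
                             data=_edges_array(gt.coupling_edges))


def read_session(path: str | Path) -> RecordingSession:
    """Read a session container; schema mismatch raises, never crashes."""
    path = Path(path)
    if path.suffix == ".npz":
        return _read_npz(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as err:
        raise SessionFormatError(f"{path} is not a readable HDF5 "
                                 f"session container: {err}") from err
    with f:
        if f.attrs.get("schema") != SCHEMA:
            raise SessionFormatError(f"{path}: not a {SCHEMA} container")
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SessionFormatError(
                f"{path}: schema version {version} unsupported "
                f"(expected {SCHEMA_VERSION})")
        try:
            gt = None
            if "ground_truth" in f:
                g = f["ground_truth"]
                gt = GroundTruth(
                    coupling_edges=_edges_from_array(g["coupling_edges"][()]),
                    wave_vector=g["wave_vector"][()],
                    scene_direction=g["scene_direction"][()],
                    speed_m_per_s=float(g.attrs["speed_m_per_s"]),
                    seed=int(g.attrs["seed"]))
            return RecordingSession(
                lfp=f["lfp"][()], rate=f["rate"][()],
                positions_mm=f["positions_mm"][()], fs_hz=float(f.attrs["fs_hz"]),
                scene_labels=f["scene_labels"][()],
                provenance=json.loads(f.attrs.get("provenance", "{}")),
                ground_truth=gt)
        except KeyError as err:
            raise SessionFormatError(f"{path}: missing dataset "
                                     f"{err}") from err


def _write_npz(session: RecordingSession, path: Path) -> None:
    np.savez(path, lfp=session.lfp, rate=session.rate,
             positions_mm=session.positions_mm,
             scene_labels=session.scene_labels,
             fs_hz=np.array(session.fs_hz),
             provenance=np.array(json.dumps(session.provenance)),
             schema=np.array(SCHEMA),
             schema_version=np.array(SCHEMA_VERSION))


def _read_npz(path: Path) -> RecordingSession:
    try:
        with np.load(path, allow_pickle=False) as z:
            if str(z["schema"]) != SCHEMA:
                raise SessionFormatError(f"{path}: not a {SCHEMA} container")
            return RecordingSession(
                lfp=z["lfp"], rate=z["rate"],
                positions_mm=z["positions_mm"], fs_hz=float(z["fs_hz"]),
                scene_labels=z["scene_labels"],
                provenance=json.loads(str(z["provenance"])))
    except (OSError, ValueError, KeyError) as err:
        if isinstance(err, SessionFormatError):
            raise
        raise SessionFormatError(f"{path}: unreadable NPZ session: "
                                 f"{err}") from err
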
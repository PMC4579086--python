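"""Seeded synthetic multi-electrode sessions with planted travelling waves.

The generator emulates the statistical structure the downstream estimators
are designed to detect, with known ground truth:

* a narrow-band carrier (default 65 Hz, the centre of the 50-80 Hz gamma
  band) propagating as a plane wave across a small electrode grid with a
  controllable direction schedule, speed and phase noise;
* nonnegative firing-rate envelopes driven by the lagged phase of designated
  "sending" electrodes (cosine phase tuning), a scene-locked stimulus drive
  shared across trials, and linear self-history;
* piecewise-constant stimulus "scenes" (default 300 ms) that can gate both
  the wave direction and the coupling gains;
* repeated trials with independent per-trial global phase offsets, so the
  absolute phase at any single electrode is not stimulus-locked while phase
  *differences* between electrodes are.

All randomness flows from a single seed, split into independent per-component
streams, so e.g. raising the rate noise does not perturb the wave field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .session import CouplingEdge, GroundTruth, RecordingSession

__all__ = [
    "SyntheticConfig",
    "generate_wave_field",
    "generate_lfp",
    "generate_mua",
    "generate_session",
    "grid_positions",
]


class ConfigError(ValueError):
    """Invalid synthetic-session configuration."""


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic session.

    Geometry defaults follow the recording layout the analysis targets
    (4x4 grid, 2 mm spacing); the carrier sits at the gamma-band centre and
    the planted propagation speed at 0.36 m/s, in the range of horizontal
    axonal conduction.
    """

    n_rows: int = 4
    n_cols: int = 4
    spacing_mm: float = 2.0
    fs_hz: float = 1000.0
    f0_hz: float = 65.0
    speed_m_per_s: float = 0.36
    #: None -> independent random unit vector per scene; a float -> constant
    #: propagation angle (radians); a sequence of floats -> per-scene angles,
    #: cycled; an (n, 2) array -> per-scene wave vectors (zero vector =
    #: global synchrony), cycled.
    direction_schedule: Any = None
    phase_noise_sd: float = 0.3
    #: timescale of the per-electrode phase jitter; long enough that the
    #: jittered carrier stays inside the analysis band.
    phase_noise_smooth_ms: float = 20.0
    coupling_edges: tuple[CouplingEdge, ...] = ()
    gate_by_direction: bool = False
    #: floor of the direction gate: gain multiplier is
    #: max(gate_floor, positive part of k_hat . u_hat).
    gate_floor: float = 0.0
    scene_len_ms: float = 300.0
    n_trials: int = 40
    n_scenes: int = 60
    #: when set, each trial gets a random global phase offset plus a slow
    #: within-trial global phase wander, so absolute phase is not
    #: stimulus-locked.  A constant offset alone leaves the across-trial
    #: phase constellation a single rigidly rotating pattern — a degenerate
    #: geometry ongoing gamma (finite phase memory) does not have.
    trial_phase_offset: bool = True
    trial_phase_wander_sd: float = 1.5
    trial_phase_wander_ms: float = 500.0
    lfp_amplitude: float = 1.0
    lfp_noise_sd: float = 0.2
    rate_baseline: float = 0.0
    rate_self: float = 0.2
    stim_gain: float = 0.5
    rate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ConfigError("spacing_mm must be > 0")
        if self.fs_hz <= 2 * self.f0_hz:
            raise ConfigError("fs_hz must exceed 2 * f0_hz")
        if self.speed_m_per_s <= 0:
            raise ConfigError("speed_m_per_s must be > 0")
        if not (0 <= self.rate_self < 1):
            raise ConfigError("rate_self must be in [0, 1)")
        n = self.scene_len_ms * self.fs_hz / 1000.0
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ConfigError("scene_len_ms must be a positive multiple of "
                              "the sample interval")
        for e in self.coupling_edges:
            if e.gain < 0:
                raise ConfigError("coupling gains must be >= 0")
            if e.lag_ms * self.fs_hz / 1000.0 < 1:
                raise ConfigError("coupling lag must be >= 1 sample")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def scene_samples(self) -> int:
        return int(round(self.scene_len_ms * self.fs_hz / 1000.0))

    @property
    def n_time(self) -> int:
        return self.n_scenes * self.scene_samples

    def with_edges(self, edges: Sequence[CouplingEdge]) -> "SyntheticConfig":
        return replace(self, coupling_edges=tuple(edges))


def grid_positions(config: SyntheticConfig) -> np.ndarray:
    """Electrode coordinates in mm, flat row-major order, shape (E, 2)."""
    cols, rows = np.meshgrid(np.arange(config.n_cols), np.arange(config.n_rows))
    return np.column_stack([cols.ravel(), rows.ravel()]) * config.spacing_mm


def _realize_schedule(config: SyntheticConfig, rng: Generator) -> np.ndarray:
    """Per-scene wave direction vectors, shape (n_scenes, 2).

    Entries are unit vectors, or the zero vector for global synchrony.
    """
    sched = config.direction_schedule
    if sched is None:
        ang = rng.uniform(-np.pi, np.pi, size=config.n_scenes)
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if np.isscalar(sched):
        ang = float(sched)
        v = np.array([np.cos(ang), np.sin(ang)])
        return np.tile(v, (config.n_scenes, 1))
    arr = np.asarray(sched, dtype=float)
    if arr.ndim == 1:                      # angles, cycled over scenes
        idx = np.arange(config.n_scenes) % len(arr)
        ang = arr[idx]
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if arr.ndim == 2 and arr.shape[1] == 2:
        norms = np.linalg.norm(arr, axis=1)
        out = np.zeros_like(arr)
        nz = norms > 0
        out[nz] = arr[nz] / norms[nz, None]
        idx = np.arange(config.n_scenes) % len(arr)
        return out[idx]
    raise ConfigError("direction_schedule must be None, an angle, a sequence "
                      "of angles, or an (n, 2) array of vectors")


def _wave_vector_per_sample(config: SyntheticConfig,
                            directions: np.ndarray) -> np.ndarray:
    """Wave vector k(t) in rad/mm, shape (n_time, 2), scene-wise constant."""
    k_mag = 2 * np.pi * config.f0_hz / (1000.0 * config.speed_m_per_s)
    per_scene = k_mag * directions
    return np.repeat(per_scene, config.scene_samples, axis=0)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2 * np.pi)


def _phase_field(config: SyntheticConfig, directions: np.ndarray,
                 rng: Generator) -> tuple[np.ndarray, np.ndarray]:
    """Planted phase (trials, electrodes, time) and k(t) (time, 2)."""
    pos = grid_positions(config)                       # (E, 2)
    t = np.arange(config.n_time) / config.fs_hz
    k_t = _wave_vector_per_sample(config, directions)  # (T, 2)
    carrier = 2 * np.pi * config.f0_hz * t             # (T,)
    spatial = pos @ k_t.T                               # (E, T)
    phi = carrier[None, None, :] - spatial[None, :, :]
    phi = np.broadcast_to(phi, (config.n_trials,) + phi.shape[1:]).copy()
    if config.phase_noise_sd > 0:
        # smooth so the jitter stays narrow-band, rescale to target sd
        noise = rng.standard_normal(phi.shape)
        sigma = max(1.0, config.phase_noise_smooth_ms / 1000.0 * config.fs_hz)
        noise = gaussian_filter1d(noise, sigma, axis=-1)
        sd = noise.std()
        if sd > 0:
            noise *= config.phase_noise_sd / sd
        phi += noise
    if config.trial_phase_offset:
        phi += rng.uniform(-np.pi, np.pi, size=(config.n_trials, 1, 1))
        if config.trial_phase_wander_sd > 0:
            wander = rng.standard_normal((config.n_trials, 1, config.n_time))
            sigma = max(1.0, config.trial_phase_wander_ms / 1000.0
                        * config.fs_hz)
            wander = gaussian_filter1d(wander, sigma, axis=-1)
            sd = wander.std()
            if sd > 0:
                wander *= config.trial_phase_wander_sd / sd
            phi += wander       # global within trial: shared by electrodes
    return wrap_phase(phi), k_t


def generate_wave_field(config: SyntheticConfig, *, seed: int | None = None,
                        return_wave_vector: bool = False):
    """Planted travelling-wave phase field.

    phi_e(t) = 2*pi*f0*t - k(t).x_e + noise (+ per-trial offset), wrapped to
    (-pi, pi], with |k| = 2*pi*f0 / v.

    Returns the phase array (n_trials, n_electrodes, n_time); with
    ``return_wave_vector=True`` also the per-sample wave vector (rad/mm).
    """
    ss = SeedSequence(config.seed if seed is None else seed)
    s_dir, s_phase = ss.spawn(5)[:2]
    directions = _realize_schedule(config, default_rng(s_dir))
    phi, k_t = _phase_field(config, directions, default_rng(s_phase))
    return (phi, k_t) if return_wave_vector else phi


def generate_lfp(phase_field: np.ndarray, config: SyntheticConfig,
                 rng: Generator | None = None) -> np.ndarray:
    """Band signal A*cos(phi) plus broadband Gaussian noise."""
    rng = default_rng(config.seed) if rng is None else rng
    sig = config.lfp_amplitude * np.cos(phase_field)
    if config.lfp_noise_sd > 0:
        sig = sig + config.lfp_noise_sd * rng.standard_normal(sig.shape)
    return sig


def _gate_multiplier(config: SyntheticConfig, k_t: np.ndarray,
                     edge: CouplingEdge, pos: np.ndarray) -> np.ndarray:
    """Time-varying gain multiplier for one edge (1-D over time)."""
    if not config.gate_by_direction:
        return np.ones(k_t.shape[0])
    u = pos[edge.receiver] - pos[edge.sender]
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ConfigError("coincident sender/receiver positions")
    u = u / nu
    k_norm = np.linalg.norm(k_t, axis=1)
    k_hat = np.divide(k_t, k_norm[:, None], out=np.zeros_like(k_t),
                      where=k_norm[:, None] > 0)
    return np.maximum(config.gate_floor, np.maximum(0.0, k_hat @ u))


def _scene_stimulus(config: SyntheticConfig, rng: Generator) -> np.ndarray:
    """Scene-locked stimulus drive per electrode, shape (E, n_time).

    Identical across trials: this is the common-stimulus confound the
    bootstrap null is built to remove.
    """
    per_scene = rng.standard_normal((config.n_electrodes, config.n_scenes))
    return np.repeat(per_scene, config.scene_samples, axis=1)


def generate_mua(phase_field: np.ndarray, config: SyntheticConfig,
                 k_t: np.ndarray | None = None,
                 stimulus: np.ndarray | None = None,
                 rng: Generator | None = None) -> np.ndarray:
    """Nonnegative rate envelopes driven by lagged sender phase.

    rate_j(t) = softplus(b + sum_i g_ij(t) cos(phi_i(t - lag) - psi_ij)
                         + c * s_j(t)) + a * rate_j(t-1) + noise, clipped
    at zero.  When ``gate_by_direction`` is set the gain is scaled by the
    positive part of the alignment between the instantaneous wave direction
    and the sender->receiver axis (floored at ``gate_floor``).
    """
    rng = default_rng(config.seed) if rng is None else rng
    n_trials, n_elec, n_time = phase_field.shape
    pos = grid_positions(config)
    if k_t is None:
        k_t = np.zeros((n_time, 2))
    drive = np.full((n_trials, n_elec, n_time), config.rate_baseline)
    if stimulus is not None:
        drive += config.stim_gain * stimulus[None, :, :]
    for edge in config.coupling_edges:
        lag = int(round(edge.lag_ms * config.fs_hz / 1000.0))
        gmul = edge.gain * _gate_multiplier(config, k_t, edge, pos)
        contrib = np.zeros((n_trials, n_time))
        contrib[:, lag:] = np.cos(
            phase_field[:, edge.sender, :n_time - lag] - edge.preferred_phase)
        drive[:, edge.receiver, :] += gmul[None, :] * contrib
    inst = _softplus(drive)
    if config.rate_noise_sd > 0:
        inst = inst + config.rate_noise_sd * rng.standard_normal(inst.shape)
    a = config.rate_self
    # linear AR(1) self-history, initialised at the noise-free fixed point
    zi = (a * inst[..., :1] / (1 - a))
    rate, _ = lfilter([1.0], [1.0, -a], inst, axis=-1, zi=zi)
    return np.maximum(rate, 0.0)


def generate_session(config: SyntheticConfig,
                     seed: int | None = None) -> tuple[RecordingSession,
                                                       GroundTruth]:
    """Assemble a full synthetic session with its ground truth.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    seed = int(config.seed if seed is None else seed)
    ss = SeedSequence(seed)
    s_dir, s_phase, s_lfp, s_mua, s_stim = ss.spawn(5)
    directions = _realize_schedule(config, default_rng(s_dir))
    phi, k_t = _phase_field(config, directions, default_rng(s_phase))
    lfp = generate_lfp(phi, config, default_rng(s_lfp))
    stim = _scene_stimulus(config, default_rng(s_stim))
    rate = generate_mua(phi, config, k_t, stim, default_rng(s_mua))
    scene_labels = np.repeat(np.arange(config.n_scenes), config.scene_samples)
    truth = GroundTruth(
        coupling_edges=list(config.coupling_edges),
        wave_vector=k_t,
        scene_direction=directions,
        speed_m_per_s=config.speed_m_per_s,
        seed=seed,
    )
    session = RecordingSession(
        lfp=lfp,
        rate=rate,
        positions_mm=grid_positions(config),
        fs_hz=config.fs_hz,
        scene_labels=scene_labels,
        provenance={"generator": "gammaflow.synth", "seed": seed,
                    "config": _config_dict(config)},
        ground_truth=truth,
    )
    return session, truth


def _config_dict(config: SyntheticConfig) -> dict:
    d = {}
    for name in config.__dataclass_fields__:
        v = getattr(config, name)
        if name == "coupling_edges":
            v = [[e.sender, e.receiver, e.gain, e.lag_ms, e.preferred_phase]
                 for e in v]
        elif name == "direction_schedule" and v is not None:
            v = np.asarray(v, dtype=float).tolist()
        d[name] = v
    return d
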
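"""Receptive-field estimation by reverse correlation and movie features.

The receptive field (RF) of each electrode is mapped by correlating its
gamma-band power with the luminance of each (smoothed, down-sampled) movie
pixel at a fixed neural lag.  From the RF, per-frame stimulus features are
extracted: local time contrast (TC, frame-to-frame luminance change), the
orientation activation (OA, cos^2 match between the local gradient
orientation and the channel's preferred orientation), orientation tuning
curves, and the directed motion of the optic flow along a sender->receiver
RF axis.  Optic flow fields are consumed as inputs, never computed here.

Orientation convention: the orientation of local structure is the direction
of spatial luminance change (the image gradient) modulo 180 degrees; a
grating whose wave vector points at angle theta therefore has orientation
theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.stats import pearsonr, wilcoxon

__all__ = [
    "ReceptiveField",
    "FeatureSeries",
    "TuningCurve",
    "reverse_correlation_map",
    "rf_from_map",
    "time_contrast",
    "orientation_activation",
    "orientation_tuning",
    "tuning_similarity",
    "directed_motion",
    "feature_signal_correlation",
    "group_signed_rank",
    "rigid_translation_flow",
]


# ---------------------------------------------------------------------------
# reverse correlation


def _preprocess_movie(movie: np.ndarray, smooth_px: int,
                      downsample: int) -> np.ndarray:
    """Spatially smooth each frame and down-sample; returns (T, h, w)."""
    m = np.asarray(movie, dtype=float)
    if m.ndim != 3:
        raise ValueError("movie must be (n_frames, height, width)")
    if smooth_px > 1:
        m = uniform_filter(m, size=(1, smooth_px, smooth_px))
    if downsample > 1:
        m = m[:, ::downsample, ::downsample]
    return m


def _remove_svd_components(lum: np.ndarray, n_remove: int) -> np.ndarray:
    """Remove the largest spatiotemporal SVD components of (T, P) luminance.

    Counteracts the broad spatial correlations of natural stimuli that blur
    reverse-correlation maps.
    """
    if n_remove <= 0:
        return lum
    mean = lum.mean(axis=0, keepdims=True)
    centred = lum - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_remove, s.size)
    return centred - (u[:, :k] * s[:k]) @ vt[:k] + mean


def reverse_correlation_map(power: np.ndarray, movie: np.ndarray,
                            fs_hz: float, frame_rate_hz: float = 30.0,
                            lag_ms: float = 60.0,
                            analysis_hz: float = 66.0,
                            smooth_px: int = 6, downsample: int = 4,
                            n_svd_remove: int = 0) -> np.ndarray:
    """Z-scored reverse-correlation map between luminance and gamma power.

    ``power`` is (n_trials, n_time) at ``fs_hz``; ``movie`` is
    (n_frames, H, W) at ``frame_rate_hz``.  Both are read out on a common
    ``analysis_hz`` grid with the neural signal lagged by ``lag_ms``.  Per
    trial, the temporal Pearson correlation with each pixel is computed and
    Z-scored across pixels; maps are then averaged over trials.
    """
    p = np.atleast_2d(np.asarray(power, dtype=float))
    frames = _preprocess_movie(movie, smooth_px, downsample)
    n_frames, h, w = frames.shape
    lum = _remove_svd_components(frames.reshape(n_frames, -1), n_svd_remove)
    duration = n_frames / frame_rate_hz
    t_grid = np.arange(0.0, duration, 1.0 / analysis_hz)
    f_idx = np.minimum((t_grid * frame_rate_hz).astype(int), n_frames - 1)
    n_idx = np.round((t_grid + lag_ms / 1000.0) * fs_hz).astype(int)
    keep = n_idx < p.shape[1]
    if keep.sum() < 10:
        raise ValueError("power series too short for the movie and lag")
    f_idx, n_idx = f_idx[keep], n_idx[keep]
    lum_a = lum[f_idx]                               # (K, P)
    lum_c = lum_a - lum_a.mean(axis=0)
    lum_norm = np.linalg.norm(lum_c, axis=0)
    maps = np.zeros((p.shape[0], lum.shape[1]))
    for tr in range(p.shape[0]):
        pw = p[tr, n_idx]
        pw_c = pw - pw.mean()
        denom = lum_norm * np.linalg.norm(pw_c)
        corr = np.divide(lum_c.T @ pw_c, denom,
                         out=np.zeros(lum.shape[1]), where=denom > 0)
        sd = corr.std()
        maps[tr] = (corr - corr.mean()) / sd if sd > 0 else 0.0
    return maps.mean(axis=0).reshape(h, w)


@dataclass
class ReceptiveField:
    """Square RF derived from a reverse-correlation map.

    The centre is the map argmax; the extent is the smallest square whose
    border falls entirely below ``threshold_frac`` of the map maximum.
    """

    map: np.ndarray
    center: tuple[int, int] | None
    half_width: int
    deg_per_px: float = 1.0
    defined: bool = True

    @property
    def slice(self) -> tuple[slice, slice]:
        if self.center is None:
            raise ValueError("undefined RF has no extent")
        r, c = self.center
        h = self.half_width
        return (slice(max(0, r - h), r + h + 1),
                slice(max(0, c - h), c + h + 1))

    @property
    def extent_deg(self) -> float:
        return (2 * self.half_width + 1) * self.deg_per_px


def rf_from_map(corr_map: np.ndarray, threshold_frac: float = 0.75,
                deg_per_px: float = 1.0) -> ReceptiveField:
    """Grow a square around the map maximum until the border drops below
    ``threshold_frac`` of the peak."""
    m = np.asarray(corr_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("map must be 2-D")
    if np.ptp(m) == 0:
        return ReceptiveField(map=m, center=None, half_width=0,
                              deg_per_px=deg_per_px, defined=False)
    r, c = np.unravel_index(int(np.argmax(m)), m.shape)
    peak = m[r, c]
    thresh = threshold_frac * peak
    h = 0
    while True:
        h += 1
        rows = np.arange(max(0, r - h), min(m.shape[0], r + h + 1))
        cols = np.arange(max(0, c - h), min(m.shape[1], c + h + 1))
        border = np.concatenate([
            m[rows[0], cols], m[rows[-1], cols],
            m[rows, cols[0]], m[rows, cols[-1]]])
        if np.all(border < thresh):
            break
        if rows[0] == 0 and cols[0] == 0 and rows[-1] == m.shape[0] - 1 \
                and cols[-1] == m.shape[1] - 1:
            # whole map covered without crossing the contour
            return ReceptiveField(map=m, center=(int(r), int(c)),
                                  half_width=int(h), deg_per_px=deg_per_px,
                                  defined=False)
    return ReceptiveField(map=m, center=(int(r), int(c)), half_width=int(h),
                          deg_per_px=deg_per_px)


# ---------------------------------------------------------------------------
# movie features


@dataclass
class FeatureSeries:
    """Per-frame stimulus features for an RF (or RF pair)."""

    frame_rate_hz: float
    tc: np.ndarray | None = None               # >= 0
    oa: np.ndarray | None = None               # in [0, 1], NaN = undefined
    directed_motion: np.ndarray | None = None  # >= 0
    flags: list[str] = field(default_factory=list)


def time_contrast(movie: np.ndarray, rf: ReceptiveField,
                  frame_rate_hz: float = 30.0) -> FeatureSeries:
    """Local time contrast: RMS frame-to-frame luminance change in the RF,
    normalised by the mean RF luminance.  TC of the first frame is 0."""
    m = np.asarray(movie, dtype=float)
    patch = m[(slice(None),) + rf.slice]
    diff = np.diff(patch, axis=0)
    rms = np.sqrt((diff ** 2).mean(axis=(1, 2)))
    tc = np.concatenate([[0.0], rms])
    mean_lum = patch.mean()
    flags = []
    if mean_lum > 0:
        tc = tc / mean_lum
    else:
        flags.append("unnormalised-zero-luminance")
    return FeatureSeries(frame_rate_hz=frame_rate_hz, tc=tc, flags=flags)


def _gradient_orientation(patch: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient orientation (mod pi) and magnitude of one frame."""
    gy, gx = np.gradient(patch)
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    return theta, np.hypot(gx, gy)


def orientation_activation(movie: np.ndarray, rf: ReceptiveField,
                           preferred_orientation: float,
                           frame_rate_hz: float = 30.0) -> FeatureSeries:
    """Gradient-magnitude-weighted mean of cos^2(theta - theta_pref) over the
    RF, per frame; in [0, 1], NaN where the patch has no gradient."""
    m = np.asarray(movie, dtype=float)
    patch = m[(slice(None),) + rf.slice]
    if patch.shape[1] < 2 or patch.shape[2] < 2:
        raise ValueError("RF must span at least 2x2 pixels")
    oa = np.full(patch.shape[0], np.nan)
    for t in range(patch.shape[0]):
        theta, mag = _gradient_orientation(patch[t])
        wsum = mag.sum()
        if wsum > 0:
            oa[t] = float((mag * np.cos(theta - preferred_orientation) ** 2)
                          .sum() / wsum)
    return FeatureSeries(frame_rate_hz=frame_rate_hz, oa=oa)


@dataclass
class TuningCurve:
    """Correlation of firing with per-orientation stimulus energy."""

    orientations_deg: np.ndarray     # bin centres on [0, 180)
    curve: np.ndarray
    preferred_deg: float


def orientation_tuning(mua: np.ndarray, movie: np.ndarray,
                       rf: ReceptiveField,
                       n_orientation_bins: int = 8) -> TuningCurve:
    """Correlate per-orientation gradient energy in the RF with MUA over
    frames.  ``mua`` must be aligned to the movie frames."""
    m = np.asarray(movie, dtype=float)
    rate = np.asarray(mua, dtype=float).ravel()
    if rate.size != m.shape[0]:
        raise ValueError("mua must be aligned with movie frames")
    if np.ptp(rate) == 0:
        raise ValueError("constant MUA has no tuning")
    patch = m[(slice(None),) + rf.slice]
    edges = np.linspace(0, np.pi, n_orientation_bins + 1)
    energy = np.zeros((m.shape[0], n_orientation_bins))
    for t in range(m.shape[0]):
        theta, mag = _gradient_orientation(patch[t])
        energy[t] = np.histogram(theta.ravel(), bins=edges,
                                 weights=(mag ** 2).ravel())[0]
    curve = np.zeros(n_orientation_bins)
    for b in range(n_orientation_bins):
        if np.ptp(energy[:, b]) > 0:
            curve[b] = pearsonr(energy[:, b], rate)[0]
    centers = np.rad2deg(0.5 * (edges[:-1] + edges[1:]))
    return TuningCurve(orientations_deg=centers, curve=curve,
                       preferred_deg=float(centers[int(np.argmax(curve))]))


def tuning_similarity(a: TuningCurve, b: TuningCurve) -> float:
    """Covariance between two orientation tuning curves."""
    return float(np.cov(a.curve, b.curve)[0, 1])


def directed_motion(flow: np.ndarray, center_send: np.ndarray,
                    center_recv: np.ndarray,
                    frame_rate_hz: float = 30.0) -> FeatureSeries:
    """Positive part of the sending-RF optic-flow vector projected onto the
    sender->receiver RF axis (visual-field coordinates)."""
    f = np.asarray(flow, dtype=float)
    if f.ndim != 2 or f.shape[1] != 2:
        raise ValueError("flow must be (n_frames, 2)")
    u = np.asarray(center_recv, dtype=float) - np.asarray(center_send,
                                                          dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("coincident RF centres define no axis")
    dm = np.maximum(0.0, f @ (u / norm))
    return FeatureSeries(frame_rate_hz=frame_rate_hz, directed_motion=dm)


# ---------------------------------------------------------------------------
# feature-to-signal correlation


def feature_signal_correlation(feature_send: np.ndarray,
                               feature_recv: np.ndarray | None,
                               target: np.ndarray,
                               combine: str = "send") -> float:
    """Pearson correlation across time between a (combined) RF feature and a
    target series (MUA or windowed phase shift).

    ``combine`` is one of ``send``, ``recv``, ``sum``, ``diff`` (sending
    minus receiving).
    """
    fs = np.asarray(feature_send, dtype=float).ravel()
    fr = None if feature_recv is None else \
        np.asarray(feature_recv, dtype=float).ravel()
    if combine == "send":
        feat = fs
    elif combine == "recv":
        if fr is None:
            raise ValueError("combine='recv' needs a receiving feature")
        feat = fr
    elif combine == "sum":
        feat = fs + fr
    elif combine == "diff":
        feat = fs - fr
    else:
        raise ValueError("combine must be send/recv/sum/diff")
    t = np.asarray(target, dtype=float).ravel()
    if feat.size != t.size:
        raise ValueError("feature and target must be aligned")
    ok = np.isfinite(feat) & np.isfinite(t)
    feat, t = feat[ok], t[ok]
    if np.ptp(feat) == 0 or np.ptp(t) == 0:
        raise ValueError("constant series have no correlation")
    return float(pearsonr(feat, t)[0])


def group_signed_rank(correlations: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test of per-pair correlations against zero."""
    c = np.asarray(correlations, dtype=float)
    stat, p = wilcoxon(c)
    return float(stat), float(p)


def rigid_translation_flow(n_frames: int,
                           velocity: np.ndarray) -> np.ndarray:
    """Toy optic-flow generator: a rigid whole-field translation per frame.

    ``velocity`` is a (2,) constant or an (n_frames, 2) per-frame vector in
    visual-field units per frame.
    """
    v = np.asarray(velocity, dtype=float)
    if v.ndim == 1:
        return np.tile(v, (n_frames, 1))
    if v.shape == (n_frames, 2):
        return v.copy()
    raise ValueError("velocity must be (2,) or (n_frames, 2)")
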
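"""Band-limited signal extraction and spectral/circular descriptive statistics.

Covers zero-phase band-pass filtering, analytic-signal phase/amplitude
(Hilbert), rectified high-frequency rate envelopes, multitaper spatial
coherence across electrode pairs, and sliding-window circular statistics
(circular mean and phase-locking value) of phase-difference series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.signal.windows import dpss

__all__ = [
    "AnalyticSeries",
    "CoherenceSpectrum",
    "bandpass",
    "analytic_signal",
    "mua_envelope",
    "spatial_coherence",
    "sliding_circular_stats",
    "settling_samples",
]


def settling_samples(fs_hz: float, lo_hz: float) -> int:
    """Filter settling length used to mask edge samples (~3 cycles of lo)."""
    return int(round(3.0 * fs_hz / lo_hz))


def bandpass(signal: np.ndarray, lo_hz: float, hi_hz: float, fs_hz: float,
             order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is applied forward-backward (SOS filtfilt), so in-band
    components keep their timing exactly.  ``order`` is the overall filter
    order (8 by default); it must be even since a band-pass doubles the
    prototype order.
    """
    signal = np.asarray(signal, dtype=float)
    if not (0 < lo_hz < hi_hz < fs_hz / 2):
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    if order % 2 or order < 2:
        raise ValueError("order must be a positive even integer")
    if signal.shape[-1] <= 3 * settling_samples(fs_hz, lo_hz):
        raise ValueError("signal too short for stable band-pass filtering")
    sos = butter(order // 2, [lo_hz, hi_hz], btype="bandpass", fs=fs_hz,
                 output="sos")
    return sosfiltfilt(sos, signal, axis=-1)


@dataclass
class AnalyticSeries:
    """Instantaneous phase and amplitude of a band-limited signal.

    ``phase`` is wrapped to (-pi, pi]; ``valid`` marks samples where the
    phase is defined (nonzero amplitude, outside masked filter edges).
    """

    phase: np.ndarray
    amplitude: np.ndarray
    valid: np.ndarray
    band: tuple[float, float] | None
    fs_hz: float


def analytic_signal(band_signal: np.ndarray, fs_hz: float,
                    band: tuple[float, float] | None = None,
                    edge_mask_samples: int = 0) -> AnalyticSeries:
    """Hilbert analytic extension along the last axis.

    For cos(2*pi*f*t) the unwrapped phase advances 2*pi*f/fs per sample and
    the amplitude is 1.  Samples with (numerically) zero amplitude carry an
    undefined phase and are flagged invalid, as are ``edge_mask_samples``
    samples at each end (filter settling).
    """
    x = np.asarray(band_signal, dtype=float)
    n = x.shape[-1]
    z = hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]
    amplitude = np.abs(z)
    phase = np.angle(z)
    tol = 1e-12 * max(1.0, float(amplitude.max(initial=0.0)))
    valid = amplitude > tol
    if edge_mask_samples > 0:
        valid[..., :edge_mask_samples] = False
        valid[..., n - edge_mask_samples:] = False
    return AnalyticSeries(phase=phase, amplitude=amplitude, valid=valid,
                          band=band, fs_hz=fs_hz)


def mua_envelope(wideband: np.ndarray, fs_hz: float,
                 cutoff_hz: float = 1000.0,
                 smooth_hz: float | None = 250.0) -> np.ndarray:
    """Firing-rate envelope: high-pass above ``cutoff_hz``, rectify, smooth.

    Only needed when raw wideband recordings are supplied; synthetic sessions
    carry rate envelopes directly.
    """
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff_hz must be below Nyquist")
    sos = butter(4, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    env = np.abs(sosfiltfilt(sos, np.asarray(wideband, dtype=float), axis=-1))
    if smooth_hz is not None:
        if smooth_hz >= fs_hz / 2:
            raise ValueError("smooth_hz must be below Nyquist")
        sos_lo = butter(4, smooth_hz, btype="lowpass", fs=fs_hz, output="sos")
        env = sosfiltfilt(sos_lo, env, axis=-1)
    return np.maximum(env, 0.0)


@dataclass
class CoherenceSpectrum:
    """Mean pairwise magnitude-squared coherence across an electrode array."""

    frequencies_hz: np.ndarray
    mean_coherence: np.ndarray     # in [0, 1]
    dispersion: np.ndarray         # SD across pairs
    pair_coherence: np.ndarray     # (n_pairs, n_freq)
    pairs: list[tuple[int, int]]


def spatial_coherence(signals: np.ndarray, fs_hz: float,
                      block_s: float = 1.0, n_tapers: int = 5,
                      time_bandwidth: float = 3.0) -> CoherenceSpectrum:
    """Multitaper coherence on nonoverlapping blocks, averaged across pairs.

    ``signals`` is (n_trials, n_electrodes, n_time); cross-spectra are
    accumulated over trials, blocks and Slepian tapers (defaults: 1 s blocks,
    NW=3, 5 tapers), then the magnitude-squared coherence is formed per
    electrode pair and averaged.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 3:
        raise ValueError("signals must be (n_trials, n_electrodes, n_time)")
    n_trials, n_elec, n_time = x.shape
    if n_elec < 2:
        raise ValueError("need at least 2 electrodes")
    block = int(round(block_s * fs_hz))
    if n_time < block:
        raise ValueError("need at least one full block of data")
    tapers = dpss(block, time_bandwidth, Kmax=n_tapers)       # (K, block)
    n_blocks = n_time // block
    n_freq = block // 2 + 1
    S = np.zeros((n_elec, n_elec, n_freq), dtype=complex)
    for tr in range(n_trials):
        for b in range(n_blocks):
            seg = x[tr, :, b * block:(b + 1) * block]          # (E, block)
            tap = tapers[:, None, :] * seg[None, :, :]         # (K, E, block)
            X = np.fft.rfft(tap, axis=-1)                      # (K, E, F)
            S += np.einsum("kef,kgf->egf", X, np.conj(X))
    S /= n_trials * n_blocks * n_tapers
    pairs = [(i, j) for i in range(n_elec) for j in range(i + 1, n_elec)]
    auto = np.real(np.einsum("eef->ef", S))
    coh = np.empty((len(pairs), n_freq))
    for p, (i, j) in enumerate(pairs):
        denom = auto[i] * auto[j]
        coh[p] = np.divide(np.abs(S[i, j]) ** 2, denom,
                           out=np.zeros(n_freq), where=denom > 0)
    freqs = np.fft.rfftfreq(block, d=1.0 / fs_hz)
    return CoherenceSpectrum(frequencies_hz=freqs,
                             mean_coherence=coh.mean(axis=0),
                             dispersion=coh.std(axis=0),
                             pair_coherence=coh, pairs=pairs)


def sliding_circular_stats(angles: np.ndarray, window_samples: int,
                           valid: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window circular mean and PLV along the last axis.

    The circular mean is the argument of the windowed mean resultant and the
    PLV its modulus (in [0, 1]; 1 iff all in-window angles coincide).
    Invalid samples are excluded from the window averages; windows with no
    valid sample yield NaN.
    """
    if window_samples < 3:
        raise ValueError("window must span at least 3 samples")
    a = np.asarray(angles, dtype=float)
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    w = valid.astype(float)
    zr = np.where(valid, np.cos(a), 0.0)
    zi = np.where(valid, np.sin(a), 0.0)
    kw = dict(size=window_samples, axis=-1, mode="constant", cval=0.0)
    sr = uniform_filter1d(zr, **kw)
    si = uniform_filter1d(zi, **kw)
    sw = uniform_filter1d(w, **kw)
    with np.errstate(invalid="ignore", divide="ignore"):
        mr = np.where(sw > 0, sr / sw, np.nan)
        mi = np.where(sw > 0, si / sw, np.nan)
        plv = np.minimum(np.hypot(mr, mi), 1.0)
        mean = np.arctan2(mi, mr)
    return mean, plv
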
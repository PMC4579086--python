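"""Bias-corrected discrete information estimators and their bootstrap nulls.

Implements the estimator family used throughout the analysis:

* equipopulated (rank-based) binning of continuous responses;
* plug-in Shannon entropy and mutual information with limited-sampling bias
  corrections (Panzeri-Treves residual-bias term by default, shuffle
  subtraction optionally);
* sensory information: mutual information between movie "scene" identity and
  a binned neural response;
* transfer entropy T(Y->X) = I(X_t; Y_past | X_past) and its variants that
  swap the conditioning variable (lagged conditional information, LCI, and
  localised LCI);
* a common-stimulus bootstrap null: the source series of trial m is paired
  with the target series of a different trial m' at identical movie time
  (random derangement across trials), which preserves stimulus-locked
  structure while destroying any within-trial interaction.  Estimates are
  Z-scored against this null.

All estimators operate on small discrete alphabets (default 3-4 bins per
variable) and are exact plug-in computations; they match exhaustive
enumeration on any joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

__all__ = [
    "DiscreteSeries",
    "EmbeddedTriplet",
    "InfoEstimate",
    "equipopulated_bin",
    "entropy",
    "mutual_information",
    "sensory_information",
    "embed_series",
    "transfer_entropy",
    "lagged_conditional_information",
    "bootstrap_null_zscore",
    "group_significance",
    "combine_symbols",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# binning and basic estimators


@dataclass
class DiscreteSeries:
    """Integer symbols obtained from equipopulated binning."""

    symbols: np.ndarray
    n_bins: int
    edges: np.ndarray | None = None


def equipopulated_bin(values: np.ndarray, n_bins: int) -> DiscreteSeries:
    """Rank-based quantile binning: occupancies differ by at most one.

    Ties are broken by stable rank, so the estimate is invariant under any
    monotone transform of the input.  A constant input admits no informative
    binning and raises.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    flat = v.ravel()
    if flat.size < n_bins:
        raise ValueError("fewer samples than bins")
    if np.ptp(flat) == 0:
        raise ValueError("constant input cannot be binned")
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(flat.size, dtype=np.int64)
    ranks[order] = np.arange(flat.size)
    symbols = (ranks * n_bins) // flat.size
    edges = np.quantile(flat, np.linspace(0, 1, n_bins + 1))
    return DiscreteSeries(symbols=symbols.reshape(v.shape).astype(np.int64),
                          n_bins=n_bins, edges=edges)


def entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy, in bits, from a nonnegative count table."""
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    n = c.sum()
    if n <= 0:
        raise ValueError("counts must sum to > 0")
    p = c[c > 0] / n
    return float(-(p * np.log2(p)).sum())


def _bayescount(counts: np.ndarray) -> float:
    """Estimated number of effectively occupied bins (Panzeri-Treves).

    Solves R_occ = R * (1 - (1 - 1/R)**N) for R, where R_occ is the observed
    number of occupied bins and N the number of samples; this is the
    standard ``bayescount`` construction behind the PT residual-bias term.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    r_occ = int((c > 0).sum())
    if r_occ <= 1 or r_occ >= n:
        return float(r_occ)

    def f(r: float) -> float:
        return r * (1.0 - (1.0 - 1.0 / r) ** n) - r_occ

    lo = float(r_occ)
    if f(lo) >= 0:
        return lo
    hi = lo
    for _ in range(60):
        hi *= 2.0
        if f(hi) > 0:
            return float(brentq(f, lo, hi, xtol=1e-6))
    return hi


def _cmi_plugin_bits(counts: np.ndarray) -> float:
    """Plug-in I(X;Y|C) in bits from a (C, X, Y) count array."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty count table")
    n_c = c.sum(axis=(1, 2))
    n_cx = c.sum(axis=2)
    n_cy = c.sum(axis=1)
    num = c * n_c[:, None, None]
    den = n_cx[:, :, None] * n_cy[:, None, :]
    mask = c > 0
    ratio = np.ones_like(c)
    ratio[mask] = num[mask] / den[mask]
    return float((c[mask] * np.log2(ratio[mask])).sum() / n)


def _cmi_pt_bias_bits(counts: np.ndarray) -> float:
    """PT residual bias of the plug-in I(X;Y|C), in bits."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    bias = 0.0
    for ci in range(c.shape[0]):
        sub = c[ci]                      # (X, Y)
        if sub.sum() == 0:
            continue
        r_cond = sum(_bayescount(sub[:, y]) - 1.0
                     for y in range(sub.shape[1]) if sub[:, y].sum() > 0)
        r_marg = _bayescount(sub.sum(axis=1)) - 1.0
        bias += r_cond - r_marg
    return bias / (2.0 * n * _LN2)


def _corrected_cmi_bits(counts: np.ndarray, correction: str,
                        shuffle_fn=None) -> float:
    plugin = _cmi_plugin_bits(counts)
    if correction == "none":
        return plugin
    if correction == "panzeri-treves":
        return plugin - _cmi_pt_bias_bits(counts)
    if correction == "shuffle-subtracted":
        if shuffle_fn is None:
            raise ValueError("shuffle correction needs a shuffle callback")
        return plugin - shuffle_fn()
    raise ValueError(f"unknown correction {correction!r}")


@dataclass
class InfoEstimate:
    """An information estimate in bits, optionally Z-scored against a null."""

    value: float
    n: int
    corrected: bool = True
    null_mean: float | None = None
    null_sd: float | None = None
    z: float | None = None
    flags: list[str] = field(default_factory=list)


def combine_symbols(parts: list[np.ndarray], alphabets: list[int]
                    ) -> tuple[np.ndarray, int]:
    """Product-alphabet symbols for joint responses."""
    out = np.zeros_like(np.asarray(parts[0]))
    total = 1
    for sym, a in zip(parts, alphabets):
        out = out * a + np.asarray(sym)
        total *= a
    return out, total


def mutual_information(response, stimulus: np.ndarray,
                       n_bins: int | None = None,
                       correction: str = "panzeri-treves",
                       n_shuffle: int = 20,
                       rng: Generator | None = None) -> InfoEstimate:
    """I(S;R) = H(R) - H(R|S) with limited-sampling bias correction.

    ``response`` is either a :class:`DiscreteSeries` (e.g. a product-alphabet
    joint response) or a continuous array to be equipopulated-binned into
    ``n_bins``.  ``stimulus`` holds integer class labels aligned with the
    response samples.
    """
    s = np.asarray(stimulus).ravel()
    classes, s_idx = np.unique(s, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two stimulus classes")
    if isinstance(response, DiscreteSeries):
        r_sym, r_alpha = response.symbols.ravel(), response.n_bins
    else:
        if n_bins is None:
            raise ValueError("n_bins required for continuous responses")
        ds = equipopulated_bin(response, n_bins)
        r_sym, r_alpha = ds.symbols.ravel(), n_bins
    if r_sym.size != s_idx.size:
        raise ValueError("response and stimulus are misaligned")
    counts = np.zeros((1, r_alpha, len(classes)))
    np.add.at(counts[0], (r_sym, s_idx), 1.0)

    def shuffle_mean() -> float:
        g = default_rng(0) if rng is None else rng
        vals = []
        for _ in range(n_shuffle):
            perm = g.permutation(r_sym.size)
            cs = np.zeros((1, r_alpha, len(classes)))
            np.add.at(cs[0], (r_sym[perm], s_idx), 1.0)
            vals.append(_cmi_plugin_bits(cs))
        return float(np.mean(vals))

    value = _corrected_cmi_bits(counts, correction, shuffle_mean)
    return InfoEstimate(value=value, n=r_sym.size,
                        corrected=correction != "none")


# ---------------------------------------------------------------------------
# sensory information over movie scenes


def _circular_smooth(a: np.ndarray, window: int) -> np.ndarray:
    kw = dict(size=window, axis=-1, mode="nearest")
    sr = uniform_filter1d(np.cos(a), **kw)
    si = uniform_filter1d(np.sin(a), **kw)
    return np.arctan2(si, sr)


def sensory_information(response: np.ndarray, fs_hz: float,
                        scene_len_ms: float = 300.0, n_bins: int = 4,
                        circular: bool = False, point_sample: bool = False,
                        smooth_ms: float = 300.0,
                        correction: str = "panzeri-treves",
                        n_boot: int = 40,
                        rng: Generator | None = None) -> InfoEstimate:
    """Information between scene identity and a per-trial, per-scene response.

    ``response`` is (n_trials, n_time).  Slow variables are smoothed over a
    ``smooth_ms`` sliding window (circular mean for circular variables) and
    read out at the centre of each scene; fast circular variables (individual
    phases) should instead be evaluated at a single point per scene with
    ``point_sample=True`` and a scene length of one oscillation period.

    Significance is assessed against a bootstrap null that circularly
    shifts each trial's scene sequence by a random (nonzero) number of
    scenes: within-trial temporal structure is preserved while the locking
    of responses to specific scenes is destroyed.
    """
    r = np.asarray(response, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("response must be (n_trials >= 2, n_time)")
    n_trials, n_time = r.shape
    scene_len = int(round(scene_len_ms * fs_hz / 1000.0))
    n_scenes = n_time // scene_len
    if n_scenes < 2:
        raise ValueError("need at least two scenes")
    centers = np.arange(n_scenes) * scene_len + scene_len // 2
    if point_sample:
        resp = r[:, centers]
    else:
        window = max(3, int(round(smooth_ms * fs_hz / 1000.0)))
        sm = _circular_smooth(r, window) if circular else \
            uniform_filter1d(r, size=window, axis=-1, mode="nearest")
        resp = sm[:, centers]
    if np.ptp(resp) == 0:
        return InfoEstimate(value=0.0, n=resp.size, corrected=False,
                            z=0.0, flags=["constant-response"])
    sym = equipopulated_bin(resp, n_bins).symbols       # (trials, scenes)
    labels = np.broadcast_to(np.arange(n_scenes), sym.shape)

    def mi_of(symbols: np.ndarray) -> float:
        counts = np.zeros((1, n_bins, n_scenes))
        np.add.at(counts[0], (symbols.ravel(), labels.ravel()), 1.0)
        return _corrected_cmi_bits(counts, correction)

    obs = mi_of(sym)
    g = default_rng(0) if rng is None else rng
    null = np.empty(n_boot)
    for b in range(n_boot):
        shuffled = np.empty_like(sym)
        for tr in range(n_trials):
            shuffled[tr] = np.roll(sym[tr], int(g.integers(1, n_scenes)))
        null[b] = mi_of(shuffled)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    est = InfoEstimate(value=obs, n=sym.size,
                       corrected=correction != "none",
                       null_mean=mu, null_sd=sd)
    if sd > 0:
        est.z = (obs - mu) / sd
    else:
        est.flags.append("zero-null-sd")
    return est


# ---------------------------------------------------------------------------
# embeddings, transfer entropy, LCI


@dataclass
class EmbeddedTriplet:
    """Aligned (present target, target past, source past) sample arrays.

    All arrays are (n_trials, n_points); pasts strictly precede the present
    sample and embeddings never cross trial boundaries.  ``z_past`` holds an
    alternative conditioning variable for the LCI variants.
    """

    x_t: np.ndarray
    x_past: np.ndarray
    y_past: np.ndarray
    z_past: np.ndarray | None
    lag_ms: float
    fs_hz: float


def embed_series(x: np.ndarray, y: np.ndarray, fs_hz: float,
                 lag_ms: float = 10.0, step_ms: float = 2.0,
                 z: np.ndarray | None = None,
                 time_mask: np.ndarray | None = None) -> EmbeddedTriplet:
    """Build dimension-1 past/present embeddings on a subsampled time grid.

    ``x`` (target) and ``y`` (source) are (n_trials, n_time).  A sample at
    time t is used only if the whole window [t - lag, t] lies inside
    ``time_mask`` (when given), so embeddings never straddle masked gaps.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y shapes differ")
    n_time = x.shape[1]
    lag = int(round(lag_ms * fs_hz / 1000.0))
    step = max(1, int(round(step_ms * fs_hz / 1000.0)))
    if lag < 1:
        raise ValueError("lag must be at least one sample")
    t_idx = np.arange(lag, n_time, step)
    if time_mask is not None:
        m = np.asarray(time_mask, dtype=bool)
        # t valid iff every sample in [t - lag, t] is unmasked
        csum = np.concatenate([[0], np.cumsum(m.astype(np.int64))])
        full = csum[t_idx + 1] - csum[t_idx - lag] == lag + 1
        t_idx = t_idx[full]
    if t_idx.size == 0:
        raise ValueError("no valid embedding points")
    trip = EmbeddedTriplet(
        x_t=x[:, t_idx], x_past=x[:, t_idx - lag], y_past=y[:, t_idx - lag],
        z_past=None, lag_ms=lag_ms, fs_hz=fs_hz)
    if z is not None:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        trip.z_past = z[:, t_idx - lag]
    return trip


def _binned_triplet(triplet: EmbeddedTriplet, n_bins: int,
                    conditioner: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (base index from conditioner and x_t, y symbols, alphabet)."""
    sx_t = equipopulated_bin(triplet.x_t, n_bins).symbols
    sy_p = equipopulated_bin(triplet.y_past, n_bins).symbols
    if conditioner == "x_past":
        cond = triplet.x_past
    elif conditioner == "z_past":
        if triplet.z_past is None:
            raise ValueError("triplet has no z_past conditioner")
        cond = triplet.z_past
    else:
        raise ValueError("conditioner must be 'x_past' or 'z_past'")
    sc = equipopulated_bin(cond, n_bins).symbols
    base = (sc * n_bins + sx_t) * n_bins
    return base, sy_p, n_bins


def _te_from_symbols(base: np.ndarray, sy: np.ndarray, n_bins: int,
                     correction: str, min_cell: int = 0
                     ) -> tuple[float, bool]:
    counts = np.bincount((base + sy).ravel(),
                         minlength=n_bins ** 3).astype(float)
    counts = counts.reshape(n_bins, n_bins, n_bins)
    low_conf = bool(min_cell > 0 and counts[counts > 0].min() < min_cell)
    return _corrected_cmi_bits(counts, correction), low_conf


def transfer_entropy(triplet: EmbeddedTriplet, n_bins: int = 3,
                     correction: str = "panzeri-treves",
                     min_cell: int = 0) -> InfoEstimate:
    """T(Y->X) = I(X_t; Y_past | X_past), bias-corrected plug-in estimate."""
    base, sy, nb = _binned_triplet(triplet, n_bins, "x_past")
    value, low_conf = _te_from_symbols(base, sy, nb, correction, min_cell)
    est = InfoEstimate(value=value, n=int(base.size),
                       corrected=correction != "none")
    if low_conf:
        est.flags.append("low-confidence")
    return est


def lagged_conditional_information(triplet: EmbeddedTriplet, n_bins: int = 3,
                                   correction: str = "panzeri-treves",
                                   min_cell: int = 0) -> InfoEstimate:
    """I(X_t; Y_past | Z_past): the TE estimator with a swapped conditioner.

    With the sender's past rate as Z this is the LCI; with the receiver's
    past phase it is the localised LCI.
    """
    base, sy, nb = _binned_triplet(triplet, n_bins, "z_past")
    value, low_conf = _te_from_symbols(base, sy, nb, correction, min_cell)
    est = InfoEstimate(value=value, n=int(base.size),
                       corrected=correction != "none")
    if low_conf:
        est.flags.append("low-confidence")
    return est


def group_significance(z_scores: np.ndarray,
                       q: float = 0.05) -> dict:
    """Which units (pairs) carry significantly positive information?

    ``z_scores`` is (n_units, n_replicates): bootstrap Z-scores per
    electrode pair across replicates (sessions, movies).  Each unit gets a
    one-sample t-test against zero; p-values are corrected by
    Benjamini-Hochberg FDR at rate ``q``.  Returns the rejection mask, the
    corrected p-values and the fraction of significant units.
    """
    from scipy.stats import ttest_1samp
    from statsmodels.stats.multitest import multipletests
    z = np.atleast_2d(np.asarray(z_scores, dtype=float))
    if z.shape[1] < 2:
        raise ValueError("need at least 2 replicates per unit")
    pvals = np.array([
        ttest_1samp(row, 0.0, alternative="greater").pvalue for row in z])
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return {"significant": reject, "p_adjusted": p_adj,
            "fraction_significant": float(reject.mean())}


def _derangement(n: int, rng: Generator) -> np.ndarray:
    """Random permutation of range(n) without fixed points."""
    if n < 2:
        raise ValueError("need at least 2 trials for a derangement")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def bootstrap_null_zscore(triplet: EmbeddedTriplet, n_bins: int = 3,
                          correction: str = "panzeri-treves",
                          conditioner: str = "x_past",
                          n_boot: int = 40,
                          rng: Generator | None = None,
                          min_cell: int = 0) -> InfoEstimate:
    """TE (or LCI) Z-scored against the common-stimulus bootstrap null.

    Each bootstrap pairs the source past of trial m with the target of a
    different trial m' at the same movie time (random derangement across
    trials): stimulus-locked structure survives, within-trial interaction
    does not.  Z = (TE_obs - mean_null) / SD_null.
    """
    if triplet.x_t.shape[0] < 2:
        raise ValueError("bootstrap null needs at least 2 trials")
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    g = default_rng(0) if rng is None else rng
    base, sy, nb = _binned_triplet(triplet, n_bins, conditioner)
    obs, low_conf = _te_from_symbols(base, sy, nb, correction, min_cell)
    null = np.empty(n_boot)
    for b in range(n_boot):
        perm = _derangement(base.shape[0], g)
        null[b], _ = _te_from_symbols(base, sy[perm], nb, correction)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    est = InfoEstimate(value=obs, n=int(base.size),
                       corrected=correction != "none",
                       null_mean=mu, null_sd=sd)
    if sd > 0:
        est.z = float((obs - mu) / sd)
    else:
        est.flags.append("zero-null-sd")
    if low_conf:
        est.flags.append("low-confidence")
    return est
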
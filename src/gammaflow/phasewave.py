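"""Phase shifts, pair-causality classification, block-conditioned transfer
entropy, and travelling-wave speed estimation.

Conventions
-----------
* The phase shift of an ordered (sender, receiver) pair is
  ``wrap(phi_send - phi_recv)``: positive shifts mean the sender's
  oscillation leads.
* The asymmetry index of a pair is |T_ab - T_ba| / max(T_ab, T_ba) on
  Z-scored transfer-entropy values clipped at zero; after excluding the 20%
  of pairs with the lowest TE, pairs with a >= 10-fold dominant direction are
  "strongly asymmetric" and pairs whose relative difference is below 20% are
  "symmetric".
* Wave speed comes from the spatial derivative of the phase at the origin of
  a (projected distance, phase shift) profile pooled over strongly
  asymmetric reference pairs: a cubic smoothing spline is fit and
  v = 2*pi*f / |slope at 0|, the origin being re-anchored so that it always
  marks the final target of the propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin
from numpy.random import Generator, default_rng
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.stats import spearmanr

from .infotheory import InfoEstimate, bootstrap_null_zscore, embed_series
from .synth import wrap_phase

__all__ = [
    "PhaseShiftSeries",
    "PairCausality",
    "BlockSegmentation",
    "WaveFit",
    "phase_shift",
    "circular_mean",
    "resultant_length",
    "rayleigh_test",
    "asymmetry_index",
    "classify_pairs",
    "correlate_shift_causation",
    "segment_blocks",
    "block_conditioned_te",
    "projected_distance",
    "pairwise_mean_shift",
    "collect_wave_profile",
    "wave_speed",
]


# ---------------------------------------------------------------------------
# circular statistics and phase shifts


def resultant_length(angles: np.ndarray,
                     valid: np.ndarray | None = None) -> float:
    a = np.asarray(angles, dtype=float).ravel()
    if valid is not None:
        a = a[np.asarray(valid, dtype=bool).ravel()]
    if a.size == 0:
        raise ValueError("no valid angles")
    return float(np.abs(np.exp(1j * a).mean()))


def circular_mean(angles: np.ndarray,
                  valid: np.ndarray | None = None) -> float:
    a = np.asarray(angles, dtype=float).ravel()
    if valid is not None:
        a = a[np.asarray(valid, dtype=bool).ravel()]
    if a.size == 0:
        raise ValueError("no valid angles")
    return float(np.angle(np.exp(1j * a).mean()))


@dataclass
class PhaseShiftSeries:
    """Wrapped phase-difference series for an ordered (sender, receiver) pair."""

    sender: int
    receiver: int
    shift: np.ndarray               # (n_trials, n_time), in (-pi, pi]
    valid: np.ndarray               # same shape
    fs_hz: float

    @property
    def mean_shift(self) -> float:
        """Movie-averaged circular mean over all valid trials and samples."""
        return circular_mean(self.shift, self.valid)

    @property
    def plv(self) -> float:
        return resultant_length(self.shift, self.valid)


def phase_shift(phi_send: np.ndarray, phi_recv: np.ndarray,
                fs_hz: float = 1.0,
                valid_send: np.ndarray | None = None,
                valid_recv: np.ndarray | None = None,
                sender: int = 0, receiver: int = 1) -> PhaseShiftSeries:
    """Wrapped per-sample difference phi_send - phi_recv (sender leads > 0)."""
    ps = np.atleast_2d(np.asarray(phi_send, dtype=float))
    pr = np.atleast_2d(np.asarray(phi_recv, dtype=float))
    if ps.shape != pr.shape:
        raise ValueError("phase arrays must be aligned")
    valid = np.ones(ps.shape, dtype=bool)
    if valid_send is not None:
        valid &= np.atleast_2d(np.asarray(valid_send, dtype=bool))
    if valid_recv is not None:
        valid &= np.atleast_2d(np.asarray(valid_recv, dtype=bool))
    return PhaseShiftSeries(sender=sender, receiver=receiver,
                            shift=wrap_phase(ps - pr), valid=valid,
                            fs_hz=fs_hz)


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity; returns (z, p)."""
    a = np.asarray(angles, dtype=float).ravel()
    if a.size < 10:
        raise ValueError("Rayleigh test needs at least 10 angles")
    z, p = pingouin.circ_rayleigh(wrap_phase(a))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# pair causality classification


def asymmetry_index(t_ab: float, t_ba: float) -> float:
    """|T_ab - T_ba| / max(T_ab, T_ba) on values clipped at zero, in [0, 1]."""
    a, b = max(float(t_ab), 0.0), max(float(t_ba), 0.0)
    m = max(a, b)
    if m <= 0:
        return float("nan")
    return abs(a - b) / m


@dataclass
class PairCausality:
    """Both-direction Z-scored TE and the causal category of a pair."""

    a: int
    b: int
    te_ab: float                    # Z-scored TE a -> b
    te_ba: float
    asymmetry: float
    category: str                   # strongly_asymmetric | symmetric | other
    #                               # | excluded_low_TE
    leading: tuple[int, int] | None


def classify_pairs(pair_table: pd.DataFrame,
                   low_te_fraction: float = 0.2,
                   asym_ratio: float = 10.0,
                   sym_rel_diff: float = 0.2,
                   value_col: str = "te_z") -> pd.DataFrame:
    """Label pairs as strongly asymmetric / symmetric / other.

    ``pair_table`` holds one row per *ordered* pair with columns
    ``sender``, ``receiver`` and ``value_col`` (the TE magnitude the rules
    operate on; values are clipped at zero).  Per unordered pair, the
    bottom ``low_te_fraction`` by max-direction TE is excluded; among the
    rest, a dominant direction at least ``asym_ratio`` times the reverse
    makes the pair strongly asymmetric, while a relative difference below
    ``sym_rel_diff`` makes it symmetric.

    The bootstrap Z-score is a natural ``value_col``, but its denominator
    is estimated from trial-level resamples and carries relative noise of
    order 1/sqrt(2 n_trials), which is comparable to ``sym_rel_diff``;
    null-mean-subtracted TE in bits (``te_excess`` from the pair tables
    produced by this package) gives the same common-stimulus removal with
    a far more stable magnitude.
    """
    rows: dict[tuple[int, int], dict] = {}
    for _, r in pair_table.iterrows():
        a, b = int(r["sender"]), int(r["receiver"])
        key = (min(a, b), max(a, b))
        entry = rows.setdefault(key, {})
        entry["ab" if (a, b) == key else "ba"] = float(r[value_col])
    pairs = []
    for (a, b), v in sorted(rows.items()):
        te_ab = max(v.get("ab", 0.0), 0.0)
        te_ba = max(v.get("ba", 0.0), 0.0)
        pairs.append(PairCausality(
            a=a, b=b, te_ab=te_ab, te_ba=te_ba,
            asymmetry=asymmetry_index(te_ab, te_ba),
            category="", leading=None))
    if len(pairs) < 5:
        warnings.warn("fewer than 5 pairs: classification skipped")
        for p in pairs:
            p.category = "unclassified"
        return _pairs_frame(pairs)
    max_te = np.array([max(p.te_ab, p.te_ba) for p in pairs])
    floor = np.quantile(max_te, low_te_fraction)
    for p in pairs:
        hi, lo = max(p.te_ab, p.te_ba), min(p.te_ab, p.te_ba)
        if hi < floor or hi <= 0:
            p.category = "excluded_low_TE"
            continue
        p.leading = (p.a, p.b) if p.te_ab >= p.te_ba else (p.b, p.a)
        ratio = np.inf if lo <= 0 else hi / lo
        if ratio >= asym_ratio:
            p.category = "strongly_asymmetric"
        elif p.asymmetry < sym_rel_diff:
            p.category = "symmetric"
            p.leading = None
        else:
            p.category = "other"
    return _pairs_frame(pairs)


def _pairs_frame(pairs: list[PairCausality]) -> pd.DataFrame:
    return pd.DataFrame([{
        "a": p.a, "b": p.b, "te_ab": p.te_ab, "te_ba": p.te_ba,
        "asymmetry": p.asymmetry, "category": p.category,
        "leading_sender": None if p.leading is None else p.leading[0],
        "leading_receiver": None if p.leading is None else p.leading[1],
    } for p in pairs])


def correlate_shift_causation(mean_shift: np.ndarray,
                              te_z: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between per-ordered-pair movie-averaged
    phase shift and directed TE Z-score."""
    s = np.asarray(mean_shift, dtype=float)
    t = np.asarray(te_z, dtype=float)
    if s.size != t.size or s.size < 10:
        raise ValueError("need >= 10 aligned pairs")
    if np.ptp(s) == 0 or np.ptp(t) == 0:
        raise ValueError("ties-only input has no rank correlation")
    rho, p = spearmanr(s, t)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# block segmentation and block-conditioned TE


@dataclass
class BlockSegmentation:
    """Single-signed periods of majority phase shift across trials."""

    majority_sign: np.ndarray       # per sample: +1, -1 or 0 (tie/unlabeled)
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    # (start, end, sign) with end exclusive; each block >= min_samples
    min_samples: int = 0
    fs_hz: float = 1.0

    def blocks_of(self, sign: int) -> list[tuple[int, int]]:
        return [(s, e) for s, e, sg in self.blocks if sg == sign]

    def duration(self, sign: int) -> int:
        return sum(e - s for s, e in self.blocks_of(sign))


def segment_blocks(shift: np.ndarray, fs_hz: float,
                   min_ms: float = 300.0,
                   valid: np.ndarray | None = None) -> BlockSegmentation:
    """Majority-vote sign per sample, then maximal single-signed runs.

    ``shift`` is (n_trials, n_time) wrapped phase shifts.  A sample gets the
    sign held by the majority of trials; exact ties stay unlabeled and break
    runs.  Runs of constant sign at least ``min_ms`` long become blocks.
    """
    sh = np.atleast_2d(np.asarray(shift, dtype=float))
    if sh.shape[0] < 3:
        raise ValueError("majority vote needs at least 3 trials")
    ok = np.ones(sh.shape, dtype=bool) if valid is None \
        else np.atleast_2d(np.asarray(valid, dtype=bool))
    pos = ((sh > 0) & ok).sum(axis=0)
    neg = ((sh < 0) & ok).sum(axis=0)
    sign = np.sign(pos - neg).astype(int)
    min_samples = int(round(min_ms * fs_hz / 1000.0))
    blocks: list[tuple[int, int, int]] = []
    start = 0
    n = sign.size
    for i in range(1, n + 1):
        if i == n or sign[i] != sign[start]:
            if sign[start] != 0 and i - start >= min_samples:
                blocks.append((start, i, int(sign[start])))
            start = i
    return BlockSegmentation(majority_sign=sign, blocks=blocks,
                             min_samples=min_samples, fs_hz=fs_hz)


def _balance_blocks(seg: BlockSegmentation, rng: Generator,
                    tolerance: float = 0.1
                    ) -> dict[int, list[tuple[int, int]]]:
    """Down-sample (and trim) the longer sign so durations match within 10%."""
    out = {+1: list(seg.blocks_of(+1)), -1: list(seg.blocks_of(-1))}
    d = {s: seg.duration(s) for s in (+1, -1)}
    if d[+1] == 0 or d[-1] == 0:
        return out
    long_s = +1 if d[+1] >= d[-1] else -1
    target = d[-long_s]
    blocks = out[long_s]
    rng.shuffle(blocks)
    kept: list[tuple[int, int]] = []
    total = 0
    for s, e in blocks:
        if total >= target:
            break
        take = min(e - s, target - total)
        kept.append((s, s + take))
        total += take
    out[long_s] = sorted(kept)
    return out


def block_conditioned_te(phase_send: np.ndarray, rate_recv: np.ndarray,
                         seg: BlockSegmentation, fs_hz: float,
                         lag_ms: float = 10.0, step_ms: float = 2.0,
                         n_bins: int = 3, n_boot: int = 40,
                         rng: Generator | None = None
                         ) -> dict[int, InfoEstimate | None]:
    """TE (with bootstrap Z) separately within positive- and negative-shift
    blocks, after down-sampling blocks so both signs use comparable time.

    Returns a dict {+1: estimate, -1: estimate}; a sign with no blocks is
    reported as None.
    """
    g = default_rng(0) if rng is None else rng
    balanced = _balance_blocks(seg, g)
    n_time = np.atleast_2d(phase_send).shape[-1]
    out: dict[int, InfoEstimate | None] = {}
    for sign in (+1, -1):
        blocks = balanced[sign]
        if not blocks:
            out[sign] = None
            continue
        mask = np.zeros(n_time, dtype=bool)
        for s, e in blocks:
            mask[s:e] = True
        trip = embed_series(rate_recv, phase_send, fs_hz, lag_ms=lag_ms,
                            step_ms=step_ms, time_mask=mask)
        out[sign] = bootstrap_null_zscore(trip, n_bins=n_bins,
                                          n_boot=n_boot, rng=g)
    return out


# ---------------------------------------------------------------------------
# travelling-wave geometry and speed


def projected_distance(positions: np.ndarray, sender: int, receiver: int,
                       candidate: int,
                       cone_deg: float = 45.0) -> float | None:
    """Signed coordinate (mm) of a candidate electrode along a causal axis.

    The candidate is included iff the displacement from it to the reference
    receiving electrode lies within ``cone_deg`` of the sender->receiver
    direction; the coordinate is the projection of (candidate - receiver)
    onto that unit axis, so upstream electrodes get negative values and the
    receiver sits at 0.  Returns None when excluded.
    """
    pos = np.asarray(positions, dtype=float)
    axis = pos[receiver] - pos[sender]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero-length pair axis")
    u = axis / norm
    if candidate == receiver:
        return 0.0
    disp = pos[receiver] - pos[candidate]
    dn = np.linalg.norm(disp)
    if dn == 0:
        return 0.0
    cos_angle = float(disp @ u) / dn
    if cos_angle < np.cos(np.deg2rad(cone_deg)) - 1e-12:
        return None
    return float((pos[candidate] - pos[receiver]) @ u)


def pairwise_mean_shift(phase: np.ndarray,
                        valid: np.ndarray | None = None) -> np.ndarray:
    """Matrix of movie-averaged circular mean shifts, entry (i, j) being the
    circular mean of phi_i - phi_j (antisymmetric up to wrapping).

    ``phase`` is (n_trials, n_electrodes, n_time).
    """
    ph = np.asarray(phase, dtype=float)
    n_trials, n_elec, n_time = ph.shape
    z = np.exp(1j * ph)
    if valid is not None:
        z = np.where(np.asarray(valid, dtype=bool), z, 0.0)
    zf = np.moveaxis(z, 1, 0).reshape(n_elec, -1)     # (E, trials*time)
    m = zf @ zf.conj().T
    return np.angle(m)


def collect_wave_profile(positions: np.ndarray, classified: pd.DataFrame,
                         mean_shift: np.ndarray,
                         cone_deg: float = 45.0) -> list[np.ndarray]:
    """(projected distance, phase shift) samples per reference causal pair.

    For each strongly asymmetric pair, candidate electrodes within the
    45-degree cone of the causal direction contribute their shift relative
    to the receiving site.  If another strongly asymmetric pair's receiver
    among the candidates achieves the minimum shift, the origin is
    re-anchored there, so the origin always marks the final target of the
    propagation.
    """
    asym = classified[classified["category"] == "strongly_asymmetric"]
    receivers = set(int(r) for r in asym["leading_receiver"])
    profiles = []
    n_elec = len(positions)
    for _, row in asym.iterrows():
        s, r = int(row["leading_sender"]), int(row["leading_receiver"])
        ds, shifts, elecs = [], [], []
        for e in range(n_elec):
            d = projected_distance(positions, s, r, e, cone_deg)
            if d is None:
                continue
            ds.append(d)
            shifts.append(0.0 if e == r else float(mean_shift[e, r]))
            elecs.append(e)
        ds, shifts = np.asarray(ds), np.asarray(shifts)
        # re-anchor at the most-downstream strongly-asymmetric receiver
        anchor_candidates = [i for i, e in enumerate(elecs)
                             if e == r or e in receivers]
        i0 = min(anchor_candidates, key=lambda i: shifts[i])
        if shifts[i0] < 0:
            ds = ds - ds[i0]
            shifts = wrap_phase(shifts - shifts[i0])
        profiles.append(np.column_stack([ds, shifts]))
    return profiles


@dataclass
class WaveFit:
    """Cubic-spline fit of phase shift versus projected distance."""

    samples: np.ndarray             # (n, 2): distance mm, shift rad
    slope_rad_per_mm: float
    speed_m_per_s: float            # inf when flagged synchronous
    f_hz: float
    speed_sd: float | None = None
    flags: list[str] = field(default_factory=list)


def _circular_slope(d: np.ndarray, shift: np.ndarray,
                    m_max: float) -> float:
    """Preliminary phase-gradient estimate by resultant maximisation.

    Finds m maximising |sum exp(i*(shift - m*d))| over |m| <= m_max; robust
    to 2*pi wrapping of the shifts as long as |m| stays below the aliasing
    bound pi / (minimum distance gap).
    """
    grid = np.linspace(-m_max, m_max, 2001)
    r = np.abs(np.exp(1j * (shift[None, :] - grid[:, None] * d[None, :]))
               .mean(axis=1))
    m0 = grid[int(np.argmax(r))]
    fine = np.linspace(m0 - 2 * m_max / 2000, m0 + 2 * m_max / 2000, 401)
    rf = np.abs(np.exp(1j * (shift[None, :] - fine[:, None] * d[None, :]))
                .mean(axis=1))
    return float(fine[int(np.argmax(rf))])


def wave_speed(profiles: list[np.ndarray] | np.ndarray, f_hz: float,
               slope_tol: float = 1e-2, n_bootstrap: int = 0,
               rng: Generator | None = None,
               max_slope_rad_per_mm: float | None = None) -> WaveFit:
    """Propagation speed from the spline slope of shift vs distance at 0.

    Samples (pooled over reference causal pairs) are first congruence-
    corrected (+-2*pi) using a preliminary circular-regression slope, then a
    cubic smoothing spline (generalised cross-validated penalty) is fit and
    the speed is v = 2*pi*f / |slope at the origin|.  With fewer than five
    distinct distances an interpolating natural cubic spline through the
    per-distance means is used.  Slopes below ``slope_tol`` (rad/mm) flag
    near-global synchrony: the speed is reported as infinite.

    ``max_slope_rad_per_mm`` bounds the preliminary slope search; by default
    it is pi over the smallest gap between distinct distances, but when the
    electrode spacing is known, pi / spacing (the spatial aliasing limit of
    the array) is the appropriate bound.

    ``n_bootstrap`` > 0 adds a bootstrap SD over reference pairs (requires a
    list of per-pair profiles).
    """
    if isinstance(profiles, np.ndarray):
        profiles = [profiles]
    samples = np.concatenate(profiles, axis=0)
    d, shift = samples[:, 0], samples[:, 1]
    distinct = np.unique(np.round(d, 6))
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct projected distances")
    slope = _fit_slope(d, shift, distinct, max_slope_rad_per_mm)
    fit = WaveFit(samples=samples, slope_rad_per_mm=slope,
                  speed_m_per_s=np.inf, f_hz=f_hz)
    if abs(slope) < slope_tol:
        fit.flags.append("near-synchronous")
        return fit
    fit.speed_m_per_s = 2 * np.pi * f_hz / (abs(slope) * 1000.0)
    if n_bootstrap > 0 and len(profiles) > 1:
        g = default_rng(0) if rng is None else rng
        speeds = []
        for _ in range(n_bootstrap):
            idx = g.integers(0, len(profiles), size=len(profiles))
            sb = np.concatenate([profiles[i] for i in idx], axis=0)
            db, shb = sb[:, 0], sb[:, 1]
            dist_b = np.unique(np.round(db, 6))
            if dist_b.size < 4:
                continue
            sl = _fit_slope(db, shb, dist_b, max_slope_rad_per_mm)
            if abs(sl) >= slope_tol:
                speeds.append(2 * np.pi * f_hz / (abs(sl) * 1000.0))
        if speeds:
            fit.speed_sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 \
                else 0.0
    return fit


def _fit_slope(d: np.ndarray, shift: np.ndarray, distinct: np.ndarray,
               max_slope: float | None = None) -> float:
    if max_slope is not None:
        m_max = max_slope
    else:
        gaps = np.diff(np.sort(distinct))
        min_gap = gaps[gaps > 1e-9].min() if np.any(gaps > 1e-9) else 1.0
        m_max = np.pi / min_gap
    m0 = _circular_slope(d, shift, m_max)
    corrected = shift + 2 * np.pi * np.round((m0 * d - shift) / (2 * np.pi))
    # aggregate duplicate distances (weighted means) for the spline fit
    key = np.round(d, 6)
    xs, ys, ws = [], [], []
    for x in distinct:
        sel = key == x
        xs.append(x)
        ys.append(corrected[sel].mean())
        ws.append(sel.sum())
    xs, ys, ws = map(np.asarray, (xs, ys, ws))
    order = np.argsort(xs)
    xs, ys, ws = xs[order], ys[order], ws[order].astype(float)
    if xs.size >= 5:
        spline = make_smoothing_spline(xs, ys, w=ws)
        return float(spline.derivative()(0.0))
    spline = CubicSpline(xs, ys, bc_type="natural")
    return float(spline.derivative()(0.0))
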
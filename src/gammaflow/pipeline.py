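"""One-command end-to-end analysis of a (synthetic or loaded) session.

Stage order mirrors the analysis sequence the package implements:
preprocess (band-pass + analytic signal) -> spatial coherence -> directed
transfer entropy with its common-stimulus bootstrap null for every ordered
electrode pair -> pair-causality classification -> phase shifts, Rayleigh
tests and the shift/TE rank correlation -> travelling-wave speed ->
block-conditioned TE -> sensory information.  Each stage is logged with its
duration; a stage failure is recorded and later stages still run where they
can.  Results are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence, default_rng

from . import infotheory, phasewave, preprocess
from .session import CouplingEdge, RecordingSession
from .synth import SyntheticConfig, generate_session

__all__ = ["PipelineResult", "run_pipeline", "config_from_dict",
           "config_to_yaml", "pair_te_table", "default_config"]

log = logging.getLogger("gammaflow.pipeline")


def config_from_dict(d: dict[str, Any]) -> SyntheticConfig:
    d = dict(d)
    edges = d.pop("coupling_edges", [])
    parsed = tuple(
        e if isinstance(e, CouplingEdge) else CouplingEdge(
            sender=int(e[0]), receiver=int(e[1]), gain=float(e[2]),
            lag_ms=float(e[3]) if len(e) > 3 else 10.0,
            preferred_phase=float(e[4]) if len(e) > 4 else 0.0)
        for e in edges)
    return SyntheticConfig(coupling_edges=parsed, **d)


def default_config() -> SyntheticConfig:
    return SyntheticConfig()


def config_to_yaml(config: SyntheticConfig) -> str:
    from .synth import _config_dict
    return yaml.safe_dump(_config_dict(config), sort_keys=False)


@dataclass
class PipelineResult:
    session: RecordingSession
    analytic: preprocess.AnalyticSeries | None = None
    coherence: preprocess.CoherenceSpectrum | None = None
    pair_table: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    shift_table: pd.DataFrame | None = None
    shift_te_spearman: tuple[float, float] | None = None
    wave: phasewave.WaveFit | None = None
    block_te: pd.DataFrame | None = None
    sensory: pd.DataFrame | None = None
    summary: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _stage(result: PipelineResult, name: str):
    """Context manager logging stage duration and recording failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage=%s status=ok duration_s=%.2f", name, dt)
                return False
            log.warning("stage=%s status=failed duration_s=%.2f error=%s",
                        name, dt, exc)
            result.errors[name] = str(exc)
            return True                      # swallow, keep going
    return _Ctx()


def pair_te_table(phase: np.ndarray, rate: np.ndarray, fs_hz: float,
                  valid: np.ndarray | None = None,
                  lag_ms: float = 10.0, step_ms: float = 2.0,
                  n_bins: int = 3, n_boot: int = 40,
                  rng=None, time_mask: np.ndarray | None = None
                  ) -> pd.DataFrame:
    """Z-scored TE from sender phase to receiver rate for all ordered pairs."""
    g = default_rng(0) if rng is None else rng
    n_elec = phase.shape[1]
    rows = []
    for s in range(n_elec):
        for r in range(n_elec):
            if s == r:
                continue
            trip = infotheory.embed_series(
                rate[:, r, :], phase[:, s, :], fs_hz, lag_ms=lag_ms,
                step_ms=step_ms, time_mask=time_mask)
            est = infotheory.bootstrap_null_zscore(
                trip, n_bins=n_bins, n_boot=n_boot, rng=g)
            rows.append({"sender": s, "receiver": r, "te_bits": est.value,
                         "te_excess": est.value - est.null_mean,
                         "te_z": est.z, "n": est.n})
    return pd.DataFrame(rows)


def run_pipeline(config: SyntheticConfig | dict | None = None,
                 session: RecordingSession | None = None,
                 seed: int | None = None,
                 outdir: str | Path | None = None,
                 band: tuple[float, float] = (50.0, 80.0),
                 lag_ms: float = 10.0, step_ms: float = 2.0,
                 n_bins: int = 3, n_boot: int = 40,
                 max_block_pairs: int = 4) -> PipelineResult:
    """Run the full analysis; simulate a session when none is given."""
    if session is None:
        if config is None:
            config = default_config()
        if isinstance(config, dict):
            config = config_from_dict(config)
        session, _ = generate_session(config, seed=seed)
    result = PipelineResult(session=session)
    fs = session.fs_hz
    ss = SeedSequence(0 if seed is None else seed)
    rng_te, rng_block, rng_sens = (default_rng(s) for s in ss.spawn(3))

    with _stage(result, "preprocess"):
        banded = preprocess.bandpass(session.lfp, band[0], band[1], fs)
        edge = preprocess.settling_samples(fs, band[0])
        result.analytic = preprocess.analytic_signal(
            banded, fs, band=band, edge_mask_samples=edge)

    with _stage(result, "coherence"):
        result.coherence = preprocess.spatial_coherence(session.lfp, fs)

    phase = result.analytic.phase if result.analytic is not None else None
    valid = result.analytic.valid if result.analytic is not None else None
    edge_mask = None
    if phase is not None:
        edge_mask = np.ones(session.n_time, dtype=bool)
        edge_mask[:edge] = False
        edge_mask[session.n_time - edge:] = False

    with _stage(result, "transfer_entropy"):
        result.pair_table = pair_te_table(
            phase, session.rate, fs, lag_ms=lag_ms, step_ms=step_ms,
            n_bins=n_bins, n_boot=n_boot, rng=rng_te, time_mask=edge_mask)

    with _stage(result, "classification"):
        result.classification = phasewave.classify_pairs(
            result.pair_table, value_col="te_excess")

    with _stage(result, "phase_shifts"):
        rows = []
        for _, r in result.pair_table.iterrows():
            s, rcv = int(r["sender"]), int(r["receiver"])
            pss = phasewave.phase_shift(
                phase[:, s, :], phase[:, rcv, :], fs,
                valid_send=valid[:, s, :], valid_recv=valid[:, rcv, :],
                sender=s, receiver=rcv)
            angles = pss.shift[pss.valid]
            sub = angles[:: max(1, angles.size // 2000)]
            _, p_ray = phasewave.rayleigh_test(sub)
            rows.append({"sender": s, "receiver": rcv,
                         "mean_shift_rad": pss.mean_shift,
                         "mean_shift_deg": np.rad2deg(pss.mean_shift),
                         "plv": pss.plv, "rayleigh_p": p_ray})
        result.shift_table = pd.DataFrame(rows)

    with _stage(result, "shift_te_correlation"):
        merged = result.pair_table.merge(result.shift_table,
                                         on=["sender", "receiver"])
        result.shift_te_spearman = phasewave.correlate_shift_causation(
            merged["mean_shift_rad"].to_numpy(),
            merged["te_z"].to_numpy())

    with _stage(result, "wave_speed"):
        if session.positions_mm is None or len(session.positions_mm) == 0:
            raise ValueError("no electrode positions: waves stage skipped")
        mean_shift = phasewave.pairwise_mean_shift(phase, valid)
        profiles = phasewave.collect_wave_profile(
            session.positions_mm, result.classification, mean_shift)
        if not profiles:
            raise ValueError("no strongly asymmetric reference pairs")
        f0 = 0.5 * (band[0] + band[1])
        result.wave = phasewave.wave_speed(
            profiles, f0, n_bootstrap=min(40, 10 * len(profiles)))

    with _stage(result, "block_te"):
        asym = result.classification[
            result.classification["category"] == "strongly_asymmetric"]
        rows = []
        for _, pr in asym.head(max_block_pairs).iterrows():
            s = int(pr["leading_sender"])
            rcv = int(pr["leading_receiver"])
            pss = phasewave.phase_shift(phase[:, s, :], phase[:, rcv, :], fs,
                                        valid_send=valid[:, s, :],
                                        valid_recv=valid[:, rcv, :])
            seg = phasewave.segment_blocks(pss.shift, fs, valid=pss.valid)
            byc = phasewave.block_conditioned_te(
                phase[:, s, :], session.rate[:, rcv, :], seg, fs,
                lag_ms=lag_ms, step_ms=step_ms, n_bins=n_bins,
                n_boot=n_boot, rng=rng_block)
            rows.append({
                "sender": s, "receiver": rcv,
                "te_pos": None if byc[+1] is None else byc[+1].value,
                "z_pos": None if byc[+1] is None else byc[+1].z,
                "te_neg": None if byc[-1] is None else byc[-1].value,
                "z_neg": None if byc[-1] is None else byc[-1].z})
        result.block_te = pd.DataFrame(rows)

    with _stage(result, "sensory_information"):
        scene_len_ms = 1000.0 * session.n_time / (session.n_scenes * fs)
        rows = []
        for e in range(session.n_electrodes):
            period_ms = 1000.0 / (0.5 * (band[0] + band[1]))
            est = infotheory.sensory_information(
                phase[:, e, :], fs, scene_len_ms=period_ms,
                circular=True, point_sample=True, rng=rng_sens)
            rows.append({"signal": f"phase[{e}]", "bits": est.value,
                         "z": est.z})
        for s in range(session.n_electrodes):
            for rcv in range(s + 1, session.n_electrodes):
                pss = phasewave.phase_shift(phase[:, s, :], phase[:, rcv, :],
                                            fs)
                est = infotheory.sensory_information(
                    pss.shift, fs, scene_len_ms=scene_len_ms,
                    circular=True, rng=rng_sens)
                rows.append({"signal": f"shift[{s},{rcv}]",
                             "bits": est.value, "z": est.z})
        result.sensory = pd.DataFrame(rows)

    result.summary = _summarize(result)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _summarize(result: PipelineResult) -> dict[str, Any]:
    s: dict[str, Any] = {"errors": result.errors}
    if result.pair_table is not None:
        s["mean_te_z"] = float(np.nanmean(result.pair_table["te_z"]))
    if result.classification is not None:
        s["categories"] = (result.classification["category"]
                           .value_counts().to_dict())
        asym = result.classification
        asym = asym[asym["category"] != "excluded_low_TE"]
        if len(asym):
            s["mean_asymmetry"] = float(np.nanmean(asym["asymmetry"]))
    if result.shift_te_spearman is not None:
        s["shift_te_spearman_rho"] = result.shift_te_spearman[0]
        s["shift_te_spearman_p"] = result.shift_te_spearman[1]
    if result.wave is not None:
        s["wave_speed_m_per_s"] = result.wave.speed_m_per_s
        s["wave_slope_rad_per_mm"] = result.wave.slope_rad_per_mm
    return s


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("pair_table", "classification", "shift_table",
                 "block_te", "sensory"):
        df = getattr(result, name)
        if df is not None:
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as f:
        json.dump(result.summary, f, indent=2, default=str)
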
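"""Configured, seeded, end-to-end analysis pipeline.

``run_pipeline`` takes a :class:`PipelineConfig` pointing at a track file
(or a synthetic-tissue specification), executes the enabled stages in
dependency order (io → structure/dynamics → clusters/events/modes →
correlations) and writes tidy CSV/JSON outputs plus a machine-readable
``summary.json``.  Identical config + seed reproduces identical outputs.

Default parameters are the reference analysis conditions: probe length
a = 1.2 μm, cluster cutoff r* = 15 μm, top 10% fast cells, 100 μm event
regions, 40/20 μm coarse-graining windows, covariance window T₁ = first
100 min, overlap window T₂ = [105, 1625] min, Einstein fit window
δt = 200–400 min, q ∈ [0.04, 0.2] μm⁻¹ in steps of 0.013.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from epidyn import clusters as cl
from epidyn import dynamics as dyn
from epidyn import events as ev
from epidyn import modes as md
from epidyn import structure as st
from epidyn.synthetic import SyntheticParams, gen_trajectories, inject_events
from epidyn.tracks import (TrackTable, filter_complete_tracks, read_tracks,
                           write_events, write_tracks)

log = logging.getLogger("epidyn.pipeline")

ALL_STAGES = ("io", "structure", "dynamics", "clusters", "events", "modes",
              "correlations")


@dataclass
class PipelineConfig:
    """Full parameterisation of one pipeline run."""

    # input: either a track file or synthetic-generator parameters
    input_path: str | None = None
    dialect: str = "plain_csv"
    synthetic: dict | None = None          # SyntheticParams fields
    events_path: str | None = None
    inject_synthetic_events: bool = False

    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "epidyn_out"
    rng_seed: int = 0
    dt: float = 5.0

    # analysis parameters (defaults = reference conditions)
    overlap_a: float = 1.2                    # μm
    overlap_lag: float = 200.0                # min
    overlap_window: tuple[float, float] = (105.0, 1625.0)
    mode_window: tuple[float, float] = (0.0, 100.0)
    n_modes: int = 10
    fit_window: tuple[float, float] = (200.0, 400.0)
    q_min: float = 0.04                       # μm⁻¹
    q_max: float = 0.2
    q_step: float = 0.013
    fast_fraction: float = 0.10
    r_star: float = 15.0                      # μm
    neighbor_cutoff: float = 13.0             # μm (cage-relative TMSD)
    event_half_width: float = 50.0            # μm (100 μm square region)
    event_dt_step: float = 10.0               # min
    cg_window: float = 40.0                   # μm
    cg_overlap: float = 20.0                  # μm
    n_lags: int = 30
    origin_stride: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)
        self.overlap_window = tuple(self.overlap_window)
        self.mode_window = tuple(self.mode_window)
        self.fit_window = tuple(self.fit_window)
        if self.mode_window[1] >= self.overlap_window[0] \
                and self.overlap_window[1] >= self.mode_window[0] \
                and "modes" in self.stages and "correlations" in self.stages:
            raise ValueError("mode window T1 must not overlap the "
                             "self-overlap window T2")

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def q_grid(self) -> np.ndarray:
        return np.arange(self.q_min, self.q_max + 1e-9, self.q_step)


def _load_tracks(cfg: PipelineConfig):
    from epidyn.tracks import read_events
    events = None
    if cfg.input_path is not None:
        tracks = read_tracks(cfg.input_path, dialect=cfg.dialect, dt=cfg.dt)
        if cfg.events_path:
            events = read_events(cfg.events_path)
    elif cfg.synthetic is not None:
        params = SyntheticParams(**{**cfg.synthetic,
                                    "rng_seed": cfg.synthetic.get(
                                        "rng_seed", cfg.rng_seed)})
        tracks = gen_trajectories(params)
        if cfg.inject_synthetic_events:
            tracks, events = inject_events(tracks, params)
    else:
        raise ValueError("config needs input_path or synthetic parameters")
    return tracks, events


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns and writes the summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    summary: dict = {"stages": {}, "seed": cfg.rng_seed}
    timings: dict[str, float] = {}

    def stage_enabled(name: str) -> bool:
        return name in cfg.stages

    t0 = time.perf_counter()
    tracks, event_list = _load_tracks(cfg)
    tracks = filter_complete_tracks(tracks)
    timings["load"] = time.perf_counter() - t0
    summary["n_tracks"] = int(tracks.n_tracks)
    summary["n_frames"] = int(tracks.n_frames)

    if stage_enabled("io"):
        t0 = time.perf_counter()
        write_tracks(tracks, out / "tracks.csv")
        if event_list:
            write_events(event_list, out / "events.csv")
        summary["stages"]["io"] = {"tracks_csv": "tracks.csv",
                                   "n_tracks": int(tracks.n_tracks)}
        timings["io"] = time.perf_counter() - t0

    mid_frame = int(tracks.frames[len(tracks.frames) // 2])
    per_cell_fields: dict[str, np.ndarray] = {}

    if stage_enabled("structure"):
        t0 = time.perf_counter()
        r_max = min(50.0, min(tracks.field_width, tracks.field_height)
                    / 2 - 1)
        g = st.pair_correlation_radial(tracks, r_max=r_max, frame=mid_frame)
        pd.DataFrame({"r_um": g.r, "g": g.g}).to_csv(
            out / "pair_correlation.csv", index=False)
        sq = st.structure_factor(tracks, frame=mid_frame)
        sq.to_csv(out / "structure_factor.csv", index=False)
        fields = st.order_fields(tracks, frame=mid_frame,
                                 entropy_kwargs={"r_max": r_max})
        fields.to_frame().to_csv(out / "order_fields.csv", index=False)
        for name in ("rho", "O2", "O6", "S"):
            v = getattr(fields, name)
            if v is not None:
                per_cell_fields[name] = v
        summary["stages"]["structure"] = {
            "first_g_minimum_um": g.first_minimum(),
            "mean_O6": float(np.nanmean(fields.O6)),
            "mean_S": float(np.nanmean(fields.S)),
        }
        timings["structure"] = time.perf_counter() - t0

    msd = None
    overlap = None
    if stage_enabled("dynamics"):
        t0 = time.perf_counter()
        msd = dyn.tmsd(tracks, dyn.default_lag_grid(tracks, cfg.n_lags))
        msd.to_frame().to_csv(out / "tmsd.csv", index=False)
        dyn_summary: dict = {}
        if msd.dt_min[-1] >= cfg.fit_window[1]:
            D = dyn.diffusion_coefficient(msd, cfg.fit_window)
            dyn_summary["D_um2_per_min"] = D
        fs = dyn.self_intermediate_scattering(
            tracks, cfg.q_grid(), dyn.default_lag_grid(tracks, cfg.n_lags),
            origin_stride=cfg.origin_stride)
        fs = dyn.fit_stretched_exponential(fs)
        pd.DataFrame(fs.Fs, index=fs.q, columns=fs.dt_min).to_csv(
            out / "fs.csv")
        if fs.fits is not None:
            fs.fits.to_csv(out / "fs_fits.csv", index=False)
        dyn_summary["tau_q_exponent"] = (None if fs.tau_exponent is None
                                         else float(fs.tau_exponent))
        vh = dyn.van_hove(tracks, dyn.default_lag_grid(tracks, 12))
        pd.DataFrame({"dt_min": vh.dt_min, "sigma_um": vh.sigma,
                      "alpha2": vh.alpha2}).to_csv(
            out / "van_hove_alpha2.csv", index=False)
        dyn_summary["alpha2_max"] = float(np.max(vh.alpha2))
        ac = dyn.displacement_autocovariance(tracks,
                                             bin_time=cfg.event_dt_step)
        pd.DataFrame({"dt_min": ac.dt_min, "C": ac.values}).to_csv(
            out / "autocovariance.csv", index=False)
        win = cfg.overlap_window
        t_max = tracks.times[-1]
        win = (min(win[0], max(0.0, t_max - cfg.overlap_lag - tracks.dt)),
               min(win[1], t_max))
        overlap = dyn.self_overlap(tracks, cfg.overlap_a, cfg.overlap_lag,
                                   window=win)
        pd.DataFrame({"track_id": overlap.track_ids,
                      "Q": overlap.Q}).to_csv(out / "self_overlap.csv",
                                              index=False)
        dyn_summary["mean_Q"] = float(overlap.Q.mean())
        summary["stages"]["dynamics"] = dyn_summary
        timings["dynamics"] = time.perf_counter() - t0

    if stage_enabled("clusters"):
        t0 = time.perf_counter()
        lag = min(cfg.overlap_lag, (tracks.n_frames - 2) * tracks.dt)
        tab = cl.pooled_cluster_sizes(tracks, lag, cfg.fast_fraction,
                                      cfg.r_star,
                                      origin_stride=cfg.origin_stride)
        tab.to_csv(out / "clusters.csv", index=False)
        cstats: dict = {"n_clusters": int(len(tab)),
                        "mean_Nc": float(tab["n_cells"].mean())}
        if tab["n_cells"].nunique() > 1 and len(tab) >= 100:
            fit = cl.size_distribution_fit(tab["n_cells"].to_numpy())
            cstats["size_fit"] = {k: fit[k] for k in
                                  ("c", "n_star", "A", "n_samples")}
        try:
            df_, se = cl.fractal_dimension(tab)
            cstats["fractal_dimension"] = df_
            cstats["fractal_dimension_stderr"] = se
        except ValueError:
            pass
        summary["stages"]["clusters"] = cstats
        timings["clusters"] = time.perf_counter() - t0

    if stage_enabled("events") and event_list:
        t0 = time.perf_counter()
        curves = ev.event_mean_displacement(tracks, event_list,
                                            cfg.event_half_width)
        curves.to_csv(out / "event_displacement.csv", index=False)
        controls = ev.random_controls(
            tracks, n_controls=5 * len(event_list),
            half_width=cfg.event_half_width, rng_seed=cfg.rng_seed + 17,
            true_events=event_list)
        ctrl = ev.event_mean_displacement(tracks, controls,
                                          cfg.event_half_width)
        ctrl.to_csv(out / "control_displacement.csv", index=False)
        steps = ev.displacement_step_series(tracks, event_list,
                                            cfg.event_dt_step,
                                            cfg.event_half_width)
        steps.to_csv(out / "event_steps.csv", index=False)
        summary["stages"]["events"] = {
            "n_events": len(event_list),
            "n_controls": len(controls),
            "peak_step_um": float(steps["step_um"].max()),
        }
        timings["events"] = time.perf_counter() - t0

    if stage_enabled("modes"):
        t0 = time.perf_counter()
        mode_set = md.eigenmodes(tracks, cfg.n_modes, cfg.mode_window)
        pd.DataFrame({"track_id": mode_set.track_ids,
                      "mean_mode_magnitude": mode_set.mean_magnitude}
                     ).to_csv(out / "mode_magnitude.csv", index=False)
        (out / "mode_eigenvalues.json").write_text(
            json.dumps({"eigenvalues": mode_set.eigenvalues.tolist()},
                       indent=2))
        summary["stages"]["modes"] = {
            "top_eigenvalue": float(mode_set.eigenvalues[0]),
            "n_modes": int(len(mode_set.eigenvalues)),
        }
        timings["modes"] = time.perf_counter() - t0

        if stage_enabled("correlations") and overlap is not None:
            t0 = time.perf_counter()
            corr = md.mode_overlap_correlation(mode_set, overlap,
                                               per_cell_fields or None)
            (out / "correlations.json").write_text(
                json.dumps({"pearson": corr["pearson"],
                            "pvalues": corr["pvalues"]}, indent=2))
            summary["stages"]["correlations"] = corr["pearson"]
            timings["correlations"] = time.perf_counter() - t0

    summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
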
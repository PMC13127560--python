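"""Synthetic monolayer generator: point patterns, trajectories, events.

The generator emulates the statistical structure of a dense, mechanically
arrested epithelial monolayer as seen through tracked nuclei:

* liquid-like short-range positional order (jittered hexagonal packing at
  ~9400 cells mm⁻²),
* subdiffusive creep crossing over to Fickian diffusion, produced by a
  trap/creep model — Brownian cage centres plus a mean-reverting
  (Ornstein-Uhlenbeck) intracage fluctuation with relaxation time τ_r —
  whose translational MSD is the closed form
  ``4·D_c·δt + 4·σ_s²·(1 − exp(−δt/τ_r))``,
* per-cell mobility heterogeneity (non-Gaussian Van Hove functions),
* diffusion anisotropy aligned with the nucleus long axis,
* spatially clustered fast cells via a smooth random mobility field,
* sparse division/extrusion events injecting transient, spatially localized
  outward velocity boosts.

The model is a statistical test harness, not a mechanistic tissue
simulation: there are no forces, shapes, or cell-cell interactions.
Every output is a deterministic function of ``rng_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from epidyn.tracks import TrackTable, EventRecord, wrap_nematic

__all__ = ["SyntheticParams", "gen_static_pattern", "gen_trajectories",
           "inject_events", "write_ground_truth"]


@dataclass
class SyntheticParams:
    """Parameters of the synthetic monolayer.

    Defaults mirror the experimental conditions the analyses target:
    828 μm × 621 μm field, 5-min frames, 325 frames (~27 h), ~9400 cells
    mm⁻² when ``n_cells`` fills the field, creep crossover τ_r ≈ 200 min,
    division/extrusion rates of one per ~10/~40 min, and event boosts of
    ~20 μm spatial and ~30 min temporal extent.
    """

    n_cells: int = 3800
    field_width: float = 828.0
    field_height: float = 621.0
    n_frames: int = 325
    dt: float = 5.0
    model: Literal["brownian", "trap_creep", "heterogeneous",
                   "anisotropic", "clustered"] = "trap_creep"
    # mobility
    D: float = 0.0125                # μm²/min (long-time diffusivity)
    D_dist: Literal["fixed", "exponential", "gamma"] = "fixed"
    D_gamma_shape: float = 2.0
    # trap/creep model
    tau_r: float = 200.0             # min, intracage relaxation time
    sigma_s: float = 1.5             # μm, stationary intracage RMS per axis
    D_c: float = 0.0125              # μm²/min, cage-centre diffusivity
    # anisotropic model
    anisotropy_ratio: float = 2.0    # D_par / D_perp
    # clustered model
    mobility_corr_length: float = 60.0   # μm
    mobility_log_std: float = 0.6        # lognormal spread of σ_s
    # nucleus geometry / orientation
    theta_diffusion: float = 0.0     # rad²/min, angular Brownian motion
    include_axes: bool = True
    mean_long_axis: float = 13.0     # μm
    mean_short_axis: float = 10.0    # μm
    # events
    division_rate: float = 0.1       # events/min (one per ~10 min)
    extrusion_rate: float = 0.025    # events/min (one per ~40 min)
    boost_amplitude: float = 0.2     # μm/min at the event centre
    boost_spatial_scale: float = 20.0    # μm
    boost_time_scale: float = 30.0       # min
    boost_axis_bias: float = 0.5     # amplitude modulation along division axis
    jitter: float = 1.5              # μm, positional jitter of the packing
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_width", "field_height", "dt", "D", "tau_r",
                     "sigma_s", "boost_spatial_scale", "boost_time_scale",
                     "mobility_corr_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("division_rate", "extrusion_rate", "D_c",
                     "boost_amplitude", "jitter", "theta_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


# ---------------------------------------------------------------------------
# static point patterns
# ---------------------------------------------------------------------------

def _hex_lattice(width: float, height: float, spacing: float,
                 margin: float = 0.0) -> np.ndarray:
    """Triangular lattice points inside [margin, width−margin] × same for y."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    dy = spacing * np.sqrt(3) / 2
    rows = []
    j = 0
    y = margin
    while y <= height - margin + 1e-9:
        xoff = margin + (spacing / 2 if j % 2 else 0.0)
        xs = np.arange(xoff, width - margin + 1e-9, spacing)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        j += 1
        y = margin + j * dy
    return np.vstack(rows)


def gen_static_pattern(
    kind: Literal["hexagonal", "poisson", "jittered_lattice"],
    params: SyntheticParams,
    spacing: float | None = None,
    jitter: float | None = None,
    n_frames: int = 1,
) -> TrackTable:
    """Generate a static (multi-)frame point pattern as a TrackTable.

    ``hexagonal`` — triangular lattice with exact 6-fold bond symmetry;
    ``poisson`` — homogeneous Poisson point process with ``params.n_cells``
    expected points; ``jittered_lattice`` — hexagonal plus isotropic
    Gaussian jitter (``jitter`` μm; 0 reproduces the exact lattice).
    """
    rng = np.random.default_rng(params.rng_seed)
    W, H = params.field_width, params.field_height
    if kind in ("hexagonal", "jittered_lattice"):
        if spacing is None:
            # spacing from target density: hex density = 2/(√3 s²)
            rho = params.n_cells / (W * H)
            spacing = float(np.sqrt(2.0 / (np.sqrt(3) * rho)))
        pts = _hex_lattice(W, H, spacing)
        if kind == "jittered_lattice":
            j = params.jitter if jitter is None else jitter
            if j > 0:
                pts = pts + rng.normal(0.0, j, pts.shape)
                pts[:, 0] = np.clip(pts[:, 0], 0, W)
                pts[:, 1] = np.clip(pts[:, 1], 0, H)
    elif kind == "poisson":
        n = rng.poisson(params.n_cells)
        pts = np.column_stack([rng.uniform(0, W, n), rng.uniform(0, H, n)])
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    n = len(pts)
    theta = rng.uniform(0, np.pi, n)
    frames = np.arange(n_frames)
    df = pd.DataFrame({
        "track_id": np.tile(np.arange(n), n_frames),
        "frame": np.repeat(frames, n),
        "x": np.tile(pts[:, 0], n_frames),
        "y": np.tile(pts[:, 1], n_frames),
        "theta": np.tile(theta, n_frames),
    })
    return TrackTable(df=df, dt=params.dt, field_width=W, field_height=H)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _initial_positions(params: SyntheticParams, rng: np.random.Generator
                       ) -> np.ndarray:
    """Jittered hexagonal packing trimmed/padded to exactly n_cells points."""
    W, H = params.field_width, params.field_height
    rho = params.n_cells / (W * H)
    spacing = np.sqrt(2.0 / (np.sqrt(3) * rho))
    pts = _hex_lattice(W, H, spacing, margin=spacing / 2)
    if len(pts) < params.n_cells:
        extra = np.column_stack([
            rng.uniform(0, W, params.n_cells - len(pts)),
            rng.uniform(0, H, params.n_cells - len(pts)),
        ])
        pts = np.vstack([pts, extra])
    idx = rng.permutation(len(pts))[:params.n_cells]
    pts = pts[idx]
    if params.jitter > 0:
        pts = pts + rng.normal(0.0, params.jitter, pts.shape)
    return pts


def _smooth_field(params: SyntheticParams, rng: np.random.Generator,
                  positions: np.ndarray) -> np.ndarray:
    """Standardized smooth Gaussian random field sampled at cell positions."""
    W, H = params.field_width, params.field_height
    cell = params.mobility_corr_length / 4.0
    nx = max(8, int(np.ceil(W / cell)) + 1)
    ny = max(8, int(np.ceil(H / cell)) + 1)
    white = rng.normal(size=(ny, nx))
    sigma_pix = params.mobility_corr_length / cell
    smooth = ndimage.gaussian_filter(white, sigma_pix, mode="nearest")
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    ix = np.clip((positions[:, 0] / cell), 0, nx - 1)
    iy = np.clip((positions[:, 1] / cell), 0, ny - 1)
    return ndimage.map_coordinates(smooth, [iy, ix], order=1, mode="nearest")


def _per_cell_D(params: SyntheticParams, rng: np.random.Generator,
                n: int) -> np.ndarray:
    if params.D_dist == "fixed":
        return np.full(n, params.D)
    if params.D_dist == "exponential":
        return rng.exponential(params.D, n)
    if params.D_dist == "gamma":
        k = params.D_gamma_shape
        return rng.gamma(k, params.D / k, n)
    raise ValueError(f"unknown D_dist {params.D_dist!r}")


def gen_trajectories(params: SyntheticParams) -> TrackTable:
    """Simulate nucleus trajectories under the configured mobility model.

    Trajectories are free (neither reflected nor wrapped at the field
    boundary); the declared field is enlarged to the data's bounding box
    when excursions leave the nominal field, matching the convention that
    analyses handle boundaries by exclusion rather than periodicity.
    """
    rng = np.random.default_rng(params.rng_seed)
    n, T, dt = params.n_cells, params.n_frames, params.dt
    pos0 = _initial_positions(params, rng)
    theta0 = rng.uniform(0, np.pi, n)

    model = params.model
    if model == "brownian":
        D = np.full(n, params.D)
        steps = rng.normal(size=(T - 1, n, 2)) * np.sqrt(2 * D * dt)[None, :, None]
        pos = pos0[None] + np.concatenate(
            [np.zeros((1, n, 2)), np.cumsum(steps, axis=0)])
    elif model == "heterogeneous":
        D = _per_cell_D(params, rng, n)
        steps = rng.normal(size=(T - 1, n, 2)) * np.sqrt(2 * D * dt)[None, :, None]
        pos = pos0[None] + np.concatenate(
            [np.zeros((1, n, 2)), np.cumsum(steps, axis=0)])
    elif model == "anisotropic":
        r = params.anisotropy_ratio
        D_par = params.D * 2 * r / (1 + r)
        D_perp = params.D * 2 / (1 + r)
        e_par = np.column_stack([np.cos(theta0), np.sin(theta0)])
        e_perp = np.column_stack([-np.sin(theta0), np.cos(theta0)])
        a = rng.normal(size=(T - 1, n)) * np.sqrt(2 * D_par * dt)
        b = rng.normal(size=(T - 1, n)) * np.sqrt(2 * D_perp * dt)
        steps = a[..., None] * e_par[None] + b[..., None] * e_perp[None]
        pos = pos0[None] + np.concatenate(
            [np.zeros((1, n, 2)), np.cumsum(steps, axis=0)])
    elif model in ("trap_creep", "clustered"):
        if params.sigma_s <= 0 or params.tau_r <= 0:
            raise ValueError("trap model requires positive sigma_s and tau_r")
        sigma = np.full(n, params.sigma_s)
        if model == "clustered":
            g = _smooth_field(params, rng, pos0)
            sigma = params.sigma_s * np.exp(params.mobility_log_std * g)
            sigma *= params.sigma_s / np.sqrt(np.mean(sigma**2))  # keep mean σ²
        # cage centres: plain Brownian motion with diffusivity D_c
        cs = rng.normal(size=(T - 1, n, 2)) * np.sqrt(2 * params.D_c * dt)
        centre = np.concatenate([np.zeros((1, n, 2)), np.cumsum(cs, axis=0)])
        # intracage fluctuation: exact OU discretization, stationary start
        rho = np.exp(-dt / params.tau_r)
        s = np.empty((T, n, 2))
        s[0] = rng.normal(size=(n, 2)) * sigma[:, None]
        innov = rng.normal(size=(T - 1, n, 2))
        amp = sigma[:, None] * np.sqrt(1 - rho**2)
        for k in range(1, T):
            s[k] = rho * s[k - 1] + amp * innov[k - 1]
        pos = pos0[None] + centre + s
    else:
        raise ValueError(f"unknown model {model!r}")

    if params.theta_diffusion > 0:
        dth = rng.normal(0.0, np.sqrt(2 * params.theta_diffusion * dt),
                         (T - 1, n))
        theta = theta0[None] + np.concatenate(
            [np.zeros((1, n)), np.cumsum(dth, axis=0)])
    else:
        theta = np.broadcast_to(theta0, (T, n)).copy()
    theta = wrap_nematic(theta)

    df = pd.DataFrame({
        "track_id": np.tile(np.arange(n), T),
        "frame": np.repeat(np.arange(T), n),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
        "theta": theta.ravel(),
    })
    if params.include_axes:
        d_long = np.maximum(rng.normal(params.mean_long_axis, 1.0, n), 2.0)
        d_short = np.minimum(
            np.maximum(rng.normal(params.mean_short_axis, 1.0, n), 1.0),
            d_long)
        df["d_long"] = np.tile(d_long, T)
        df["d_short"] = np.tile(d_short, T)
    W = max(params.field_width, float(df["x"].max()))
    H = max(params.field_height, float(df["y"].max()))
    df["x"] -= min(0.0, float(df["x"].min()))
    df["y"] -= min(0.0, float(df["y"].min()))
    W = max(W, float(df["x"].max()))
    H = max(H, float(df["y"].max()))
    return TrackTable(df=df, dt=dt, field_width=W, field_height=H,
                      meta={"model": model, "params": asdict(params)})


def closed_form_tmsd(params: SyntheticParams, dts: np.ndarray) -> np.ndarray:
    """Closed-form TMSD of the trap/creep model on a δt grid (min)."""
    dts = np.asarray(dts, float)
    return (4 * params.D_c * dts
            + 4 * params.sigma_s**2 * (1 - np.exp(-dts / params.tau_r)))


# ---------------------------------------------------------------------------
# division / extrusion events
# ---------------------------------------------------------------------------

def inject_events(
    tracks: TrackTable,
    params: SyntheticParams,
    events: list[EventRecord] | None = None,
) -> tuple[TrackTable, list[EventRecord]]:
    """Overlay transient outward displacement boosts for division/extrusion.

    Events are drawn as Poisson processes in time (rates in events/min)
    at uniform positions inside the nominal field, unless an explicit
    ``events`` list is given.  Each event adds, for frames at time
    t ≥ t_event, a per-frame outward displacement increment of magnitude
    ``A·dt·exp(−d/λ)·exp(−(t−t_event)/τ_b)`` to every cell, where d and the
    outward direction are fixed at the event time, λ is
    ``boost_spatial_scale`` and τ_b is ``boost_time_scale``.  The cumulative
    outward offset therefore saturates at ``A·τ_b·exp(−d/λ)``.  Division
    boosts are modulated by ``(1 + boost_axis_bias·cos 2φ)`` with φ the
    angle from the division axis, so the outflow is strongest along it.
    """
    if not tracks.is_complete():
        raise ValueError("inject_events requires complete tracks")
    rng = np.random.default_rng(params.rng_seed + 1)
    _, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    t_total = times[-1] - times[0]
    W, H = params.field_width, params.field_height

    if events is None:
        events = []
        for kind, rate in (("division", params.division_rate),
                           ("extrusion", params.extrusion_rate)):
            n_ev = rng.poisson(rate * t_total)
            for _ in range(n_ev):
                t_e = float(rng.uniform(times[0], times[-1]))
                x = float(rng.uniform(0, W))
                y = float(rng.uniform(0, H))
                ax = float(rng.uniform(0, np.pi)) if kind == "division" else None
                events.append(EventRecord(kind=kind, t_event=t_e, x=x, y=y,
                                          axis_theta=ax))
        events.sort(key=lambda e: (e.t_event, e.kind, e.x))

    pos = pos.copy()
    kept: list[EventRecord] = []
    cutoff = 5.0 * params.boost_spatial_scale
    for ev in events:
        if not (times[0] <= ev.t_event <= times[-1]):
            warnings.warn(f"event at t={ev.t_event} outside recording window; "
                          "skipped")
            continue
        kept.append(ev)
        if params.boost_amplitude == 0:
            continue
        k0 = int(np.searchsorted(times, ev.t_event))
        tree = cKDTree(pos[k0])
        members = np.asarray(tree.query_ball_point([ev.x, ev.y], cutoff))
        if members.size == 0:
            continue
        rel = pos[k0, members] - np.array([ev.x, ev.y])
        d = np.linalg.norm(rel, axis=1)
        ok = d > 1e-9
        members, rel, d = members[ok], rel[ok], d[ok]
        u = rel / d[:, None]
        amp = params.boost_amplitude * np.exp(-d / params.boost_spatial_scale)
        if ev.kind == "division" and ev.axis_theta is not None \
                and params.boost_axis_bias != 0:
            phi = np.arctan2(rel[:, 1], rel[:, 0]) - ev.axis_theta
            amp = amp * (1 + params.boost_axis_bias * np.cos(2 * phi))
        decay = np.exp(-(times[k0:] - ev.t_event) / params.boost_time_scale)
        incr = tracks.dt * np.cumsum(decay)          # (T-k0,)
        offset = incr[:, None, None] * (amp[:, None] * u)[None]
        pos[k0:, members] += offset

    n = pos.shape[1]
    T = pos.shape[0]
    df = tracks.df.sort_values(["frame", "track_id"]).reset_index(drop=True)
    df = df.copy()
    df["x"] = pos[:, :, 0].ravel()
    df["y"] = pos[:, :, 1].ravel()
    shift_x = min(0.0, float(df["x"].min()))
    shift_y = min(0.0, float(df["y"].min()))
    df["x"] -= shift_x
    df["y"] -= shift_y
    kept = [EventRecord(e.kind, e.t_event, e.x - shift_x, e.y - shift_y,
                        e.axis_theta) for e in kept]
    W2 = max(tracks.field_width, float(df["x"].max()))
    H2 = max(tracks.field_height, float(df["y"].max()))
    out = TrackTable(df=df, dt=tracks.dt, field_width=W2, field_height=H2,
                     meta=dict(tracks.meta))
    return out, kept


def write_ground_truth(params: SyntheticParams, path: str | Path) -> None:
    """JSON sidecar with the generator's ground-truth parameters."""
    Path(path).write_text(json.dumps(asdict(params), indent=2))
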
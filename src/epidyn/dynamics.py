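"""Single-cell dynamics statistics for dense monolayers.

Implements the trajectory-statistics toolkit used to diagnose caging,
creep and dynamic heterogeneity: translational / cage-relative / rotational
mean squared displacements and Einstein-relation diffusivities (including
the direction-resolved variant relative to the nucleus long axis), the self
intermediate scattering function with stretched/compressed-exponential
fits, the self-part of the Van Hove function with Gumbel fit and
non-Gaussian parameter α₂, the displacement autocovariance, conditional
step-memory statistics (d12∥, d12⊥ given d01), and the Gaussian
self-overlap parameter Q_i(a, δt).

All statistics use sliding time origins (maximal overlap averaging) and
report sample counts so Monte-Carlo standard errors are computable.  They
are invariant under global translation; isotropic ones are also invariant
under global rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

from epidyn.tracks import TrackTable, nematic_difference

__all__ = [
    "MSDCurve", "ScatteringSet", "VanHoveSet", "MemorySet", "AutocovSet",
    "OverlapSet", "tmsd", "cage_relative_tmsd", "rotational_msd",
    "diffusion_coefficient", "directional_diffusion",
    "self_intermediate_scattering", "fit_stretched_exponential",
    "van_hove", "fit_gumbel", "gumbel_displacement_pdf",
    "displacement_autocovariance", "conditional_step_stats", "self_overlap",
    "default_lag_grid",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Mean squared displacement curve on a δt grid (min)."""

    dt_min: np.ndarray
    values: np.ndarray            # μm² (or rad² for the rotational variant)
    counts: np.ndarray
    variant: Literal["translational", "cage_relative", "rotational"]
    D: float | None = None        # μm²/min, filled by diffusion_coefficient
    fit_window: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dt_min": self.dt_min, "msd": self.values,
                             "count": self.counts})

    def loglog_slope(self, window: tuple[float, float]) -> float:
        """Log-log slope of the curve inside a δt window (min)."""
        m = (self.dt_min >= window[0]) & (self.dt_min <= window[1]) \
            & (self.values > 0)
        if m.sum() < 2:
            raise ValueError("fewer than 2 grid points in window")
        return float(np.polyfit(np.log(self.dt_min[m]),
                                np.log(self.values[m]), 1)[0])


@dataclass
class ScatteringSet:
    """Self intermediate scattering function Fs(q, δt) and its fits."""

    q: np.ndarray                 # μm⁻¹
    dt_min: np.ndarray
    Fs: np.ndarray                # shape (n_q, n_dt)
    fits: pd.DataFrame | None = None      # per-q τ, β
    tau_exponent: float | None = None     # τ(q) ~ q^−exponent
    tau_exponent_stderr: float | None = None


@dataclass
class VanHoveSet:
    """Self-part of the Van Hove function and non-Gaussian parameter."""

    dt_min: np.ndarray
    bins: np.ndarray              # shared rescaled-δx bin edges (units of σ)
    pdfs: np.ndarray              # (n_dt, n_bins) rescaled PDFs
    sigma: np.ndarray             # σ_x(δt), μm
    alpha2: np.ndarray            # α₂(δt)
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bins[:-1] + self.bins[1:])

    def master_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Count-weighted average of the rescaled PDFs over δt."""
        w = self.counts / self.counts.sum()
        return self.centers, (self.pdfs * w[:, None]).sum(axis=0)


@dataclass
class MemorySet:
    """Conditional statistics of consecutive displacement steps."""

    dt_min: float
    d01_edges: np.ndarray
    d12_edges: np.ndarray
    P_par: np.ndarray             # P(d12∥ | d01), columns normalized
    P_perp: np.ndarray
    mean_par: np.ndarray          # ⟨d12∥⟩ per d01 bin
    mean_perp: np.ndarray
    fwhm_par: np.ndarray
    fwhm_perp: np.ndarray
    counts: np.ndarray

    @property
    def d01_centers(self) -> np.ndarray:
        return 0.5 * (self.d01_edges[:-1] + self.d01_edges[1:])

    def memory_slope(self) -> float:
        """Slope of ⟨d12∥⟩ vs d01 (negative ⇒ anticorrelated, creep-like)."""
        m = self.counts > 0
        return float(np.polyfit(self.d01_centers[m], self.mean_par[m], 1,
                                w=np.sqrt(self.counts[m]))[0])


@dataclass
class AutocovSet:
    """Autocovariance of unit displacement vectors."""

    bin_time: float               # τ, min
    dt_min: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    n_zero_steps: int = 0


@dataclass
class OverlapSet:
    """Per-cell Gaussian self-overlap Q_i(a, δt)."""

    a: float
    dt_min: float
    window: tuple[float, float]
    track_ids: np.ndarray
    Q: np.ndarray

    def mobile_cells(self, fraction: float = 0.10) -> np.ndarray:
        """Track ids of the given fraction with the smallest Q (most mobile)."""
        k = max(1, int(np.ceil(fraction * len(self.Q))))
        order = np.lexsort((self.track_ids, self.Q))
        return self.track_ids[order[:k]]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def default_lag_grid(tracks: TrackTable, n: int = 40) -> np.ndarray:
    """Log-spaced lag grid in frames, 1 .. n_frames−1."""
    T = tracks.n_frames
    lags = np.unique(np.round(np.geomspace(1, T - 1, n)).astype(int))
    return lags


def _lags_in_frames(tracks: TrackTable, lags) -> np.ndarray:
    if lags is None:
        return default_lag_grid(tracks)
    lags = np.atleast_1d(np.asarray(lags))
    if np.issubdtype(lags.dtype, np.floating):
        lags = np.round(lags / tracks.dt).astype(int)
    T = tracks.n_frames
    if np.any(lags >= T):
        warnings.warn("lags beyond record length dropped")
        lags = lags[lags < T]
    lags = lags[lags >= 1]
    if lags.size == 0:
        raise ValueError("no valid lags")
    return np.unique(lags)


# ---------------------------------------------------------------------------
# mean squared displacements
# ---------------------------------------------------------------------------

def tmsd(tracks: TrackTable, lags=None) -> MSDCurve:
    """Translational MSD ⟨|r(t+δt) − r(t)|²⟩ over cells and sliding origins.

    ``lags`` may be lag times in minutes (floats) or frame counts (ints);
    defaults to a log-spaced grid.
    """
    lags = _lags_in_frames(tracks, lags)
    _, _, pos = tracks.position_array()
    vals, counts = [], []
    for lag in lags:
        d = pos[lag:] - pos[:-lag]
        vals.append(float((d ** 2).sum(axis=-1).mean()))
        counts.append(d.shape[0] * d.shape[1])
    return MSDCurve(dt_min=lags * tracks.dt, values=np.array(vals),
                    counts=np.array(counts), variant="translational")


def cage_relative_tmsd(tracks: TrackTable, lags=None,
                       neighbor_cutoff: float = 13.0,
                       origin_stride: int = 1) -> MSDCurve:
    """Cage-relative MSD: each cell's displacement minus the mean
    displacement of its initial neighbors (cells closer than
    ``neighbor_cutoff`` μm at the origin time), removing local collective
    drift before squaring.  Cells with no neighbors keep their own
    displacement.
    """
    lags = _lags_in_frames(tracks, lags)
    _, _, pos = tracks.position_array()
    T, N = pos.shape[:2]
    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    origins = range(0, T - 1, origin_stride)
    for t0 in origins:
        tree = cKDTree(pos[t0])
        pairs = tree.query_pairs(neighbor_cutoff, output_type="ndarray")
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        deg = np.bincount(rows, minlength=N).astype(float)
        for k, lag in enumerate(lags):
            if t0 + lag >= T:
                continue
            disp = pos[t0 + lag] - pos[t0]
            nbr_sum = np.zeros((N, 2))
            np.add.at(nbr_sum, rows, disp[cols])
            mean_nbr = np.where(deg[:, None] > 0,
                                nbr_sum / np.maximum(deg, 1)[:, None], 0.0)
            rel = disp - mean_nbr
            sums[k] += (rel ** 2).sum()
            counts[k] += N
    ok = counts > 0
    return MSDCurve(dt_min=lags[ok] * tracks.dt, values=sums[ok] / counts[ok],
                    counts=counts[ok], variant="cage_relative")


def rotational_msd(tracks: TrackTable, lags=None) -> MSDCurve:
    """Rotational MSD ⟨Δθ(δt)²⟩ of nucleus orientations.

    Per-frame angular steps are taken as nematic differences (mod π,
    mapped to (−π/2, π/2]) and accumulated along each track before
    differencing, i.e. the orientation is unwrapped under the assumption
    that single-frame rotations stay below π/2.
    """
    if not tracks.has_theta:
        raise ValueError("theta column required for rotational MSD")
    lags = _lags_in_frames(tracks, lags)
    th = tracks.value_array("theta")
    steps = nematic_difference(th[1:], th[:-1])
    unwrapped = np.concatenate([np.zeros((1, th.shape[1])),
                                np.cumsum(steps, axis=0)])
    vals, counts = [], []
    for lag in lags:
        d = unwrapped[lag:] - unwrapped[:-lag]
        vals.append(float((d ** 2).mean()))
        counts.append(d.size)
    return MSDCurve(dt_min=lags * tracks.dt, values=np.array(vals),
                    counts=np.array(counts), variant="rotational")


def diffusion_coefficient(msd: MSDCurve,
                          fit_window: tuple[float, float] = (200.0, 400.0),
                          ) -> float:
    """Einstein-relation diffusivity from the MSD slope in ``fit_window``.

    Least-squares line fit of MSD vs δt inside the window; D = slope / 4
    (2D translational convention).  The fitted value is also stored on the
    curve.
    """
    m = (msd.dt_min >= fit_window[0]) & (msd.dt_min <= fit_window[1])
    if m.sum() < 2:
        raise ValueError("fewer than 2 MSD grid points in the fit window")
    slope = np.polyfit(msd.dt_min[m], msd.values[m], 1)[0]
    msd.D = float(slope / 4.0)
    msd.fit_window = fit_window
    return msd.D


def directional_diffusion(tracks: TrackTable,
                          angles: np.ndarray | None = None,
                          lags=None,
                          fit_window: tuple[float, float] = (200.0, 400.0),
                          ) -> pd.DataFrame:
    """Diffusivity vs direction relative to the nucleus long axis.

    Each displacement over δt is projected on the direction at angle φ from
    the cell's long axis at the step start; the 1D MSD = 2·D(φ)·δt is fitted
    in ``fit_window``.  Returns a DataFrame with columns ``phi_rad, D``.
    """
    if not tracks.has_theta:
        raise ValueError("theta column required")
    if angles is None:
        angles = np.linspace(0, np.pi, 13)[:-1]
    lags = _lags_in_frames(tracks, lags)
    _, _, pos = tracks.position_array()
    th = tracks.value_array("theta")
    msd1d = np.zeros((len(angles), len(lags)))
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]                    # (T-lag, N, 2)
        th0 = th[:-lag]
        for a, phi in enumerate(angles):
            ang = th0 + phi
            proj = disp[..., 0] * np.cos(ang) + disp[..., 1] * np.sin(ang)
            msd1d[a, k] = (proj ** 2).mean()
    dts = lags * tracks.dt
    m = (dts >= fit_window[0]) & (dts <= fit_window[1])
    if m.sum() < 2:
        raise ValueError("fewer than 2 grid points in the fit window")
    Ds = [float(np.polyfit(dts[m], msd1d[a, m], 1)[0] / 2.0)
          for a in range(len(angles))]
    return pd.DataFrame({"phi_rad": angles, "D": Ds})


# ---------------------------------------------------------------------------
# intermediate scattering function
# ---------------------------------------------------------------------------

def self_intermediate_scattering(
    tracks: TrackTable,
    q: np.ndarray | None = None,
    lags=None,
    n_directions: int = 12,
    origin_stride: int = 1,
    use_modulus: bool = False,
) -> ScatteringSet:
    """Self intermediate scattering function Fs(q, δt).

    Fs is the real part of ⟨exp(i q·Δr)⟩ averaged over cells, sliding time
    origins and ``n_directions`` equally spaced q directions (the isotropic
    average implied by reporting a scalar q).  With ``use_modulus`` the
    literal one-dimensional form ⟨cos(q·|Δr|)⟩ is computed instead.
    Default q grid: 0.04–0.2 μm⁻¹ in steps of 0.013 μm⁻¹.
    """
    if q is None:
        q = np.arange(0.04, 0.2 + 1e-9, 0.013)
    q = np.asarray(q, float)
    if np.any(q <= 0):
        warnings.warn("non-positive q excluded")
        q = q[q > 0]
    lags = _lags_in_frames(tracks, lags)
    _, _, pos = tracks.position_array()
    dirs = np.linspace(0, np.pi, n_directions, endpoint=False)
    U = np.column_stack([np.cos(dirs), np.sin(dirs)])
    Fs = np.empty((len(q), len(lags)))
    for k, lag in enumerate(lags):
        disp = (pos[lag::origin_stride] - pos[:-lag:origin_stride]
                ).reshape(-1, 2)
        if use_modulus:
            mod = np.linalg.norm(disp, axis=1)
            for j, qv in enumerate(q):
                Fs[j, k] = np.cos(qv * mod).mean()
        else:
            proj = disp @ U.T                            # (M, n_dir)
            for j, qv in enumerate(q):
                Fs[j, k] = np.cos(qv * proj).mean()
    return ScatteringSet(q=q, dt_min=lags * tracks.dt, Fs=Fs)


def fit_stretched_exponential(ss: ScatteringSet,
                              decay_threshold: float = 0.2,
                              beta_bounds: tuple[float, float] = (0.2, 3.0),
                              ) -> ScatteringSet:
    """Fit Fs(q, δt) = exp[−(δt/τ)^β] per q; then τ(q) ~ q^−exponent.

    Only q values whose Fs decays below ``decay_threshold`` within the
    sampled window are fitted (others are excluded and reported with NaN).
    β > 1 signals compressed-exponential, stress-driven relaxation.
    Unweighted least squares on Fs itself; τ initialised at the 1/e
    crossing, β at 1.  The power-law exponent of τ(q) is the negative
    log-log slope, with its standard error.
    """
    t = ss.dt_min
    rows = []
    for j, qv in enumerate(ss.q):
        f = ss.Fs[j]
        if f.min() > decay_threshold:
            rows.append((qv, np.nan, np.nan, False))
            continue
        below = np.nonzero(f <= np.exp(-1.0))[0]
        tau0 = t[below[0]] if below.size else t[-1] / 2

        def model(tt, tau, beta):
            return np.exp(-(tt / tau) ** beta)

        try:
            popt, _ = optimize.curve_fit(
                model, t, f, p0=[tau0, 1.0],
                bounds=([1e-6, beta_bounds[0]], [np.inf, beta_bounds[1]]),
                maxfev=10000)
            rows.append((qv, float(popt[0]), float(popt[1]), True))
        except RuntimeError:
            rows.append((qv, np.nan, np.nan, False))
    fits = pd.DataFrame(rows, columns=["q", "tau", "beta", "converged"])
    ok = fits["converged"] & np.isfinite(fits["tau"])
    if ok.sum() >= 2:
        lx = np.log(fits.loc[ok, "q"].to_numpy())
        ly = np.log(fits.loc[ok, "tau"].to_numpy())
        if ok.sum() >= 3:
            coef, cov = np.polyfit(lx, ly, 1, cov=True)
            ss.tau_exponent_stderr = float(np.sqrt(cov[0, 0]))
        else:
            coef = np.polyfit(lx, ly, 1)
        ss.tau_exponent = float(-coef[0])
    ss.fits = fits
    return ss


# ---------------------------------------------------------------------------
# Van Hove function, Gumbel fit, non-Gaussian parameter
# ---------------------------------------------------------------------------

def van_hove(tracks: TrackTable, lags=None, bins: int = 61,
             extent: float = 6.0, include_y: bool = True) -> VanHoveSet:
    """Self-part of the Van Hove function G_s(δx, δt), rescaled by σ_x(δt).

    Per lag, the PDF of 1D displacements (δx, and δy when ``include_y``)
    is histogrammed after rescaling by the RMS displacement, together with
    the non-Gaussian parameter α₂ = ⟨δx⁴⟩ / (3⟨δx²⟩²) − 1 computed from the
    raw (unbinned) moments.
    """
    lags = _lags_in_frames(tracks, lags)
    _, _, pos = tracks.position_array()
    edges = np.linspace(-extent, extent, bins + 1)
    pdfs, sig, a2, counts = [], [], [], []
    for lag in lags:
        d = pos[lag:] - pos[:-lag]
        dx = d[..., 0].ravel()
        if include_y:
            dx = np.concatenate([dx, d[..., 1].ravel()])
        m2 = np.mean(dx ** 2)
        m4 = np.mean(dx ** 4)
        s = np.sqrt(m2)
        hist, _ = np.histogram(dx / s, bins=edges, density=True)
        pdfs.append(hist)
        sig.append(s)
        a2.append(m4 / (3 * m2 ** 2) - 1.0)
        counts.append(dx.size)
    return VanHoveSet(dt_min=lags * tracks.dt, bins=edges,
                      pdfs=np.array(pdfs), sigma=np.array(sig),
                      alpha2=np.array(a2), counts=np.array(counts))


def gumbel_displacement_pdf(x: np.ndarray, zeta: float) -> np.ndarray:
    """Displacement-form Gumbel density A(ζ)·exp[−|x|/ζ − exp(−|x|/ζ)].

    A(ζ) = 1 / (2ζ(1 − e⁻¹)) normalizes the density on the real line.
    """
    A = 1.0 / (2.0 * zeta * (1.0 - np.exp(-1.0)))
    ax = np.abs(x) / zeta
    return A * np.exp(-ax - np.exp(-ax))


def fit_gumbel(centers: np.ndarray, pdf: np.ndarray,
               fit_range: float = 3.0) -> dict:
    """Fit the Gumbel displacement law to a (rescaled) Van Hove PDF.

    Least squares on ln f over |δx|/σ ≤ ``fit_range`` (bins with positive
    density); the normalization A(ζ) is fixed analytically.  Returns the
    length scale ζ, A(ζ), the rms log-residual of the fit, and the excess
    tail (mean data/fit ratio beyond the fit range) — a Gaussian input
    yields a visibly poor fit (large residual), heavy tails yield
    tail_excess > 1.
    """
    centers = np.asarray(centers, float)
    pdf = np.asarray(pdf, float)
    core = (np.abs(centers) <= fit_range) & (pdf > 0)
    if core.sum() < 5:
        raise ValueError("fewer than 5 usable bins inside the fit range")

    def log_model(x, zeta):
        return np.log(gumbel_displacement_pdf(x, zeta))

    popt, _ = optimize.curve_fit(log_model, centers[core], np.log(pdf[core]),
                                 p0=[1.0], bounds=(1e-3, 100.0))
    zeta = float(popt[0])
    resid = np.log(pdf[core]) - log_model(centers[core], zeta)
    tail = (np.abs(centers) > fit_range) & (pdf > 0)
    tail_excess = (float(np.mean(pdf[tail]
                                 / gumbel_displacement_pdf(centers[tail], zeta)))
                   if tail.any() else np.nan)
    return {
        "zeta": zeta,
        "A": float(1.0 / (2.0 * zeta * (1.0 - np.exp(-1.0)))),
        "log_rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "tail_excess": tail_excess,
    }


# ---------------------------------------------------------------------------
# displacement memory
# ---------------------------------------------------------------------------

def displacement_autocovariance(tracks: TrackTable, bin_time: float = 10.0,
                                lags=None) -> AutocovSet:
    """Autocovariance C_τ(δt) = ⟨û(δt)·û(0)⟩ of unit displacement vectors.

    Steps are displacements over the bin time τ; zero-length steps are
    excluded from the average and counted.  Negative values at short lags
    are the signature of anticorrelated, creep-like motion.
    """
    m = int(round(bin_time / tracks.dt))
    if abs(m * tracks.dt - bin_time) > 1e-9 or m < 1:
        raise ValueError("bin_time must be a positive multiple of the frame "
                         "interval")
    _, _, pos = tracks.position_array()
    steps = pos[m:] - pos[:-m]                            # (T-m, N, 2)
    norm = np.linalg.norm(steps, axis=-1)
    nonzero = norm > 0
    n_zero = int((~nonzero).sum())
    unit = np.where(nonzero[..., None], steps / np.where(
        nonzero, norm, 1.0)[..., None], np.nan)
    S = unit.shape[0]
    if lags is None:
        lag_frames = np.unique(np.round(
            np.geomspace(1, max(S - 1, 1), 30)).astype(int))
        lag_frames = np.concatenate([[0], lag_frames[lag_frames < S]])
    else:
        lag_frames = np.asarray(lags)
        if np.issubdtype(lag_frames.dtype, np.floating):
            lag_frames = np.round(lag_frames / tracks.dt).astype(int)
        lag_frames = np.unique(lag_frames[(lag_frames >= 0)
                                          & (lag_frames < S)])
    vals, counts = [], []
    for lag in lag_frames:
        if lag == 0:
            prod = np.ones_like(norm)
            prod[~nonzero] = np.nan
        else:
            prod = (unit[lag:] * unit[:-lag]).sum(axis=-1)
        vals.append(float(np.nanmean(prod)))
        counts.append(int(np.isfinite(prod).sum()))
    return AutocovSet(bin_time=bin_time, dt_min=lag_frames * tracks.dt,
                      values=np.array(vals), counts=np.array(counts),
                      n_zero_steps=n_zero)


def conditional_step_stats(tracks: TrackTable, dt_step: float = 10.0,
                           n_d01_bins: int = 12,
                           n_d12_bins: int = 61) -> MemorySet:
    """Conditional statistics of consecutive steps: P(d12∥|d01), P(d12⊥|d01).

    For every sliding pair of consecutive displacements over ``dt_step``
    (intervals [t, t+δt] and [t+δt, t+2δt]), d01 is the first step length
    and d12∥ / d12⊥ the second step's projections on / perpendicular to the
    first step's direction.  Columns of the conditional histograms are
    normalized to unit integral; per-column means and the moment-based
    FWHM = 2√(2 ln 2)·√m₂ are reported.  Pairs with d01 = 0 are excluded.
    """
    m = int(round(dt_step / tracks.dt))
    if m < 1:
        raise ValueError("dt_step below the frame interval")
    _, _, pos = tracks.position_array()
    T = pos.shape[0]
    if T < 2 * m + 1:
        raise ValueError("record shorter than 2·δt")
    s1 = pos[m:T - m] - pos[:T - 2 * m]
    s2 = pos[2 * m:] - pos[m:T - m]
    d01 = np.linalg.norm(s1, axis=-1).ravel()
    keep = d01 > 0
    e = (s1 / np.maximum(np.linalg.norm(s1, axis=-1), 1e-300)[..., None])
    e = e.reshape(-1, 2)[keep]
    s2 = s2.reshape(-1, 2)[keep]
    d01 = d01[keep]
    par = (s2 * e).sum(axis=-1)
    perp = s2[:, 0] * (-e[:, 1]) + s2[:, 1] * e[:, 0]
    d01_edges = np.linspace(0, np.quantile(d01, 0.995), n_d01_bins + 1)
    lim = np.quantile(np.abs(par), 0.999)
    d12_edges = np.linspace(-lim, lim, n_d12_bins + 1)

    def conditional(v):
        H, _, _ = np.histogram2d(d01, v, bins=[d01_edges, d12_edges])
        col = H.sum(axis=1, keepdims=True)
        width = np.diff(d12_edges)
        P = np.where(col > 0, H / np.maximum(col, 1) / width, 0.0)
        centers = 0.5 * (d12_edges[:-1] + d12_edges[1:])
        means = np.where(col[:, 0] > 0,
                         (H * centers).sum(axis=1) / np.maximum(col[:, 0], 1),
                         np.nan)
        m2 = np.where(
            col[:, 0] > 0,
            (H * (centers[None, :] - np.nan_to_num(means)[:, None]) ** 2
             ).sum(axis=1) / np.maximum(col[:, 0], 1),
            np.nan)
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * np.sqrt(m2)
        return P, means, fwhm, col[:, 0].astype(int)

    P_par, mean_par, fwhm_par, counts = conditional(par)
    P_perp, mean_perp, fwhm_perp, _ = conditional(perp)
    return MemorySet(dt_min=m * tracks.dt, d01_edges=d01_edges,
                     d12_edges=d12_edges, P_par=P_par, P_perp=P_perp,
                     mean_par=mean_par, mean_perp=mean_perp,
                     fwhm_par=fwhm_par, fwhm_perp=fwhm_perp, counts=counts)


# ---------------------------------------------------------------------------
# self-overlap
# ---------------------------------------------------------------------------

def self_overlap(tracks: TrackTable, a: float = 1.2, dt_lag: float = 200.0,
                 window: tuple[float, float] = (105.0, 1625.0)) -> OverlapSet:
    """Per-cell self-overlap Q_i(a, δt) = ⟨exp(−|Δr(δt)|² / 2a²)⟩_t.

    Averaged over time origins t inside ``window`` (min); origins whose
    endpoint t+δt falls outside the record are dropped.  Q_i = 1 for a
    static cell and → 0 once the cell has moved beyond the probe length a.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if window[1] - window[0] < dt_lag:
        raise ValueError("averaging window shorter than the lag")
    m = int(round(dt_lag / tracks.dt))
    ids, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    T = pos.shape[0]
    origin_ok = ((times >= window[0]) & (times <= window[1])
                 & (np.arange(T) + m < T))
    idx = np.nonzero(origin_ok)[0]
    if idx.size == 0:
        raise ValueError("no valid time origins in the averaging window")
    d2 = ((pos[idx + m] - pos[idx]) ** 2).sum(axis=-1)    # (n_origin, N)
    Q = np.exp(-d2 / (2.0 * a ** 2)).mean(axis=0)
    return OverlapSet(a=a, dt_min=m * tracks.dt, window=window,
                      track_ids=ids, Q=Q)
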
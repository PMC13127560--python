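"""Fast-cell clusters: identification, size statistics, shape, correlations.

The most mobile cells (top fraction by displacement magnitude over a lag
δt, default 10%) are grouped into clusters by transitive closure of a
neighbor relation (pair distance below a cutoff r*, default 15 μm — the
first valley of the radial distribution function of a dense monolayer).
Cluster morphology is summarised by the gyration (inertia) tensor: the
characteristic diameter D_c = 2√(Tr M / N_c) and the principal-frame
anisotropy ξ_c = (λ₁ − λ₂)/(λ₁ + λ₂) ∈ [0, 1] (1 for a line, 0 for a
disk).  Cluster sizes follow a truncated power law
P(N_c) = A·N_c^−c·exp(−N_c/N_c*), fitted by discrete maximum likelihood,
and size scales with diameter as N_c ∝ D_c^{d_f} (fractal dimension).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from epidyn.tracks import TrackTable

__all__ = [
    "select_fast_cells", "build_clusters", "cluster_shape", "cluster_table",
    "pooled_cluster_sizes", "mean_cluster_size_curve",
    "truncated_powerlaw_pmf", "sample_truncated_powerlaw",
    "size_distribution_fit", "fractal_dimension",
    "velocity_correlation_aligned",
]


# ---------------------------------------------------------------------------
# selection and clustering
# ---------------------------------------------------------------------------

def select_fast_cells(tracks: TrackTable, t: float, dt_lag: float,
                      fraction: float = 0.10) -> np.ndarray:
    """Indices (into the sorted track-id order) of the top-``fraction``
    most mobile cells over [t, t + δt].

    Exactly ⌈fraction·N⌉ cells are selected, ranked by displacement
    magnitude with ties broken by track id for determinism.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    k0 = int(np.argmin(np.abs(times - t)))
    k1 = int(np.argmin(np.abs(times - (t + dt_lag))))
    if k1 >= len(times) or k1 == k0:
        raise ValueError("t + δt outside the record")
    d = np.linalg.norm(pos[k1] - pos[k0], axis=1)
    n_fast = int(np.ceil(fraction * len(ids)))
    order = np.lexsort((ids, -d))                # fastest first, ties by id
    return np.sort(order[:n_fast])


def build_clusters(points: np.ndarray, r_star: float = 15.0) -> np.ndarray:
    """Connected components of the graph linking points closer than r*.

    Returns an integer label per point; labels enumerate clusters.
    """
    if r_star <= 0:
        raise ValueError("r_star must be positive")
    points = np.asarray(points, float)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    pairs = cKDTree(points).query_pairs(r_star, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_shape(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Gyration tensor M_ab = Σ_i (r_a − r̄_a)(r_b − r̄_b) of one cluster,
    with diameter D_c = 2√(Tr M / N_c) and principal-frame anisotropy
    ξ_c = (λ₁ − λ₂)/(λ₁ + λ₂)."""
    points = np.asarray(points, float)
    if len(points) < 2:
        raise ValueError("shape statistics need at least 2 points")
    rel = points - points.mean(axis=0)
    M = rel.T @ rel
    lam = np.sort(np.linalg.eigvalsh(M))[::-1]
    Dc = 2.0 * np.sqrt(np.trace(M) / len(points))
    xi = float((lam[0] - lam[1]) / (lam[0] + lam[1])) if lam.sum() > 0 else 0.0
    return M, float(Dc), xi


def cluster_table(points: np.ndarray, labels: np.ndarray,
                  min_size_shape: int = 2) -> pd.DataFrame:
    """Per-cluster summary: size, centroid, and (when N_c ≥ min_size_shape)
    diameter and anisotropy."""
    rows = []
    for lab in np.unique(labels):
        p = points[labels == lab]
        if len(p) >= min_size_shape:
            _, Dc, xi = cluster_shape(p)
        else:
            Dc, xi = np.nan, np.nan
        rows.append((int(lab), len(p), p[:, 0].mean(), p[:, 1].mean(),
                     Dc, xi))
    return pd.DataFrame(rows, columns=["cluster", "n_cells", "cx", "cy",
                                       "Dc", "xi"])


def pooled_cluster_sizes(tracks: TrackTable, dt_lag: float,
                         fraction: float = 0.10, r_star: float = 15.0,
                         origin_stride: int = 1) -> pd.DataFrame:
    """Cluster tables pooled over sliding time origins at one lag."""
    _, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    m = int(round(dt_lag / tracks.dt))
    out = []
    for k0 in range(0, len(times) - m, origin_stride):
        fast = select_fast_cells(tracks, times[k0], dt_lag, fraction)
        pts = pos[k0, fast]
        labels = build_clusters(pts, r_star)
        tab = cluster_table(pts, labels)
        tab.insert(0, "t", times[k0])
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def mean_cluster_size_curve(tracks: TrackTable, lags_min,
                            fraction: float = 0.10, r_star: float = 15.0,
                            origin_stride: int = 5) -> pd.DataFrame:
    """⟨N_c⟩ (mean fast-cluster size) as a function of lag δt."""
    rows = []
    for dt_lag in np.atleast_1d(lags_min):
        tab = pooled_cluster_sizes(tracks, float(dt_lag), fraction, r_star,
                                   origin_stride)
        rows.append((float(dt_lag), float(tab["n_cells"].mean()),
                     len(tab)))
    return pd.DataFrame(rows, columns=["dt_min", "mean_Nc", "n_clusters"])


# ---------------------------------------------------------------------------
# truncated power-law size distribution
# ---------------------------------------------------------------------------

def truncated_powerlaw_pmf(n: np.ndarray, c: float, n_star: float,
                           n_max: int = 100000) -> np.ndarray:
    """P(N_c) = A·N_c^−c·exp(−N_c/N_c*), normalized over N_c = 1..∞.

    The normalizing sum is truncated adaptively; with the exponential
    cutoff the truncation error is below 1e-12 for n_max ≫ N_c*.
    """
    kmax = min(n_max, max(1000, int(50 * n_star)))
    k = np.arange(1, kmax + 1)
    w = k ** (-c) * np.exp(-k / n_star)
    A = 1.0 / w.sum()
    n = np.asarray(n)
    return A * n ** (-c) * np.exp(-n / n_star)


def sample_truncated_powerlaw(size: int, c: float, n_star: float,
                              rng: np.random.Generator,
                              n_max: int = 10000) -> np.ndarray:
    """Draw cluster sizes from the discrete truncated power law."""
    k = np.arange(1, n_max + 1)
    p = truncated_powerlaw_pmf(k, c, n_star, n_max)
    p = p / p.sum()
    return rng.choice(k, size=size, p=p)


def size_distribution_fit(sizes: np.ndarray,
                          c0: float = 1.5, n_star0: float = 10.0) -> dict:
    """Maximum-likelihood fit of P(N_c) = A·N_c^−c·exp(−N_c/N_c*).

    Discrete MLE over (c, N_c*) with A fixed by normalization over
    N_c = 1..∞ (singletons included).  Returns the parameters, A, the
    log-likelihood, and the sample size.
    """
    sizes = np.asarray(sizes, int)
    if len(sizes) == 0:
        raise ValueError("no cluster sizes")
    if sizes.min() < 1:
        raise ValueError("cluster sizes must be ≥ 1")
    if np.all(sizes == sizes[0]):
        raise ValueError("degenerate fit: all clusters have the same size")
    vals, counts = np.unique(sizes, return_counts=True)

    def nll(theta):
        c, log_ns = theta
        p = truncated_powerlaw_pmf(vals, c, np.exp(log_ns))
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            return 1e12
        return -float((counts * np.log(p)).sum())

    res = optimize.minimize(nll, x0=[c0, np.log(n_star0)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    c_hat = float(res.x[0])
    n_star_hat = float(np.exp(res.x[1]))
    A = float(truncated_powerlaw_pmf(np.array([1]), c_hat, n_star_hat)[0]
              * 1.0 ** c_hat * np.exp(1.0 / n_star_hat))
    return {"c": c_hat, "n_star": n_star_hat, "A": A,
            "loglik": -float(res.fun), "n_samples": int(len(sizes)),
            "converged": bool(res.success)}


def fractal_dimension(cluster_tab: pd.DataFrame,
                      min_size: int = 5) -> tuple[float, float]:
    """Fractal dimension d_f from N_c ∝ D_c^{d_f} (log-log LSQ slope).

    Only clusters with N_c > min_size enter (shape statistics are noisy
    below); returns (d_f, standard error).
    """
    tab = cluster_tab[(cluster_tab["n_cells"] > min_size)
                      & np.isfinite(cluster_tab["Dc"])
                      & (cluster_tab["Dc"] > 0)]
    if len(tab) < 3:
        raise ValueError("need at least 3 clusters above the size cut")
    lx = np.log(tab["Dc"].to_numpy())
    ly = np.log(tab["n_cells"].to_numpy())
    coef, cov = np.polyfit(lx, ly, 1, cov=True)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


# ---------------------------------------------------------------------------
# aligned velocity correlation maps
# ---------------------------------------------------------------------------

def velocity_correlation_aligned(
    tracks: TrackTable, dt_lag: float,
    population: str = "all",
    half_extent: float = 60.0, bin_width: float = 4.0,
    fraction: float = 0.10, r_star: float = 15.0,
    min_cluster_size: int = 5,
    origin_stride: int = 10,
) -> dict:
    """2D velocity correlation map in the velocity-aligned frame.

    Velocities are displacements over δt.  For each reference cell the
    separations to the other cells of the population are rotated so the
    reference velocity points along +x_v; C_v(δr) = ⟨v_ref·v_nbr⟩ binned
    on the grid and normalized by ⟨|v|²⟩ of the population, so the origin
    is 1.  ``population`` is ``"all"`` or ``"fast_clusters"`` (cells in
    fast clusters with N_c > min_cluster_size).  Zero-velocity references
    are excluded.
    """
    if population not in ("all", "fast_clusters"):
        raise ValueError("population must be 'all' or 'fast_clusters'")
    _, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    m = int(round(dt_lag / tracks.dt))
    nb = int(np.ceil(2 * half_extent / bin_width))
    edges = np.linspace(-half_extent, half_extent, nb + 1)
    num = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb))
    v2_sum, v2_n = 0.0, 0
    for k0 in range(0, len(times) - m, origin_stride):
        vel = (pos[k0 + m] - pos[k0]) / (m * tracks.dt)
        pts = pos[k0]
        if population == "fast_clusters":
            fast = select_fast_cells(tracks, times[k0], dt_lag, fraction)
            labels = build_clusters(pts[fast], r_star)
            sizes = np.bincount(labels)
            keep = fast[sizes[labels] > min_cluster_size]
            if keep.size < 2:
                continue
            pts, vel = pts[keep], vel[keep]
        speed = np.linalg.norm(vel, axis=1)
        ok = speed > 0
        v2_sum += float((speed[ok] ** 2).sum())
        v2_n += int(ok.sum())
        refs = np.nonzero(ok)[0]
        tree = cKDTree(pts)
        rad = half_extent * np.sqrt(2.0)
        for i in refs:
            idx = np.array(tree.query_ball_point(pts[i], rad))
            idx = idx[idx != i]
            if idx.size == 0:
                continue
            rel = pts[idx] - pts[i]
            e = vel[i] / speed[i]
            xr = rel[:, 0] * e[0] + rel[:, 1] * e[1]
            yr = -rel[:, 0] * e[1] + rel[:, 1] * e[0]
            corr = vel[idx] @ vel[i]
            H, _, _ = np.histogram2d(yr, xr, bins=[edges, edges])
            Hw, _, _ = np.histogram2d(yr, xr, bins=[edges, edges],
                                      weights=corr)
            num += Hw
            cnt += H
    v2 = v2_sum / max(v2_n, 1)
    with np.errstate(invalid="ignore"):
        Cv = np.where(cnt > 0, num / np.maximum(cnt, 1) / v2, np.nan)
    # the origin bin is the reference itself: C_v(0) = 1 by normalization
    i0 = nb // 2
    Cv[i0, i0] = 1.0
    return {"edges": edges, "C": Cv, "population": population,
            "v2_mean": v2, "dt_min": float(m * tracks.dt)}
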
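"""Soft (low-frequency) modes from the displacement covariance matrix.

Early-time position fluctuations u_k = (x_k − ⟨x_k⟩_t, y_k − ⟨y_k⟩_t)
over an analysis window T₁ (default the first 100 min) define the 2N × 2N
covariance D_kl = ⟨u_k u_l⟩_t.  Its large-eigenvalue eigenmodes are the
low-frequency (soft) modes, ω_k = 1/√λ_k; the per-cell mean magnitude ⟨M⟩
over the n lowest-frequency modes marks mechanically compliant regions.
Correlating ⟨M⟩ (and structural fields) with the self-overlap parameter
computed on a disjoint later window T₂ tests whether softness predicts
subsequent rearrangements.

The spectrum is computed from the economy SVD of the (T × 2N) fluctuation
matrix — identical eigenpairs to diagonalising D (whose rank is at most
the number of frames) without materialising the 2N × 2N matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from epidyn.tracks import TrackTable
from epidyn.dynamics import OverlapSet

__all__ = ["ModeSet", "displacement_covariance", "eigenmodes",
           "mode_overlap_correlation"]


@dataclass
class ModeSet:
    """Eigenpairs of the displacement covariance and per-cell magnitudes."""

    track_ids: np.ndarray
    window: tuple[float, float]            # T₁ in min
    eigenvalues: np.ndarray                # descending, length n_modes
    modes: np.ndarray                      # (n_modes, 2N), orthonormal rows
    mean_magnitude: np.ndarray             # ⟨M⟩ per cell

    @property
    def frequencies(self) -> np.ndarray:
        """Mode frequencies ω = 1/√λ (low frequency = soft = large λ)."""
        return 1.0 / np.sqrt(self.eigenvalues)

    def magnitude(self, k: int) -> np.ndarray:
        """Per-cell magnitude |M_k,i| = √(M_kx,i² + M_ky,i²) of mode k."""
        m = self.modes[k].reshape(-1, 2)
        return np.linalg.norm(m, axis=1)


def _fluctuations(tracks: TrackTable, window: tuple[float, float]
                  ) -> tuple[np.ndarray, np.ndarray]:
    ids, frames, pos = tracks.position_array()
    times = frames * tracks.dt
    sel = (times >= window[0]) & (times <= window[1])
    if sel.sum() < 3:
        raise ValueError("analysis window must contain at least 3 frames")
    p = pos[sel]                                   # (T, N, 2)
    u = p - p.mean(axis=0, keepdims=True)
    return ids, u.reshape(u.shape[0], -1)          # (T, 2N)


def displacement_covariance(tracks: TrackTable,
                            window: tuple[float, float] = (0.0, 100.0)
                            ) -> np.ndarray:
    """Full covariance D_kl = ⟨u_k u_l⟩_t over the window (biased 1/T).

    Intended for small N (validation, reconstruction checks); the mode
    analysis itself never needs the dense matrix.
    """
    _, u = _fluctuations(tracks, window)
    return (u.T @ u) / u.shape[0]


def eigenmodes(tracks: TrackTable, n_modes: int = 10,
               window: tuple[float, float] = (0.0, 100.0),
               weight_by_eigenvalue: bool = False) -> ModeSet:
    """Top-``n_modes`` eigenpairs of the displacement covariance.

    Modes are ranked by descending eigenvalue (ascending frequency
    ω = 1/√λ); ⟨M⟩_i is the per-cell mean of the mode magnitudes
    |M_k,i| over those modes (unweighted by default; eigenvalue-weighted
    behind the flag).  Mode signs are arbitrary and never interpreted.
    """
    ids, u = _fluctuations(tracks, window)
    T, two_n = u.shape
    if n_modes > two_n:
        raise ValueError("n_modes exceeds the number of coordinates")
    # economy SVD: u = U S Vt  ⇒  D = Vtᵀ (S²/T) Vt
    _, s, vt = np.linalg.svd(u, full_matrices=False)
    lam = s ** 2 / T
    k = min(n_modes, len(lam))
    lam, vt = lam[:k], vt[:k]
    mags = np.linalg.norm(vt.reshape(k, -1, 2), axis=2)   # (k, N)
    if weight_by_eigenvalue:
        w = lam / lam.sum()
        mean_mag = (mags * w[:, None]).sum(axis=0)
    else:
        mean_mag = mags.mean(axis=0)
    return ModeSet(track_ids=ids, window=window, eigenvalues=lam,
                   modes=vt, mean_magnitude=mean_mag)


def mode_overlap_correlation(mode_set: ModeSet, overlap: OverlapSet,
                             structure_fields: dict[str, np.ndarray]
                             | None = None,
                             mobile_fraction: float = 0.10) -> dict:
    """Pearson correlation of Q_i with ⟨M⟩ and per-cell structural fields.

    Enforces the disjoint-window protocol: the covariance window T₁ must
    not overlap the overlap-averaging window T₂ (otherwise the prediction
    would be circular).  Cells with NaN in a field are dropped pairwise.
    Also returns the track ids of the most mobile cells (smallest Q) for
    map overlays.
    """
    t1 = mode_set.window
    t2 = overlap.window
    if not (t1[1] < t2[0] or t2[1] < t1[0]):
        raise ValueError(
            f"windows overlap: T1={t1} vs T2={t2}; the soft-mode/overlap "
            "correlation requires disjoint windows")
    if not np.array_equal(mode_set.track_ids, overlap.track_ids):
        raise ValueError("mode set and overlap set cover different cells")
    fields = {"mean_mode_magnitude": mode_set.mean_magnitude}
    if structure_fields:
        fields.update(structure_fields)
    out = {"windows": {"T1": t1, "T2": t2},
           "mobile_cells": overlap.mobile_cells(mobile_fraction).tolist(),
           "pearson": {}, "pvalues": {}}
    Q = overlap.Q
    for name, v in fields.items():
        v = np.asarray(v, float)
        if v.shape != Q.shape:
            raise ValueError(f"field {name!r} is not aligned with Q")
        m = np.isfinite(v) & np.isfinite(Q)
        if m.sum() < 3 or np.std(v[m]) == 0 or np.std(Q[m]) == 0:
            out["pearson"][name] = float("nan")
            continue
        r, p = stats.pearsonr(v[m], Q[m])
        out["pearson"][name] = float(r)
        out["pvalues"][name] = float(p)
    return out
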
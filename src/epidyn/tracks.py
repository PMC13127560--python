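"""Data model for tracked nuclei: tables, readers/writers, QC filters.

A :class:`TrackTable` is a tidy per-(track, frame) table of nucleus centroid
positions (μm), optional long-axis orientation (nematic, radians in [0, π))
and optional long/short axis lengths (μm), on a uniform frame grid with a
fixed frame interval (default 5 min).  All downstream statistics operate on
differences of positions and angles, so the coordinate convention (origin at
the field's top-left, y downward, image convention) never enters results.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackTable",
    "EventRecord",
    "SchemaError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "write_events",
    "read_events",
    "filter_complete_tracks",
    "estimate_static_noise",
    "shape_change_stats",
    "wrap_nematic",
    "nematic_difference",
]

CORE_COLUMNS = ("track_id", "frame", "x", "y")
OPTIONAL_COLUMNS = ("theta", "d_long", "d_short")


class SchemaError(ValueError):
    """A file does not match the expected dialect schema."""


class ValidationError(ValueError):
    """A table violates a TrackTable invariant."""


def wrap_nematic(theta: np.ndarray) -> np.ndarray:
    """Wrap orientations into the nematic fundamental domain [0, π)."""
    return np.mod(theta, np.pi)


def nematic_difference(theta_b, theta_a):
    """Signed nematic angular difference theta_b − theta_a in (−π/2, π/2]."""
    d = np.mod(np.asarray(theta_b) - np.asarray(theta_a), np.pi)
    return np.where(d > np.pi / 2, d - np.pi, d)


@dataclass(frozen=True)
class EventRecord:
    """A division or extrusion event.

    Parameters
    ----------
    kind : {"division", "extrusion"}
    t_event : float
        Event time in minutes.
    x, y : float
        Event position in μm.
    axis_theta : float or None
        Division-axis orientation in radians (the condensed-chromosome long
        axis); typically None for extrusions.
    """

    kind: Literal["division", "extrusion"]
    t_event: float
    x: float
    y: float
    axis_theta: float | None = None


@dataclass
class TrackTable:
    """Tidy table of tracked nuclei on a uniform frame grid.

    ``df`` holds columns ``track_id, frame, x, y`` and optionally
    ``theta, d_long, d_short``.  Time in minutes is ``frame * dt``.
    """

    df: pd.DataFrame
    dt: float = 5.0
    field_width: float = 828.0
    field_height: float = 621.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        if self.dt <= 0:
            raise ValidationError("frame interval dt must be positive")
        if len(df) and df.duplicated(["track_id", "frame"]).any():
            dup = df[df.duplicated(["track_id", "frame"], keep=False)]
            raise ValidationError(
                "duplicate (track_id, frame) pairs, e.g. "
                f"{dup[['track_id', 'frame']].iloc[0].tolist()}"
            )
        if len(df):
            frames = np.sort(df["frame"].unique())
            if len(frames) > 1:
                gaps = np.diff(frames)
                if not np.all(gaps == gaps[0]):
                    bad = frames[1:][gaps != gaps[0]]
                    raise ValidationError(
                        f"non-uniform frame spacing at frames {bad[:5].tolist()}"
                    )
            if (df["x"].min() < 0 or df["x"].max() > self.field_width
                    or df["y"].min() < 0 or df["y"].max() > self.field_height):
                raise ValidationError("positions outside the field bounds")
        if "theta" in df.columns and len(df):
            th = df["theta"].to_numpy(float)
            ok = np.isnan(th) | ((th >= 0) & (th < np.pi))
            if not ok.all():
                raise ValidationError("theta must lie in [0, π) (nematic)")
        if "d_long" in df.columns and "d_short" in df.columns and len(df):
            dl = df["d_long"].to_numpy(float)
            ds = df["d_short"].to_numpy(float)
            m = ~(np.isnan(dl) | np.isnan(ds))
            if np.any(dl[m] < ds[m]) or np.any(ds[m] <= 0):
                raise ValidationError("require d_long ≥ d_short > 0")

    # -- conveniences ----------------------------------------------------
    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    @property
    def track_ids(self) -> np.ndarray:
        return np.sort(self.df["track_id"].unique())

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def n_frames(self) -> int:
        return self.df["frame"].nunique()

    @property
    def times(self) -> np.ndarray:
        """Times (min) of the frame grid."""
        return self.frames * self.dt

    @property
    def has_theta(self) -> bool:
        return "theta" in self.df.columns and self.df["theta"].notna().any()

    @property
    def has_axes(self) -> bool:
        return ("d_long" in self.df.columns and "d_short" in self.df.columns
                and self.df["d_long"].notna().any())

    def is_complete(self) -> bool:
        counts = self.df.groupby("track_id")["frame"].nunique()
        return bool((counts == self.n_frames).all())

    def position_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense arrays for complete tables.

        Returns ``(track_ids, frames, pos)`` with ``pos`` of shape
        (n_frames, n_tracks, 2).  Requires every track present at every frame.
        """
        if not self.is_complete():
            raise ValidationError(
                "position_array requires complete tracks; "
                "apply filter_complete_tracks first"
            )
        d = self.df.sort_values(["frame", "track_id"])
        T, N = self.n_frames, self.n_tracks
        pos = d[["x", "y"]].to_numpy(float).reshape(T, N, 2)
        return self.track_ids, self.frames, pos

    def value_array(self, column: str) -> np.ndarray:
        """Dense (n_frames, n_tracks) array of one column (complete tables)."""
        if not self.is_complete():
            raise ValidationError("value_array requires complete tracks")
        d = self.df.sort_values(["frame", "track_id"])
        return d[column].to_numpy(float).reshape(self.n_frames, self.n_tracks)

    def frame_slice(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def copy_with(self, df: pd.DataFrame) -> "TrackTable":
        return replace(self, df=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRACKMATE_COLMAP = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "ELLIPSE_THETA": "theta",
    "ELLIPSE_MAJOR": "d_long",
    "ELLIPSE_MINOR": "d_short",
}


def read_tracks(
    path: str | Path,
    dialect: Literal["plain_csv", "trackmate_csv", "trackmate_xml"] = "plain_csv",
    dt: float = 5.0,
    field_width: float | None = None,
    field_height: float | None = None,
    position_scale: float = 1.0,
) -> TrackTable:
    """Read a tracked-nuclei file into a :class:`TrackTable`.

    ``position_scale`` multiplies raw coordinates to convert them to μm
    (1.0 when the export is already calibrated in μm).  Field dimensions
    default to the data's bounding box when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain_csv":
        df = _read_plain_csv(path)
    elif dialect == "trackmate_csv":
        df = _read_trackmate_csv(path)
    elif dialect == "trackmate_xml":
        df = _read_trackmate_xml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["x"] *= position_scale
    df["y"] *= position_scale
    if "d_long" in df.columns:
        df["d_long"] *= position_scale
        df["d_short"] *= position_scale
    if "theta" in df.columns:
        df["theta"] = wrap_nematic(df["theta"].to_numpy(float))
    w = field_width if field_width is not None else float(df["x"].max())
    h = field_height if field_height is not None else float(df["y"].max())
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackTable(df=df, dt=dt, field_width=w, field_height=h)


def _read_plain_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rename = {"x_um": "x", "y_um": "y", "theta_rad": "theta",
              "long_um": "d_long", "short_um": "d_short"}
    df = df.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"plain CSV {path.name}: missing columns {missing}; expected "
            "track_id,frame,x_um,y_um[,theta_rad,long_um,short_um]"
        )
    keep = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].astype({"track_id": int, "frame": int})
    return df


def _read_trackmate_csv(path: Path) -> pd.DataFrame:
    # TrackMate spot tables carry up to three extra header rows (names,
    # units, dimensions); keep only rows with a numeric FRAME.
    raw = pd.read_csv(path, dtype=str)
    if "TRACK_ID" not in raw.columns or "POSITION_X" not in raw.columns:
        raise SchemaError(
            f"TrackMate CSV {path.name}: expected TRACK_ID/POSITION_X/"
            "POSITION_Y/FRAME columns"
        )
    numeric = pd.to_numeric(raw["FRAME"], errors="coerce").notna()
    raw = raw[numeric]
    cols = {src: dst for src, dst in _TRACKMATE_COLMAP.items() if src in raw.columns}
    df = raw[list(cols)].rename(columns=cols)
    df = df.apply(pd.to_numeric, errors="coerce")
    df = df.dropna(subset=["track_id", "frame", "x", "y"])
    return df.astype({"track_id": int, "frame": int}).reset_index(drop=True)


def _read_trackmate_xml(path: Path) -> pd.DataFrame:
    """TrackMate model XML: spots from AllSpots, linkage from AllTracks edges.

    Gaps are kept as missing frames (never interpolated); gapped tracks are
    dropped later by :func:`filter_complete_tracks`.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise SchemaError(f"{path.name}: no <Model> element")
    spots: dict[int, tuple[int, float, float]] = {}
    all_spots = model.find("AllSpots")
    if all_spots is None:
        raise SchemaError(f"{path.name}: no <AllSpots> element")
    for sif in all_spots.findall("SpotsInFrame"):
        for sp in sif.findall("Spot"):
            sid = int(sp.attrib["ID"])
            spots[sid] = (
                int(float(sp.attrib["FRAME"])),
                float(sp.attrib["POSITION_X"]),
                float(sp.attrib["POSITION_Y"]),
            )
    rows = []
    all_tracks = model.find("AllTracks")
    if all_tracks is None:
        raise SchemaError(f"{path.name}: no <AllTracks> element")
    for tr in all_tracks.findall("Track"):
        tid = int(tr.attrib["TRACK_ID"])
        members: set[int] = set()
        for edge in tr.findall("Edge"):
            members.add(int(edge.attrib["SPOT_SOURCE_ID"]))
            members.add(int(edge.attrib["SPOT_TARGET_ID"]))
        for sid in members:
            f, x, y = spots[sid]
            rows.append((tid, f, x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    return df.drop_duplicates(["track_id", "frame"]).reset_index(drop=True)


def write_tracks(tracks: TrackTable, path: str | Path) -> None:
    """Write a TrackTable as plain CSV (the package's canonical dialect)."""
    df = tracks.df.copy()
    rename = {"x": "x_um", "y": "y_um", "theta": "theta_rad",
              "d_long": "long_um", "d_short": "short_um"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    df.to_csv(path, index=False)


def write_events(events: Sequence[EventRecord], path: str | Path) -> None:
    rows = [(e.kind, e.t_event, e.x, e.y,
             "" if e.axis_theta is None else e.axis_theta) for e in events]
    pd.DataFrame(rows, columns=["kind", "t_event", "x", "y", "axis_theta"]).to_csv(
        path, index=False)


def read_events(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        ax = r.get("axis_theta")
        ax = None if pd.isna(ax) else float(ax)
        out.append(EventRecord(kind=str(r["kind"]), t_event=float(r["t_event"]),
                               x=float(r["x"]), y=float(r["y"]), axis_theta=ax))
    return out


# ---------------------------------------------------------------------------
# QC filters and control statistics
# ---------------------------------------------------------------------------

def filter_complete_tracks(tracks: TrackTable) -> TrackTable:
    """Keep only tracks present at every frame of the recording.

    Mirrors the standard practice of analysing only trajectories followed
    through the whole movie; gapped or lost tracks are removed outright.
    Idempotent; may return an empty table.
    """
    n_frames = tracks.n_frames
    counts = tracks.df.groupby("track_id")["frame"].nunique()
    keep = counts.index[counts == n_frames]
    df = tracks.df[tracks.df["track_id"].isin(keep)]
    return tracks.copy_with(df)


def estimate_static_noise(tracks: TrackTable,
                          max_lag: int | None = None) -> pd.DataFrame:
    """Mean displacement magnitude per lag for a static control sample.

    Run on a fixed (dead-cell) recording this estimates the tracking error:
    a time-independent value (≈0.1 μm for the imaging conditions the
    defaults target).  Returns a DataFrame with columns ``dt_min`` and
    ``mean_disp_um``.
    """
    if tracks.n_frames < 2:
        raise ValidationError("need at least 2 frames to estimate noise")
    t = filter_complete_tracks(tracks)
    _, frames, pos = t.position_array()
    T = pos.shape[0]
    lags = range(1, T if max_lag is None else min(T, max_lag + 1))
    rows = []
    for lag in lags:
        d = pos[lag:] - pos[:-lag]
        rows.append((lag * t.dt, float(np.linalg.norm(d, axis=-1).mean())))
    return pd.DataFrame(rows, columns=["dt_min", "mean_disp_um"])


def shape_change_stats(tracks: TrackTable,
                       max_lag: int | None = None) -> pd.DataFrame:
    """Signed mean nucleus-axis change ⟨d_α(t+δt) − d_α(t)⟩ per lag.

    Quantifies whether apparent motion could be driven by nucleus shape
    change; for stationary shape statistics the curves sit at 0.
    """
    if not tracks.has_axes:
        raise ValidationError("d_long/d_short columns are required")
    t = filter_complete_tracks(tracks)
    dl = t.value_array("d_long")
    ds = t.value_array("d_short")
    T = dl.shape[0]
    lags = range(1, T if max_lag is None else min(T, max_lag + 1))
    rows = []
    for lag in lags:
        rows.append((
            lag * t.dt,
            float((dl[lag:] - dl[:-lag]).mean()),
            float((ds[lag:] - ds[:-lag]).mean()),
        ))
    return pd.DataFrame(rows, columns=["dt_min", "delta_long_um", "delta_short_um"])
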
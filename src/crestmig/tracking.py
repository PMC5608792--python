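"""Single-cell motility metrics from time-lapse track tables.

Tracks are (frame, x, y) sequences recorded at a fixed frame interval (the
assay images every 15 min).  Metrics are the ones the migration study reports:
accumulated distance (sum of step lengths), straight-line Euclidean
displacement, and mean speed (accumulated distance over elapsed time).
Single-frame gaps are bridged (the straight step simply spans two intervals);
longer gaps split the track, since interpolating across them would fabricate
path length.

Statistical comparisons use the well as the replicate unit (the mean of its
tracks) to avoid pseudo-replication; per-track testing is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "read_tracks",
    "accumulated_distance",
    "euclidean_displacement",
    "mean_speed",
    "track_metrics",
    "summarize_condition",
    "compare_conditions",
]

#: column aliases accepted by :func:`read_tracks` (manual-tracking exports
#: vary; "Track n" / "Slice n" are ImageJ Manual-Track conventions)
_COLUMN_ALIASES = {
    "track_id": ("track_id", "track", "track n", "trackid"),
    "frame": ("frame", "slice", "slice n", "t"),
    "x_px": ("x_px", "x"),
    "y_px": ("y_px", "y"),
}

#: conditions with fewer followed cells than this are flagged as invalid
MIN_TRACKS_PER_CONDITION = 10


@dataclass
class Track:
    track_id: str
    frames: np.ndarray  # strictly increasing integer frame indices
    xy: np.ndarray  # (n, 2) pixel coordinates, columns (x, y)
    frame_interval: float  # minutes
    pixel_size: float  # um / px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames must strictly increase")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and coordinates disagree in length")

    @property
    def n_points(self) -> int:
        return len(self.frames)


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
        else:
            raise ValueError(f"track table is missing a '{canon}' column")
    return df.rename(columns=rename)


def read_tracks(
    source: str | Path | pd.DataFrame,
    frame_interval: float = 15.0,
    pixel_size: float = 0.65,
    max_gap: int = 1,
) -> list[Track]:
    """Read a track CSV (columns track_id, frame, x_px, y_px, or common
    manual-tracking aliases) into Track objects.

    Gaps of up to ``max_gap`` missing frames are bridged as a single straight
    segment spanning the elapsed intervals; larger gaps split the track into
    independent pieces (suffixes ``/1``, ``/2``, ...).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if df.empty:
        return []
    df = _normalize_columns(df)
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise ValueError("duplicate (track_id, frame) rows")

    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        xy = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        splits = np.where(np.diff(frames) > max_gap + 1)[0] + 1
        pieces = np.split(np.arange(len(frames)), splits)
        for j, idx in enumerate(pieces):
            name = str(tid) if len(pieces) == 1 else f"{tid}/{j + 1}"
            tracks.append(
                Track(
                    track_id=name,
                    frames=frames[idx],
                    xy=xy[idx],
                    frame_interval=frame_interval,
                    pixel_size=pixel_size,
                )
            )
    return tracks


def _step_lengths(track: Track) -> np.ndarray:
    if track.n_points < 2:
        raise ValueError("distance metrics require >= 2 points")
    return np.hypot(*(np.diff(track.xy, axis=0).T))


def accumulated_distance(track: Track) -> float:
    """Total path length in micrometres (sum of Euclidean steps x pixel size)."""
    return float(_step_lengths(track).sum() * track.pixel_size)


def euclidean_displacement(track: Track) -> float:
    """Straight-line start-to-end distance in micrometres."""
    if track.n_points < 2:
        raise ValueError("distance metrics require >= 2 points")
    return float(np.hypot(*(track.xy[-1] - track.xy[0])) * track.pixel_size)


def mean_speed(track: Track) -> float:
    """Accumulated distance over elapsed time, in um/min.

    Elapsed time is the spanned frame count times the frame interval, so a
    bridged single-frame gap correctly contributes two intervals.
    """
    dist = accumulated_distance(track)
    n_intervals = int(track.frames[-1] - track.frames[0])
    return dist / (n_intervals * track.frame_interval)


def track_metrics(
    tracks: Sequence[Track],
    condition: str = "",
    concentration: float = 0.0,
    well_id: str = "",
) -> pd.DataFrame:
    """Per-track metric table."""
    rows = []
    for t in tracks:
        rows.append(
            {
                "well_id": well_id,
                "condition": condition,
                "concentration_pM": concentration,
                "track_id": t.track_id,
                "n_points": t.n_points,
                "accumulated_distance_um": accumulated_distance(t),
                "euclidean_displacement_um": euclidean_displacement(t),
                "mean_speed_um_per_min": mean_speed(t),
            }
        )
    return pd.DataFrame(rows)


def summarize_condition(metrics: pd.DataFrame) -> pd.DataFrame:
    """Condition-level summary; conditions with < 10 tracks are flagged."""
    rows = []
    for (cond, conc), grp in metrics.groupby(["condition", "concentration_pM"]):
        rows.append(
            {
                "condition": cond,
                "concentration_pM": conc,
                "n_tracks": int(len(grp)),
                "mean_accumulated_distance_um": float(
                    grp["accumulated_distance_um"].mean()
                ),
                "sd_accumulated_distance_um": float(
                    grp["accumulated_distance_um"].std(ddof=1)
                )
                if len(grp) > 1
                else np.nan,
                "mean_speed_um_per_min": float(grp["mean_speed_um_per_min"].mean()),
                "valid": bool(len(grp) >= MIN_TRACKS_PER_CONDITION),
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    metrics: pd.DataFrame,
    control_concentration: float = 0.0,
    value_column: str = "accumulated_distance_um",
    unit: str = "well",
) -> dict:
    """Welch t-test of control vs the highest tested concentration.

    ``unit="well"`` (default) averages tracks within each well first and
    tests the per-well means; ``unit="track"`` tests individual tracks
    (pseudo-replicated, provided for comparison only).  Also reports a
    one-way ANOVA across all concentrations.
    """
    concs = sorted(metrics["concentration_pM"].unique())
    if control_concentration not in concs:
        raise ValueError("control concentration missing from metrics")
    top = max(concs)
    if top == control_concentration:
        raise ValueError("no treated concentration present")

    if unit == "well":
        reps = (
            metrics.groupby(["concentration_pM", "well_id"])[value_column]
            .mean()
            .reset_index()
        )
    elif unit == "track":
        reps = metrics[["concentration_pM", value_column]].copy()
    else:
        raise ValueError("unit must be 'well' or 'track'")

    ctrl = reps.loc[reps["concentration_pM"] == control_concentration, value_column]
    treat = reps.loc[reps["concentration_pM"] == top, value_column]
    if len(ctrl) < 2 or len(treat) < 2:
        raise ValueError("need >= 2 replicates per compared group")
    t_res = stats.ttest_ind(treat, ctrl, equal_var=False)

    groups = [
        reps.loc[reps["concentration_pM"] == c, value_column].to_numpy()
        for c in concs
    ]
    anova = stats.f_oneway(*groups) if all(len(g) >= 2 for g in groups) else None

    return {
        "control_concentration_pM": control_concentration,
        "top_concentration_pM": float(top),
        "control_mean": float(ctrl.mean()),
        "treated_mean": float(treat.mean()),
        "t_statistic": float(t_res.statistic),
        "p_value": float(t_res.pvalue),
        "anova_p": float(anova.pvalue) if anova is not None else np.nan,
        "unit": unit,
    }
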
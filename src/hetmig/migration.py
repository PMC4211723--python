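"""Migration phenology from GPS collar tracks.

Spring and fall migration dates are demarcated with minimum convex
polygons (MCPs): the origin range is the convex hull of fixes occupied
before the seasonal window, migration initiation is the last fix inside
that hull with no later same-season re-entry ("directed movement,
without return"), and termination is the first fix inside the
destination-range hull after which the animal stays there.  Range
centroids are fix means over the residency periods.

Dates are Julian day-of-year integers; coordinates must be planar
projected (meters) -- geographic input is not reprojected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from .matrices import PairwiseMatrix

__all__ = [
    "MigrationRecord",
    "GpsTrack",
    "RangeCentroids",
    "SeasonWindows",
    "correct_to_earliest",
    "timing_distance_matrix",
    "centroid_distance_matrix",
    "extract_migration_dates",
    "read_gps_csv",
]


@dataclass
class SeasonWindows:
    """Day-of-year windows bracketing the observed migration periods."""

    spring_start: int = 60    # Mar 1
    spring_end: int = 196     # Jul 15
    fall_start: int = 244     # Sep 1
    fall_end: int = 349       # Dec 15


@dataclass
class MigrationRecord:
    individual_id: str
    year: int
    spring_start: Optional[int] = None
    spring_end: Optional[int] = None
    fall_start: Optional[int] = None
    fall_end: Optional[int] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e, season in (
            (self.spring_start, self.spring_end, "spring"),
            (self.fall_start, self.fall_end, "fall"),
        ):
            if s is not None and e is not None and s > e:
                raise ValueError(f"{season} initiation after termination")


@dataclass
class GpsTrack:
    individual_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    xy: np.ndarray     # (n, 2) projected meters

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.times), 2):
            raise ValueError("xy shape must be (n_fixes, 2)")
        if len(self.times) > 1 and not np.all(np.diff(self.times).astype(int) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def day_of_year(self) -> np.ndarray:
        return pd.DatetimeIndex(self.times).dayofyear.to_numpy()

    def year(self) -> int:
        return int(pd.DatetimeIndex(self.times).year[0])


@dataclass
class RangeCentroids:
    """Per-individual winter and summer range centroids (projected meters)."""

    winter: dict[str, tuple[float, float]] = field(default_factory=dict)
    summer: dict[str, tuple[float, float]] = field(default_factory=dict)

    def season(self, season: str) -> dict[str, tuple[float, float]]:
        if season not in ("winter", "summer"):
            raise ValueError(f"unknown season {season!r}")
        return self.winter if season == "winter" else self.summer


# ---------------------------------------------------------------------------
# date arithmetic and matrices
# ---------------------------------------------------------------------------

def correct_to_earliest(dates: Mapping[str, Optional[float]]) -> dict[str, Optional[int]]:
    """Shift Julian dates so the earliest migrant maps to day 0.

    The result is a count of days since the earliest migration event;
    missing dates propagate as ``None``.
    """
    present = [d for d in dates.values() if d is not None]
    if not present:
        raise ValueError("no non-missing dates")
    m = min(present)
    return {
        k: (None if d is None else int(round(d - m))) for k, d in dates.items()
    }


def timing_distance_matrix(dates: Mapping[str, Optional[float]]) -> PairwiseMatrix:
    """Absolute pairwise day differences; ids with missing dates are dropped."""
    usable = {k: float(v) for k, v in dates.items() if v is not None}
    dropped = sorted(set(dates) - set(usable))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} ids with missing dates: {dropped[:5]}...")
    if len(usable) < 2:
        raise ValueError("fewer than 2 ids with dates")
    ids = list(usable)
    v = np.array([usable[i] for i in ids])
    return PairwiseMatrix(ids, np.abs(v[:, None] - v[None, :]), "distance", "days")


def centroid_distance_matrix(c: RangeCentroids, season: str) -> PairwiseMatrix:
    """Pairwise Euclidean distance (meters) between range centroids."""
    cents = c.season(season)
    ids = sorted(cents)
    pts = np.array([cents[i] for i in ids], dtype=float)
    missing = [i for i, p in zip(ids, pts) if not np.all(np.isfinite(p))]
    if missing:
        warnings.warn(f"dropping ids with missing centroids: {missing}")
        keep = [i for i in ids if i not in missing]
        pts = np.array([cents[i] for i in keep])
        ids = keep
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    return PairwiseMatrix(ids, d, "distance", "meters")


# ---------------------------------------------------------------------------
# MCP demarcation
# ---------------------------------------------------------------------------

def _hull(points: np.ndarray):
    distinct = np.unique(points, axis=0)
    if len(distinct) < 3:
        raise ValueError("degenerate hull: fewer than 3 distinct fixes")
    return MultiPoint([tuple(p) for p in distinct]).convex_hull


def _covers(hull, pts: np.ndarray) -> np.ndarray:
    # boundary fixes count as inside
    import shapely

    return shapely.covers(hull, shapely.points(pts))


def extract_migration_dates(
    track: GpsTrack,
    season: str,
    windows: Optional[SeasonWindows] = None,
    min_resident_fixes: int = 3,
) -> tuple[MigrationRecord, RangeCentroids]:
    """Extract migration initiation/termination for one season.

    The origin MCP is built from fixes before the season window and the
    destination MCP from fixes after it.  Initiation is the last
    origin-MCP fix with no later in-window re-entry; termination is the
    first destination-MCP fix after which all in-window fixes stay
    inside.  Animals that never leave the origin range get a
    ``no_migration`` flag and missing dates.
    """
    if windows is None:
        windows = SeasonWindows()
    if season not in ("spring", "fall"):
        raise ValueError(f"unknown season {season!r}")
    w0, w1 = (
        (windows.spring_start, windows.spring_end)
        if season == "spring"
        else (windows.fall_start, windows.fall_end)
    )
    doy = track.day_of_year()
    pre = doy < w0
    post = doy > w1
    inwin = ~pre & ~post
    rec = MigrationRecord(track.individual_id, track.year())
    cents = RangeCentroids()

    if pre.sum() < min_resident_fixes:
        rec.flags.append(f"{season}:insufficient_pre_window_fixes")
        return rec, cents
    origin_hull = _hull(track.xy[pre])

    win_idx = np.nonzero(inwin)[0]
    if win_idx.size == 0:
        rec.flags.append(f"{season}:no_window_fixes")
        return rec, cents
    inside_origin = _covers(origin_hull, track.xy[win_idx])

    if inside_origin.all() or not inside_origin.any():
        # never left the origin range, or was already away at window start
        flag = "no_migration" if inside_origin.all() else "already_departed"
        rec.flags.append(f"{season}:{flag}")
        _set_centroids(cents, season, track, pre, None, None)
        return rec, cents

    last_inside = int(np.nonzero(inside_origin)[0].max())
    if last_inside == len(win_idx) - 1:
        rec.flags.append(f"{season}:no_permanent_departure")
        _set_centroids(cents, season, track, pre, None, None)
        return rec, cents
    init_day = int(doy[win_idx[last_inside]])

    # destination hull from post-window fixes; fall back to the tail of the window
    if post.sum() >= min_resident_fixes:
        dest_pts = track.xy[post]
    else:
        dest_pts = track.xy[win_idx[-min_resident_fixes * 5 :]]
    try:
        dest_hull = _hull(dest_pts)
    except ValueError:
        rec.flags.append(f"{season}:degenerate_destination_range")
        _set_centroids(cents, season, track, pre, None, None)
        return rec, cents
    # the post-window sample undersamples the full residency spread; dilate
    # the hull by the observed residency radius so arrival is judged against
    # the range, not the subsample
    centroid = dest_pts.mean(axis=0)
    r95 = float(np.percentile(np.hypot(*(dest_pts - centroid).T), 95))
    dest_region = dest_hull.buffer(r95)

    after = win_idx[last_inside + 1 :]
    inside_dest = _covers(dest_region, track.xy[after])
    returns_origin = _covers(origin_hull, track.xy[after])
    if not inside_dest.any():
        rec.flags.append(f"{season}:no_arrival")
        _set_centroids(cents, season, track, pre, None, None)
        return rec, cents
    arrive_pos = int(np.nonzero(inside_dest)[0].min())
    if returns_origin[arrive_pos:].any():
        # came back to the origin range after reaching the destination:
        # not a completed directed movement
        rec.flags.append(f"{season}:returned_to_origin")
        _set_centroids(cents, season, track, pre, None, None)
        return rec, cents
    term_day = int(doy[after[arrive_pos]])

    if season == "spring":
        rec.spring_start, rec.spring_end = init_day, term_day
    else:
        rec.fall_start, rec.fall_end = init_day, term_day
    _set_centroids(cents, season, track, pre, post, after[arrive_pos:])
    return rec, cents


def _set_centroids(cents, season, track, pre, post, arrived_idx) -> None:
    """Origin centroid from pre-window fixes; destination from post-arrival fixes."""
    origin = tuple(track.xy[pre].mean(axis=0))
    dest = None
    if arrived_idx is not None and len(arrived_idx) > 0:
        pts = track.xy[arrived_idx]
        if post is not None and post.any():
            pts = np.vstack([pts, track.xy[post]])
        dest = tuple(pts.mean(axis=0))
    ind = track.individual_id
    if season == "spring":
        cents.winter[ind] = origin
        if dest is not None:
            cents.summer[ind] = dest
    else:
        cents.summer[ind] = origin
        if dest is not None:
            cents.winter[ind] = dest


def read_gps_csv(path) -> list[GpsTrack]:
    """Read ``id,timestamp,x,y`` CSV into one track per individual."""
    df = pd.read_csv(path, comment="#")
    need = {"id", "timestamp", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"GPS CSV must have columns {sorted(need)}")
    tracks = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("timestamp")
        tracks.append(
            GpsTrack(
                str(ind),
                pd.to_datetime(sub["timestamp"]).to_numpy().astype("datetime64[s]"),
                sub[["x", "y"]].to_numpy(float),
            )
        )
    return tracks
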
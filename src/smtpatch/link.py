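"""Trajectory building by proximity linking with gap closing.

Localizations in successive frames are linked when they fall within
``search_radius`` (100 nm default) of an open track's last position; when
several spots compete for the same track ends, the frame-pair assignment
minimizing total distance wins (scipy's linear-sum assignment), which is
deterministic and keeps track purity high at near-radius separations.
A track may survive up to ``max_gap_frames`` frames counted including the
frame before and after the gap (default 6, i.e. at most 4 consecutive
missed detections); tracks with fewer than ``min_spots`` localizations
are discarded, as are tracks whose centroid falls outside an optional
cell mask.  No motion prediction is used -- the 100 nm limit is small
compared to typical frame-to-frame motion of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LinkParams",
    "LinkResult",
    "link_tracks",
    "gap_length_histogram",
    "sweep_gap_parameter",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "movie_id", "frame", "t_s", "x_nm", "y_nm"]

_FORBIDDEN = 1e12


@dataclass(frozen=True)
class LinkParams:
    """Linking limits.

    ``max_gap_frames`` follows the convention "frames including the
    endpoints": a value of 6 links spots up to 5 frame indices apart,
    i.e. across at most 4 consecutive missed detections.
    """

    search_radius: float = 100.0
    max_gap_frames: int = 6
    min_spots: int = 3

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.max_gap_frames < 1:
            raise ValueError("max_gap_frames must be >= 1")
        if self.min_spots < 2:
            raise ValueError("min_spots must be >= 2")

    @property
    def max_frame_delta(self) -> int:
        # gap convention "frames including endpoints": 6 -> spots up to 5
        # frame indices apart.  A value of 1 degenerates to plain
        # successive-frame linking (no gap closing) rather than nothing.
        return max(self.max_gap_frames - 1, 1)


@dataclass
class LinkResult:
    """Tracks plus the localizations dropped by the min-spots/mask rules."""

    tracks: pd.DataFrame
    dropped: pd.DataFrame
    params: LinkParams


class _OpenTrack:
    __slots__ = ("tid", "last_frame", "x", "y", "rows")

    def __init__(self, tid, frame, x, y, row):
        self.tid = tid
        self.last_frame = frame
        self.x = x
        self.y = y
        self.rows = [row]

    def extend(self, frame, x, y, row):
        self.last_frame = frame
        self.x = x
        self.y = y
        self.rows.append(row)


def link_tracks(
    locs: pd.DataFrame,
    params: LinkParams | None = None,
    cell_mask: np.ndarray | None = None,
    pixel_size: float = 178.0,
    movie_id=0,
) -> LinkResult:
    """Build tracks from a localization table.

    ``locs`` must carry ``frame``, ``x_nm`` and ``y_nm`` columns (the
    standard localization table works as is).  Rows keep their stable
    input order within a frame, so duplicate positions link
    deterministically.  Returns a :class:`LinkResult` whose ``tracks``
    DataFrame is the input rows annotated with ``track_id`` and
    ``movie_id`` (only tracks passing the min-spots and mask rules).
    """
    params = params or LinkParams()
    if not {"frame", "x_nm", "y_nm"}.issubset(locs.columns):
        raise ValueError("locs must have frame, x_nm and y_nm columns")
    locs = locs.reset_index(drop=True)

    open_tracks: list[_OpenTrack] = []
    all_tracks: list[_OpenTrack] = []
    next_id = 0
    # tiny per-gap penalty: prefer the more recent track end on near-ties,
    # deterministic and far below any meaningful distance difference
    gap_eps = params.search_radius * 1e-9

    for frame, group in locs.groupby("frame", sort=True):
        frame = int(frame)
        open_tracks = [
            t for t in open_tracks if frame - t.last_frame <= params.max_frame_delta
        ]
        idx = group.index.to_numpy()
        xs = group["x_nm"].to_numpy()
        ys = group["y_nm"].to_numpy()
        assigned = np.full(len(idx), False)
        if open_tracks and len(idx):
            cost = np.full((len(open_tracks), len(idx)), _FORBIDDEN)
            for i, t in enumerate(open_tracks):
                d = np.hypot(xs - t.x, ys - t.y)
                ok = d <= params.search_radius
                cost[i, ok] = d[ok] + (frame - t.last_frame - 1) * gap_eps
            rows_a, cols_a = linear_sum_assignment(cost)
            for i, j in zip(rows_a, cols_a):
                if cost[i, j] < _FORBIDDEN:
                    open_tracks[i].extend(frame, xs[j], ys[j], idx[j])
                    assigned[j] = True
        for j in np.nonzero(~assigned)[0]:
            t = _OpenTrack(next_id, frame, xs[j], ys[j], idx[j])
            next_id += 1
            open_tracks.append(t)
            all_tracks.append(t)

    keep_rows: list[int] = []
    keep_ids: list[int] = []
    drop_rows: list[int] = []
    tid_out = 0
    for t in all_tracks:
        ok = len(t.rows) >= params.min_spots
        if ok and cell_mask is not None:
            sub = locs.loc[t.rows]
            cx = int(round(sub["x_nm"].mean() / pixel_size))
            cy = int(round(sub["y_nm"].mean() / pixel_size))
            inside = (
                0 <= cy < cell_mask.shape[0]
                and 0 <= cx < cell_mask.shape[1]
                and bool(cell_mask[cy, cx])
            )
            ok = inside
        if ok:
            keep_rows.extend(t.rows)
            keep_ids.extend([tid_out] * len(t.rows))
            tid_out += 1
        else:
            drop_rows.extend(t.rows)

    tracks = locs.loc[keep_rows].copy()
    tracks.insert(0, "track_id", keep_ids)
    if "movie_id" not in tracks.columns:
        tracks.insert(1, "movie_id", movie_id)
    tracks = tracks.sort_values(["track_id", "frame"]).reset_index(drop=True)
    dropped = locs.loc[sorted(drop_rows)].reset_index(drop=True)
    return LinkResult(tracks=tracks, dropped=dropped, params=params)


def gap_length_histogram(tracks: pd.DataFrame) -> pd.Series:
    """Counts of within-track missed-detection run lengths (frames).

    A gap of length k means k consecutive frames with no localization
    between two linked spots.  Gap-free tracks yield an empty histogram.
    The distribution of gap lengths should decay roughly geometrically at
    the per-frame miss rate; a heavy tail flags over-linking.
    """
    gaps: list[int] = []
    for _, sub in tracks.groupby("track_id"):
        d = np.diff(np.sort(sub["frame"].to_numpy()))
        gaps.extend((d[d > 1] - 1).tolist())
    if not gaps:
        return pd.Series(dtype=int, name="count")
    counts = pd.Series(gaps).value_counts().sort_index()
    counts.name = "count"
    counts.index.name = "gap_frames"
    return counts


def sweep_gap_parameter(
    locs: pd.DataFrame,
    gap_values,
    params: LinkParams | None = None,
    frame_interval: float = 0.1,
) -> pd.DataFrame:
    """Re-link at each gap limit; report track count and mean lifetime.

    The diagnostic sweep used to choose the gap-closing limit: too small
    splits single molecules into several short tracks, too large links
    independent molecules and inflates lifetimes.
    """
    gap_values = list(gap_values)
    if len(gap_values) < 2:
        raise ValueError("need at least two gap values to sweep")
    params = params or LinkParams()
    rows = []
    for gap in gap_values:
        p = LinkParams(
            search_radius=params.search_radius,
            max_gap_frames=int(gap),
            min_spots=params.min_spots,
        )
        res = link_tracks(locs, p)
        if len(res.tracks):
            per = res.tracks.groupby("track_id")["frame"].agg(["min", "max"])
            lifetimes = (per["max"] - per["min"] + 1) * frame_interval
            rows.append((gap, len(per), float(lifetimes.mean())))
        else:
            rows.append((gap, 0, np.nan))
    return pd.DataFrame(rows, columns=["max_gap_frames", "n_tracks", "mean_lifetime_s"])
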
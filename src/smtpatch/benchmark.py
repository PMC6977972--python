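"""Scoring recovered tracks against synthetic ground truth.

Each localization is matched to the nearest truth emitter alive in the
same frame (within ``match_radius_nm``); a track's identity is the
majority emitter among its matched spots.  Purity is the pooled fraction
of spots agreeing with their track's majority emitter; recall is the
fraction of *eligible* truth emitters recovered by at least one track.
Emitters are eligible when they have at least ``min_frames`` visible
frames whose positions keep a full fit window inside the field --
spots closer to the border cannot be localized because clipped fit
windows are refused by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import TruthTrackSet

__all__ = ["TrackingScore", "evaluate_tracking"]


@dataclass
class TrackingScore:
    recall: float
    purity: float
    n_eligible: int
    n_tracks: int
    per_track: pd.DataFrame


def _match_localizations(
    tracks: pd.DataFrame, truth: TruthTrackSet, match_radius_nm: float
) -> np.ndarray:
    """Truth emitter id per localization row (-1 when unmatched)."""
    matched = np.full(len(tracks), -1, dtype=int)
    truth_by_frame = dict(tuple(truth.positions.groupby("frame")))
    for i, (_, row) in enumerate(tracks.iterrows()):
        tp = truth_by_frame.get(int(row["frame"]))
        if tp is None:
            continue
        d = np.hypot(tp["x_nm"].to_numpy() - row["x_nm"], tp["y_nm"].to_numpy() - row["y_nm"])
        j = int(np.argmin(d))
        if d[j] <= match_radius_nm:
            matched[i] = int(tp["id"].to_numpy()[j])
    return matched


def evaluate_tracking(
    tracks: pd.DataFrame,
    truth: TruthTrackSet,
    match_radius_nm: float = 250.0,
    min_frames: int = 3,
    border_margin_px: int = 4,
) -> TrackingScore:
    """Recall and purity of a track table against a :class:`TruthTrackSet`."""
    optics = truth.optics
    field_nm = truth.params.field_size * optics.pixel_size
    margin_nm = border_margin_px * optics.pixel_size
    pos = truth.positions
    interior = (
        (pos["x_nm"] >= margin_nm)
        & (pos["x_nm"] <= field_nm - margin_nm)
        & (pos["y_nm"] >= margin_nm)
        & (pos["y_nm"] <= field_nm - margin_nm)
    )
    eligible = set(
        pos[interior].groupby("id").size().pipe(lambda s: s[s >= min_frames]).index
    )

    if len(tracks) == 0:
        return TrackingScore(0.0, float("nan"), len(eligible), 0, pd.DataFrame())

    matched = _match_localizations(tracks, truth, match_radius_nm)
    df = tracks[["track_id"]].copy()
    df["emitter"] = matched
    rows = []
    for tid, sub in df.groupby("track_id"):
        vals = sub["emitter"].to_numpy()
        real = vals[vals >= 0]
        if real.size:
            ids, counts = np.unique(real, return_counts=True)
            majority = int(ids[np.argmax(counts)])
            n_major = int(counts.max())
        else:
            majority, n_major = -1, 0
        rows.append((tid, majority, n_major, len(vals)))
    per_track = pd.DataFrame(rows, columns=["track_id", "majority_emitter", "n_majority", "n_spots"])

    purity = float(per_track["n_majority"].sum() / per_track["n_spots"].sum())
    recovered = set(
        per_track.loc[
            (per_track["majority_emitter"] >= 0) & (per_track["n_majority"] >= min_frames),
            "majority_emitter",
        ]
    )
    recall = (
        float(len(recovered & eligible) / len(eligible)) if eligible else float("nan")
    )
    return TrackingScore(
        recall=recall,
        purity=purity,
        n_eligible=len(eligible),
        n_tracks=int(per_track.shape[0]),
        per_track=per_track,
    )
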
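"""Configuration, table I/O and pipeline orchestration.

Tables are tab-separated text with a one-line schema header, times in
seconds and positions in nm throughout; frames are 0-based and positions
refer to pixel centers with the origin at the top-left pixel center.
All randomness flows from a single global seed through per-stage spawned
seeds, and every effective parameter is written to the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import link as _link
from . import localize as _localize
from . import trackstats as _ts
from .imaging import (
    CameraModel,
    EmitterSimParams,
    OpticsModel,
    generate_truth_tracks,
    render_movie,
)
from .link import LinkParams, link_tracks
from .localize import DetectionParams, LocFilterSpec, localize_stack
from .turnover import ModelParams, simulate_model, occupancy_profile

__all__ = [
    "PipelineConfig",
    "write_localizations",
    "read_localizations",
    "write_tracks",
    "read_tracks",
    "run_pipeline",
    "make_fixtures",
]

_LOC_HEADER = "# smtpatch localizations v1"
_TRACK_HEADER = "# smtpatch tracks v1"

logger = logging.getLogger("smtpatch")


def _write_table(df: pd.DataFrame, path, header: str, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path, header: str, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != header:
            raise ValueError(
                f"{path}: expected schema header {header!r}, found {first!r}"
            )
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    _write_table(df, path, _LOC_HEADER, _localize.LOC_COLUMNS)


def read_localizations(path) -> pd.DataFrame:
    return _read_table(path, _LOC_HEADER, _localize.LOC_COLUMNS)


def write_tracks(df: pd.DataFrame, path) -> None:
    _validate_tracks(df)
    _write_table(df, path, _TRACK_HEADER, _link.TRACK_COLUMNS)


def read_tracks(path) -> pd.DataFrame:
    df = _read_table(path, _TRACK_HEADER, _link.TRACK_COLUMNS)
    _validate_tracks(df)
    return df


def _validate_tracks(df: pd.DataFrame) -> None:
    for key, sub in df.groupby(["movie_id", "track_id"]):
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {key}: frames are not strictly increasing")


def _build(cls, data: dict | None, where: str):
    """Instantiate a params dataclass, rejecting unknown keys."""
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """One run: how many movies to simulate and every stage's parameters."""

    seed: int = 0
    n_movies: int = 1
    emitter: EmitterSimParams = field(default_factory=EmitterSimParams)
    optics: OpticsModel = field(default_factory=OpticsModel)
    camera: CameraModel = field(default_factory=CameraModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    loc_filter: LocFilterSpec = field(default_factory=LocFilterSpec)
    link: LinkParams = field(default_factory=LinkParams)
    track_filter: _ts.TrackFilterSpec = field(default_factory=_ts.TrackFilterSpec)
    mobility: _ts.MobilityClassification = field(default_factory=_ts.MobilityClassification)
    start_cutoff: str | float = 0.0  # "auto" to select by the KS procedure
    save_movies: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sub = {
            "emitter": EmitterSimParams,
            "optics": OpticsModel,
            "camera": CameraModel,
            "detection": DetectionParams,
            "loc_filter": LocFilterSpec,
            "link": LinkParams,
            "track_filter": _ts.TrackFilterSpec,
            "mobility": _ts.MobilityClassification,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config: unknown key(s) {sorted(unknown)}")
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                block = val
                if key == "detection" and isinstance(block, dict) and "bandpass_sigmas" in block:
                    block = dict(block)
                    block["bandpass_sigmas"] = tuple(block["bandpass_sigmas"])
                if key == "loc_filter" and isinstance(block, dict):
                    block = dict(block)
                    for rk in ("intensity_range", "sigma_range"):
                        if rk in block:
                            block[rk] = tuple(block[rk])
                kwargs[key] = _build(sub[key], block, key)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mobility"].pop("boundary_table", None)
        return d


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """simulate -> render -> localize -> track -> analyze, one run directory.

    Writes per-movie localization/track tables, the pooled filtered track
    table, a one-row summary (lifetime statistics, net distances,
    apparent D, mobility fractions) and a log of every effective
    parameter.  Byte-identical outputs for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(json.dumps(config.to_dict(), indent=2, default=str) + "\n")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_movies * 2)
    all_tracks = []
    spot_counts = None
    for m in range(config.n_movies):
        truth_rng = np.random.default_rng(children[2 * m])
        noise_rng = np.random.default_rng(children[2 * m + 1])
        truth = generate_truth_tracks(config.emitter, config.optics, truth_rng)
        stack = render_movie(truth, config.optics, config.camera, rng=noise_rng)
        if config.save_movies:
            stack.save(outdir / f"movie_{m:03d}.tif")
            truth.positions.to_csv(outdir / f"truth_{m:03d}.tsv", sep="\t", index=False)
        locs = localize_stack(
            stack, config.detection, filter_spec=config.loc_filter
        )
        write_localizations(locs, outdir / f"locs_{m:03d}.tsv")
        res = link_tracks(
            locs, config.link, pixel_size=config.optics.pixel_size, movie_id=m
        )
        tracks = res.tracks
        all_tracks.append(tracks)
        counts = locs.groupby("frame").size()
        counts = counts.reindex(range(config.emitter.n_frames), fill_value=0)
        spot_counts = counts if spot_counts is None else spot_counts + counts
        logger.info("movie %d: %d localizations, %d tracks", m, len(locs),
                    tracks["track_id"].nunique() if len(tracks) else 0)

    pooled = pd.concat(all_tracks, ignore_index=True)
    # make track ids unique across movies
    pooled["track_id"] = pooled.groupby(["movie_id", "track_id"]).ngroup()
    write_tracks(pooled[_link.TRACK_COLUMNS], outdir / "tracks.tsv")

    dt = config.emitter.frame_interval
    if config.start_cutoff == "auto":
        cutoff = _ts.select_start_cutoff(pooled, frame_interval=dt)
    else:
        cutoff = float(config.start_cutoff)
    spec = _ts.TrackFilterSpec(
        min_lifetime=config.track_filter.min_lifetime,
        max_lifetime=config.track_filter.max_lifetime,
        start_cutoff=cutoff,
    )
    filtered, removed = _ts.filter_tracks(pooled, spec, dt)
    summary = _ts.lifetime_summary(filtered, dt)
    pairs = _ts.pairwise_displacements(filtered)
    fit = _ts.msd_and_fit(pairs, frame_interval=dt)
    mobility = _ts.classify_mobility(pairs, config.mobility, frame_interval=dt)
    try:
        e2e = _ts.end_to_end_stats(filtered, frame_interval=dt)
    except ValueError:
        e2e = {"fraction_over": float("nan")}
    bleach = _ts.photobleach_rate(spot_counts.to_numpy(), dt)

    row = {
        "median_lifetime_s": summary.median,
        "mean_lifetime_s": summary.mean,
        "sd_across_movies_s": summary.sd_across_movies,
        "p95_lifetime_s": summary.p95,
        "median_end_to_end_nm": float(np.median(e2e.get("distances_nm", [np.nan]))),
        "fraction_over_250nm": e2e["fraction_over"],
        "n_tracks": summary.n_tracks,
        "n_movies": summary.n_movies,
        "D_nm2_per_s": fit.D,
        "D_ci_lo": fit.ci_D[0],
        "D_ci_hi": fit.ci_D[1],
        "msd_intercept_nm2": fit.intercept_b,
        "frac_low": mobility.fractions["low"],
        "frac_mid": mobility.fractions["mid"],
        "frac_high": mobility.fractions["high"],
        "bleach_rate_per_s": bleach,
        "start_cutoff_s": cutoff,
        "n_removed_short": removed["too_short"],
        "n_removed_long": removed["too_long"],
        "n_removed_early": removed["early_start"],
    }
    pd.DataFrame([row]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(log_path, "a") as fh:
        fh.write(json.dumps({"summary": row}, default=str) + "\n")
    return outdir


def make_fixtures(seed: int, outdir) -> Path:
    """Small bundled datasets for offline testing and demos.

    Writes (a) event tables for all three turnover models at reduced n,
    (b) a 200-frame 64x64 movie with ~5 emitters visible at a time and
    (c) its ground-truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    for i, model in enumerate(("random", "fifo", "turnover")):
        params = ModelParams(n_molecules=200, model=model, n_repeats=5, seed=seeds[i])
        events = simulate_model(params)
        events.to_frame().to_csv(outdir / f"events_{model}.tsv", sep="\t", index=False)
        occupancy_profile(events).to_frame().to_csv(
            outdir / f"occupancy_{model}.tsv", sep="\t", index=False
        )
    em = EmitterSimParams(
        field_size=64, duration=20.0, birth_rate=2.5,
        residence_model="gamma", residence_shape=2.0, residence_scale=1.0,
        diffusion_D=3000.0, bleach_rate=0.15, seed=seeds[3],
    )
    truth = generate_truth_tracks(em)
    stack = render_movie(truth)
    stack.save(outdir / "movie.tif")
    truth.positions.to_csv(outdir / "truth_positions.tsv", sep="\t", index=False)
    truth.emitters.to_csv(outdir / "truth_emitters.tsv", sep="\t", index=False)
    return outdir
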
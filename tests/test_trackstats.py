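"""Track statistics: lifetimes, cutoff selection, MSD, mobility, bleaching."""

import numpy as np
import pandas as pd
import pytest

import smtpatch as sp
from smtpatch.trackstats import (
    MobilityClassification,
    TrackFilterSpec,
    classify_mobility,
    compare_distributions,
    end_to_end_stats,
    filter_tracks,
    lifetime_summary,
    msd_and_fit,
    pairwise_displacements,
    photobleach_rate,
    select_start_cutoff,
    summarize_tracks,
)

from conftest import brownian_track_table, lifetime_track_table


def simple_tracks(lifetimes, starts=None, movie_id=0, dt=0.1):
    starts = np.zeros(len(lifetimes)) if starts is None else np.asarray(starts)
    return lifetime_track_table(starts, np.asarray(lifetimes), dt=dt, movie_id=movie_id)


class TestFilterTracks:
    def test_lifetime_bounds(self):
        tracks = simple_tracks([0.2, 1.0, 45.0])
        out, removed = filter_tracks(tracks, TrackFilterSpec())
        assert out["track_id"].nunique() == 1
        assert removed["too_short"] == 1
        assert removed["too_long"] == 1

    def test_identity_when_all_inside(self):
        tracks = simple_tracks([1.0, 2.0, 3.0])
        out, removed = filter_tracks(tracks, TrackFilterSpec(start_cutoff=0.0))
        assert out.equals(tracks)
        assert sum(removed.values()) == 0

    def test_start_cutoff_removes_early_tracks(self):
        tracks = simple_tracks([1.0, 1.0], starts=[0.5, 2.0])
        out, removed = filter_tracks(tracks, TrackFilterSpec(start_cutoff=1.0))
        assert out["track_id"].nunique() == 1
        assert removed["early_start"] == 1

    def test_three_spot_track_lifetime_is_point_three(self):
        # lifetime convention: span + one frame interval
        tracks = pd.DataFrame(
            {"track_id": 0, "movie_id": 0, "frame": [0, 1, 2],
             "t_s": [0.0, 0.1, 0.2], "x_nm": 0.0, "y_nm": 0.0}
        )
        summ = summarize_tracks(tracks)
        assert summ["lifetime_s"].iloc[0] == pytest.approx(0.3)


class TestStartCutoff:
    def test_homogeneous_returns_first_candidate(self):
        rng = np.random.default_rng(41)
        tracks = lifetime_track_table(rng.uniform(0, 20, 3000), rng.exponential(1.5, 3000))
        assert select_start_cutoff(tracks) == 0.0

    def test_planted_contamination_detected(self):
        rng = np.random.default_rng(42)
        start = rng.uniform(0, 20, 5000)
        life = rng.exponential(1.5, 5000)
        life = np.where(start < 2.0, life * 10, life)
        cutoff = select_start_cutoff(lifetime_track_table(start, life))
        assert cutoff >= 2.0

    def test_identical_distributions_immediate(self):
        # all starts at 0 except a pair per candidate; lifetimes identical
        tracks = simple_tracks([1.0] * 50, starts=np.linspace(0, 5, 50))
        assert select_start_cutoff(tracks, min_tracks=5) == 0.0

    def test_error_when_no_cutoff_found(self):
        rng = np.random.default_rng(43)
        start = rng.uniform(0, 6, 2000)
        life = np.exp(start / 2.0) + rng.exponential(0.1, 2000)  # keeps changing
        with pytest.raises(ValueError, match="p-value"):
            select_start_cutoff(lifetime_track_table(start, life), max_cutoff=4.0)

    def test_never_later_than_last_testable_candidate(self):
        rng = np.random.default_rng(44)
        start = rng.uniform(0, 20, 2000)
        life = rng.exponential(1.5, 2000)
        cutoff = select_start_cutoff(lifetime_track_table(start, life))
        assert cutoff <= start.max() - 1.0


class TestLifetimeSummary:
    def test_single_movie_mean_median(self):
        summ = lifetime_summary(simple_tracks([1.0, 1.0, 1.0, 3.0]))
        assert summ.mean == pytest.approx(1.5)
        assert summ.median == pytest.approx(1.0)
        assert summ.n_tracks == 4

    def test_sd_across_two_big_movies(self):
        a = simple_tracks([1.0] * 50, movie_id=0)
        b = simple_tracks([2.0] * 50, movie_id=1)
        b["track_id"] += 100
        summ = lifetime_summary(pd.concat([a, b], ignore_index=True))
        assert summ.sd_across_movies == pytest.approx(np.sqrt(0.5), rel=1e-6)
        assert summ.n_movies_over_40 == 2

    def test_small_movie_pooled_but_not_in_sd(self):
        a = simple_tracks([1.0] * 50, movie_id=0)
        b = simple_tracks([2.0] * 50, movie_id=1)
        b["track_id"] += 100
        c = simple_tracks([10.0] * 30, movie_id=2)  # 30 tracks: below the rule
        c["track_id"] += 200
        summ = lifetime_summary(pd.concat([a, b, c], ignore_index=True))
        assert summ.sd_across_movies == pytest.approx(np.sqrt(0.5), rel=1e-6)
        assert summ.n_tracks == 130
        assert summ.n_movies == 3
        assert summ.n_movies_over_40 == 2

    def test_no_movie_over_40_gives_nan_sd(self):
        summ = lifetime_summary(simple_tracks([1.0] * 10))
        assert np.isnan(summ.sd_across_movies)

    def test_order_invariance(self):
        tracks = simple_tracks([1.0, 2.0, 3.0, 4.0])
        shuffled = tracks.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = lifetime_summary(tracks)
        b = lifetime_summary(shuffled)
        for k, va in a.__dict__.items():
            vb = b.__dict__[k]
            assert (np.isnan(va) and np.isnan(vb)) or va == vb


class TestEndToEnd:
    def test_three_four_five(self):
        tracks = pd.DataFrame(
            {"track_id": [0, 0], "movie_id": 0, "frame": [0, 1],
             "t_s": [0.0, 0.1], "x_nm": [0.0, 300.0], "y_nm": [0.0, 400.0]}
        )
        summ = summarize_tracks(tracks)
        assert summ["end_to_end_nm"].iloc[0] == pytest.approx(500.0)

    def test_fraction_over_zero_when_all_short(self):
        rng = np.random.default_rng(45)
        tracks = brownian_track_table(20, 4, 50.0, 0.0, rng)
        out = end_to_end_stats(tracks)
        assert out["fraction_over"] == 0.0

    def test_decile_medians_grow_with_lifetime_for_diffusion(self):
        rng = np.random.default_rng(46)
        rows = []
        for tid in range(300):
            n = rng.integers(4, 40)
            t = brownian_track_table(1, n, 2000.0, 0.0, rng)
            t["track_id"] = tid
            rows.append(t)
        tracks = pd.concat(rows, ignore_index=True)
        out = end_to_end_stats(tracks)
        assert out["top_decile_median_nm"] > out["bottom_decile_median_nm"]

    def test_refuses_fewer_than_ten_tracks(self):
        rng = np.random.default_rng(47)
        with pytest.raises(ValueError):
            end_to_end_stats(brownian_track_table(5, 4, 100.0, 0.0, rng))


class TestPairwiseDisplacements:
    def test_pair_count(self):
        rng = np.random.default_rng(48)
        tracks = brownian_track_table(1, 3, 100.0, 0.0, rng)
        assert len(pairwise_displacements(tracks)) == 3

    def test_stationary_all_zero(self):
        tracks = brownian_track_table(2, 5, 0.0, 0.0, np.random.default_rng(49))
        pairs = pairwise_displacements(tracks)
        assert np.allclose(pairs["dr_nm"], 0.0)

    def test_brownian_msd_follows_4Ddt(self):
        rng = np.random.default_rng(50)
        D = 1500.0
        tracks = brownian_track_table(800, 12, D, 0.0, rng)
        pairs = pairwise_displacements(tracks)
        assert len(pairs) >= 10_000
        from smtpatch.trackstats import msd_curve

        msd = msd_curve(pairs)
        for _, row in msd[msd["dt_s"] <= 0.5].iterrows():
            assert row["msd_nm2"] == pytest.approx(4 * D * row["dt_s"], rel=0.05)


class TestDiffusionFit:
    def test_exact_on_noiseless_line(self):
        dt = np.repeat(np.arange(1, 13) * 0.1, 5)
        pairs = pd.DataFrame(
            {"dt_s": dt, "dr_nm": np.sqrt(4 * 1000.0 * dt), "track_id": 0}
        )
        fit = msd_and_fit(pairs)
        assert fit.D == pytest.approx(1000.0, rel=1e-9)
        assert fit.intercept_b == pytest.approx(0.0, abs=1e-6)
        assert fit.n_points_used == 10

    def test_constant_offset_goes_to_intercept(self):
        dt = np.repeat(np.arange(1, 13) * 0.1, 5)
        pairs = pd.DataFrame(
            {"dt_s": dt, "dr_nm": np.sqrt(4 * 1000.0 * dt + 1e4), "track_id": 0}
        )
        fit = msd_and_fit(pairs)
        assert fit.D == pytest.approx(1000.0, rel=1e-9)
        assert fit.intercept_b == pytest.approx(1e4, rel=1e-9)

    def test_localization_noise_offset_recovered(self):
        rng = np.random.default_rng(51)
        D, sigma = 2000.0, 50.0
        tracks = brownian_track_table(500, 15, D, sigma, rng)
        fit = msd_and_fit(pairwise_displacements(tracks))
        assert fit.D == pytest.approx(D, rel=0.15)
        assert fit.intercept_b == pytest.approx(4 * sigma**2, rel=0.5)

    def test_insufficient_bins_rejected(self):
        pairs = pd.DataFrame({"dt_s": [0.1, 0.2], "dr_nm": [10, 20], "track_id": 0})
        with pytest.raises(ValueError):
            msd_and_fit(pairs)


class TestMobilityClassification:
    def test_low_cutoff_from_precision(self):
        cls = MobilityClassification(precision_multiplier=2.5, avg_precision_nm=50.0)
        assert cls.low_cutoff == pytest.approx(125.0)

    def test_small_displacement_is_low(self):
        pairs = pd.DataFrame({"dt_s": [0.5], "dr_nm": [100.0], "track_id": 0})
        out = classify_mobility(pairs)
        assert out.fractions["low"] == 1.0

    def test_above_boundary_is_high(self):
        cls = MobilityClassification(d_ref=1000.0)
        dt = 2.0
        dr = np.sqrt(4 * 1000.0 * dt) * 2  # above the curve and the 125 nm floor
        pairs = pd.DataFrame({"dt_s": [dt], "dr_nm": [dr], "track_id": 0})
        out = classify_mobility(pairs, cls)
        assert out.fractions["high"] == 1.0

    def test_stationary_with_noise_mostly_low(self):
        rng = np.random.default_rng(52)
        tracks = brownian_track_table(200, 8, 0.0, 30.0, rng)
        out = classify_mobility(pairwise_displacements(tracks))
        assert out.fractions["low"] >= 0.95

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(53)
        tracks = brownian_track_table(100, 10, 2000.0, 40.0, rng)
        out = classify_mobility(pairwise_displacements(tracks))
        assert sum(out.fractions.values()) == pytest.approx(1.0)

    def test_boundary_table_and_range_error(self):
        tab = pd.DataFrame({"dt_s": [0.1, 1.0], "dr_nm": [50.0, 200.0]})
        cls = MobilityClassification(boundary_table=tab)
        pairs = pd.DataFrame({"dt_s": [2.0], "dr_nm": [300.0], "track_id": 0})
        with pytest.raises(ValueError):
            classify_mobility(pairs, cls)


class TestCompareDistributions:
    def test_identical_samples_p_near_one(self):
        a = np.arange(1, 101, dtype=float)
        assert compare_distributions(a, a.copy()) >= 0.99

    def test_separated_distributions_tiny_p(self):
        rng = np.random.default_rng(54)
        a = rng.exponential(1.0, 200)
        b = rng.exponential(5.0, 200)
        assert compare_distributions(a, b) < 1e-4

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [1.0, 2.0])


class TestPhotobleachRate:
    def test_exact_exponential(self):
        t = np.arange(600) * 0.1
        rate = photobleach_rate(100 * np.exp(-0.15 * t))
        assert rate == pytest.approx(0.15, abs=0.005)

    def test_constant_counts_zero_rate(self):
        assert abs(photobleach_rate(np.full(100, 50.0))) < 0.005

    def test_poisson_noise_within_ten_percent(self):
        rng = np.random.default_rng(55)
        t = np.arange(600) * 0.1
        counts = rng.poisson(200 * np.exp(-0.15 * t)).astype(float)
        assert photobleach_rate(counts) == pytest.approx(0.15, rel=0.10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            photobleach_rate(np.zeros(50))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            photobleach_rate(np.ones(5))
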
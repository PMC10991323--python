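"""Synthetic walk, renderer and group-distance generator."""

import dataclasses

import numpy as np
import pytest

from anttrail import (
    ArenaConfig,
    GeometryError,
    GroupDesign,
    RenderParams,
    TrailLine,
    WalkParams,
    point_segment_distance,
    render_frames,
    simulate_group_distances,
    simulate_trajectory,
)
from anttrail.synthetic import arena_template, default_design


class TestWalk:
    def test_seeded_reproducibility(self, small_arena, trail):
        wp = WalkParams(trail_attraction=0.7, seed=5)
        a = simulate_trajectory(wp, small_arena, trail)
        b = simulate_trajectory(wp, small_arena, trail)
        np.testing.assert_array_equal(a.x_mm, b.x_mm)
        np.testing.assert_array_equal(a.y_mm, b.y_mm)

    def test_zero_speed_is_stationary(self, small_arena, trail):
        traj = simulate_trajectory(
            WalkParams(mean_speed_mm_s=0.0, seed=2), small_arena, trail
        )
        assert np.all(traj.x_mm == traj.x_mm[0])
        assert np.all(traj.y_mm == traj.y_mm[0])
        assert np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm)).sum() == 0.0

    def test_trail_outside_arena_rejected(self, small_arena):
        bad = TrailLine((-10.0, 45.0), (150.0, 45.0))
        with pytest.raises(GeometryError):
            simulate_trajectory(WalkParams(), small_arena, bad)

    def test_stays_inside_arena(self, small_arena, trail):
        traj = simulate_trajectory(WalkParams(seed=3), small_arena, trail)
        assert traj.x_mm.min() >= 0 and traj.x_mm.max() <= small_arena.width_mm
        assert traj.y_mm.min() >= 0 and traj.y_mm.max() <= small_arena.height_mm

    def test_unbiased_walk_matches_band_area_fraction(self, trail):
        """With zero attraction the walk explores uniformly, so the
        time in the 5 mm band matches its share of the arena area."""
        arena = ArenaConfig(px_per_mm=2.0, duration_s=600.0)
        xs = np.linspace(0, arena.width_mm, 801)
        ys = np.linspace(0, arena.height_mm, 451)
        X, Y = np.meshgrid(xs, ys)
        d = point_segment_distance(np.column_stack([X.ravel(), Y.ravel()]), trail)
        area_frac = (d < 5.0).mean()
        fracs = [
            simulate_trajectory(
                WalkParams(trail_attraction=0.0, seed=s), arena, trail
            ).on_trail_true.mean()
            for s in range(8)
        ]
        assert np.mean(fracs) == pytest.approx(area_frac, abs=0.02)

    def test_on_trail_fraction_monotone_in_attraction(self, trail):
        arena = ArenaConfig(px_per_mm=2.0, duration_s=120.0)
        means = []
        for a in (0.0, 0.3, 1.0, 3.0):
            fr = [
                simulate_trajectory(
                    WalkParams(trail_attraction=a, seed=s), arena, trail
                ).on_trail_true.mean()
                for s in range(20)
            ]
            means.append(np.mean(fr))
        assert all(m1 < m2 for m1, m2 in zip(means, means[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WalkParams(mean_speed_mm_s=-1.0)
        with pytest.raises(ValueError):
            WalkParams(pause_prob=1.5)


class TestRender:
    def test_frame_count_matches_trajectory(self, clean_video, walk_traj, small_arena):
        assert clean_video.n_frames == len(walk_traj)
        assert clean_video.n_frames == small_arena.n_frames
        assert clean_video.duration_s == pytest.approx(small_arena.duration_s)

    def test_three_minutes_at_25hz_is_4500_frames(self):
        assert ArenaConfig(duration_s=180.0, frame_rate_hz=25.0).n_frames == 4500

    def test_invalid_samples_render_bare_template(self, small_arena, trail):
        from anttrail.trajectory import Trajectory

        n = 5
        traj = Trajectory(
            t_s=np.arange(n) * 0.04,
            x_mm=np.full(n, np.nan),
            y_mm=np.full(n, np.nan),
            valid=np.zeros(n, bool),
            frame_period_ms=40.0,
        )
        rp = RenderParams(noise_sd=0.0)
        frames = render_frames(traj, small_arena, rp, trail)
        template = np.clip(np.rint(arena_template(small_arena, trail, rp)), 0, 255)
        for f in frames.frames:
            np.testing.assert_array_equal(f, template.astype(np.uint8))

    def test_dark_centroid_matches_true_position(self, small_arena, trail):
        """Brute-force intensity-weighted dark-pixel centroid (line band
        masked out) recovers the true centre to < 0.5 px."""
        rp = RenderParams(noise_sd=0.0)
        traj = simulate_trajectory(
            WalkParams(trail_attraction=0.0, seed=7), small_arena, trail
        )
        frames = render_frames(traj, small_arena, rp, trail)
        template = arena_template(small_arena, trail, rp)
        line_mask = template < rp.background_intensity
        ppm = small_arena.px_per_mm
        from anttrail import point_segment_distance

        checked = 0
        for i in range(0, len(traj), 11):
            # masking the band clips any overlapping ant and would bias
            # the oracle, so only clear-of-the-line frames qualify
            clearance = point_segment_distance((traj.x_mm[i], traj.y_mm[i]), trail)
            if clearance < rp.ant_length_mm / 2 + rp.line_halfwidth_mm + 1.0:
                continue
            checked += 1
            d = rp.background_intensity - frames.frames[i].astype(float)
            d[line_mask] = 0.0
            d[d < 5.0] = 0.0
            rows, cols = np.mgrid[0 : d.shape[0], 0 : d.shape[1]]
            cx = (cols * d).sum() / d.sum()
            cy = (rows * d).sum() / d.sum()
            tx = traj.x_mm[i] * ppm - 0.5
            ty = traj.y_mm[i] * ppm - 0.5
            assert np.hypot(cx - tx, cy - ty) < 0.5
        assert checked >= 5

    def test_out_of_arena_trajectory_rejected(self, small_arena, trail):
        from anttrail.trajectory import Trajectory

        traj = Trajectory(
            t_s=[0.0], x_mm=[-5.0], y_mm=[10.0], valid=[True], frame_period_ms=40.0
        )
        with pytest.raises(GeometryError):
            render_frames(traj, small_arena, RenderParams(), trail)


class TestGroupDistances:
    def test_row_count_13_groups_times_15(self):
        g = simulate_group_distances(default_design(n_per_group=15, seed=0))
        assert len(g.data) == 13 * 15
        assert len(g.labels) == 13

    def test_seeded_reproducibility(self):
        d = default_design(seed=42)
        a = simulate_group_distances(d).data
        b = simulate_group_distances(d).data
        assert a.equals(b)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(groups=(("blank", "-"), ("x", "1")), dispersion=-0.1)

    def test_control_must_be_present_exactly_once(self):
        with pytest.raises(ValueError):
            GroupDesign(groups=(("x", "1"), ("y", "2")), control=("blank", "-"))
        with pytest.raises(ValueError):
            GroupDesign(
                groups=(("blank", "-"), ("blank", "-")), control=("blank", "-")
            )

    def test_y_nonnegative_and_lln_group_means(self):
        """Empirical ln(y+1) means converge to the design means."""
        design = GroupDesign(
            groups=(("blank", "-"), ("x", "1e0")),
            n_per_group=10_000,
            effect_profile={("x", "1e0"): 1.5},
            control=("blank", "-"),
            seed=9,
        )
        g = simulate_group_distances(design)
        assert (g.data["y_mm"] >= 0).all()
        got_control = np.log1p(g.values("blank@-")).mean()
        got_shift = np.log1p(g.values("x@1e0")).mean() - got_control
        assert got_control == pytest.approx(design.control_ln_mean, abs=0.03)
        assert got_shift == pytest.approx(1.5, abs=0.04)

    def test_nonresponders_excluded_and_tallied(self):
        design = dataclasses.replace(
            default_design(seed=3), nonresponder_prob=0.3
        )
        g = simulate_group_distances(design)
        assert len(g.data) + sum(g.excluded.values()) == 13 * 15
        assert sum(g.excluded.values()) > 0
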
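"""Trajectory statistics: dwell accounting, linearity, wall episodes,
contact angles, wigwag extraction, and the occupancy KDE."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import wigwag as w
from wigwag.arena import Region


def band_point(partition, inset=0.0):
    """A point inside the wall band of a circular partition."""
    r = partition.field.radius - partition.wall_margin / 2 - inset
    return (r, 0.0)


class TestPreference:
    def test_all_wall_trajectory(self, circle_partition, toy_trajectory_factory):
        traj = toy_trajectory_factory([band_point(circle_partition)] * 5)
        res = w.preference_indices(traj, circle_partition)
        assert res.wall_index == 1.0 and res.central_index == 0.0

    def test_toy_counts(self, circle_partition, toy_trajectory_factory):
        wallp = band_point(circle_partition)
        pts = [wallp] * 4 + [(0.0, 0.0)] * 6
        res = w.preference_indices(toy_trajectory_factory(pts), circle_partition)
        assert res.wall_index == pytest.approx(0.4)
        assert res.central_index == pytest.approx(0.6)
        assert res.T == pytest.approx(1.0)
        assert res.T_w == pytest.approx(0.4)

    def test_dwell_conservation(self, circle_field, circle_partition, intact_params):
        traj = w.simulate(intact_params, circle_field, 120, 3)
        times = w.region_times(traj, circle_partition)
        total = sum(times.values())
        assert total == pytest.approx(len(traj) * traj.dt)
        assert Region.OUTSIDE not in times

    def test_indices_sum_at_most_one(self, circle_field, circle_partition, intact_params):
        for seed in range(5):
            traj = w.simulate(intact_params, circle_field, 60, seed)
            res = w.preference_indices(traj, circle_partition)
            assert 0.0 <= res.wall_index + res.central_index <= 1.0 + 1e-12

    def test_empty_trajectory_rejected(self, circle_partition):
        traj = w.Trajectory(times=np.array([]), positions=np.empty((0, 2)))
        with pytest.raises(ValueError):
            w.preference_indices(traj, circle_partition)


class TestTnRatio:
    def test_straight_path_is_one(self, toy_trajectory_factory):
        traj = toy_trajectory_factory([(0, t) for t in range(10)])
        assert w.tn_ratio(traj) == pytest.approx(1.0)

    def test_right_angle_equal_legs_is_sqrt2(self, toy_trajectory_factory):
        pts = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2)]
        assert w.tn_ratio(toy_trajectory_factory(pts)) == pytest.approx(math.sqrt(2))

    def test_zero_net_displacement_rejected(self, toy_trajectory_factory):
        traj = toy_trajectory_factory([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError, match="undefined"):
            w.tn_ratio(traj)

    def test_approach_segments_are_near_straight(self, circle_field, intact_params):
        """Linearity of the approach step (center to first wall
        contact): most T/N ratios fall in 1..1.2."""
        ratios = []
        for seed in range(20):
            traj = w.simulate(intact_params, circle_field, 120, seed)
            r = np.linalg.norm(traj.positions, axis=1)
            hit = np.nonzero(r >= circle_field.radius - 1e-6)[0]
            stop = hit[0] + 1 if len(hit) else len(traj)
            approach = w.Trajectory(times=traj.times[:stop], positions=traj.positions[:stop])
            ratios.append(w.tn_ratio(approach))
        ratios = np.array(ratios)
        assert (ratios >= 1.0).all()
        # the bulk of approaches is nearly straight; occasional wander
        # before the first contact produces a long tail
        assert np.percentile(ratios, 25) <= 1.2
        assert np.median(ratios) <= 1.5

    @given(
        pts=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)), min_size=2, max_size=30
        )
    )
    def test_ratio_at_least_one(self, pts):
        pts = [(float(x), float(y)) for x, y in pts]
        traj = w.Trajectory(times=np.arange(len(pts)) * 0.1, positions=np.array(pts))
        net = math.hypot(pts[-1][0] - pts[0][0], pts[-1][1] - pts[0][1])
        if net == 0:
            return
        assert w.tn_ratio(traj) >= 1.0 - 1e-12


class TestWallEpisodes:
    def test_never_entering_band_gives_empty_list(self, circle_partition, toy_trajectory_factory):
        episodes, mean_dwell = w.wall_episodes(
            toy_trajectory_factory([(0, 0)] * 10), circle_partition
        )
        assert episodes == [] and math.isnan(mean_dwell)

    def test_single_closed_episode(self, circle_partition, toy_trajectory_factory):
        wallp = band_point(circle_partition)
        # enter band at t=5.0, exit at t=12.0 (dt = 0.1 grid -> 50, 120)
        pts = [(0, 0)] * 50 + [wallp] * 70 + [(0, 0)] * 30
        episodes, mean_dwell = w.wall_episodes(toy_trajectory_factory(pts), circle_partition)
        assert len(episodes) == 1
        ep = episodes[0]
        assert not ep.open
        assert ep.t_contact == pytest.approx(5.0)
        assert ep.t_detach == pytest.approx(12.0)
        assert ep.dwell == pytest.approx(7.0)
        assert mean_dwell == pytest.approx(7.0)

    def test_open_trailing_episode(self, circle_partition, toy_trajectory_factory):
        wallp = band_point(circle_partition)
        pts = [(0, 0)] * 50 + [wallp] * 51
        episodes, _ = w.wall_episodes(toy_trajectory_factory(pts), circle_partition)
        (ep,) = episodes
        assert ep.open and ep.t_detach is None
        assert ep.dwell == pytest.approx(10.0 - 5.0)

    def test_closed_dwell_sum_matches_band_time(self, circle_partition, toy_trajectory_factory):
        wallp = band_point(circle_partition)
        pts = [(0, 0)] * 10 + [wallp] * 20 + [(0, 0)] * 10 + [wallp] * 30 + [(0, 0)] * 10
        traj = toy_trajectory_factory(pts)
        episodes, _ = w.wall_episodes(traj, circle_partition)
        assert all(not e.open for e in episodes)
        res = w.preference_indices(traj, circle_partition)
        assert sum(e.dwell for e in episodes) == pytest.approx(res.T_w)


class TestIncidenceReflection:
    def test_no_contact_gives_empty_list(self, circle_field, toy_trajectory_factory):
        traj = toy_trajectory_factory([(0, t) for t in range(10)], field=circle_field)
        assert w.incidence_reflection(traj) == []

    def test_simulated_contacts_are_tangential(self, circle_field, intact_params):
        pairs = []
        for seed in range(10):
            traj = w.simulate(intact_params, circle_field, 120, seed)
            pairs.extend(w.incidence_reflection(traj))
        assert len(pairs) > 0
        incid = np.array([p[0] for p in pairs])
        refl = np.array([p[1] for p in pairs])
        assert incid.max() <= 90.0 + 1e-9
        # sliding keeps the post-contact heading along the wall; only a
        # wigwag landing exactly on the contact tick can deflect it
        assert np.median(np.abs(refl)) <= 1.0

    def test_open_field_rejected(self, intact_params):
        traj = w.simulate(intact_params, w.make_field("open"), 10, 1)
        with pytest.raises(ValueError):
            w.incidence_reflection(traj)


class TestKinematics:
    def test_interior_speed_is_ten_units_per_s(self, circle_field, circle_partition, intact_params):
        traj = w.simulate(intact_params, circle_field, 15, 2)  # still far from wall
        kin = w.kinematics(traj, circle_partition)
        assert kin.speeds == pytest.approx(10.0)
        assert kin.total_distance == pytest.approx(150.0)

    def test_stationary_trajectory(self, circle_partition, toy_trajectory_factory):
        kin = w.kinematics(toy_trajectory_factory([(0, 0)] * 5), circle_partition)
        assert kin.total_distance == 0.0
        assert kin.time_to_first_wall is None


class TestExtractWigwag:
    def test_round_trips_simulator_event_log(self, intact_params):
        """Events recovered from positions match the logged wigwags:
        same ticks, angles to the 0.01-rad rounding, intervals from the
        countdowns (zero-angle wigwags are invisible and merge their
        neighbors' intervals)."""
        traj = w.simulate(intact_params, w.make_field("open"), 300, 11)
        ext = w.extract_wigwag(traj)
        visible = [e for e in traj.event_log if e.angle != 0.0]
        assert len(visible) > 50
        assert np.array_equal(ext.ticks, [e.tick for e in visible])
        assert ext.angles == pytest.approx([e.angle for e in visible], abs=1e-9)
        assert ext.intervals == pytest.approx(np.diff(ext.ticks) * 0.1)

    def test_straight_trajectory_has_no_events(self, toy_trajectory_factory):
        traj = toy_trajectory_factory([(0, t) for t in range(20)])
        ext = w.extract_wigwag(traj)
        assert len(ext.angles) == 0

    def test_intervals_are_positive_multiples_of_dt(self, intact_params):
        traj = w.simulate(intact_params, w.make_field("open"), 120, 4)
        ext = w.extract_wigwag(traj)
        ticks = np.round(ext.intervals / traj.dt)
        assert (ticks >= 1).all()
        assert ext.intervals == pytest.approx(ticks * traj.dt)

    def test_too_few_points_rejected(self, toy_trajectory_factory):
        with pytest.raises(ValueError):
            w.extract_wigwag(toy_trajectory_factory([(0, 0), (0, 1)]))


class TestOccupancyKde:
    def make_traj(self, intact_params, circle_field, seed=1, duration=60):
        return w.simulate(intact_params, circle_field, duration, seed)

    def test_density_sums_to_one(self, intact_params, circle_field):
        traj = self.make_traj(intact_params, circle_field)
        grid = w.occupancy_kde(traj, circle_field, bandwidth_mm=3.0)
        assert grid.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (grid.density >= 0).all()

    def test_point_mass_peaks_at_its_cell(self, circle_field, toy_trajectory_factory):
        loc = (100.0, 50.0)  # sim-units
        traj = toy_trajectory_factory([loc] * 10)
        grid = w.occupancy_kde(traj, circle_field, bandwidth_mm=2.0)
        iy, ix = np.unravel_index(grid.density.argmax(), grid.density.shape)
        mm = 3.0 / 14.0
        assert abs(grid.x_centers[ix] - loc[0] * mm) <= grid.cell_mm
        assert abs(grid.y_centers[iy] - loc[1] * mm) <= grid.cell_mm

    def test_deterministic_and_order_invariant(self, intact_params, circle_field):
        a = self.make_traj(intact_params, circle_field, seed=1)
        b = self.make_traj(intact_params, circle_field, seed=2)
        g1 = w.occupancy_kde([a, b], circle_field)
        g2 = w.occupancy_kde([b, a], circle_field)
        assert g1.bandwidth_mm == g2.bandwidth_mm
        assert np.array_equal(g1.density, g2.density)

    def test_duplication_invariance_at_fixed_bandwidth(self, intact_params, circle_field):
        traj = self.make_traj(intact_params, circle_field)
        g1 = w.occupancy_kde([traj], circle_field, bandwidth_mm=3.0)
        g2 = w.occupancy_kde([traj, traj], circle_field, bandwidth_mm=3.0)
        assert np.allclose(g1.density, g2.density, atol=1e-12)

    def test_lscv_picks_interior_bandwidth_on_smooth_data(self, intact_params, circle_field):
        traj = self.make_traj(intact_params, circle_field, duration=120)
        grid = w.occupancy_kde(traj, circle_field)
        assert grid.bandwidth_mm > 0

    def test_empty_input_rejected(self, circle_field):
        with pytest.raises(ValueError):
            w.occupancy_kde([], circle_field)
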
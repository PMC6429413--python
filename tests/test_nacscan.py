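import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hingewatch import synthetic
from hingewatch.errors import GeometryError, SelectionError, TrajectoryError
from hingewatch.nacscan import (
    NacRecord,
    SiteDefinition,
    closure_series,
    nac_filter,
    nac_scatter,
    op_distance_series,
    opo_angle_series,
)
from hingewatch.structio import GeometrySeries, Trajectory

from conftest import toy_structure


def triad_structure(o_nuc, p, o_leaving, extra=None):
    """Minimal site: nucleophile O, γ-P, leaving O (+ optional closure pair)."""
    coords = [o_nuc, p, o_leaving] + (extra or [[20.0, 0, 0], [30.0, 0, 0]])
    return toy_structure(np.asarray(coords, float))


def triad_site():
    return SiteDefinition(
        label="L2-K1",
        closure_pair=(3, 4),
        nucleophile_oxygens={"O3": 0},
        gamma_phosphorus=1,
        leaving_oxygen=2,
    )


def static_traj(structure, n=3):
    return Trajectory(structure, np.arange(float(n)), np.repeat(structure.coords[None], n, axis=0))


class TestClosureSeries:
    def test_static_pair_distance(self):
        s = triad_structure([0, 0, 0], [3, 0, 0], [4.6, 0, 0], extra=[[0, 0, 10], [0, 0, 0]])
        series = closure_series(static_traj(s), triad_site())
        np.testing.assert_allclose(series.values, 10.0, atol=1e-12)

    def test_planted_linear_approach(self):
        s = triad_structure([0, 0, 0], [3, 0, 0], [4.6, 0, 0])
        ramp = np.linspace(14.0, 4.0, 25)
        frames = np.repeat(s.coords[None], 25, axis=0)
        frames[:, 4, 0] = frames[:, 3, 0] + ramp  # move closure atom B
        traj = Trajectory(s, np.arange(25.0), frames)
        series = closure_series(traj, triad_site())
        np.testing.assert_allclose(series.values, ramp, atol=1e-6)

    def test_single_frame_series(self):
        s = triad_structure([0, 0, 0], [3, 0, 0], [4.6, 0, 0])
        series = closure_series(static_traj(s, n=1), triad_site())
        assert len(series) == 1


class TestDistanceSeries:
    def test_boundary_distance_value(self):
        s = triad_structure([0.0, 0, 0], [3.5, 0, 0], [5.1, 0, 0])
        series = op_distance_series(static_traj(s), triad_site(), "O3")
        np.testing.assert_allclose(series.values, 3.5, atol=1e-12)

    def test_coincident_atoms_are_flagged_nonphysical(self):
        s = triad_structure([3.5, 0, 0], [3.5, 0, 0], [5.1, 0, 0])
        with pytest.raises(GeometryError, match="nonphysical"):
            op_distance_series(static_traj(s), triad_site(), "O3")

    def test_unknown_oxygen_label(self):
        s = triad_structure([0, 0, 0], [3.5, 0, 0], [5.1, 0, 0])
        with pytest.raises(SelectionError):
            op_distance_series(static_traj(s), triad_site(), "O9")


class TestAngleSeries:
    def test_in_line_is_180(self):
        s = triad_structure([-2.0, 0, 0], [0.0, 0, 0], [1.6, 0, 0])
        series = opo_angle_series(static_traj(s), triad_site(), "O3")
        np.testing.assert_allclose(series.values, 180.0, atol=1e-9)

    def test_right_angle_is_90(self):
        s = triad_structure([0.0, 2.0, 0], [0.0, 0, 0], [1.6, 0, 0])
        series = opo_angle_series(static_traj(s), triad_site(), "O3")
        np.testing.assert_allclose(series.values, 90.0, atol=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 120.0, 155.0, 178.45])
    def test_constructed_angle_is_recovered(self, theta):
        rad = np.radians(theta)
        o_nuc = 3.0 * np.array([np.cos(rad), np.sin(rad), 0.0])
        s = triad_structure(o_nuc, [0.0, 0, 0], [1.6, 0, 0])
        series = opo_angle_series(static_traj(s), triad_site(), "O3")
        np.testing.assert_allclose(series.values, theta, atol=1e-6)

    def test_zero_length_vector_is_an_error(self):
        s = triad_structure([-2.0, 0, 0], [0.0, 0, 0], [0.0, 0, 0])
        with pytest.raises(GeometryError):
            opo_angle_series(static_traj(s), triad_site(), "O3")

    def test_geometry_invariant_under_rigid_motion(self, rng):
        o_nuc = np.array([-3.1, 0.4, 0.2])
        s = triad_structure(o_nuc, [0.0, 0, 0], [1.5, 0.3, 0])
        base_d = op_distance_series(static_traj(s), triad_site(), "O3").values
        base_a = opo_angle_series(static_traj(s), triad_site(), "O3").values
        rot = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        moved = toy_structure(s.coords @ rot.T + rng.normal(scale=30.0, size=3))
        d = op_distance_series(static_traj(moved), triad_site(), "O3").values
        a = opo_angle_series(static_traj(moved), triad_site(), "O3").values
        np.testing.assert_allclose(d, base_d, atol=1e-9)
        np.testing.assert_allclose(a, base_a, atol=1e-9)


def series_pair(distances, angles):
    t = np.arange(float(len(distances)))
    return (
        GeometrySeries(t, np.asarray(distances, float), kind="distance"),
        GeometrySeries(t, np.asarray(angles, float), kind="angle"),
    )


class TestNacFilter:
    def test_reference_near_attack_geometry_passes(self):
        d, a = series_pair([3.16], [170.0])
        census = nac_filter(d, a)
        assert census.n_pass == 1
        assert census.records[0].vdw_contact  # 3.16 < 3.3 vdW contact sum

    def test_thresholds_are_strict(self):
        d, a = series_pair([3.5, 3.49, 3.49], [178.0, 155.0, 155.01])
        census = nac_filter(d, a)
        assert [r.passes for r in census.records] == [False, False, True]

    def test_planted_census_is_exact(self, rng):
        n = 500
        distances = rng.uniform(4.0, 12.0, size=n)
        angles = rng.uniform(60.0, 150.0, size=n)
        planted = rng.choice(n, size=37, replace=False)
        distances[planted] = rng.uniform(3.0, 3.4, size=37)
        angles[planted] = rng.uniform(156.0, 180.0, size=37)
        d, a = series_pair(distances, angles)
        census = nac_filter(d, a)
        assert census.n_pass == 37
        assert census.time_fraction == pytest.approx(37 / n)

    def test_mismatched_time_grids_rejected(self):
        d, _ = series_pair([3.0, 3.0], [160.0, 160.0])
        a = GeometrySeries(np.array([0.0, 2.0]), np.array([160.0, 160.0]), kind="angle")
        with pytest.raises(TrajectoryError):
            nac_filter(d, a)

    @given(
        seed=st.integers(0, 2**31 - 1),
        d_relax=st.floats(0.0, 2.0),
        a_relax=st.floats(0.0, 30.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_filter_is_monotone_in_thresholds(self, seed, d_relax, a_relax):
        """Relaxing d_cut upward or a_cut downward never loses passing frames."""
        rng = np.random.default_rng(seed)
        d, a = series_pair(rng.uniform(2.5, 6.0, 50), rng.uniform(120.0, 180.0, 50))
        strict = nac_filter(d, a, d_cut=3.5, a_cut=155.0).n_pass
        relaxed = nac_filter(d, a, d_cut=3.5 + d_relax, a_cut=155.0 - a_relax).n_pass
        assert relaxed >= strict

    def test_invalid_record_geometry_rejected(self):
        with pytest.raises(GeometryError):
            NacRecord(0.0, "O3", -1.0, 160.0, True)
        with pytest.raises(GeometryError):
            NacRecord(0.0, "O3", 3.0, 190.0, True)


class TestNacScatter:
    def test_all_passing_input_is_fully_selectable(self):
        d, a = series_pair([3.0, 3.1], [170.0, 165.0])
        table = nac_scatter(nac_filter(d, a))
        assert len(table) == 2
        assert table["passes"].all()

    def test_empty_passing_subset_is_not_an_error(self):
        d, a = series_pair([5.0, 6.0], [100.0, 120.0])
        table = nac_scatter(nac_filter(d, a))
        assert len(table) == 2
        assert not table["passes"].any()

    def test_two_cluster_row_counts(self, rng):
        near = (rng.uniform(3.0, 3.4, 20), rng.uniform(160.0, 180.0, 20))
        far = (rng.uniform(8.0, 12.0, 30), rng.uniform(60.0, 100.0, 30))
        d, a = series_pair(
            np.concatenate([near[0], far[0]]), np.concatenate([near[1], far[1]])
        )
        table = nac_scatter(nac_filter(d, a))
        assert int(table["passes"].sum()) == 20
        assert int((~table["passes"]).sum()) == 30


class TestPlantedEpisodes:
    def test_planted_extremes_and_census(self, small_spec, small_dimer):
        traj = synthetic.make_hinge_trajectory(small_dimer, small_spec, n_frames=2000)
        site = synthetic.site_definitions(small_dimer)[0]
        episode = synthetic.NacEpisode(
            300.0, 1500.0, oxygen="O3", min_distance=3.16, max_angle=178.45, n_pass=395
        )
        planted = synthetic.plant_nac_episode(traj, site, episode)
        d = op_distance_series(planted, site, "O3")
        a = opo_angle_series(planted, site, "O3")
        census = nac_filter(d, a)
        assert census.n_pass == 395
        assert min(r.distance for r in census.passing) == pytest.approx(3.16, abs=1e-9)
        assert max(r.angle for r in census.passing) == pytest.approx(178.45, abs=1e-9)

    def test_no_episode_means_no_passing_frames(self, small_spec, small_dimer):
        traj = synthetic.make_hinge_trajectory(small_dimer, small_spec, n_frames=300)
        site = synthetic.site_definitions(small_dimer)[0]
        d = op_distance_series(traj, site, "O3")
        a = opo_angle_series(traj, site, "O3")
        assert nac_filter(d, a).n_pass == 0
        assert d.values.min() > 10.0  # baseline geometry stays far

    def test_disjoint_single_frame_episodes_count_exactly(self, small_spec, small_dimer):
        traj = synthetic.make_hinge_trajectory(small_dimer, small_spec, n_frames=400)
        site = synthetic.site_definitions(small_dimer)[0]
        episodes = [
            synthetic.NacEpisode(t, t + 1.0, oxygen="O3", min_distance=3.0,
                                 max_angle=175.0, n_pass=1)
            for t in (50.0, 120.0, 290.0)
        ]
        planted = synthetic.plant_nac_episode(traj, site, episodes)
        d = op_distance_series(planted, site, "O3")
        a = opo_angle_series(planted, site, "O3")
        assert nac_filter(d, a).n_pass == 3

    def test_overlapping_episodes_rejected(self, small_spec, small_dimer):
        traj = synthetic.make_hinge_trajectory(small_dimer, small_spec, n_frames=100)
        site = synthetic.site_definitions(small_dimer)[0]
        episodes = [
            synthetic.NacEpisode(10.0, 50.0, oxygen="O3"),
            synthetic.NacEpisode(40.0, 80.0, oxygen="O3"),
        ]
        with pytest.raises(TrajectoryError, match="overlap"):
            synthetic.plant_nac_episode(traj, site, episodes)
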
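import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_trajectory
from oracles import oracle_features

from kinvae import (
    FEATURE_NAMES,
    CohortData,
    FeatureDataset,
    Trajectory,
    acceleration_series,
    build_dataset,
    directional_change_series,
    generate_trajectory,
    speed_series,
    straightness,
    trajectory_features,
)
from kinvae.exceptions import (
    DegenerateTrajectoryError,
    SchemaError,
    ZeroVarianceFeatureError,
)
from kinvae.trajectory import KinematicParams

DT = 0.025


def make_traj(points, dt=DT):
    pts = np.asarray(points, dtype=float)
    return Trajectory("P0", 0, 0, np.arange(len(pts)) * dt, pts[:, 0], pts[:, 1])


class TestSpeedSeries:
    def test_stationary_finger_gives_zero_speeds(self):
        tr = make_traj([(5, 5)] * 4)
        assert np.all(speed_series(tr) == 0)

    def test_unit_steps_at_40hz_give_40_units_per_second(self):
        tr = make_traj([(i, 0) for i in range(5)])
        assert speed_series(tr) == pytest.approx([40.0] * 4)

    def test_length_is_samples_minus_one(self):
        tr = make_traj([(i, i % 2) for i in range(5)])
        assert len(speed_series(tr)) == 4


class TestAccelerationSeries:
    def test_constant_speed_gives_zero_acceleration(self):
        assert np.all(acceleration_series(np.full(6, 40.0), DT) == 0)

    def test_single_step_value(self):
        assert acceleration_series(np.array([0.0, 40.0]), DT) == pytest.approx([1600.0])

    def test_reversed_ramp_negates(self):
        v = np.array([0.0, 10.0, 25.0, 45.0])
        assert acceleration_series(v[::-1], DT) == pytest.approx(
            -acceleration_series(v, DT)[::-1]
        )

    def test_too_short_raises(self):
        with pytest.raises(DegenerateTrajectoryError):
            acceleration_series(np.array([1.0]), DT)


class TestDirectionalChange:
    def test_collinear_motion_gives_zero(self):
        tr = make_traj([(i, 2 * i) for i in range(6)])
        assert directional_change_series(tr) == pytest.approx([0.0] * 4, abs=1e-9)

    def test_right_angle_turn(self):
        tr = make_traj([(0, 0), (1, 0), (1, 1)])
        assert directional_change_series(tr) == pytest.approx([(np.pi / 2) / DT])

    def test_zero_length_displacements_skipped(self):
        tr = make_traj([(0, 0), (1, 0), (1, 0), (1, 1)])
        # 3 nonzero displacements -> series of length 2... here only 2 nonzero
        assert len(directional_change_series(tr)) == 1

    def test_all_zero_displacements_raise(self):
        tr = make_traj([(1, 1)] * 3)
        with pytest.raises(DegenerateTrajectoryError):
            directional_change_series(tr)


class TestStraightness:
    def test_straight_path(self):
        assert straightness(make_traj([(0, 0), (1, 1), (2, 2)])) == 1.0

    def test_closed_path_is_zero(self):
        assert straightness(make_traj([(0, 0), (1, 0), (0, 0)])) == 0.0

    def test_l_shaped_path(self):
        tr = make_traj([(0, 0), (1, 0), (1, 1)])
        assert straightness(tr) == pytest.approx(np.sqrt(2) / 2)


class TestTrajectoryFeatures:
    def test_constant_velocity_straight_drag(self):
        tr = make_traj([(i, 0) for i in range(8)])
        f = trajectory_features(tr)
        assert f["sdSpeed"] == 0
        assert f["MeanSpeed"] == f["MaxSpeed"] == f["MinSpeed"] == pytest.approx(40.0)
        assert f["MeanAcceleration"] == f["MaxAcceleration"] == f["MinAcceleration"] == 0
        assert f["sdAcceleration"] == 0
        assert f["STH"] == 1.0
        assert f["DC"] == 0 and f["sdDC"] == 0
        assert f["MeanLength"] == pytest.approx(7.0)

    def test_single_peak_profile_max_stat_is_peak(self):
        # positions with speed profile 40,80,120,80,40 -> unique interior max
        steps = [1, 2, 3, 2, 1]
        xs = np.concatenate([[0], np.cumsum(steps)])
        tr = make_traj([(x, 0) for x in xs])
        f = trajectory_features(tr)
        assert f["MaxSpeed"] == pytest.approx(120.0)

    def test_global_peaks_respect_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tr = random_trajectory(rng, n=12)
            f = trajectory_features(tr, peaks="global")
            assert f["MinSpeed"] <= f["MeanSpeed"] <= f["MaxSpeed"]
            assert f["MinAcceleration"] <= f["MeanAcceleration"] <= f["MaxAcceleration"]

    def test_oracle_equivalence_on_random_trajectories(self):
        rng = np.random.default_rng(123)
        for peaks in ("local", "global"):
            for _ in range(30):
                tr = random_trajectory(rng, n=10)
                got = trajectory_features(tr, peaks=peaks)
                want = oracle_features(tr.t, tr.x, tr.y, peaks=peaks)
                for name in FEATURE_NAMES:
                    assert got[name] == pytest.approx(want[name], abs=1e-10, rel=1e-10), name


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 50.0))
def test_scale_equivariance(seed, c):
    """Scaling coordinates by c scales speed/acceleration/length features by c
    and leaves the dimensionless/angular features unchanged."""
    rng = np.random.default_rng(seed)
    tr = random_trajectory(rng, n=12)
    scaled = Trajectory("P0", 0, 0, tr.t, c * tr.x, c * tr.y)
    f, g = trajectory_features(tr), trajectory_features(scaled)
    for name in ("MeanSpeed", "MaxSpeed", "MinSpeed", "sdSpeed", "MeanAcceleration",
                 "MaxAcceleration", "MinAcceleration", "sdAcceleration", "MeanLength"):
        assert g[name] == pytest.approx(c * f[name], rel=1e-9)
    for name in ("STH", "DC", "sdDC"):
        assert g[name] == pytest.approx(f[name], rel=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_time_reversal_invariants(seed):
    rng = np.random.default_rng(seed)
    tr = random_trajectory(rng, n=12)
    rev = Trajectory("P0", 0, 0, tr.t, tr.x[::-1].copy(), tr.y[::-1].copy())
    f, g = trajectory_features(tr), trajectory_features(rev)
    for name in ("STH", "MeanLength", "MeanSpeed", "sdSpeed"):
        assert g[name] == pytest.approx(f[name], rel=1e-9)


class TestBuildDataset:
    def _tiny_cohort(self, n_participants=2, n_tasks=3, incorrect=()):
        trajs, labels, flags = [], {}, {}
        rng = np.random.default_rng(5)
        for p in range(n_participants):
            pid = f"P{p}"
            labels[pid] = p % 2
            for task in range(n_tasks):
                flags[(pid, task)] = (pid, task) not in incorrect
                for j in range(2):
                    tr = generate_trajectory((100, 100), (800, 600), 0.8,
                                             KinematicParams(), 40, rng)
                    tr.participant_id, tr.task_id, tr.trajectory_index = pid, task, j
                    trajs.append(tr)
        return CohortData(trajs, labels, flags)

    def test_one_row_per_retained_task(self):
        ds = build_dataset(self._tiny_cohort())
        assert ds.n_rows == 6
        assert list(ds.frame.columns[:4]) == ["participant_id", "group", "task_id", "difficulty"]

    def test_incorrect_tasks_dropped(self):
        ds = build_dataset(self._tiny_cohort(incorrect=(("P0", 1),)))
        assert ds.n_rows == 5
        assert ("P0", 1) not in set(zip(ds.frame.participant_id, ds.frame.task_id))

    def test_single_task_identical_trajectories_row_equals_trajectory(self):
        tr = generate_trajectory((100, 100), (800, 600), 0.8, KinematicParams(), 40, 1)
        tr.participant_id, tr.task_id, tr.trajectory_index = "P0", 0, 0
        tr2 = Trajectory("P0", 0, 1, tr.t, tr.x.copy(), tr.y.copy())
        cohort = CohortData([tr, tr2], {"P0": 0}, {("P0", 0): True})
        ds = build_dataset(cohort)
        single = trajectory_features(tr)
        for name in FEATURE_NAMES:
            assert ds.frame[name].iloc[0] == pytest.approx(single[name])

    def test_degenerate_trajectory_excluded_not_fatal(self, caplog):
        cohort = self._tiny_cohort()
        bad = Trajectory("P0", 0, 9, np.arange(3) * DT,
                         np.ones(3), np.ones(3))  # stationary
        cohort.trajectories.append(bad)
        ds = build_dataset(cohort)
        assert ds.n_rows == 6  # unchanged


class TestStandardize:
    def test_self_standardized_columns_are_zero_mean_unit_sd(self, small_table):
        z = small_table.standardize()
        assert np.allclose(z.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.X.std(axis=0, ddof=1), 1, atol=1e-9)
        assert z.stats is not None

    def test_train_stats_on_disjoint_split_leave_nonzero_means(self, small_table):
        half = small_table.n_rows // 2
        train = small_table.subset(np.arange(half)).standardize()
        test = small_table.subset(np.arange(half, small_table.n_rows)).standardize(train.stats)
        assert not np.allclose(test.X.mean(axis=0), 0, atol=1e-3)

    def test_standardizing_with_unit_stats_is_identity(self, small_table):
        stats = pd.DataFrame({"mean": 0.0, "sd": 1.0}, index=FEATURE_NAMES)
        z = small_table.standardize(stats)
        assert np.allclose(z.X, small_table.X)

    def test_zero_variance_column_raises_named_error(self, small_table):
        frame = small_table.frame.copy()
        frame["DC"] = 3.14
        with pytest.raises(ZeroVarianceFeatureError) as exc:
            FeatureDataset(frame).standardize()
        assert "DC" in str(exc.value)

    def test_missing_feature_column_raises_schema_error(self, small_table):
        with pytest.raises(SchemaError):
            FeatureDataset(small_table.frame.drop(columns=["sdDC"]))
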
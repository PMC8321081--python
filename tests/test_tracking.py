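"""Greedy linker semantics, trajectory assembly, filtering and thresholds."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from phasetrack import (
    ConfigurationError,
    ImageSequence,
    LinkSet,
    ObjectSet,
    ThresholdRule,
    Track,
    TrajectorySet,
    build_trajectories,
    filter_trajectories,
    link_frames,
    mask_to_objects,
    subsample_sequence,
    threshold_for_interval,
)


def objset(positions, frame_index=0):
    positions = np.asarray(positions, float).reshape(-1, 2)
    return ObjectSet(frame_index, np.full(len(positions), 100.0), positions)


def greedy_oracle(A, B, D):
    """Literal recursion: re-scan the whole remaining distance array each
    step, pick the global minimum (ties to smallest (i, j)), delete that
    row and column, stop when the minimum exceeds D."""
    d = cdist(np.asarray(A, float), np.asarray(B, float))
    live_i = list(range(d.shape[0]))
    live_j = list(range(d.shape[1]))
    links = []
    while live_i and live_j:
        best = None
        for i in live_i:
            for j in live_j:
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        dist, i, j = best
        if dist > D:
            break
        links.append((i, j, dist))
        live_i.remove(i)
        live_j.remove(j)
    return links


class TestMaskToObjects:
    def test_area_filter_drops_small_blob(self):
        mask = np.zeros((30, 30), bool)
        mask[2:12, 2:7] = True  # 50 px
        mask[20:22, 20:25] = True  # 10 px
        objs = mask_to_objects(mask, area_bounds=(20, 5000))
        assert len(objs) == 1
        assert objs.areas[0] == 50

    def test_square_centroid(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:3] = True
        objs = mask_to_objects(mask, area_bounds=(1, 100))
        np.testing.assert_allclose(objs.centroids[0], [1.0, 1.0])

    def test_empty_mask(self):
        objs = mask_to_objects(np.zeros((5, 5), bool))
        assert len(objs) == 0

    def test_diagonal_pixels_are_one_object(self):
        mask = np.zeros((6, 6), bool)
        mask[np.arange(5), np.arange(5)] = True
        objs = mask_to_objects(mask, area_bounds=(1, 100))
        assert len(objs) == 1

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            mask_to_objects(np.zeros((4, 4), bool), area_bounds=(50, 20))


class TestLinkFrames:
    def test_single_pair_within_threshold(self):
        links = link_frames(objset([(0, 0)]), objset([(1, 0)]), D=5.0)
        assert len(links) == 1
        assert links.distances[0] == pytest.approx(1.0)

    def test_pair_beyond_threshold_unlinked(self):
        links = link_frames(objset([(0, 0)]), objset([(9, 0)]), D=5.0)
        assert len(links) == 0

    def test_greedy_is_not_optimal_assignment(self):
        # greedy takes (a1,b1) d=1 then (a2,b2) d=5 (total 6), although
        # the optimal assignment (a1,b2)+(a2,b1) totals 4
        A = objset([(0, 0), (2, 0)])
        B = objset([(1, 0), (-3, 0)])
        links = link_frames(A, B, D=5.0)
        assert [tuple(p) for p in links.pairs] == [(0, 0), (1, 1)]
        np.testing.assert_allclose(sorted(links.distances), [1.0, 5.0])

    def test_empty_sets(self):
        assert len(link_frames(objset([]), objset([(1, 1)]), D=5.0)) == 0
        assert len(link_frames(objset([(1, 1)]), objset([]), D=5.0)) == 0

    def test_matches_resort_every_step_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            nA, nB = rng.integers(0, 7, size=2)
            A = rng.uniform(0, 10, size=(nA, 2))
            B = rng.uniform(0, 10, size=(nB, 2))
            D = rng.uniform(1, 8)
            got = link_frames(objset(A), objset(B), D)
            want = greedy_oracle(A, B, D)
            assert [tuple(p) for p in got.pairs] == [(i, j) for i, j, _ in want]

    def test_injective_and_within_threshold(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0, 30, size=(40, 2))
        B = rng.uniform(0, 30, size=(35, 2))
        links = link_frames(objset(A), objset(B), D=6.0)
        assert len(set(links.pairs[:, 0])) == len(links)
        assert len(set(links.pairs[:, 1])) == len(links)
        assert (links.distances <= 6.0).all()

    def test_deterministic_under_ties(self):
        # four equidistant candidates: lexicographically smallest wins
        A = objset([(0, 0), (0, 2)])
        B = objset([(0, 1), (0, -1)])
        links = link_frames(A, B, D=5.0)
        assert tuple(links.pairs[0]) == (0, 0)


class TestBuildTrajectories:
    def chain(self, link_pairs, n_frames, positions):
        object_sets = [
            objset(positions[t], frame_index=t) for t in range(n_frames)
        ]
        link_sets = []
        for pairs in link_pairs:
            pairs = np.array(pairs, int).reshape(-1, 2)
            link_sets.append(LinkSet(pairs, np.zeros(len(pairs))))
        return build_trajectories(link_sets, object_sets, interval=30.0)

    def test_chained_links_become_one_track(self):
        trajs = self.chain(
            [[(0, 0)], [(0, 0)]], 3,
            [[(0.0, 0.0)], [(1.0, 0.0)], [(2.0, 0.0)]],
        )
        assert len(trajs) == 1
        assert len(trajs.tracks[0].frames) == 3
        np.testing.assert_allclose(trajs.tracks[0].times, [0.0, 30.0, 60.0])

    def test_broken_link_starts_new_track(self):
        trajs = self.chain(
            [[(0, 0)], []], 3,
            [[(0.0, 0.0)], [(1.0, 0.0)], [(9.0, 9.0)]],
        )
        lengths = sorted(len(t.frames) for t in trajs.tracks)
        assert lengths == [1, 2]

    def test_no_links_gives_single_point_tracks(self):
        trajs = self.chain(
            [[], []], 3,
            [[(0.0, 0.0)], [(1.0, 0.0)], [(2.0, 0.0)]],
        )
        assert len(trajs) == 3
        assert all(len(t.frames) == 1 for t in trajs.tracks)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            self.chain([[]], 3, [[(0.0, 0.0)]] * 3)


class TestFilterTrajectories:
    def track_of_duration(self, hours, interval=30.0):
        n = int(hours * 3600 / interval) + 1
        frames = np.arange(n)
        return Track(0, frames, frames * interval,
                     np.zeros((n, 2)))

    def test_15pct_of_24h_is_3p6h(self):
        # threshold inclusive: exactly 3.6 h is kept, 3.59 h is not
        day = 24 * 3600.0
        kept = filter_trajectories(
            TrajectorySet([self.track_of_duration(3.6)], 30.0), 0.15, day
        )
        assert len(kept) == 1
        rejected = filter_trajectories(
            TrajectorySet([self.track_of_duration(3.59)], 30.0), 0.15, day
        )
        assert len(rejected) == 0

    def test_empty_set(self):
        assert len(filter_trajectories(TrajectorySet([], 30.0), 0.15, 100.0)) == 0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_trajectories(TrajectorySet([], 30.0), 1.0, 100.0)


class TestSubsampleSequence:
    def seq(self, n):
        return ImageSequence(np.zeros((n, 4, 4), np.uint8), 1.61, 30.0)

    def test_2880_frames_every_10th_gives_288(self):
        sub = subsample_sequence(self.seq(2880), 10)
        assert len(sub) == 288
        assert sub.interval == 300.0
        assert sub.origin_interval == 30.0

    def test_k1_is_identity(self):
        seq = self.seq(7)
        sub = subsample_sequence(seq, 1)
        assert (sub.frames == seq.frames).all()
        assert sub.interval == seq.interval

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            subsample_sequence(self.seq(10), 2.5)


class TestThresholdForInterval:
    rule = ThresholdRule()

    @pytest.mark.parametrize(
        "interval_s,expected",
        [
            (30.0, 10.0),  # anchor: 10 px at 30 s
            (900.0, 50.0),  # anchor: 50 px at 15 min
            (300.0, 10.0 + 40.0 * (5.0 - 0.5) / (15.0 - 0.5)),  # ~22.41
            (10.0, 10.0),  # clamped below
            (1800.0, 50.0),  # clamped above
        ],
    )
    def test_linear_interpolation_with_clamping(self, interval_s, expected):
        assert threshold_for_interval(self.rule, interval_s) == pytest.approx(
            expected
        )

    def test_monotone_in_interval(self):
        intervals = np.linspace(10, 1200, 60)
        values = [threshold_for_interval(self.rule, i) for i in intervals]
        assert (np.diff(values) >= 0).all()
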
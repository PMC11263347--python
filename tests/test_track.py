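import numpy as np
import pandas as pd
import pytest

from shearcolony.colony import history_to_trajectories
from shearcolony.segment import SegmentationParams, segment_stack
from shearcolony.track import (LinkConfig, Trajectory,
                               detect_attach_detach_events,
                               detect_division_events, link_trajectories)


def detections_from(points):
    """points: list of (frame, x, y) tuples."""
    return pd.DataFrame(points, columns=["frame", "x", "y"])


class TestLinking:
    def test_two_static_cells(self):
        rows = [(f, 5.0, 5.0) for f in range(50)] \
            + [(f, 20.0, 20.0) for f in range(50)]
        trajectories = link_trajectories(detections_from(rows), LinkConfig())
        assert len(trajectories) == 2
        assert all(tr.n_points == 50 for tr in trajectories)

    def test_flicker_gap_bridged_by_memory(self):
        rows = [(f, 5.0, 5.0) for f in range(40) if f not in (10, 11)]
        trajectories = link_trajectories(detections_from(rows),
                                         LinkConfig(memory_frames=3))
        assert len(trajectories) == 1
        assert trajectories[0].n_points == 38

    def test_gap_beyond_memory_splits(self):
        rows = [(f, 5.0, 5.0) for f in range(40) if f not in (10, 11, 12)]
        trajectories = link_trajectories(detections_from(rows),
                                         LinkConfig(memory_frames=2))
        assert len(trajectories) == 2

    def test_each_detection_in_exactly_one_trajectory(self):
        rng = np.random.default_rng(0)
        rows = []
        for cell in range(5):
            x, y = rng.uniform(5, 45, 2)
            for f in range(30):
                rows.append((f, x + rng.normal(0, 0.05),
                             y + rng.normal(0, 0.05)))
        trajectories = link_trajectories(detections_from(rows), LinkConfig())
        assert sum(tr.n_points for tr in trajectories) == len(rows)

    def test_motion_prediction_follows_moving_cell(self):
        # steady 0.8 um/frame drift exceeds a 1.0 um radius around the
        # last position after a gap, but not around the predicted position
        rows = [(f, 5.0 + 0.8 * f, 5.0) for f in range(20) if f != 10]
        cfg = LinkConfig(search_radius=1.0, memory_frames=2,
                         use_motion_prediction=True)
        assert len(link_trajectories(detections_from(rows), cfg)) == 1

    def test_ground_truth_correspondence_at_study_density(self, growth_fixture):
        # >= 99% of trajectory points carry the correct ground-truth agent
        detections = segment_stack(growth_fixture["stack"].frames,
                                   SegmentationParams(),
                                   background=growth_fixture["background"])
        trajectories = link_trajectories(detections, LinkConfig())
        gt = growth_fixture["ground_truth"]
        margin = growth_fixture["optics"].margin
        by_frame = {f: g for f, g in gt[~gt.omitted].groupby("frame")}
        total = correct = 0
        for tr in trajectories:
            ids = []
            for t, (x, y) in zip(tr.times, tr.xy):
                g = by_frame[int(round(t))]
                d = np.hypot(g.x + margin - x, g.y + margin - y)
                ids.append(int(g.agent_id.iloc[np.argmin(d.to_numpy())]))
            majority = max(set(ids), key=ids.count)
            correct += sum(i == majority for i in ids)
            total += len(ids)
        assert correct / total >= 0.99


class TestDivisionDetection:
    @staticmethod
    def toy_division():
        rows = [(f, 10.0, 10.0) for f in range(40)]           # mother
        rows += [(f, 8.8, 10.0) for f in range(40, 60)]       # daughters
        rows += [(f, 11.2, 10.0) for f in range(40, 60)]
        rows += [(f, 30.0, 30.0) for f in range(60)]          # bystander
        return detections_from(rows)

    def test_single_division_recovered(self):
        trajectories = link_trajectories(self.toy_division(), LinkConfig())
        events = detect_division_events(trajectories, LinkConfig())
        assert len(events) == 1
        assert events[0].division_time == 39.0
        mother = next(t for t in trajectories
                      if t.traj_id == events[0].mother_traj)
        assert mother.end_reason == "division"

    def test_no_divisions_in_static_movie(self):
        rows = [(f, 5.0, 5.0) for f in range(30)]
        trajectories = link_trajectories(detections_from(rows), LinkConfig())
        assert detect_division_events(trajectories, LinkConfig()) == []

    def test_rendered_colony_recall_and_accuracy(self, growth_fixture):
        detections = segment_stack(growth_fixture["stack"].frames,
                                   SegmentationParams(),
                                   background=growth_fixture["background"])
        trajectories = link_trajectories(detections, LinkConfig())
        events = detect_division_events(trajectories, LinkConfig())
        history = growth_fixture["history"]
        n_true = (history.events.kind == "division_complete").sum()
        assert len(events) >= 0.95 * n_true
        # fixed 40-min clock: every recovered division time within 2 frames
        # of the clock minus the one-frame loss of the mother's last point
        taus = np.array([ev.division_time for ev in events])
        assert np.mean(np.abs(taus - 40.0) <= 2.0) >= 0.95

    def test_ground_truth_division_recall(self):
        # event-log trajectories of a divider colony: near-perfect recall
        from shearcolony.colony import SimConfig, simulate_colony
        cfg = SimConfig(divider_fraction_f=0.8, lagged_fraction=0.0,
                        n_initial=100, domain_size=(100.0, 100.0),
                        duration=200.0, seed=11, resolve_overlaps=False)
        history = simulate_colony(cfg)
        trajectories = history_to_trajectories(history)
        events = detect_division_events(trajectories, LinkConfig())
        n_true = (history.events.kind == "division_complete").sum()
        assert len(events) >= 0.97 * n_true


class TestAttachDetach:
    def test_static_movie_has_no_events(self):
        rows = [(f, 5.0, 5.0) for f in range(30)]
        trajectories = link_trajectories(detections_from(rows), LinkConfig())
        events, series = detect_attach_detach_events(trajectories,
                                                     LinkConfig(), [])
        assert len(events) == 0
        assert np.all(series.N_d == 0) and np.all(series.N_a == 0)

    def test_hop_counts_one_detach_one_attach(self):
        # a cell that moves 7 um and re-adheres: once in N_d, once in N_a
        rows = [(f, 5.0 + (7.0 if f >= 15 else 0.0), 5.0) for f in range(30)]
        rows += [(f, 20.0, 20.0) for f in range(30)]
        trajectories = link_trajectories(detections_from(rows),
                                         LinkConfig(search_radius=1.0))
        events, series = detect_attach_detach_events(trajectories,
                                                     LinkConfig(), [])
        assert (events.kind == "detach").sum() == 1
        assert (events.kind == "attach").sum() == 1
        assert series.N_d.iloc[-1] == 1 and series.N_a.iloc[-1] == 1

    def test_reattachment_ratio_recovered(self, erosion_history):
        trajectories = history_to_trajectories(erosion_history)
        cfg = LinkConfig()
        division_events = detect_division_events(trajectories, cfg)
        assert division_events == []
        events, _ = detect_attach_detach_events(trajectories, cfg,
                                                division_events)
        n_d = (events.kind == "detach").sum()
        n_a = (events.kind == "attach").sum()
        p = erosion_history.config.reattachment_prob
        assert n_d > 100
        ci = 3 * np.sqrt(p * (1 - p) / n_d)
        assert abs(n_a / n_d - p) < ci

    def test_open_trajectory_conservation(self):
        # per frame: open = previously open + starts - ends
        rng = np.random.default_rng(2)
        rows = []
        for cell in range(8):
            x, y = rng.uniform(5, 45, 2)
            f0 = rng.integers(0, 10)
            f1 = rng.integers(30, 40)
            rows += [(f, x, y) for f in range(f0, f1)]
        trajectories = link_trajectories(detections_from(rows), LinkConfig())
        frames = np.arange(40)
        open_count = np.zeros(40)
        starts = np.zeros(40)
        ends = np.zeros(40)
        for tr in trajectories:
            open_count[(frames >= tr.start_time)
                       & (frames <= tr.end_time)] += 1
            starts[int(tr.start_time)] += 1
            ends[int(tr.end_time)] += 1
        running = np.cumsum(starts) - np.concatenate([[0],
                                                      np.cumsum(ends)[:-1]])
        assert np.array_equal(open_count, running)


class TestTrajectoryInvariants:
    def test_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(0, np.array([0.0, 0.0]), np.zeros((2, 2)),
                       np.zeros((2, 2)), np.zeros((2, 2)), np.ones(2),
                       np.ones(2))

    def test_unknown_end_reason_rejected(self):
        with pytest.raises(ValueError, match="end_reason"):
            Trajectory(0, np.array([0.0, 1.0]), np.zeros((2, 2)),
                       np.zeros((2, 2)), np.zeros((2, 2)), np.ones(2),
                       np.ones(2), end_reason="vanished")

    def test_pole_identity_consistent_across_frames(self):
        # detections deliver poles in arbitrary order; linking must keep a
        # consistent assignment (no axis flip)
        rows = []
        for f in range(20):
            pa, pb = ((4.0, 5.0), (6.0, 5.0)) if f % 2 == 0 \
                else ((6.0, 5.0), (4.0, 5.0))
            rows.append({"frame": f, "x": 5.0, "y": 5.0,
                         "pole_ax": pa[0], "pole_ay": pa[1],
                         "pole_bx": pb[0], "pole_by": pb[1]})
        trajectories = link_trajectories(pd.DataFrame(rows), LinkConfig())
        tr = trajectories[0]
        assert np.ptp(tr.pole_a[:, 0]) == 0.0
        assert np.ptp(tr.pole_b[:, 0]) == 0.0
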
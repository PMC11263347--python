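"""Trajectory linking with gap closing, plus division and erosion events.

Detections are linked frame to frame by solving the optimal assignment
between predicted track positions and new detections (Hungarian algorithm),
rejecting links farther than a search radius.  A track that finds no match
stays open for ``memory_frames`` frames — bridging detection flicker — with
an optional constant-velocity position prediction.

A trajectory end is a *division* when at least two new trajectories begin
next to its endpoint in the following occupied frame.  Ends that are not
divisions are *detachments*; starts that are neither daughters nor at the
start of the movie are *attachments*.  Cumulative counts of the latter two
feed the erosion-corrected growth-rate decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Trajectory",
    "LinkConfig",
    "DivisionEvent",
    "link_trajectories",
    "detect_division_events",
    "detect_attach_detach_events",
    "trajectories_to_frame",
]

_END_REASONS = ("division", "detachment", "censored_end_of_movie", "lost")


@dataclass
class Trajectory:
    """Linked per-cell time series.

    Times in minutes, coordinates in micrometres.  ``duration_T`` is the
    trajectory's life duration ``end_time - start_time``; for a cell that is
    eventually seen to divide it is the measured division time.
    """

    traj_id: int
    times: np.ndarray
    xy: np.ndarray
    pole_a: np.ndarray
    pole_b: np.ndarray
    length: np.ndarray
    eccentricity: np.ndarray
    end_reason: str = "censored_end_of_movie"
    agent_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.end_reason not in _END_REASONS:
            raise ValueError(f"unknown end_reason {self.end_reason!r}")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def start_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    @property
    def duration_T(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class LinkConfig:
    """Linking and event-detection parameters (um, frames).

    ``division_pair_radius`` defaults to one cell length; the detachment
    displacement threshold to the low end of the observed 5-10 um
    reattachment hops.
    """

    search_radius: float = 1.0
    memory_frames: int = 3
    use_motion_prediction: bool = True
    division_pair_radius: float = 2.0
    detach_displacement_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be >= 0")


class _OpenTrack:
    __slots__ = ("rows", "missing", "velocity")

    def __init__(self, row):
        self.rows = [row]
        self.missing = 0
        self.velocity = np.zeros(2)

    @property
    def last_xy(self):
        return np.array([self.rows[-1]["x"], self.rows[-1]["y"]])

    def predict(self, n_ahead: int, use_prediction: bool) -> np.ndarray:
        if use_prediction:
            return self.last_xy + self.velocity * n_ahead
        return self.last_xy


_DET_COLUMNS = ("frame", "x", "y", "pole_ax", "pole_ay", "pole_bx", "pole_by",
                "major_axis", "eccentricity")


def _orient_poles(row: dict, prev: dict) -> dict:
    """Keep pole identity consistent with the previous frame (no axis flip)."""
    a = np.array([row["pole_ax"], row["pole_ay"]])
    b = np.array([row["pole_bx"], row["pole_by"]])
    pa = np.array([prev["pole_ax"], prev["pole_ay"]])
    pb = np.array([prev["pole_bx"], prev["pole_by"]])
    keep = np.hypot(*(a - pa)) + np.hypot(*(b - pb))
    swap = np.hypot(*(b - pa)) + np.hypot(*(a - pb))
    if swap < keep:
        row = dict(row)
        row["pole_ax"], row["pole_bx"] = row["pole_bx"], row["pole_ax"]
        row["pole_ay"], row["pole_by"] = row["pole_by"], row["pole_ay"]
    return row


def link_trajectories(detections: pd.DataFrame, config: LinkConfig,
                      frame_interval: float = 1.0) -> list[Trajectory]:
    """Link a tidy detection table (one row per detection) into trajectories.

    ``detections`` must carry the columns ``frame, x, y`` and may carry
    ``pole_ax/ay, pole_bx/by, major_axis, eccentricity``; missing geometry
    columns are filled with NaN.  Times are ``frame * frame_interval``
    minutes.  Every detection ends up in exactly one trajectory.
    """
    det = detections.copy()
    for c in _DET_COLUMNS:
        if c not in det.columns:
            det[c] = np.nan
    det = det.sort_values("frame")

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    frames = np.arange(int(det["frame"].min()), int(det["frame"].max()) + 1) \
        if len(det) else np.empty(0, dtype=int)
    grouped = {int(f): g for f, g in det.groupby("frame")}

    for frame in frames:
        g = grouped.get(int(frame))
        rows = [] if g is None else g.to_dict("records")
        candidates = [tr for tr in open_tracks
                      if tr.missing <= config.memory_frames]
        matched_rows = set()
        if candidates and rows:
            pred = np.array([tr.predict(tr.missing + 1,
                                        config.use_motion_prediction)
                             for tr in candidates])
            pos = np.array([[r["x"], r["y"]] for r in rows])
            cost = np.linalg.norm(pred[:, None, :] - pos[None, :, :], axis=2)
            big = 1e6
            cost_f = np.where(cost <= config.search_radius, cost, big)
            ti, di = linear_sum_assignment(cost_f)
            for a, b in zip(ti, di):
                if cost[a, b] > config.search_radius:
                    continue
                tr = candidates[a]
                row = _orient_poles(rows[b], tr.rows[-1])
                dt_frames = row["frame"] - tr.rows[-1]["frame"]
                tr.velocity = (np.array([row["x"], row["y"]]) - tr.last_xy) \
                    / max(dt_frames, 1)
                tr.rows.append(row)
                tr.missing = 0
                matched_rows.add(b)
        still_open = []
        for tr in open_tracks:
            if tr.rows[-1]["frame"] == frame:
                still_open.append(tr)
            else:
                tr.missing += 1
                if tr.missing > config.memory_frames:
                    closed.append(tr)
                else:
                    still_open.append(tr)
        for b, row in enumerate(rows):
            if b not in matched_rows:
                still_open.append(_OpenTrack(row))
        open_tracks = still_open
    closed.extend(open_tracks)

    trajectories = []
    for k, tr in enumerate(sorted(closed, key=lambda t: (t.rows[0]["frame"],
                                                         t.rows[0]["x"]))):
        rows = tr.rows
        arr = {c: np.array([r[c] for r in rows], dtype=float)
               for c in _DET_COLUMNS}
        trajectories.append(Trajectory(
            traj_id=k,
            times=arr["frame"] * frame_interval,
            xy=np.stack([arr["x"], arr["y"]], axis=1),
            pole_a=np.stack([arr["pole_ax"], arr["pole_ay"]], axis=1),
            pole_b=np.stack([arr["pole_bx"], arr["pole_by"]], axis=1),
            length=arr["major_axis"],
            eccentricity=arr["eccentricity"],
        ))
    return trajectories


@dataclass(frozen=True)
class DivisionEvent:
    mother_traj: int
    daughter_trajs: tuple[int, int]
    time: float
    division_time: float   # the mother's trajectory duration


def detect_division_events(trajectories: list[Trajectory], config: LinkConfig,
                           frame_interval: float = 1.0,
                           ) -> list[DivisionEvent]:
    """Find trajectory ends at which two new trajectories appear nearby.

    The mother's centroid track is lost at the completed division and the
    two daughters open new tracks within ``division_pair_radius`` of its
    endpoint.  Multi-way ambiguities are resolved by distance (closest two
    daughters win); daughters are consumed at most once.  Mothers marked
    here get ``end_reason = "division"``.
    """
    if not trajectories:
        return []
    last_time = max(tr.end_time for tr in trajectories)
    start_times = np.array(sorted({tr.start_time for tr in trajectories}))

    # each ended track is eligible for daughters at the next occupied frame
    # after its end, within the linker's memory window
    enders_by_next: dict[float, list[Trajectory]] = {}
    for tr in trajectories:
        if tr.end_time >= last_time:
            continue
        later = start_times[start_times > tr.end_time + 1e-9]
        if len(later) == 0:
            continue
        t_next = float(later[0])
        if t_next - tr.end_time > (config.memory_frames + 1) * frame_interval:
            continue
        enders_by_next.setdefault(t_next, []).append(tr)

    # capacitated assignment per frame: every ended track may absorb up to
    # two new tracks (it is duplicated in the cost matrix), and the global
    # minimum-distance matching resolves contention between
    # near-simultaneous divisions in adjacent colonies
    starters_by_time: dict[float, list[Trajectory]] = {}
    for tr in trajectories:
        starters_by_time.setdefault(tr.start_time, []).append(tr)

    big = 1e6
    events: list[DivisionEvent] = []
    for t_next, enders in sorted(enders_by_next.items()):
        starters = starters_by_time.get(t_next, [])
        if not starters:
            continue
        end_xy = np.array([m.xy[-1] for m in enders])
        start_xy = np.array([d.xy[0] for d in starters])
        dist = np.linalg.norm(end_xy[:, None, :] - start_xy[None, :, :],
                              axis=2)
        dist = np.where(dist <= config.division_pair_radius, dist, big)
        cost = np.repeat(dist, 2, axis=0)        # capacity 2 per mother
        ri, ci = linear_sum_assignment(cost)
        assigned: dict[int, list[tuple[float, Trajectory]]] = {}
        for a, b in zip(ri, ci):
            if cost[a, b] >= big:
                continue
            assigned.setdefault(a // 2, []).append((cost[a, b], starters[b]))
        for mi, claimed in assigned.items():
            if len(claimed) < 2:
                continue
            claimed.sort(key=lambda c: c[0])
            mother = enders[mi]
            mother.end_reason = "division"
            events.append(DivisionEvent(
                mother_traj=mother.traj_id,
                daughter_trajs=(claimed[0][1].traj_id, claimed[1][1].traj_id),
                time=mother.end_time,
                division_time=mother.duration_T))
    events.sort(key=lambda e: e.time)
    return events


def detect_attach_detach_events(trajectories: list[Trajectory],
                                config: LinkConfig,
                                division_events: list[DivisionEvent] | None = None,
                                frame_interval: float = 1.0,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative detachment/attachment counts and the underlying events.

    Returns ``(events, series)``: ``events`` has columns (time, kind,
    traj_id) with kind in {detach, attach}; ``series`` carries the frame
    grid with cumulative ``N_d`` and ``N_a``.  Division endings and daughter
    starts are excluded (resolved first by the division-pair rule); a large
    in-trajectory hop (single step longer than the displacement threshold)
    counts one detachment and one attachment.
    """
    if division_events is None:
        division_events = detect_division_events(trajectories, config,
                                                 frame_interval)
    daughters = {d for ev in division_events for d in ev.daughter_trajs}
    first_time = min((tr.start_time for tr in trajectories), default=0.0)
    last_time = max((tr.end_time for tr in trajectories), default=0.0)
    rows = []
    for tr in trajectories:
        steps = np.linalg.norm(np.diff(tr.xy, axis=0), axis=1)
        for k in np.flatnonzero(steps > config.detach_displacement_threshold):
            rows.append((float(tr.times[k]), "detach", tr.traj_id))
            rows.append((float(tr.times[k + 1]), "attach", tr.traj_id))
        if tr.end_reason != "division" and tr.end_time < last_time:
            tr.end_reason = "detachment"
            rows.append((tr.end_time, "detach", tr.traj_id))
        if tr.start_time > first_time and tr.traj_id not in daughters:
            rows.append((tr.start_time, "attach", tr.traj_id))
    events = pd.DataFrame(rows, columns=["time", "kind", "traj_id"])
    events = events.sort_values("time", kind="stable").reset_index(drop=True)
    times = np.arange(first_time, last_time + 1e-9, frame_interval)
    n_d = np.zeros(len(times))
    n_a = np.zeros(len(times))
    for _, ev in events.iterrows():
        idx = int(np.searchsorted(times, ev.time - 1e-9))
        if ev.kind == "detach":
            n_d[idx:] += 1
        else:
            n_a[idx:] += 1
    series = pd.DataFrame({"time": times, "N_d": n_d, "N_a": n_a})
    return events, series


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Tidy table: one row per trajectory-timepoint."""
    chunks = []
    for tr in trajectories:
        chunks.append(pd.DataFrame({
            "traj_id": tr.traj_id,
            "time": tr.times,
            "x": tr.xy[:, 0], "y": tr.xy[:, 1],
            "pole_ax": tr.pole_a[:, 0], "pole_ay": tr.pole_a[:, 1],
            "pole_bx": tr.pole_b[:, 0], "pole_by": tr.pole_b[:, 1],
            "length": tr.length, "eccentricity": tr.eccentricity,
            "end_reason": tr.end_reason,
            "agent_id": -1 if tr.agent_id is None else tr.agent_id,
        }))
    if not chunks:
        return pd.DataFrame(columns=["traj_id", "time", "x", "y", "pole_ax",
                                     "pole_ay", "pole_bx", "pole_by",
                                     "length", "eccentricity", "end_reason",
                                     "agent_id"])
    return pd.concat(chunks, ignore_index=True)
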
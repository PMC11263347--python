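"""Agent-based generator of surface-colonization ground truth.

The simulator emulates a monolayer of rod-shaped cells attached to the floor
of a flow channel.  Each agent carries one of three phenotypes:

* **continuous dividers** elongate linearly from one to two cell lengths and
  divide when an exponential clock (mean ``mean_division_time``, support
  starting at ``division_time_floor``) fires.  One pole (the inherited "old"
  pole) is anchored; the opposite pole extends downstream and jitters more.
* **lagged dividers** behave like continuous dividers after an initial delay
  during which they neither grow nor divide.
* **non-dividers** never divide; both their poles are firmly attached and
  jitter weakly and symmetrically.

At division the mother is replaced by two daughters of unit cell length
placed end-to-end along her axis.  Each daughter independently becomes a
divider with probability ``divider_fraction_f`` (the bistable daughter
assignment) and a non-divider otherwise.  Attached agents can detach as a
Poisson process; a detached agent reattaches immediately at a downstream
offset with probability ``reattachment_prob`` and otherwise leaves the
system.  Every birth, completed division, detachment and reattachment is
written to an event log that serves as the oracle for the downstream imaging
/ tracking / rate-estimation stages.

The division clock is parameterised by its *mean*: with the default
``truncated_exponential`` law the clock is ``floor + Exp(mean - floor)``, an
exponential shifted to the observed support whose mean is exactly
``mean_division_time``.  A near-deterministic ``gamma`` law (small CV) and a
``fixed`` law are available for scenarios that assume synchronous
generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from shearcolony import rates as _rates
from shearcolony.track import Trajectory

__all__ = [
    "PHENOTYPES",
    "SimConfig",
    "ColonyHistory",
    "SingleLayerViolationError",
    "simulate_colony",
    "history_to_trajectories",
    "oracle_rates",
    "check_conservation",
]

#: exhaustive phenotype labels; every agent carries exactly one
PHENOTYPES = ("continuous_divider", "lagged_divider", "non_divider")
_CONT, _LAG, _NON = 0, 1, 2


class SingleLayerViolationError(RuntimeError):
    """Projected cell area exceeded the single-layer capacity of the domain."""

    def __init__(self, time: float, area_fraction: float):
        self.time = time
        self.area_fraction = area_fraction
        super().__init__(
            f"single-layer violation at t = {time:g} min: projected cell "
            f"area fraction {area_fraction:.2f} exceeds 0.90")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the colonization simulator.

    Durations are minutes, lengths micrometres, rates per hour.  Jitters are
    per-frame Gaussian displacement scales (um/frame) of the pole positions,
    calibrated for 1-min frames.
    """

    divider_fraction_f: float = 0.80
    mean_division_time: float = 40.0
    model_division_time: float = 52.0
    division_time_floor: float = 20.0
    division_time_distribution: str = "truncated_exponential"
    division_time_cv: float = 0.15
    lagged_fraction: float = 0.125
    daughter_lagged_fraction: float = 0.0
    lagged_delay: float = 240.0
    detachment_rate: float = 0.0
    reattachment_prob: float = 0.0
    reattachment_offset: float = 7.0
    reattachment_offset_sd: float = 1.5
    anchored_pole_jitter: float = 0.010
    free_pole_jitter: float = 0.020
    nondivider_jitter: float = 0.004
    initial_density: float = 1e-2
    domain_size: tuple[float, float] = (100.0, 100.0)
    n_initial: int | None = None
    cell_length: float = 2.0
    cell_width: float = 1.0
    division_gap: float = 0.4
    division_angle_noise: float = 0.08
    frame_interval: float = 1.0
    duration: float = 360.0
    initial_age_randomized: bool = False
    resolve_overlaps: bool = True
    overlap_clearance: float = 0.3
    record_states: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divider_fraction_f", "lagged_fraction",
                     "daughter_lagged_fraction", "reattachment_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name in ("mean_division_time", "model_division_time",
                     "lagged_delay", "frame_interval", "duration",
                     "cell_length", "cell_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.division_time_floor < self.mean_division_time:
            raise ValueError(
                "division_time_floor must lie in (0, mean_division_time)")
        for name in ("anchored_pole_jitter", "free_pole_jitter",
                     "nondivider_jitter", "detachment_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.division_time_distribution not in (
                "truncated_exponential", "gamma", "fixed"):
            raise ValueError(
                f"unknown division_time_distribution "
                f"{self.division_time_distribution!r}")


@dataclass
class ColonyHistory:
    """Ground-truth event log and per-agent state series.

    ``agents``: one row per agent ever created (agent_id, mother_id,
    phenotype, birth_time, anchored_pole_id, division_clock).
    ``states``: tidy per-frame table (frame, time, agent_id, x, y, pole_ax,
    pole_ay, pole_bx, pole_by, length) for *attached* agents only.
    ``events``: ordered log with columns (time, frame, kind, agent_id,
    mother_id), kind in {birth, division_complete, detach, reattach}.
    """

    config: SimConfig
    agents: pd.DataFrame
    states: pd.DataFrame
    events: pd.DataFrame
    times: np.ndarray

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def attached_counts(self) -> np.ndarray:
        """Number of attached agents at every frame, from the event log."""
        n = np.zeros(len(self.times))
        deltas = {"birth": 1, "division_complete": -1, "detach": -1,
                  "reattach": 1}
        for _, ev in self.events.iterrows():
            n[int(ev.frame):] += deltas[ev.kind]
        return n


def _draw_clocks(rng: np.random.Generator, config: SimConfig, n: int,
                 ) -> np.ndarray:
    mean = config.mean_division_time
    floor = config.division_time_floor
    dist = config.division_time_distribution
    if n == 0:
        return np.empty(0)
    if dist == "fixed":
        return np.full(n, mean)
    if dist == "gamma":
        cv = config.division_time_cv
        if cv <= 0:
            return np.full(n, mean)
        shape = 1.0 / cv**2
        return np.maximum(floor, rng.gamma(shape, mean * cv**2, size=n))
    return floor + rng.exponential(mean - floor, size=n)


def _assign_phenotypes(rng: np.random.Generator, n: int, f: float,
                       lagged_frac: float) -> np.ndarray:
    """Divider with probability f, lagged among dividers with lagged_frac."""
    phen = np.full(n, _NON, dtype=np.int8)
    divider = rng.random(n) < f
    phen[divider] = _CONT
    lagged = divider & (rng.random(n) < lagged_frac)
    phen[lagged] = _LAG
    return phen


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2 (Ericson's routine)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f_ = d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.hypot(*(p1 - p2)))
    if a <= eps:
        s, t = 0.0, np.clip(f_ / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f_ - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f_) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.hypot(*(closest1 - closest2)))


class _Colony:
    """Mutable per-agent state arrays during a simulation."""

    def __init__(self):
        self.aid = np.empty(0, dtype=np.int64)
        self.phen = np.empty(0, dtype=np.int8)
        self.birth = np.empty(0)
        self.delay = np.empty(0)
        self.clock = np.empty(0)
        self.pa = np.empty((0, 2))   # anchored pole for dividers
        self.pb = np.empty((0, 2))   # free pole
        self.length = np.empty(0)

    def keep(self, mask: np.ndarray) -> None:
        for name in ("aid", "phen", "birth", "delay", "clock", "length"):
            setattr(self, name, getattr(self, name)[mask])
        self.pa = self.pa[mask]
        self.pb = self.pb[mask]

    def append(self, **arrays) -> None:
        for name in ("aid", "phen", "birth", "delay", "clock", "length"):
            setattr(self, name,
                    np.concatenate([getattr(self, name), arrays[name]]))
        self.pa = np.vstack([self.pa, arrays["pa"]])
        self.pb = np.vstack([self.pb, arrays["pb"]])

    @property
    def n(self) -> int:
        return len(self.aid)

    @property
    def centroid(self) -> np.ndarray:
        return 0.5 * (self.pa + self.pb)


def simulate_colony(config: SimConfig) -> ColonyHistory:
    """Run the agent-based colonization model and return its ground truth.

    The simulation advances on a uniform frame grid.  Per frame, in fixed
    order so that identical seeds give identical histories: detachment draws,
    reattachment placement, division of agents whose clocks have fired,
    elongation, pole jitter, optional hard-overlap relaxation, state
    recording.
    """
    rng = np.random.default_rng(config.seed)
    wx, wy = config.domain_size
    area = wx * wy
    n0 = config.n_initial
    if n0 is None:
        n0 = int(round(config.initial_density * area))
        if n0 < 1:
            raise ValueError(
                "domain too small: initial_density * area must be >= 1 agent")
    elif n0 < 0:
        raise ValueError("n_initial must be >= 0")

    times = np.arange(0.0, config.duration + 1e-9, config.frame_interval)
    col = _Colony()
    events: list[tuple] = []          # (time, frame, kind, agent_id, mother)
    agent_rows: list[tuple] = []      # (aid, mother, phen, birth, clock, delay)
    next_id = 0

    def register(n_new, mother_ids, phen, birth, t, frame):
        nonlocal next_id
        ids = np.arange(next_id, next_id + n_new, dtype=np.int64)
        next_id += n_new
        clock = _draw_clocks(rng, config, n_new)
        delay = np.where(phen == _LAG, config.lagged_delay, 0.0)
        delay[phen == _NON] = np.inf
        clock[phen == _NON] = np.inf
        for i in range(n_new):
            events.append((t, frame, "birth", int(ids[i]), int(mother_ids[i])))
            agent_rows.append((int(ids[i]), int(mother_ids[i]),
                               PHENOTYPES[phen[i]], birth[i],
                               float(clock[i]) if np.isfinite(clock[i]) else np.nan,
                               float(delay[i]) if np.isfinite(delay[i]) else np.nan))
        return ids, clock, delay

    # --- initial population -------------------------------------------------
    phen0 = _assign_phenotypes(rng, n0, config.divider_fraction_f,
                               config.lagged_fraction)
    ids0, clock0, delay0 = register(
        n0, np.full(n0, -1), phen0, np.zeros(n0), 0.0, 0)
    if config.initial_age_randomized:
        grower = phen0 != _NON
        clock0[grower] *= rng.uniform(0.05, 1.0, size=grower.sum())
    centers = rng.uniform([0, 0], [wx, wy], size=(n0, 2))
    theta = rng.uniform(0, 2 * np.pi, size=n0)
    u0 = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    half = 0.5 * config.cell_length
    col.append(aid=ids0, phen=phen0, birth=np.zeros(n0), delay=delay0,
               clock=clock0, pa=centers - half * u0, pb=centers + half * u0,
               length=np.full(n0, config.cell_length))

    state_chunks: list[tuple] = []

    def record(frame, t):
        if not config.record_states or col.n == 0:
            return
        c = col.centroid
        state_chunks.append((
            np.full(col.n, frame, dtype=np.int64), np.full(col.n, t),
            col.aid.copy(), c[:, 0].copy(), c[:, 1].copy(),
            col.pa[:, 0].copy(), col.pa[:, 1].copy(),
            col.pb[:, 0].copy(), col.pb[:, 1].copy(), col.length.copy()))

    record(0, 0.0)
    dt = config.frame_interval
    p_detach = 1.0 - np.exp(-config.detachment_rate * dt / 60.0)

    for frame in range(1, len(times)):
        t = times[frame]
        # single-layer capacity check
        area_fraction = float(np.sum(col.length) * config.cell_width) / area
        if area_fraction > 0.90:
            raise SingleLayerViolationError(t, area_fraction)

        # --- detachment / reattachment ------------------------------------
        if p_detach > 0 and col.n > 0:
            detaching = rng.random(col.n) < p_detach
            if detaching.any():
                reattach = rng.random(col.n) < config.reattachment_prob
                for i in np.flatnonzero(detaching):
                    events.append((t, frame, "detach", int(col.aid[i]), -1))
                stay = ~detaching | reattach
                moved = detaching & reattach
                if moved.any():
                    n_m = int(moved.sum())
                    off = np.empty((n_m, 2))
                    off[:, 0] = np.abs(rng.normal(config.reattachment_offset,
                                                  config.reattachment_offset_sd,
                                                  n_m))
                    off[:, 1] = rng.normal(0.0, config.reattachment_offset_sd,
                                           n_m)
                    col.pa[moved] += off
                    col.pb[moved] += off
                    for i in np.flatnonzero(moved):
                        events.append((t, frame, "reattach", int(col.aid[i]), -1))
                col.keep(stay)

        # --- divisions -----------------------------------------------------
        if col.n > 0:
            due = (col.phen != _NON) & (t >= col.birth + col.delay + col.clock)
            if due.any():
                idx = np.flatnonzero(due)
                new = {k: [] for k in ("aid", "phen", "birth", "delay",
                                       "clock", "pa", "pb", "length")}
                for i in idx:
                    events.append((t, frame, "division_complete",
                                   int(col.aid[i]), -1))
                    u = col.pb[i] - col.pa[i]
                    u = u / max(np.hypot(*u), 1e-12)
                    L0 = config.cell_length
                    g = config.division_gap
                    # daughter A keeps the mother's anchored end, daughter B
                    # anchors at the mother's free end; both outer-shifted by
                    # half the gap so that the two capsules do not touch
                    pa_A = col.pa[i] - 0.5 * g * u
                    pa_B = col.pa[i] + (2 * L0 + 0.5 * g) * u
                    phen_d = _assign_phenotypes(
                        rng, 2, config.divider_fraction_f,
                        config.daughter_lagged_fraction)
                    ids_d, clock_d, delay_d = register(
                        2, np.full(2, col.aid[i]), phen_d,
                        np.full(2, t), t, frame)
                    for k, (anchor, direction) in enumerate(
                            ((pa_A, u), (pa_B, -u))):
                        ang = rng.normal(0.0, config.division_angle_noise)
                        ca, sa = np.cos(ang), np.sin(ang)
                        ud = np.array([ca * direction[0] - sa * direction[1],
                                       sa * direction[0] + ca * direction[1]])
                        new["aid"].append(ids_d[k])
                        new["phen"].append(phen_d[k])
                        new["birth"].append(t)
                        new["delay"].append(delay_d[k])
                        new["clock"].append(clock_d[k])
                        new["pa"].append(anchor)
                        new["pb"].append(anchor + L0 * ud)
                        new["length"].append(L0)
                col.keep(~due)
                col.append(aid=np.asarray(new["aid"], dtype=np.int64),
                           phen=np.asarray(new["phen"], dtype=np.int8),
                           birth=np.asarray(new["birth"]),
                           delay=np.asarray(new["delay"]),
                           clock=np.asarray(new["clock"]),
                           pa=np.asarray(new["pa"]).reshape(-1, 2),
                           pb=np.asarray(new["pb"]).reshape(-1, 2),
                           length=np.asarray(new["length"]))

        # --- elongation (anchored pole fixed) ------------------------------
        if col.n > 0:
            growing = (col.phen != _NON) & (t > col.birth + col.delay)
            if growing.any():
                elapsed = t - col.birth[growing] - col.delay[growing]
                progress = np.minimum(elapsed / col.clock[growing], 1.0)
                new_len = config.cell_length * (1.0 + progress)
                u = col.pb[growing] - col.pa[growing]
                norm = np.maximum(np.hypot(u[:, 0], u[:, 1]), 1e-12)
                u /= norm[:, None]
                col.pb[growing] = col.pa[growing] + new_len[:, None] * u
                col.length[growing] = new_len

        # --- pole jitter ----------------------------------------------------
        if col.n > 0:
            divider = col.phen != _NON
            non = ~divider
            if divider.any():
                nd = int(divider.sum())
                col.pa[divider] += rng.normal(
                    0.0, config.anchored_pole_jitter, (nd, 2))
                col.pb[divider] += rng.normal(
                    0.0, config.free_pole_jitter, (nd, 2))
            if non.any():
                nn = int(non.sum())
                col.pa[non] += rng.normal(0.0, config.nondivider_jitter, (nn, 2))
                col.pb[non] += rng.normal(0.0, config.nondivider_jitter, (nn, 2))
            col.length = np.hypot(*(col.pb - col.pa).T)

        # --- hard-overlap relaxation ---------------------------------------
        if config.resolve_overlaps and col.n > 1:
            _relax_overlaps(col, config)

        record(frame, t)

    agents = pd.DataFrame(
        agent_rows, columns=["agent_id", "mother_id", "phenotype",
                             "birth_time", "division_clock", "lag_delay"])
    agents["anchored_pole_id"] = 0
    events_df = pd.DataFrame(
        events, columns=["time", "frame", "kind", "agent_id", "mother_id"])
    if state_chunks:
        cols = ["frame", "time", "agent_id", "x", "y", "pole_ax", "pole_ay",
                "pole_bx", "pole_by", "length"]
        states = pd.DataFrame(
            {c: np.concatenate([chunk[i] for chunk in state_chunks])
             for i, c in enumerate(cols)})
    else:
        states = pd.DataFrame(columns=["frame", "time", "agent_id", "x", "y",
                                       "pole_ax", "pole_ay", "pole_bx",
                                       "pole_by", "length"])
    return ColonyHistory(config=config, agents=agents, states=states,
                         events=events_df, times=times)


def _relax_overlaps(col: _Colony, config: SimConfig, iterations: int = 2,
                    ) -> None:
    """Push overlapping capsules apart along the line joining their centroids.

    Non-dividers are firmly anchored by both poles and act as immovable
    obstacles; dividers (anchored by a single pole) absorb the displacement.
    Two overlapping non-dividers are left alone.
    """
    target = config.cell_width + config.overlap_clearance
    reach = float(np.max(col.length)) + config.cell_width
    mobile = col.phen != _NON
    for _ in range(iterations):
        c = col.centroid
        tree = cKDTree(c)
        pairs = tree.query_pairs(r=reach, output_type="ndarray")
        if len(pairs) == 0:
            return
        moved = False
        for i, j in pairs:
            if not (mobile[i] or mobile[j]):
                continue
            d = _segment_distance(col.pa[i], col.pb[i], col.pa[j], col.pb[j])
            if d >= target:
                continue
            push = (target - d)
            axis = c[j] - c[i]
            nrm = np.hypot(*axis)
            if nrm < 1e-9:
                axis = np.array([1.0, 0.0])
                nrm = 1.0
            axis = axis / nrm
            if mobile[i] and mobile[j]:
                shifts = (-0.5 * push * axis, 0.5 * push * axis)
            elif mobile[i]:
                shifts = (-push * axis, np.zeros(2))
            else:
                shifts = (np.zeros(2), push * axis)
            for k, s in zip((i, j), shifts):
                col.pa[k] += s
                col.pb[k] += s
            moved = True
        if not moved:
            return


def _capsule_eccentricity(length: np.ndarray, width: float) -> np.ndarray:
    ratio = np.minimum(width / np.maximum(length, 1e-9), 1.0)
    return np.sqrt(1.0 - ratio**2)


def history_to_trajectories(history: ColonyHistory) -> list[Trajectory]:
    """Ground-truth trajectories, split the way an ideal tracker would split.

    Each agent's state series becomes one trajectory; a detach-and-reattach
    hop splits the series in two (end_reason ``detachment`` before the hop),
    exactly mirroring how a linker with a finite search radius breaks tracks.
    End reasons come from the event log: ``division``, ``detachment`` or
    ``censored_end_of_movie``.
    """
    cfg = history.config
    end_frame = len(history.times) - 1
    divided: set[int] = set()
    hop_frames_by_agent: dict[int, set[int]] = {}
    detached_for_good: set[int] = set()
    reattach_frames: dict[int, set[int]] = {}
    for _, ev in history.events.iterrows():
        aid = int(ev.agent_id)
        if ev.kind == "division_complete":
            divided.add(aid)
        elif ev.kind == "reattach":
            reattach_frames.setdefault(aid, set()).add(int(ev.frame))
    for _, ev in history.events.iterrows():
        if ev.kind == "detach":
            aid = int(ev.agent_id)
            if int(ev.frame) in reattach_frames.get(aid, ()):  # hop
                hop_frames_by_agent.setdefault(aid, set()).add(int(ev.frame))
            else:
                detached_for_good.add(aid)

    trajectories: list[Trajectory] = []
    traj_id = 0
    for agent_id, grp in history.states.groupby("agent_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        # split at reattachment hops: the agent was repositioned before the
        # state of the hop frame was recorded, so a new piece starts there
        hop_frames = hop_frames_by_agent.get(int(agent_id), set())
        breaks = [0]
        for k in range(1, len(frames)):
            if frames[k] in hop_frames:
                breaks.append(k)
        breaks.append(len(frames))
        for b0, b1 in zip(breaks[:-1], breaks[1:]):
            piece = grp.iloc[b0:b1]
            if len(piece) == 0:
                continue
            last_frame = int(piece["frame"].iloc[-1])
            if b1 < len(frames):
                reason = "detachment"
            elif int(agent_id) in divided:
                reason = "division"
            elif int(agent_id) in detached_for_good:
                reason = "detachment"
            elif last_frame >= end_frame:
                reason = "censored_end_of_movie"
            else:
                reason = "lost"
            length = piece["length"].to_numpy()
            trajectories.append(Trajectory(
                traj_id=traj_id,
                times=piece["time"].to_numpy(),
                xy=piece[["x", "y"]].to_numpy(),
                pole_a=piece[["pole_ax", "pole_ay"]].to_numpy(),
                pole_b=piece[["pole_bx", "pole_by"]].to_numpy(),
                length=length,
                eccentricity=_capsule_eccentricity(length, cfg.cell_width),
                end_reason=reason,
                agent_id=int(agent_id),
            ))
            traj_id += 1
    return trajectories


def check_conservation(history: ColonyHistory) -> bool:
    """Event-log bookkeeping: the attached count reconstructed from events
    matches the per-frame state table at every frame."""
    n_events = history.attached_counts()
    counted = history.states.groupby("frame")["agent_id"].count()
    n_states = np.zeros(len(history.times))
    n_states[counted.index.to_numpy()] = counted.to_numpy()
    return bool(np.array_equal(n_events, n_states))


def oracle_rates(history: ColonyHistory,
                 window: tuple[float, float] | None = None,
                 ) -> "_rates.RateEstimates":
    """Rate estimates computed directly from the event log (no imaging).

    Uses the same estimators as :mod:`shearcolony.rates` applied to the
    exact attached-count and cumulative event-count series, so that a
    pipeline run on noiseless ground-truth trajectories reproduces these
    numbers identically.
    """
    times = history.times
    if window is None:
        window = (float(times[0]), float(times[-1]))
    if window[1] <= window[0]:
        raise ValueError("empty oracle window")
    n = history.attached_counts()
    n_d = np.zeros(len(times))
    n_a = np.zeros(len(times))
    for _, ev in history.events.iterrows():
        if ev.kind == "detach":
            n_d[int(ev.frame):] += 1
        elif ev.kind == "reattach":
            n_a[int(ev.frame):] += 1
    series = _rates.PopulationSeries(times=times, N=n, N_d=n_d, N_a=n_a)
    eta, eta_se = _rates.observed_growth_rate(series, window)
    return _rates.rate_decomposition(eta, series, window, eta_se=eta_se)
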
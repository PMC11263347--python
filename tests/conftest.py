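import numpy as np
import pandas as pd
import pytest

from shearcolony.colony import ColonyHistory, SimConfig, simulate_colony
from shearcolony.render import OpticsConfig, render_blank_frames, render_frames
from shearcolony.segment import SegmentationParams, background_model
from shearcolony.track import Trajectory

EMPTY_EVENTS = pd.DataFrame(columns=["time", "frame", "kind", "agent_id",
                                     "mother_id"])


def static_history(cells, n_frames=6, domain=(20.0, 20.0), frame_interval=1.0):
    """Hand-built history of static cells; ``cells`` is a list of
    (x, y, length, angle_rad) tuples."""
    times = np.arange(n_frames, dtype=float) * frame_interval
    rows = []
    for fi, t in enumerate(times):
        for aid, (x, y, length, ang) in enumerate(cells):
            dx, dy = 0.5 * length * np.cos(ang), 0.5 * length * np.sin(ang)
            rows.append((fi, t, aid, x, y, x - dx, y - dy, x + dx, y + dy,
                         length))
    states = pd.DataFrame(rows, columns=["frame", "time", "agent_id", "x",
                                         "y", "pole_ax", "pole_ay", "pole_bx",
                                         "pole_by", "length"])
    agents = pd.DataFrame({"agent_id": range(len(cells)), "mother_id": -1,
                           "phenotype": "non_divider", "birth_time": 0.0,
                           "division_clock": np.nan, "lag_delay": np.nan,
                           "anchored_pole_id": 0})
    cfg = SimConfig(n_initial=len(cells), domain_size=domain,
                    duration=float(times[-1]) if n_frames > 1 else 1.0,
                    frame_interval=frame_interval)
    return ColonyHistory(config=cfg, agents=agents, states=states,
                         events=EMPTY_EVENTS.copy(), times=times)


def make_trajectory(xy, traj_id=0, dt=1.0, pole_a=None, pole_b=None,
                    end_reason="censored_end_of_movie"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if pole_a is None:
        pole_a = xy - [1.0, 0.0]
    if pole_b is None:
        pole_b = xy + [1.0, 0.0]
    return Trajectory(traj_id=traj_id, times=np.arange(n) * dt, xy=xy,
                      pole_a=np.asarray(pole_a, float),
                      pole_b=np.asarray(pole_b, float),
                      length=np.full(n, 2.0), eccentricity=np.full(n, 0.87),
                      end_reason=end_reason)


@pytest.fixture(scope="session")
def growth_fixture():
    """Small rendered growth movie with ground truth: 20 initial pure
    dividers on a fixed 40-min clock over 100 min (two division rounds)."""
    cfg = SimConfig(divider_fraction_f=1.0, mean_division_time=40.0,
                    division_time_distribution="fixed", lagged_fraction=0.0,
                    n_initial=20, domain_size=(50.0, 50.0), duration=100.0,
                    seed=7, resolve_overlaps=True)
    history = simulate_colony(cfg)
    optics = OpticsConfig(seed=8)
    stack, ground_truth = render_frames(history, optics)
    blank = render_blank_frames(optics, stack.frames.shape[1:], 10)
    background = background_model(blank, 10)
    return {"config": cfg, "history": history, "optics": optics,
            "stack": stack, "ground_truth": ground_truth,
            "background": background}


@pytest.fixture(scope="session")
def replication_bundle():
    """Full rendered pipeline at desk scale under the lowest-shear study
    conditions: f = 0.80, near-synchronous 52-min clock, no erosion."""
    from shearcolony.pipeline import PipelineConfig, run_pipeline
    config = PipelineConfig(
        sim=SimConfig(divider_fraction_f=0.80, mean_division_time=52.0,
                      division_time_distribution="gamma",
                      division_time_cv=0.15, lagged_fraction=0.0,
                      n_initial=40, domain_size=(64.0, 64.0), duration=200.0,
                      seed=41, initial_age_randomized=True),
        optics=OpticsConfig(seed=42),
        rate_window=(80.0, None))
    return config, run_pipeline(config)


@pytest.fixture(scope="session")
def threshold_report(growth_fixture):
    """+/- 18% segmentation-threshold perturbation on the growth movie."""
    from shearcolony.segment import threshold_sensitivity
    return threshold_sensitivity(
        growth_fixture["stack"].frames, SegmentationParams(), 0.18,
        fit_window=(20.0, None), background=growth_fixture["background"])


@pytest.fixture(scope="session")
def erosion_history():
    """Dilute non-divider population with detachment and 40% reattachment,
    the regime in which erosion rates are quantified."""
    cfg = SimConfig(divider_fraction_f=0.0, lagged_fraction=0.0,
                    n_initial=250, domain_size=(300.0, 300.0), duration=300.0,
                    seed=21, detachment_rate=0.5, reattachment_prob=0.4,
                    resolve_overlaps=False)
    return simulate_colony(cfg)
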
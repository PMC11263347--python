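"""End-to-end orchestration: simulate, render, segment, track, classify, rate.

:func:`run_pipeline` wires the stages together and returns a results bundle
with the oracle (event-log) rates, the measured rates, phenotype fractions,
division-time statistics and the growth-model consistency check.  Every
stochastic stage consumes an explicit seed from the config, so identical
configs give identical bundles.  ``use_rendering=False`` bypasses the
imaging emulation and feeds ground-truth trajectories straight into the
classification and rate stages, which is the noiseless reference mode used
for oracle-equivalence checks (and is much faster at large colony sizes).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from shearcolony import io as scio
from shearcolony.colony import (ColonyHistory, SimConfig,
                                history_to_trajectories, oracle_rates,
                                simulate_colony)
from shearcolony.growth import fit_mean_division_time, fraction_from_growth
from shearcolony.msd import ClassifierParams, classify_phenotype
from shearcolony.rates import (divider_fraction_series,
                               division_time_statistics, observed_growth_rate,
                               population_series_from_trajectories,
                               rate_decomposition)
from shearcolony.render import (OpticsConfig, render_blank_frames,
                                render_frames)
from shearcolony.segment import (SegmentationParams, background_model,
                                 segment_stack)
from shearcolony.track import (LinkConfig, detect_attach_detach_events,
                               detect_division_events, link_trajectories)

logger = logging.getLogger("shearcolony")

__all__ = ["PipelineConfig", "run_pipeline", "pipeline_config_from_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    link: LinkConfig = field(default_factory=LinkConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    rate_window: tuple[float | None, float | None] = (80.0, None)
    truncate_after: float | None = None
    use_rendering: bool = True


_NESTED = {"sim": SimConfig, "optics": OpticsConfig,
           "segmentation": SegmentationParams, "link": LinkConfig,
           "classifier": ClassifierParams}


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a (YAML-loaded) nested dict.

    Unknown keys raise, so configuration typos fail loudly.
    """
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            cls = _NESTED[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
            if key == "sim" and "domain_size" in value:
                value = {**value, "domain_size": tuple(value["domain_size"])}
            if key == "optics" and value.get("image_shape") is not None:
                value = {**value, "image_shape": tuple(value["image_shape"])}
            kwargs[key] = cls(**value)
        elif key == "rate_window":
            kwargs[key] = tuple(value)
        elif key in ("truncate_after", "use_rendering"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown pipeline config key {key!r}")
    return PipelineConfig(**kwargs)


def _empty_bundle(config: PipelineConfig) -> dict:
    return {
        "n_initial": 0, "n_frames": 0, "n_trajectories": 0,
        "oracle": None, "measured": None,
        "divider_fraction_mean": None,
        "phenotype_counts": {"divider": 0, "non_divider": 0, "censored": 0,
                             "lagged": 0},
        "division_time_stats": None, "model": None,
        "seeds": {"sim": config.sim.seed, "optics": config.optics.seed},
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 ) -> dict:
    """Execute the full analysis chain and return the results bundle.

    Stages: simulate -> (render -> segment) -> track -> classify -> rates
    -> growth-model consistency.  Any stage failure propagates with a
    stage-tagged log record.  If ``out_dir`` is given, tables, the stack
    and the results JSON are written there along with a config echo.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        scio.dump_config(out / "config_echo.yaml", config)

    logger.info("stage=simulate seed=%d n0=%s", config.sim.seed,
                config.sim.n_initial)
    history = simulate_colony(config.sim)
    if history.n_agents == 0:
        logger.info("stage=simulate empty history; returning empty bundle")
        bundle = _empty_bundle(config)
        if out is not None:
            scio.write_json(out / "results.json", bundle)
        return bundle
    frame_interval = config.sim.frame_interval

    window = config.rate_window
    if config.truncate_after is not None:
        hi = window[1] if window[1] is not None else history.times[-1]
        window = (window[0], min(hi, config.truncate_after))

    oracle = oracle_rates(history, (window[0], window[1] if window[1]
                                    is not None else float(history.times[-1])))
    logger.info("stage=oracle eta_eff=%.3f", oracle.eta_eff)

    if config.use_rendering:
        stack, ground_truth = render_frames(history, config.optics)
        logger.info("stage=render frames=%d shape=%s", stack.n_frames,
                    stack.frames.shape[1:])
        # the simulated movie carries cells from frame 0, so the background
        # model comes from rendered cell-free frames rather than the first
        # frames of the movie (which a real, nearly-empty acquisition allows)
        blank = render_blank_frames(config.optics, stack.frames.shape[1:],
                                    config.segmentation.background_frames)
        background = background_model(blank,
                                      config.segmentation.background_frames)
        detections = segment_stack(stack.frames, config.segmentation,
                                   pixel_size=config.optics.pixel_size,
                                   background=background)
        logger.info("stage=segment detections=%d", len(detections))
        trajectories = link_trajectories(detections, config.link,
                                         frame_interval=frame_interval)
        if out is not None:
            scio.write_tiff_stack(out / "stack.tiff", stack.frames)
            scio.write_table(out / "ground_truth.csv", ground_truth)
            scio.write_table(out / "detections.csv", detections)
    else:
        trajectories = history_to_trajectories(history)
    logger.info("stage=track trajectories=%d", len(trajectories))

    division_events = detect_division_events(trajectories, config.link,
                                             frame_interval)
    ad_events, ad_series = detect_attach_detach_events(
        trajectories, config.link, division_events, frame_interval)
    logger.info("stage=events divisions=%d detach/attach=%d",
                len(division_events), len(ad_events))

    calls = []
    division_time_by_traj = {ev.mother_traj: ev.division_time
                             for ev in division_events}
    for tr in trajectories:
        calls.append(classify_phenotype(
            tr, config.classifier,
            division_time=division_time_by_traj.get(tr.traj_id)))
    counts = {"divider": sum(c.call == "divider" for c in calls),
              "non_divider": sum(c.call == "non_divider" for c in calls),
              "censored": sum(c.call == "censored" for c in calls),
              "lagged": sum(c.lagged_flag for c in calls)}
    frac_series, frac_mean = divider_fraction_series(
        calls, trajectories, history.times)
    logger.info("stage=classify %s divider_fraction=%.3f", counts,
                frac_mean if frac_mean is not None else float("nan"))

    series = population_series_from_trajectories(
        trajectories, history.times, event_series=ad_series)
    eta, eta_se = observed_growth_rate(series, window)
    measured = rate_decomposition(eta, series, window, eta_se=eta_se)
    logger.info("stage=rates eta=%.3f eta_eff=%.3f", measured.eta,
                measured.eta_eff)

    division_stats = None
    if division_events:
        tau = np.array([ev.division_time for ev in division_events])
        births = np.array([
            next(tr for tr in trajectories
                 if tr.traj_id == ev.mother_traj).start_time
            for ev in division_events])
        if len(tau) >= 10:
            division_stats = division_time_statistics(tau, birth_times=births)

    tau_model = config.sim.model_division_time
    model = {
        "tau_bar_d_config": tau_model,
        "fraction_from_growth": None,
        "tau_fit_min": None,
    }
    try:
        model["fraction_from_growth"] = fraction_from_growth(
            measured.eta_eff, tau_model)
    except ValueError:
        pass
    if frac_mean is not None and np.isfinite(frac_mean) and frac_mean > 0.5:
        fit = fit_mean_division_time([(frac_mean, measured.eta_eff)])
        model["tau_fit_min"] = fit.tau_bar_d

    bundle = {
        "n_initial": int((history.agents["birth_time"] == 0).sum()),
        "n_frames": len(history.times),
        "n_trajectories": len(trajectories),
        "n_divisions": len(division_events),
        "oracle": oracle,
        "measured": measured,
        "divider_fraction_mean": frac_mean,
        "phenotype_counts": counts,
        "division_time_stats": None if division_stats is None else {
            "mean_division_time": division_stats.mean_division_time,
            "lambda_hat": division_stats.lambda_hat,
            "lagged_fraction_hat": division_stats.lagged_fraction_hat,
            "n_samples": len(division_stats.samples),
        },
        "model": model,
        "seeds": {"sim": config.sim.seed, "optics": config.optics.seed},
    }
    if out is not None:
        scio.write_trajectories(out / "trajectories.csv", trajectories)
        scio.write_table(out / "events.csv", ad_events)
        scio.write_json(out / "results.json", bundle)
    return bundle
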
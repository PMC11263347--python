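"""Population bookkeeping for surface-attached colonies.

The observed growth rate of the attached population,
``eta = <(1/N) dN/dt>``, is estimated as the least-squares slope of
``ln N`` versus time (the two are equivalent for exponential growth).
Erosion is accounted for through the cumulative detachment and
reattachment counts: the detachment ratio ``R_d = N_d / N``, the
reattachment ratio ``R_a = N_a / N_d``, the per-capita rates
``eta_d = <(1/N) dN_d/dt>`` and ``eta_a = <(1/N) dN_a/dt>``, and the
effective (erosion-corrected) growth rate
``eta_eff = eta + eta_d - eta_a``, which measures daughter production per
attached cell regardless of whether the daughters stay attached.

Division-time statistics: in the bulk of the distribution the division
times of dividers follow an exponential law ``p(tau) = lambda e^(-lambda
tau)`` on a support starting at a physiological floor (~20 min); cells
beyond a long-time cutoff (~160 min) form the separate lagged cohort.  The
exponential rate is fitted by maximum likelihood on the bulk, accounting
for the floor shift and the right truncation at the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PopulationSeries",
    "RateEstimates",
    "DivisionTimeStats",
    "population_series_from_trajectories",
    "observed_growth_rate",
    "instantaneous_growth_rate",
    "detachment_attachment_ratios",
    "rate_decomposition",
    "birth_class_partition",
    "division_time_statistics",
    "mean_division_time_in_birth_window",
    "divider_fraction_series",
]


@dataclass
class PopulationSeries:
    """Per-frame attached count and cumulative detachment/attachment counts.

    ``birth_class_counts`` (optional) is an (n_frames, n_classes) array of
    attached counts per 40-min birth class.
    """

    times: np.ndarray
    N: np.ndarray
    N_d: np.ndarray | None = None
    N_a: np.ndarray | None = None
    birth_class_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if np.any(self.N < 0):
            raise ValueError("attached counts must be non-negative")
        for name in ("N_d", "N_a"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(np.diff(v) < 0):
                    raise ValueError(f"{name} must be non-decreasing")
                setattr(self, name, v)


@dataclass
class RateEstimates:
    """Growth and erosion rates for one experiment window (h^-1)."""

    eta: float
    eta_d: float
    eta_a: float
    eta_eff: float
    R_d: float
    R_a: float | None
    fit_window: tuple[float, float]
    eta_se: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.eta_eff - (self.eta + self.eta_d - self.eta_a)) > 1e-9:
            raise ValueError("eta_eff must equal eta + eta_d - eta_a")


def population_series_from_trajectories(
        trajectories, frame_times: np.ndarray,
        event_series: pd.DataFrame | None = None,
        class_interval: float = 40.0, n_classes: int = 9,
        ) -> PopulationSeries:
    """Assemble the per-frame population series from linked trajectories.

    The attached count at a frame is the number of trajectories with a
    recorded point spanning it (open interval [start, end]).  Cumulative
    detach/attach counts come from ``event_series`` (as produced by
    :func:`shearcolony.track.detect_attach_detach_events`), interpolated on
    the frame grid.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = np.zeros(len(frame_times))
    for tr in trajectories:
        n += (frame_times >= tr.start_time - 1e-9) \
            & (frame_times <= tr.end_time + 1e-9)
    n_d = n_a = None
    if event_series is not None and len(event_series):
        t_ev = event_series["time"].to_numpy()
        idx = np.clip(np.searchsorted(t_ev, frame_times, side="right") - 1,
                      0, len(t_ev) - 1)
        n_d = event_series["N_d"].to_numpy()[idx].astype(float)
        n_a = event_series["N_a"].to_numpy()[idx].astype(float)
        n_d[frame_times < t_ev[0]] = 0.0
        n_a[frame_times < t_ev[0]] = 0.0
    classes = birth_class_partition(trajectories, frame_times,
                                    interval=class_interval,
                                    n_classes=n_classes)
    return PopulationSeries(times=frame_times, N=n, N_d=n_d, N_a=n_a,
                            birth_class_counts=classes)


def _window_mask(times: np.ndarray, window: tuple[float | None, float | None],
                 ) -> np.ndarray:
    lo = times[0] if window[0] is None else window[0]
    hi = times[-1] if window[1] is None else window[1]
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def observed_growth_rate(series: PopulationSeries,
                         window: tuple[float | None, float | None] = (80.0, None),
                         ) -> tuple[float, float]:
    """Observed growth rate eta (h^-1) and its standard error.

    Least-squares slope of ``ln N`` versus time over the window, which for
    exponential growth equals the time-averaged per-capita rate.
    """
    mask = _window_mask(series.times, window)
    if mask.sum() < 3:
        raise ValueError("growth-rate window must contain at least 3 frames")
    n = series.N[mask]
    if np.any(n <= 0):
        raise ValueError("attached count must be positive over the fit window")
    t = series.times[mask]
    import statsmodels.api as sm
    model = sm.OLS(np.log(n), sm.add_constant(t)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    return slope * 60.0, se * 60.0


def instantaneous_growth_rate(series: PopulationSeries,
                              window: tuple[float | None, float | None] = (80.0, None),
                              ) -> float:
    """Time-average of (1/N) dN/dt (h^-1), the direct per-capita estimator.

    Provided for comparison with the log-linear fit; the two agree for
    clean exponential growth.
    """
    mask = _window_mask(series.times, window)
    t = series.times[mask]
    n = series.N[mask]
    if len(t) < 2 or np.any(n <= 0):
        raise ValueError("need >= 2 frames with positive counts")
    dt = np.diff(t)
    per_capita = np.diff(n) / dt / n[:-1]
    return float(np.mean(per_capita)) * 60.0


def detachment_attachment_ratios(series: PopulationSeries,
                                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pointwise R_d(t) = N_d/N and R_a(t) = N_a/N_d, plus summary values.

    R_a is NaN (undefined, not zero) wherever no detachment has occurred
    yet.  The summary dict carries time-averaged and end-of-run values.
    """
    if series.N_d is None or series.N_a is None:
        raise ValueError("series must carry cumulative N_d and N_a counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        r_d = np.where(series.N > 0, series.N_d / series.N, np.nan)
        r_a = np.where(series.N_d > 0, series.N_a / series.N_d, np.nan)
    summary = {
        "R_d_end": float(r_d[-1]) if np.isfinite(r_d[-1]) else np.nan,
        "R_a_end": float(r_a[-1]) if np.isfinite(r_a[-1]) else np.nan,
        "R_d_mean": float(np.nanmean(r_d)) if np.isfinite(r_d).any() else np.nan,
        "R_a_mean": float(np.nanmean(r_a)) if np.isfinite(r_a).any() else np.nan,
    }
    return r_d, r_a, summary


def rate_decomposition(eta: float, series: PopulationSeries,
                       window: tuple[float | None, float | None] = (80.0, None),
                       eta_se: float = np.nan) -> RateEstimates:
    """Assemble eta_eff = eta + eta_d - eta_a from cumulative event counts.

    The per-capita event rates use left-aligned finite differences of the
    cumulative counts divided by the current attached count, then a time
    average over the window.
    """
    mask = _window_mask(series.times, window)
    if mask.sum() < 2:
        raise ValueError("decomposition window must contain >= 2 frames")
    t = series.times[mask]
    n = series.N[mask]
    if series.N_d is None or series.N_a is None:
        eta_d = eta_a = 0.0
        r_d_end, r_a_end = 0.0, None
    else:
        n_d = series.N_d[mask]
        n_a = series.N_a[mask]
        dt = np.diff(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc_d = np.diff(n_d) / dt / n[:-1]
            inc_a = np.diff(n_a) / dt / n[:-1]
        eta_d = float(np.mean(inc_d[np.isfinite(inc_d)])) * 60.0 \
            if np.isfinite(inc_d).any() else 0.0
        eta_a = float(np.mean(inc_a[np.isfinite(inc_a)])) * 60.0 \
            if np.isfinite(inc_a).any() else 0.0
        _, _, summary = detachment_attachment_ratios(series)
        r_d_end = summary["R_d_end"]
        r_a_end = summary["R_a_end"] if np.isfinite(summary["R_a_end"]) else None
    lo = float(t[0])
    hi = float(t[-1])
    return RateEstimates(eta=eta, eta_d=eta_d, eta_a=eta_a,
                         eta_eff=eta + eta_d - eta_a,
                         R_d=r_d_end if np.isfinite(r_d_end) else 0.0,
                         R_a=r_a_end, fit_window=(lo, hi), eta_se=eta_se)


def birth_class_partition(trajectories, frame_times: np.ndarray,
                          interval: float = 40.0, n_classes: int = 9,
                          ) -> np.ndarray:
    """Attached counts per birth class, (n_frames, n_classes).

    A cell is tagged by the interval during which it appeared by division;
    cells already attached at the start of the movie belong to the first
    class.  Birth times beyond the class range are clipped to the last
    class with a warning.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    counts = np.zeros((len(frame_times), n_classes))
    clipped = 0
    t0 = frame_times[0] if len(frame_times) else 0.0
    for tr in trajectories:
        birth = tr.start_time
        cls = 0 if birth <= t0 + 1e-9 else int((birth - t0) // interval)
        if cls >= n_classes:
            cls = n_classes - 1
            clipped += 1
        open_mask = (frame_times >= tr.start_time - 1e-9) \
            & (frame_times <= tr.end_time + 1e-9)
        counts[open_mask, cls] += 1
    if clipped:
        warnings.warn(f"{clipped} trajectories born beyond the class range "
                      f"were clipped to class {n_classes}", stacklevel=2)
    return counts


@dataclass
class DivisionTimeStats:
    """Exponential fit of the division-time bulk and cohort summaries."""

    samples: np.ndarray
    lambda_hat: float            # min^-1; 1/lambda_hat is the fitted mean
    mean_division_time: float    # = 1 / lambda_hat
    lagged_fraction_hat: float
    n_bulk: int
    degenerate: bool = False
    mean_vs_observation_time: pd.DataFrame | None = None


def _truncated_exponential_mle(shifted: np.ndarray, c: float) -> float:
    """MLE of the exponential scale theta from samples of
    ``Exp(theta)`` right-truncated at ``c`` (samples already floor-shifted)."""
    m = float(np.mean(shifted))
    if m >= c / 2 - 1e-12:
        # flatter than any truncated exponential can be; fall back to the
        # untruncated estimator
        return m

    def g(theta):
        with np.errstate(over="ignore"):
            return theta - c / np.expm1(c / theta) - m

    return float(brentq(g, 1e-6, 1e7))


def division_time_statistics(division_times: np.ndarray,
                             floor: float = 20.0, cutoff: float = 160.0,
                             birth_times: np.ndarray | None = None,
                             bin_width: float = 40.0) -> DivisionTimeStats:
    """Fit the exponential division-time law on the sub-cutoff bulk.

    ``division_times`` in minutes.  Samples above ``cutoff`` form the
    lagged cohort and are excluded from the fit; the fitted mean accounts
    for the support floor and the right truncation.  When ``birth_times``
    is given, the per-birth-bin mean division time series is attached
    (the time-resolved average that relaxes toward the continuous
    dividers' mean as the lagged cohort divides out).
    """
    tau = np.asarray(division_times, dtype=float)
    if len(tau) < 10:
        raise ValueError("need at least 10 division-time samples to fit")
    bulk = tau[(tau > floor) & (tau <= cutoff)]
    if len(bulk) == 0:
        raise ValueError("all samples above the lag cutoff; exponential fit "
                         "refused (population appears fully lagged)")
    degenerate = bool(np.ptp(bulk) < 1e-9)
    if degenerate:
        mean_hat = float(np.mean(bulk))
    else:
        theta = _truncated_exponential_mle(bulk - floor, cutoff - floor)
        mean_hat = floor + theta
    lagged_frac = float(np.mean(tau > cutoff))
    per_bin = None
    if birth_times is not None:
        birth_times = np.asarray(birth_times, dtype=float)
        bins = (birth_times // bin_width).astype(int)
        per_bin = (pd.DataFrame({"bin": bins, "tau_d": tau})
                   .groupby("bin")["tau_d"]
                   .agg(["mean", "count"])
                   .reset_index()
                   .rename(columns={"mean": "mean_tau_d", "count": "n"}))
        per_bin["bin_start"] = per_bin["bin"] * bin_width
    return DivisionTimeStats(samples=tau, lambda_hat=1.0 / mean_hat,
                             mean_division_time=mean_hat,
                             lagged_fraction_hat=lagged_frac,
                             n_bulk=int(len(bulk)), degenerate=degenerate,
                             mean_vs_observation_time=per_bin)


def mean_division_time_in_birth_window(division_times: np.ndarray,
                                       birth_times: np.ndarray,
                                       window: tuple[float, float],
                                       ) -> tuple[float, int]:
    """Mean observed division time of cells born inside a time window.

    Used for the late-observation-bin average: choosing the window so that
    lagged cells born inside it cannot yet have divided (and continuous
    ones are unlikely to be censored) isolates the continuous dividers'
    clock.
    """
    tau = np.asarray(division_times, dtype=float)
    birth = np.asarray(birth_times, dtype=float)
    mask = (birth >= window[0]) & (birth < window[1])
    if mask.sum() == 0:
        raise ValueError("no division events with births inside the window")
    return float(np.mean(tau[mask])), int(mask.sum())


def divider_fraction_series(calls, trajectories, frame_times: np.ndarray,
                            ) -> tuple[np.ndarray, float]:
    """Cumulative divider fraction over time, and its time average.

    ``calls`` are phenotype calls (objects with ``traj_id`` and ``call``
    attributes); censored trajectories are excluded.  At each frame the
    fraction is (cumulative classified dividers) / (cumulative classified
    dividers + non-dividers) among trajectories that have started by then.
    Frames before the first classified trajectory are NaN.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    start_by_id = {tr.traj_id: tr.start_time for tr in trajectories}
    div = np.zeros(len(frame_times))
    non = np.zeros(len(frame_times))
    for call in calls:
        if call.call == "censored":
            continue
        started = frame_times >= start_by_id[call.traj_id] - 1e-9
        if call.call == "divider":
            div += started
        else:
            non += started
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(div + non > 0, div / (div + non), np.nan)
    mean = float(np.nanmean(frac)) if np.isfinite(frac).any() else np.nan
    return frac, mean
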
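import numpy as np
import pytest

from conftest import make_trajectory
from shearcolony.rates import (PopulationSeries, RateEstimates,
                               birth_class_partition,
                               detachment_attachment_ratios,
                               division_time_statistics,
                               instantaneous_growth_rate,
                               mean_division_time_in_birth_window,
                               observed_growth_rate, rate_decomposition)


def exponential_series(eta_h=0.54, n0=100.0, t_end=360.0):
    t = np.arange(0.0, t_end + 1e-9, 1.0)
    return PopulationSeries(times=t, N=n0 * np.exp(eta_h * t / 60.0))


class TestObservedGrowthRate:
    def test_exact_exponential_input(self):
        eta, se = observed_growth_rate(exponential_series(0.54), (0.0, None))
        assert eta == pytest.approx(0.54, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_population(self):
        t = np.arange(0.0, 100.0)
        eta, _ = observed_growth_rate(PopulationSeries(times=t,
                                                       N=np.full(100, 50.0)),
                                      (0.0, None))
        assert eta == pytest.approx(0.0, abs=1e-12)

    def test_instantaneous_average_agrees_on_clean_exponential(self):
        series = exponential_series(0.42)
        eta_fit, _ = observed_growth_rate(series, (0.0, None))
        eta_inst = instantaneous_growth_rate(series, (0.0, None))
        # forward differences overshoot by eta*dt/2, i.e. ~0.35% here
        assert eta_inst == pytest.approx(eta_fit, rel=6e-3)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="at least 3 frames"):
            observed_growth_rate(exponential_series(), (0.0, 1.0))


class TestRatios:
    def test_end_of_run_detachment_ratio(self):
        t = np.arange(0.0, 11.0)
        series = PopulationSeries(times=t, N=np.full(11, 100.0),
                                  N_d=np.linspace(0, 50, 11),
                                  N_a=np.zeros(11))
        r_d, r_a, summary = detachment_attachment_ratios(series)
        assert summary["R_d_end"] == pytest.approx(0.5)
        assert np.isnan(r_a[0])          # undefined before any detachment

    def test_no_detachment_leaves_ra_undefined(self):
        t = np.arange(0.0, 11.0)
        series = PopulationSeries(times=t, N=np.full(11, 100.0),
                                  N_d=np.zeros(11), N_a=np.zeros(11))
        r_d, r_a, summary = detachment_attachment_ratios(series)
        assert np.all(r_d == 0.0)
        assert np.all(np.isnan(r_a))
        assert np.isnan(summary["R_a_end"])

    def test_cumulative_counts_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            PopulationSeries(times=np.arange(3.0), N=np.ones(3),
                             N_d=np.array([1.0, 0.0, 2.0]))


class TestDecomposition:
    def test_printed_high_regime_arithmetic(self):
        # eta 0.21 + eta_d 0.09 - eta_a 0 = 0.30 (the implied split)
        t = np.arange(0.0, 361.0)
        n = 100 * np.exp(0.21 * t / 60.0)
        n_d = np.cumsum(np.concatenate([[0.0], 0.09 / 60.0 * n[:-1]]))
        series = PopulationSeries(times=t, N=n, N_d=n_d, N_a=np.zeros(len(t)))
        estimates = rate_decomposition(0.21, series, (0.0, None))
        assert estimates.eta_d == pytest.approx(0.09, rel=1e-6)
        assert estimates.eta_eff == pytest.approx(0.30, rel=1e-6)

    def test_no_events_means_eta_eff_equals_eta(self):
        series = exponential_series(0.42)
        estimates = rate_decomposition(0.42, series, (0.0, None))
        assert estimates.eta_eff == 0.42
        assert estimates.eta_d == 0.0 and estimates.eta_a == 0.0

    def test_identity_enforced_on_construction(self):
        with pytest.raises(ValueError, match="eta_eff"):
            RateEstimates(eta=0.5, eta_d=0.1, eta_a=0.0, eta_eff=0.7,
                          R_d=0.0, R_a=None, fit_window=(0.0, 1.0))


class TestBirthClasses:
    def test_single_division_moves_mass_between_classes(self):
        mother = make_trajectory(np.tile([5.0, 5.0], (51, 1)),
                                 traj_id=0, end_reason="division")
        d1 = make_trajectory(np.tile([4.0, 5.0], (50, 1)), traj_id=1)
        d2 = make_trajectory(np.tile([6.0, 5.0], (50, 1)), traj_id=2)
        for d in (d1, d2):
            d.times = d.times + 51.0
        frame_times = np.arange(0.0, 101.0)
        counts = birth_class_partition([mother, d1, d2], frame_times)
        assert counts[30, 0] == 1 and counts[30, 1] == 0
        assert counts[60, 0] == 0 and counts[60, 1] == 2

    def test_no_divisions_all_mass_in_first_class(self):
        trajs = [make_trajectory(np.tile([i * 5.0, 5.0], (100, 1)), traj_id=i)
                 for i in range(4)]
        counts = birth_class_partition(trajs, np.arange(0.0, 100.0))
        assert np.all(counts[:, 0] == 4)
        assert np.all(counts[:, 1:] == 0)
        # class counts always sum to the attached count
        assert np.all(counts.sum(axis=1) == 4)

    def test_birth_beyond_range_clipped_with_warning(self):
        late = make_trajectory(np.tile([5.0, 5.0], (10, 1)), traj_id=0)
        late.times = late.times + 400.0
        with pytest.warns(UserWarning, match="clipped"):
            counts = birth_class_partition([late], np.arange(0.0, 411.0))
        assert counts[405, 8] == 1

    def test_oracle_identity_on_simulated_colony(self):
        from shearcolony.colony import (SimConfig, history_to_trajectories,
                                        simulate_colony)
        cfg = SimConfig(divider_fraction_f=0.9, lagged_fraction=0.0,
                        n_initial=30, domain_size=(160.0, 160.0),
                        duration=320.0, seed=19, resolve_overlaps=False)
        history = simulate_colony(cfg)
        trajs = history_to_trajectories(history)
        counts = birth_class_partition(trajs, history.times)
        # recompute from the event log
        oracle = np.zeros_like(counts)
        for aid, grp in history.states.groupby("agent_id"):
            birth = history.agents.set_index("agent_id").loc[aid,
                                                             "birth_time"]
            cls = min(int(birth // 40.0), 8) if birth > 0 else 0
            oracle[grp.frame.to_numpy(), cls] += 1
        assert np.array_equal(counts, oracle)
        # rise-then-fall: early classes peak and then decline
        peak = counts[:, 0].argmax()
        assert counts[peak, 0] > counts[-1, 0]


class TestDivisionTimeStatistics:
    def test_generator_clock_mean_recovered(self):
        # 1500 clock draws (floor 20, mean 40): fitted mean within 2 min
        from shearcolony.colony import SimConfig, _draw_clocks
        rng = np.random.default_rng(10)
        draws = _draw_clocks(rng, SimConfig(), 1500)
        stats = division_time_statistics(draws)
        assert stats.mean_division_time == pytest.approx(40.0, abs=2.0)
        assert 1.0 / stats.lambda_hat == stats.mean_division_time

    def test_degenerate_sample_flagged(self):
        stats = division_time_statistics(np.full(50, 40.0))
        assert stats.degenerate
        assert stats.mean_division_time == pytest.approx(40.0)

    def test_mixture_mean_matches_closed_form(self):
        # 87.5% exp(mean 40) + 12.5% (delay 120 + exp 40):
        # mixture mean = 0.875*40 + 0.125*160 = 55 min
        rng = np.random.default_rng(4)
        n = 8000
        lagged = rng.random(n) < 0.125
        tau = 20.0 + rng.exponential(20.0, n)
        tau[lagged] += 120.0
        assert tau.mean() == pytest.approx(55.0, abs=1.0)

    def test_bulk_fit_isolates_continuous_clock_in_mixture(self):
        # with the lagged cohort fully beyond the 160-min cutoff the
        # truncated-exponential fit on the bulk recovers the 40-min clock
        rng = np.random.default_rng(4)
        n = 8000
        lagged = rng.random(n) < 0.125
        tau = 20.0 + rng.exponential(20.0, n)
        tau[lagged] += 160.0
        stats = division_time_statistics(tau)
        assert stats.mean_division_time == pytest.approx(40.0, abs=2.0)
        assert stats.lagged_fraction_hat == pytest.approx(
            float(np.mean(tau > 160.0)), abs=1e-9)

    def test_all_lagged_fit_refused(self):
        with pytest.raises(ValueError, match="lag cutoff"):
            division_time_statistics(np.full(20, 300.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 10"):
            division_time_statistics(np.array([40.0, 50.0]))

    def test_time_resolved_mean_relaxes_to_continuous_clock(self):
        # the first observation bin carries the lagged cohort and sits well
        # above 40 min; once the lagged cells have divided out the mean
        # division time relaxes to the continuous dividers' clock (bins
        # whose births can still be fully observed, i.e. <= horizon - 160)
        from shearcolony.colony import SimConfig, simulate_colony
        cfg = SimConfig(divider_fraction_f=1.0, lagged_fraction=0.125,
                        lagged_delay=180.0, n_initial=100,
                        domain_size=(300.0, 300.0), duration=280.0, seed=5,
                        resolve_overlaps=False, record_states=False)
        history = simulate_colony(cfg)
        div = history.events[history.events.kind == "division_complete"]
        agents = history.agents.set_index("agent_id")
        births = agents.loc[div.agent_id, "birth_time"].to_numpy()
        tau = div.time.to_numpy() - births
        stats = division_time_statistics(tau, birth_times=births)
        per_bin = stats.mean_vs_observation_time
        trend = per_bin[per_bin.bin_start <= 280.0 - 160.0] \
            .mean_tau_d.to_numpy()
        assert trend[0] > 45.0
        assert trend[0] > trend[2]
        assert trend[2] == pytest.approx(40.0, abs=2.5)
        late, n_late = mean_division_time_in_birth_window(
            tau, births, (80.0, 120.0))
        assert n_late > 300
        assert late == pytest.approx(40.0, abs=2.0)
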
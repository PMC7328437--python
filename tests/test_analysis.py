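"""Schedule statistics, target evaluation, curves and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surf.activities import ACTIVITIES, AT_HOME, SHOP_FOOD, TRAVEL, WORK
from surf.analysis import (
    ScheduleStats,
    TargetSet,
    compare,
    compare_per_sensor,
    evaluate_targets,
    pooled_hourly_curve,
    schedule_stats,
    smooth_curve,
    zscore,
)
from surf.sensors import FootfallTable

SPD = 288


def make_log(episodes, spd=SPD):
    """Build one agent's log from (activity, start_step, length) triples;
    everything else is at_home."""
    log = np.full(spd, AT_HOME, dtype=np.int8)
    for act, start, length in episodes:
        log[start:start + length] = act
    return log


class TestScheduleStats:
    def test_single_half_hour_episode(self):
        log = make_log([(SHOP_FOOD, 100, 6)])[None, :]
        st_ = schedule_stats(log, np.array([0]))
        assert st_.get("commuter", "shop_food", "participation") == 100.0
        assert st_.get("commuter", "shop_food", "duration_mean") == 30.0
        assert st_.get("commuter", "shop_food", "duration_median") == 30.0

    def test_participation_counts_agents_not_episodes(self):
        logs = np.stack([
            make_log([(SHOP_FOOD, 100, 6), (SHOP_FOOD, 150, 6)]),
            make_log([]),
        ])
        st_ = schedule_stats(logs, np.array([0, 0]))
        assert st_.get("commuter", "shop_food", "participation") == 50.0
        assert st_.table.loc[("commuter", "shop_food"), "n_episodes"] == 2

    def test_travel_breaks_runs_and_is_excluded(self):
        log = np.full(SPD, AT_HOME, dtype=np.int8)
        log[100:103] = TRAVEL
        log[103:109] = SHOP_FOOD
        log[109:112] = TRAVEL
        st_ = schedule_stats(log[None, :], np.array([0]))
        assert st_.get("commuter", "shop_food", "duration_mean") == 30.0
        # at_home splits into two episodes around the trip
        assert st_.table.loc[("commuter", "at_home"), "n_episodes"] == 2

    def test_scripted_population_matches_hand_tally(self):
        """Random scripted episodes across agents, replicates and groups
        reproduce an independently coded tally of runs."""
        rng = np.random.default_rng(0)
        n = 100
        logs = []
        for _ in range(2):
            rep = np.full((n, SPD), AT_HOME, dtype=np.int8)
            for i in range(n):
                for _ in range(rng.integers(0, 4)):
                    start = int(rng.integers(0, SPD - 30))
                    rep[i, start:start + int(rng.integers(3, 25))] = SHOP_FOOD
            logs.append(rep)
        groups = np.array([0] * 60 + [1] * 40)
        st_ = schedule_stats(logs, groups)

        # independent oracle: naive python scan
        durations, participants = [], set()
        for r, rep in enumerate(logs):
            for i in range(60):
                row = rep[i]
                j = 0
                while j < SPD:
                    if row[j] == SHOP_FOOD:
                        k = j
                        while k < SPD and row[k] == SHOP_FOOD:
                            k += 1
                        durations.append((k - j) * 5)
                        participants.add((r, i))
                        j = k
                    else:
                        j += 1
        assert st_.get("commuter", "shop_food", "participation") == pytest.approx(
            100.0 * len(participants) / (60 * 2)
        )
        assert st_.get("commuter", "shop_food", "duration_mean") == pytest.approx(
            np.mean(durations)
        )
        assert st_.get("commuter", "shop_food", "duration_median") == pytest.approx(
            np.median(durations)
        )

    def test_start_and_end_histograms_sum_to_episode_count(self):
        log = make_log([(SHOP_FOOD, 100, 6), (WORK, 120, 50)])[None, :]
        st_ = schedule_stats(log, np.array([0]))
        for key, hist in st_.start_hist.items():
            assert hist.sum() == st_.table.loc[key, "n_episodes"]

    def test_empty_logs_error(self):
        with pytest.raises(ValueError, match="empty"):
            schedule_stats([], np.array([]))


class TestTargets:
    def _stats_equal_to_targets(self):
        ts = TargetSet.packaged()
        rows = []
        for _, tr in ts.table.iterrows():
            rows.append({"group": tr["group"], "activity": tr["activity"],
                         "metric": tr["metric"], "value": tr["value"]})
        df = pd.DataFrame(rows).pivot_table(
            index=["group", "activity"], columns="metric", values="value"
        )
        return ScheduleStats(df), ts

    def test_exact_match_passes_with_zero_deviation(self):
        stats, ts = self._stats_equal_to_targets()
        report = evaluate_targets(stats, ts)
        assert report["passed"].all()
        assert (report["abs_deviation"] == 0).all()
        assert len(report) == len(ts.table)

    def test_double_tolerance_deviation_fails_that_row(self):
        stats, ts = self._stats_equal_to_targets()
        stats.table.loc[("commuter", "shop_food"), "participation"] += 6.0
        report = evaluate_targets(stats, ts)
        bad = report[(report.group == "commuter") & (report.activity == "shop_food")
                     & (report.metric == "participation")]
        assert not bad["passed"].item()
        assert report["passed"].sum() == len(report) - 1

    def test_missing_pair_errors(self):
        stats, ts = self._stats_equal_to_targets()
        stats.table = stats.table.drop(index=("retired", "shop_food"))
        with pytest.raises(KeyError):
            evaluate_targets(stats, ts)


class TestCurves:
    def test_pooled_curve_of_single_sensor_is_its_series(self):
        c = np.arange(24.0)[None, :]
        t = FootfallTable(c, ["s"])
        assert np.array_equal(pooled_hourly_curve(t), c[0])

    def test_pooled_curve_averages_sensors(self):
        t = FootfallTable(np.vstack([np.full(24, 2.0), np.full(24, 4.0)]),
                          ["a", "b"])
        assert np.array_equal(pooled_hourly_curve(t), np.full(24, 3.0))

    def test_pooled_curve_matches_mean_oracle(self):
        rng = np.random.default_rng(2)
        c = rng.poisson(10, (5, 24)).astype(float)
        assert np.allclose(pooled_hourly_curve(FootfallTable(c, list("abcde"))),
                           c.mean(axis=0))


class TestZScore:
    def test_closed_form_example(self):
        assert np.allclose(zscore([1, 2, 3]), [-1.2247448, 0.0, 1.2247448])

    def test_standardisation_properties(self):
        x = np.random.default_rng(3).normal(5, 2, 24)
        z = zscore(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std() == pytest.approx(1)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(np.full(24, 3.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 50), b=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    def test_invariance_under_positive_affine_transforms(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 1, 24)
        assert np.allclose(zscore(a * x + b), zscore(x), atol=1e-8)


class TestSmoothing:
    def test_preserves_constants(self):
        assert np.allclose(smooth_curve(np.full(24, 7.0)), 7.0)

    def test_reproduces_linear_series(self):
        x = np.linspace(0, 10, 24)
        assert np.allclose(smooth_curve(x, 0.4), x, atol=1e-8)

    def test_reduces_noise_around_a_sinusoid(self):
        rng = np.random.default_rng(9)
        t = np.arange(24)
        clean = np.sin(2 * np.pi * t / 24)
        noisy = clean + rng.normal(0, 0.3, 24)
        smoothed = smooth_curve(noisy, 0.3)
        assert np.var(smoothed - clean) < np.var(noisy - clean)

    def test_invalid_bandwidth_errors(self):
        with pytest.raises(ValueError):
            smooth_curve(np.arange(24.0), 0.0)


class TestCompare:
    def test_identical_curves(self):
        x = np.random.default_rng(1).poisson(20, 24).astype(float)
        rep = compare(x, x)
        assert rep.rmse == pytest.approx(0, abs=1e-12)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_sign_flipped_curve_anticorrelates(self):
        x = np.random.default_rng(1).normal(0, 1, 24)
        rep = compare(x, -x)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        sim = rng.poisson(30, 24).astype(float)
        obs = rng.poisson(30, 24).astype(float)
        rep = compare(sim, obs)
        zs = (sim - sim.mean()) / sim.std()
        zo = (obs - obs.mean()) / obs.std()
        assert np.allclose(rep.residual, zo - zs)
        assert rep.rmse == pytest.approx(float(np.sqrt(np.mean((zo - zs) ** 2))))
        assert rep.pearson_r == pytest.approx(float(np.corrcoef(zs, zo)[0, 1]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            compare(np.arange(24.0), np.arange(23.0))

    def test_per_sensor_variant_iterates_sensors(self):
        rng = np.random.default_rng(13)
        sim = FootfallTable(rng.poisson(20, (2, 24)).astype(float), ["a", "b"])
        obs = FootfallTable(rng.poisson(20, (2, 24)).astype(float), ["a", "b"])
        reports = compare_per_sensor(sim, obs)
        assert set(reports) == {"a", "b"}
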
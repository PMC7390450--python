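"""Bout calling, the six sleep parameters, profiles and exclusion hygiene."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_zero_runs
from damsleep.errors import CoverageError, EmptyInputError
from damsleep.sleep_metrics import (
    SleepBout,
    clip_bouts,
    compute_sleep_parameters,
    detect_sleep_bouts,
    exclude_dead_flies,
    sleep_parameter_table,
    sleep_profile,
)
from damsleep.synthetic_data import FlyModelConfig, simulate_fly


class TestBoutDetection:
    def test_all_zero_window_is_one_bout(self, make_trace):
        bouts = detect_sleep_bouts(make_trace([0] * 720, t0_zt=100.0))
        assert bouts == [SleepBout(100.0, 820.0)]

    def test_short_pauses_are_wake(self, make_trace):
        counts = ([0, 0, 0, 0, 1] * 20)  # zero runs of 4 min never qualify
        assert detect_sleep_bouts(make_trace(counts)) == []

    def test_run_at_threshold_qualifies(self, make_trace):
        counts = [1] + [0] * 5 + [1] * 4
        assert detect_sleep_bouts(make_trace(counts)) == [SleepBout(1.0, 6.0)]

    def test_matches_brute_force_on_random_traces(self, make_trace):
        """200 random 1000-bin traces agree exactly with a maximal-run scanner."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = (rng.random(1000) > 0.75).astype(int)
            trace = make_trace(counts)
            got = [(int(b.start_zt), int(b.end_zt)) for b in detect_sleep_bouts(trace)]
            assert got == brute_force_zero_runs(counts)

    def test_empty_trace_rejected(self, make_trace):
        with pytest.raises(EmptyInputError):
            detect_sleep_bouts(make_trace([]))

    @given(st.lists(st.integers(min_value=0, max_value=2), min_size=30, max_size=200))
    @settings(max_examples=60, derandomize=True)
    def test_raising_threshold_never_increases_sleep(self, counts):
        trace_counts = np.asarray(counts)
        from damsleep.dam_io import ActivityTrace
        trace = ActivityTrace("f", 1, 0.0, 1, trace_counts,
                              np.zeros(len(counts), dtype=bool))
        b5 = detect_sleep_bouts(trace, 5)
        b10 = detect_sleep_bouts(trace, 10)
        assert sum(b.duration for b in b10) <= sum(b.duration for b in b5)
        assert len(b10) <= len(b5)


class TestClipping:
    def test_overlap_clipped(self):
        assert clip_bouts([SleepBout(700, 730)], (720, 1440)) == [SleepBout(720, 730)]

    def test_short_clipped_segment_keeps_sleep_status(self):
        # the parent bout qualified; 2 clipped minutes are still sleep
        assert clip_bouts([SleepBout(718, 722)], (720, 1440)) == [SleepBout(720, 722)]

    def test_random_clips_match_interval_arithmetic(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            bouts = []
            t = 0.0
            while t < 1440:
                s = t + rng.integers(1, 30)
                e = s + rng.integers(5, 120)
                bouts.append(SleepBout(s, min(e, 1440.0)))
                t = e
            lo = float(rng.integers(0, 700))
            hi = lo + float(rng.integers(100, 740))
            clipped_total = sum(b.duration for b in clip_bouts(bouts, (lo, hi)))
            oracle = sum(max(0.0, min(b.end_zt, hi) - max(b.start_zt, lo)) for b in bouts)
            assert clipped_total == pytest.approx(oracle)


def _per_bin_oracle(counts, window, t0=0.0):
    """Independent six-parameter computation straight from the bin sequence."""
    runs = brute_force_zero_runs(counts)  # indices; t0-relative minutes
    lo, hi = window[0] - t0, window[1] - t0
    segs = [(max(s, lo), min(e, hi)) for s, e in runs if min(e, hi) > max(s, lo)]
    total = sum(e - s for s, e in segs)
    freq = len(segs)
    loff = 720.0 + 1440.0 * (window[0] // 1440) - t0
    post = [s for s, _ in segs if s >= loff]
    latency = (post[0] - loff) if post else (hi - lo)
    asleep = set()
    for s, e in segs:
        asleep.update(range(int(s), int(e)))
    wake_counts = sum(c for i, c in enumerate(counts)
                      if lo <= i < hi and i not in asleep)
    wake_min = (hi - lo) - total
    return {
        "total_sleep": total,
        "sleep_frequency": freq,
        "mean_sleep": total / freq if freq else 0.0,
        "max_sleep": max((e - s for s, e in segs), default=0.0),
        "sleep_latency": latency,
        "activity_index": wake_counts / wake_min if wake_min > 0 else math.nan,
    }


class TestSleepParameters:
    def test_fully_asleep_window(self, make_trace, ld):
        trace = make_trace([0] * 1440)
        bouts = detect_sleep_bouts(trace)
        p = compute_sleep_parameters(trace, bouts, (720.0, 1440.0), ld)
        assert p.total_sleep == 720 and p.sleep_frequency == 1
        assert p.mean_sleep == p.max_sleep == 720
        assert p.sleep_latency == 0 and not p.latency_censored
        assert p.activity_index_undefined and math.isnan(p.activity_index)

    def test_fully_awake_window(self, make_trace, ld):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 5, 1440)
        trace = make_trace(counts)
        p = compute_sleep_parameters(trace, [], (720.0, 1440.0), ld)
        assert p.total_sleep == 0 and p.sleep_frequency == 0 and p.mean_sleep == 0
        assert p.sleep_latency == 720 and p.latency_censored
        assert p.activity_index == pytest.approx(counts[720:].sum() / 720)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("window", [(0.0, 720.0), (720.0, 1440.0)])
    def test_simulated_traces_match_per_bin_oracle(self, make_trace, ld, seed, window):
        cfg = FlyModelConfig(seed=seed)
        trace, _ = simulate_fly(cfg, ld, fly_seed=seed)
        bouts = detect_sleep_bouts(trace)
        p = compute_sleep_parameters(trace, bouts, window, ld)
        want = _per_bin_oracle(trace.counts.tolist(), window)
        assert p.total_sleep == want["total_sleep"]
        assert p.sleep_frequency == want["sleep_frequency"]
        assert p.mean_sleep == pytest.approx(want["mean_sleep"])
        assert p.max_sleep == want["max_sleep"]
        assert p.sleep_latency == want["sleep_latency"]
        if math.isnan(want["activity_index"]):
            assert p.activity_index_undefined
        else:
            assert p.activity_index == pytest.approx(want["activity_index"])

    def test_boundary_bout_counted_in_both_windows(self, make_trace, ld):
        counts = [1] * 700 + [0] * 40 + [1] * 700
        trace = make_trace(counts)
        bouts = detect_sleep_bouts(trace)
        day = compute_sleep_parameters(trace, bouts, (0.0, 720.0), ld)
        night = compute_sleep_parameters(trace, bouts, (720.0, 1440.0), ld)
        assert day.total_sleep == 20 and night.total_sleep == 20
        assert day.sleep_frequency == night.sleep_frequency == 1
        # total sleep conserved across the windows
        assert day.total_sleep + night.total_sleep == 40

    def test_window_outside_trace_rejected(self, make_trace, ld):
        trace = make_trace([0] * 100)
        with pytest.raises(CoverageError):
            compute_sleep_parameters(trace, [], (0.0, 720.0), ld)

    def test_conservation_over_simulated_cohort(self, ld):
        """total_sleep + waking minutes == 720 for every fly and window."""
        for seed in range(10):
            trace, _ = simulate_fly(FlyModelConfig(seed=seed), ld, fly_seed=100 + seed)
            bouts = detect_sleep_bouts(trace)
            for window in ((0.0, 720.0), (720.0, 1440.0)):
                p = compute_sleep_parameters(trace, bouts, window, ld)
                assert p.max_sleep <= p.total_sleep <= 720
                assert p.mean_sleep * p.sleep_frequency == pytest.approx(p.total_sleep)


class TestParameterTable:
    def test_one_row_per_fly_day_window(self, ld):
        cfg = FlyModelConfig(n_days=2)
        traces = [simulate_fly(cfg, ld, fly_seed=s, fly_id=f"f{s}")[0] for s in range(3)]
        table = sleep_parameter_table(traces, ld)
        assert len(table) == 3 * 2 * 2
        assert set(table["window"]) == {"ZT0-12", "ZT12-24"}
        assert set(table.columns) >= {"fly_id", "day", "total_sleep", "treatment"}


class TestProfile:
    def test_always_asleep_fly(self, make_trace):
        prof = sleep_profile([make_trace([0] * 1440)])
        assert (prof["mean"] == 1.0).all() and (prof["sem"] == 0.0).all()
        assert len(prof) == 48

    def test_half_sleeping_population(self, make_trace):
        sleeper = make_trace([0] * 720)
        # waker never accumulates 5 zero minutes
        waker = make_trace([1] * 720, fly_id="f2")
        prof = sleep_profile([sleeper, waker])
        assert (prof["mean"] == 0.5).all()

    def test_matches_coverage_oracle(self, ld):
        traces = [simulate_fly(FlyModelConfig(seed=3), ld, fly_seed=s, fly_id=f"f{s}")[0]
                  for s in range(5)]
        prof = sleep_profile(traces, profile_bin=30)
        # coverage oracle: fraction of each 30-min block inside brute-force runs
        fracs = []
        for tr in traces:
            runs = brute_force_zero_runs(tr.counts.tolist())
            asleep = np.zeros(tr.n_bins, dtype=bool)
            for s, e in runs:
                asleep[s:e] = True
            fracs.append(asleep.reshape(-1, 30).mean(axis=1))
        want = np.mean(fracs, axis=0)
        np.testing.assert_allclose(prof["mean"].to_numpy(), want)

    def test_empty_population_rejected(self):
        with pytest.raises(EmptyInputError):
            sleep_profile([])


class TestDeadFlyExclusion:
    def test_dead_fly_excluded_only_when_enabled(self, make_trace):
        dead = make_trace([3] * 1440 + [0] * 1440, fly_id="dead")
        alive = make_trace([3] * 2880, fly_id="alive")
        kept, report = exclude_dead_flies([dead, alive], enabled=True)
        assert [t.fly_id for t in kept] == ["alive"]
        kept_off, report_off = exclude_dead_flies([dead, alive], enabled=False)
        assert len(kept_off) == 2
        assert report_off.loc[report_off.fly_id == "dead", "dead_final_window"].item()

    def test_random_cohort_matches_suffix_oracle(self, make_trace):
        rng = np.random.default_rng(9)
        traces, want_dead = [], []
        for i in range(20):
            counts = rng.poisson(0.5, 2880)
            if rng.random() < 0.3:
                counts[-1440:] = 0
            traces.append(make_trace(counts, fly_id=f"f{i}"))
            want_dead.append(counts[-1440:].sum() == 0)
        _, report = exclude_dead_flies(traces, enabled=True)
        assert report["dead_final_window"].tolist() == want_dead


@pytest.mark.parametrize("mu", [10.0, 30.0, 60.0])
def test_mean_sleep_recovery_under_censoring(ld, mu):
    """Pipeline mean_sleep matches censoring-adjusted truth within 3 SE (n=50)."""
    cfg = FlyModelConfig(sleep_bout_mean={"light": 15.0, "dark": mu},
                         latency_shift=0.0, seed=int(mu))
    window = (720.0, 1440.0)
    est, truth_vals = [], []
    for i in range(50):
        trace, truth = simulate_fly(cfg, ld, fly_seed=1000 + i)
        bouts = detect_sleep_bouts(trace)
        p = compute_sleep_parameters(trace, bouts, window, ld)
        est.append(p.mean_sleep)
        truth_vals.append(truth.censored_mean_sleep(window))
    est = np.asarray(est)
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - np.mean(truth_vals)) <= 3 * se
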
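import numpy as np
import pytest

from hypnokit import (
    SLEEP,
    HypnogramError,
    Stage,
    cohort_table,
    compute_sleep_metrics,
    continuous_active_wake_bouts,
    count_soremp,
    first_sleep_latency,
    rem_latency,
    sleep_cycle_count,
    sleep_efficiency,
    stage_percentages,
    total_sleep_time,
    waso,
)


class TestTotalSleepTime:
    def test_all_wake_night_is_zero(self, hyp):
        h = hyp(["AW*720", "QW*720"], start="19:00", kind="nighttime")
        assert total_sleep_time(h) == 0.0

    def test_hand_counted_mixture(self, hyp):
        h = hyp(["QW*394", "N2*1046"], start="19:00", kind="nighttime")
        assert total_sleep_time(h) == 523.0

    def test_single_epoch(self, hyp):
        assert total_sleep_time(hyp(["N3"])) == 0.5

    def test_conservation_with_wake(self, hyp):
        rng = np.random.default_rng(3)
        tokens = list(rng.choice(["AW", "QW", "N1", "N2", "N3", "R"], size=1440))
        h = hyp(tokens)
        wake_min = 0.5 * sum(1 for s in h.stages if s not in SLEEP)
        assert total_sleep_time(h) + wake_min == h.duration_minutes


class TestSleepEfficiency:
    def test_boundaries(self):
        assert sleep_efficiency(0.0) == 0.0
        assert sleep_efficiency(720.0) == 100.0

    def test_rejects_tst_above_nocturnal_time(self):
        with pytest.raises(ValueError):
            sleep_efficiency(721.0, 720.0)

    def test_equals_direct_sleep_fraction(self, hyp):
        rng = np.random.default_rng(4)
        tokens = list(rng.choice(["AW", "QW", "N1", "N2", "N3", "R"], size=1440))
        h = hyp(tokens, start="19:00", kind="nighttime")
        frac = sum(1 for s in h.stages if s in SLEEP) / h.n_epochs
        assert sleep_efficiency(total_sleep_time(h)) == pytest.approx(
            100 * frac, abs=0.05)


class TestLatencies:
    def test_sleep_at_epoch_zero(self, hyp):
        assert first_sleep_latency(hyp(["N1", "AW*10"])) == 0.0

    def test_daytime_clock_arithmetic(self, hyp):
        # first N1 at 08:10 on a 07:00 recording: epoch 140
        h = hyp(["AW*140", "N1", "AW*1299"])
        assert first_sleep_latency(h) == 70.0

    def test_no_sleep_is_absent(self, hyp):
        assert first_sleep_latency(hyp(["AW*1440"])) is None

    def test_rem_latency_subtraction(self, hyp):
        # first sleep at 10.0 min (epoch 20), first R at 14.5 min (epoch 29)
        h = hyp(["AW*20", "N1*9", "R*2", "AW*100"])
        assert rem_latency(h) == 4.5

    def test_rem_latency_absent_without_rem(self, hyp):
        assert rem_latency(hyp(["AW*10", "N1*10"])) is None

    def test_first_epoch_rem(self, hyp):
        assert rem_latency(hyp(["R", "AW*10"])) == 0.0


class TestSoremp:
    def test_no_rem_no_soremp(self, hyp):
        assert count_soremp(hyp(["AW*100", "N1*40", "AW*100"])) == 0

    def test_rem_soon_after_onset_counts(self, hyp):
        # onset at 50 min, first R 4.5 min later
        h = hyp(["AW*100", "N1*9", "R*4", "N2*20", "AW*200"])
        assert count_soremp(h) == 1

    def test_rem_outside_window_does_not_count(self, hyp):
        # first R 16 min after onset
        h = hyp(["AW*100", "N1*32", "R*4", "AW*200"])
        assert count_soremp(h) == 0

    def test_brief_wake_does_not_reset_onset(self, hyp):
        # 5-min wake gap keeps one episode: R at 16 min from true onset
        h = hyp(["AW*100", "N1*20", "AW*10", "N1*2", "R*4", "AW*200"])
        assert count_soremp(h) == 0
        # a >=10-min gap starts a new episode whose R is sleep-onset
        h2 = hyp(["AW*100", "N1*20", "AW*20", "N1*2", "R*4", "AW*200"])
        assert count_soremp(h2) == 1

    def test_monotone_in_window(self, hyp):
        rng = np.random.default_rng(11)
        tokens = list(rng.choice(["AW", "QW", "N1", "N2", "R"], size=1440,
                                 p=[0.4, 0.2, 0.2, 0.15, 0.05]))
        h = hyp(tokens)
        counts = [count_soremp(h, window_min=w) for w in (5, 10, 15, 20)]
        assert counts == sorted(counts)

    def test_cumulative_sleep_mode_never_exceeds_elapsed(self, hyp):
        rng = np.random.default_rng(12)
        tokens = list(rng.choice(["AW", "N1", "N2", "R"], size=1440,
                                 p=[0.5, 0.25, 0.2, 0.05]))
        h = hyp(tokens)
        assert count_soremp(h, use_cumulative_sleep=True) >= count_soremp(h)


class TestStagePercentages:
    def test_all_active_wake(self, hyp):
        pct = stage_percentages(hyp(["AW*100"]))
        assert pct[Stage.AW] == 100.0
        assert sum(pct.values()) == 100.0

    def test_hand_fraction(self, hyp):
        h = hyp(["N1*72", "AW*648"])
        assert stage_percentages(h)[Stage.N1] == pytest.approx(10.0)

    def test_sums_to_100_on_random_input(self, hyp):
        rng = np.random.default_rng(5)
        tokens = list(rng.choice(["AW", "QW", "N1", "N2", "N3", "R"], size=999))
        assert sum(stage_percentages(hyp(tokens)).values()) == pytest.approx(
            100.0, abs=0.1)


class TestWaso:
    def test_sleep_period_convention(self, hyp):
        # SL 13.5 min (epoch 27), then a sleep/wake mixture
        h = hyp(["AW*27", "N2*1046", "QW*367"], start="19:00", kind="nighttime")
        spt = 720.0 - 13.5
        assert waso(h) == pytest.approx(spt - 523.0)

    def test_zero_when_sleep_until_end(self, hyp):
        h = hyp(["AW*20", "N2*1420"], start="19:00", kind="nighttime")
        assert waso(h) == 0.0

    def test_sleep_only_final_epoch(self, hyp):
        h = hyp(["AW*1439", "N1"], start="19:00", kind="nighttime")
        assert waso(h) == 0.0

    def test_undefined_without_sleep(self, hyp):
        with pytest.raises(HypnogramError):
            waso(hyp(["AW*1440"], start="19:00", kind="nighttime"))


class TestActiveWakeBouts:
    def test_quiet_wake_terminates_run(self, hyp):
        h = hyp(["AW*20", "QW", "AW*10"])
        assert continuous_active_wake_bouts(h) == [10.0, 5.0]

    def test_no_active_wake(self, hyp):
        assert continuous_active_wake_bouts(hyp(["QW*10"])) == []

    def test_all_day_single_bout(self, hyp):
        assert continuous_active_wake_bouts(hyp(["AW*1440"])) == [720.0]


class TestSleepCycles:
    def test_no_rem_no_cycles(self, hyp):
        h = hyp(["N2*1440"], start="19:00", kind="nighttime")
        assert sleep_cycle_count(h) == 0

    def test_single_block_then_rem(self, hyp):
        h = hyp(["N2*120", "R*20", "AW*1300"], start="19:00", kind="nighttime")
        assert sleep_cycle_count(h) == 1

    def test_alternating_nrem_rem(self, hyp):
        h = hyp(["N2*60", "R*10"] * 4 + ["AW*1160"], start="19:00",
                kind="nighttime")
        assert sleep_cycle_count(h) == 4

    def test_insufficient_nrem_accumulation(self, hyp):
        # only 5 min of NREM before REM: below the 10-min default
        h = hyp(["N2*10", "R*10", "AW*1420"], start="19:00", kind="nighttime")
        assert sleep_cycle_count(h) == 0


class TestCohortTable:
    def test_table_shape_and_rem_presence_pct(self, hyp):
        rng = np.random.default_rng(9)
        rows = []
        for _ in range(6):
            tokens = list(rng.choice(["AW", "QW", "N1", "N2"], size=1440))
            rows.append(compute_sleep_metrics(hyp(tokens)))
        t = cohort_table(rows)
        assert set(["SL (min)", "TST (min)", "# SOREMP/day"]) <= set(t["metric"])
        rem_row = t[t["metric"] == "REM latency (min)"].iloc[0]
        assert rem_row["pct_recordings_present"] == 0.0

    def test_mixed_kinds_rejected(self, hyp):
        day = compute_sleep_metrics(hyp(["AW*1440"]))
        night = compute_sleep_metrics(
            hyp(["AW*720", "N1*720"], start="19:00", kind="nighttime"))
        with pytest.raises(ValueError):
            cohort_table([day, night])
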
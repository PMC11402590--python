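import numpy as np
import pytest

from wriststep.daily import (
    MinuteSeries,
    detect_nonwear,
    impute_nonwear,
    median_daily_steps,
    peak_1min_cadence,
    qc_checks,
    steps_per_minute,
    summarize_recording,
)
from wriststep.detector import StepEvents
from wriststep.signal_io import AccelRecording
from wriststep.synthetic import GaitProfile, simulate_participant


def series(counts, worn=None):
    counts = np.asarray(counts, dtype=float)
    worn = np.ones_like(counts, bool) if worn is None else np.asarray(worn, bool)
    return MinuteSeries(counts=counts, worn=worn)


def day_grid_counts(**minute_values):
    counts = np.zeros((1, 1440))
    for k, v in minute_values.items():
        counts[0, int(k)] = v
    return counts


class TestStepsPerMinute:
    def test_empty_steps_give_all_zero(self):
        out = steps_per_minute(StepEvents(np.empty(0)), 0.0, 1)
        assert out.sum() == 0

    def test_half_open_minute_binning(self):
        steps = StepEvents(np.array([60.1, 60.5, 119.9]))
        out = steps_per_minute(steps, 0.0, 1)
        assert out[0, 1] == 3
        assert out.sum() == 3

    def test_total_count_conserved(self, rng):
        times = np.sort(rng.uniform(0, 86400 * 2, 500))
        times = np.unique(times)
        out = steps_per_minute(StepEvents(times), 0.0, 2)
        assert out.sum() == times.size


class TestDetectNonwear:
    def _recording(self, blocks, rate=15.0):
        """blocks: list of (minutes, per-axis noise sd)."""
        rng = np.random.default_rng(0)
        parts = [
            rng.normal(0, sd, (int(m * 60 * rate), 3)) + [0, 0, 1]
            for m, sd in blocks
        ]
        return AccelRecording(np.vstack(parts), rate)

    def test_two_hours_constant_all_nonwear(self):
        rec = self._recording([(120, 0.0)])
        worn = detect_nonwear(rec, 0.0, 1)
        assert not worn[0, :120].any()

    def test_gait_is_worn(self):
        rec = simulate_participant(
            [("walk", GaitProfile(), 600.0)], 25.0, seed=1
        ).recording
        worn = detect_nonwear(rec, 0.0, 1)
        assert worn[0, :10].all()

    def test_thirty_minute_stationary_block_stays_worn(self):
        rec = self._recording([(30, 0.0), (60, 0.05)])
        worn = detect_nonwear(rec, 0.0, 1)
        assert worn[0, :90].all()


class TestImputation:
    def test_no_nonwear_is_identity(self, rng):
        s = series(rng.integers(0, 50, (3, 1440)))
        out = impute_nonwear(s)
        np.testing.assert_array_equal(out.counts, s.counts)
        assert not out.imputed.any()

    def test_mean_of_same_minute_on_other_days(self):
        counts = np.zeros((3, 1440))
        counts[0, 600] = 30
        counts[2, 600] = 50
        worn = np.ones((3, 1440), bool)
        worn[1, 600] = False
        out = impute_nonwear(MinuteSeries(counts=counts, worn=worn))
        assert out.counts[1, 600] == pytest.approx(40.0)
        assert out.imputed[1, 600]

    def test_worn_slots_never_altered(self, rng):
        counts = rng.integers(0, 40, (4, 1440)).astype(float)
        worn = rng.random((4, 1440)) > 0.2
        out = impute_nonwear(MinuteSeries(counts=counts * worn, worn=worn))
        np.testing.assert_array_equal(out.counts[worn], (counts * worn)[worn])

    def test_minute_worn_nowhere_imputes_zero_with_warning(self):
        counts = np.zeros((2, 1440))
        worn = np.ones((2, 1440), bool)
        worn[:, 100] = False
        with pytest.warns(UserWarning):
            out = impute_nonwear(MinuteSeries(counts=counts, worn=worn))
        assert out.counts[:, 100].sum() == 0

    def test_imputed_total_never_below_observed(self, rng):
        counts = rng.integers(0, 30, (3, 1440)).astype(float)
        worn = rng.random((3, 1440)) > 0.1
        s = MinuteSeries(counts=counts * worn, worn=worn)
        out = impute_nonwear(s)
        assert out.counts.sum() >= s.counts.sum()


class TestSummaries:
    @pytest.mark.parametrize(
        "totals,expected",
        [([8000, 9000, 10000], 9000), ([8000, 10000], 9000), ([7000] * 3, 7000)],
    )
    def test_median_daily_steps(self, totals, expected):
        counts = np.zeros((len(totals), 1440))
        counts[:, 0] = totals
        assert median_daily_steps(series(counts)) == expected

    def test_peak_cadence_mean_of_daily_maxima(self):
        counts = np.zeros((2, 1440))
        counts[0, 700] = 110
        counts[0, 10] = 40  # below the daily max: must not matter
        counts[1, 300] = 120
        assert peak_1min_cadence(series(counts)) == pytest.approx(115.0)

    def test_peak_cadence_single_day(self):
        counts = day_grid_counts(**{"100": 95})
        assert peak_1min_cadence(series(counts)) == 95


class TestQC:
    def test_typical_cohort_values_pass(self):
        flags = qc_checks(80.0, np.ones(24, bool), 27.5)
        assert not any(flags.values())

    @pytest.mark.parametrize(
        "wear,accel,flag",
        [
            (71.9, 28.0, "insufficient_wear"),
            (80.0, 150.0, "implausible_acceleration"),
        ],
    )
    def test_boundary_violations_flagged(self, wear, accel, flag):
        flags = qc_checks(wear, np.ones(24, bool), accel)
        assert flags[flag]

    def test_strict_boundaries_pass_exactly(self):
        flags = qc_checks(72.0, np.ones(24, bool), 100.0)
        assert not flags["insufficient_wear"]
        assert not flags["implausible_acceleration"]

    def test_diurnal_gap(self):
        cov = np.ones(24, bool)
        cov[3] = False
        assert qc_checks(80.0, cov, 28.0)["diurnal_gap"]


class TestSummarizeRecording:
    def test_three_day_pipeline_with_nonwear(self):
        plan = []
        for day in range(3):
            plan.append(("sedentary", None, 6 * 3600.0))
            plan.append(("walk", GaitProfile(cadence_spm=100, cadence_jitter=0.0), 600.0))
            if day == 1:
                plan.append(("nonwear", None, 2 * 3600.0))
                plan.append(("sedentary", None, 15 * 3600.0 + 2400.0))
            else:
                plan.append(("sedentary", None, 17 * 3600.0 + 2400.0))
        rec = simulate_participant(plan, 15.0, seed=9)
        summary, minutes = summarize_recording(
            rec.recording, rec.truth_steps, include_partial_days=True
        )
        assert minutes.n_days == 3
        assert minutes.imputed.sum() >= 120  # the off-wrist afternoon
        # 3 days minus the 2-h off-wrist gap = 70 h worn, below the 72-h bar
        assert summary.qc_flags["insufficient_wear"]
        assert summary.median_daily_steps > 900  # ~1000 steps walked per day
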
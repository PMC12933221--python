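from datetime import datetime, timedelta, timezone

import pandas as pd
import pytest

from hrmsqc import (
    HistoryStore,
    PeakMeasurement,
    QCConfig,
    evaluate_run,
    rolling_median,
    summarize_verdicts,
    update_history,
)

T0 = datetime(2024, 6, 1, tzinfo=timezone.utc)


def _seed_history(
    history, compound_id, values, field="height", sample_type="sample", start=None
):
    start = start or (T0 - timedelta(days=30))
    for i, v in enumerate(values):
        history.add_record(
            run_id=f"h{i}",
            at=start + timedelta(hours=i),
            sample_type=sample_type,
            compound_id=compound_id,
            height=v if field == "height" else 1e5,
            apex_rt=v if field == "rt" else 300.0,
            mass_error=0.0,
            qc_pass=True,
            n_detected=8,
        )


def _measurement(cid, height=100.0, apex_rt=300.0, mass_error=0.0, detected=True):
    return PeakMeasurement(
        cid, detected=detected, height=height, apex_rt=apex_rt, mass_error=mass_error
    )


class TestRollingMedian:
    def test_median_of_heights(self):
        h = HistoryStore()
        _seed_history(h, "x", [80.0, 100.0, 120.0, 90.0, 110.0])
        assert rolling_median(h, "x", T0, "height") == pytest.approx(100.0)

    def test_below_minimum_history_returns_none(self):
        h = HistoryStore()
        _seed_history(h, "x", [80.0, 100.0, 120.0])
        assert rolling_median(h, "x", T0, "height", min_records=5) is None

    def test_window_is_half_open_sixty_days(self):
        h = HistoryStore()
        exactly = T0 - timedelta(days=60)
        _seed_history(h, "x", [999.0], start=exactly)  # exactly 60 d old: excluded
        _seed_history(h, "x", [100.0] * 5, start=T0 - timedelta(days=10))
        assert rolling_median(h, "x", T0, "height") == pytest.approx(100.0)

    def test_blank_heights_excluded_but_rts_pooled(self):
        h = HistoryStore()
        _seed_history(h, "x", [100.0] * 5)
        _seed_history(h, "x", [9999.0] * 5, sample_type="blank")
        assert rolling_median(h, "x", T0, "height") == pytest.approx(100.0)
        # rt pool sees both sample and blank records (all at 300 s here)
        _seed_history(h, "x", [320.0] * 10, field="rt", sample_type="blank")
        assert rolling_median(h, "x", T0, "rt") == pytest.approx(310.0)


@pytest.fixture()
def seeded():
    """History with stable medians: height 100, rt 300, for compounds a/b."""
    h = HistoryStore()
    for cid in ("a", "b"):
        _seed_history(h, cid, [100.0] * 10)
    return h


class TestEvaluateRun:
    def test_all_nominal_passes(self, seeded, cfg):
        ms = [_measurement("a"), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0)
        assert v.passed and v.category == "pass" and not v.reasons

    def test_low_intensity_flags_height_category(self, seeded, cfg):
        ms = [_measurement("a", height=40.0), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0)
        assert not v.passed
        assert v.category == "height"
        assert v.records["a"].normalised_intensity == pytest.approx(0.4)

    def test_two_limit_reasons_categorise_multiple(self, seeded, cfg):
        ms = [_measurement("a", apex_rt=311.0, mass_error=12.0), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0)
        assert v.category == "multiple"
        assert v.reasons == {"retention_time", "mass_error"}

    def test_missing_standard_takes_precedence(self, seeded, cfg):
        ms = [_measurement("a", detected=False), _measurement("b", height=1000.0)]
        v = evaluate_run(ms, seeded, cfg, T0)
        assert v.category == "missing_is"
        assert {"missing_is", "height"} <= v.reasons

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"height": 50.0},      # normalised intensity exactly 0.5
            {"height": 200.0},     # exactly 2.0
            {"apex_rt": 310.0},    # rt deviation exactly +10 s
            {"apex_rt": 290.0},    # exactly -10 s
            {"mass_error": 10.0},  # exactly +10 ppm
            {"mass_error": -10.0},
        ],
    )
    def test_limits_are_inclusive_bounds_of_acceptable_region(self, seeded, cfg, kwargs):
        ms = [_measurement("a", **kwargs), _measurement("b")]
        assert evaluate_run(ms, seeded, cfg, T0).passed

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            ({"height": 49.0}, "height"),
            ({"height": 201.0}, "height"),
            ({"apex_rt": 310.5}, "retention_time"),
            ({"mass_error": 10.5}, "mass_error"),
        ],
    )
    def test_just_beyond_limits_flags(self, seeded, cfg, kwargs, reason):
        ms = [_measurement("a", **kwargs), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0)
        assert v.category == reason

    def test_thin_history_skips_checks_instead_of_guessing(self, cfg):
        h = HistoryStore()
        _seed_history(h, "a", [100.0, 100.0])  # 2 records < min_history
        ms = [_measurement("a", height=1.0, apex_rt=500.0)]
        v = evaluate_run(ms, h, cfg, T0)
        assert v.passed
        assert {"height:a", "retention_time:a"} <= v.skipped_checks

    def test_blank_runs_skip_the_intensity_check(self, seeded, cfg):
        ms = [_measurement("a", height=1.0), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0, sample_type="blank")
        assert v.passed

    def test_deterministic(self, seeded, cfg):
        ms = [_measurement("a", apex_rt=311.0), _measurement("b")]
        assert evaluate_run(ms, seeded, cfg, T0) == evaluate_run(ms, seeded, cfg, T0)


class TestUpdateHistory:
    def test_detected_standards_appended(self, seeded, cfg):
        ms = [_measurement("a"), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0, run_id="r1")
        n0 = len(seeded)
        update_history(seeded, v, ms)
        assert len(seeded) == n0 + 2

    def test_blank_contributes_rt_but_no_height(self, cfg):
        h = HistoryStore()
        ms = [_measurement("a")]
        v = evaluate_run(ms, h, cfg, T0, run_id="b1", sample_type="blank")
        update_history(h, v, ms)
        rec = h.frame().iloc[-1]
        assert rec["apex_rt"] == 300.0 and pd.isna(rec["height"])

    def test_failing_run_recorded_with_qc_fail_flag(self, seeded, cfg):
        ms = [_measurement("a", height=1000.0), _measurement("b")]
        v = evaluate_run(ms, seeded, cfg, T0, run_id="bad")
        update_history(seeded, v, ms)
        assert not seeded.frame().iloc[-1]["qc_pass"]


class TestCounting:
    def test_reason_counts_satisfy_the_overlap_identity(self, seeded, cfg):
        runs = [
            [_measurement("a"), _measurement("b")],                       # pass
            [_measurement("a", height=40.0), _measurement("b")],          # height
            [_measurement("a", height=300.0), _measurement("b")],         # height
            [_measurement("a", apex_rt=315.0), _measurement("b")],        # rt
            [_measurement("a", mass_error=11.0), _measurement("b")],      # mass
            [_measurement("a", height=40.0, apex_rt=315.0), _measurement("b")],  # multiple
            [_measurement("a", detected=False), _measurement("b")],       # missing
        ]
        verdicts = [evaluate_run(ms, seeded, cfg, T0, run_id=str(i))
                    for i, ms in enumerate(runs)]
        c = summarize_verdicts(verdicts)
        assert c["total"] == 7 and c["flagged"] == 6 and c["missing_is"] == 1
        assert (c["height"], c["retention_time"], c["mass_error"]) == (3, 2, 1)
        assert c["multiple"] == 1
        # flagged minus missing = sum of per-reason counts minus overlap
        assert c["flagged"] - c["missing_is"] == (
            c["height"] + c["retention_time"] + c["mass_error"] - c["overlap"]
        )
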
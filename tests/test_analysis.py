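import numpy as np
import pandas as pd
import pytest

from morphsense import (
    AnalysisSettings,
    FitResult,
    ObserverSpec,
    PsychometricParams,
    ScheduleSpec,
    analyze_participant,
    analyze_study,
    bin_trials,
    fit_pf,
    generate_schedule,
    group_curve,
    make_synthetic_study,
    paired_threshold_test,
    predict_percent_correct,
    preset_config,
    simulate_observer,
    tailored_levels,
)
from morphsense.io import records_to_frame


def _two_condition_participant(thr_happy, thr_fear, seed, repeats=40, offsets=None):
    """Simulate one participant measured in happy and fear conditions."""
    records = []
    rng = np.random.default_rng(seed)
    for label, thr in (("happy", thr_happy), ("fear", thr_fear)):
        params = PsychometricParams(alpha=100.0 - thr, beta=0.3)
        obs = ObserverSpec(params={label: params}, face_offsets=offsets or {})
        spec = ScheduleSpec(
            dilution_levels=tailored_levels((thr_happy + thr_fear) / 2),
            repeats_per_face=repeats,
            condition_label=label,
        )
        sched = generate_schedule(spec, seed=int(rng.integers(2**31)))
        records.extend(
            simulate_observer(
                sched, obs, seed=int(rng.integers(2**31)), condition=label
            )
        )
    return records


class TestBinning:
    def test_exp1_condition_binning(self):
        records = _two_condition_participant(92.0, 86.0, seed=1)
        binned = bin_trials(records, by=["condition"])
        for (_,), data in binned.items():
            assert data.dilution_pct.size == 7
            assert np.all(data.n_trials == 240)

    def test_face_binning(self):
        records = _two_condition_participant(92.0, 86.0, seed=2)
        binned = bin_trials(records, by=["condition", "face_id"])
        assert len(binned) == 12
        assert all(d.total_trials == 280 for d in binned.values())

    def test_conservation(self):
        records = _two_condition_participant(92.0, 86.0, seed=3)
        binned = bin_trials(records, by=["participant_id", "condition", "face_id"])
        assert sum(d.total_trials for d in binned.values()) == len(records)

    def test_empty_input(self):
        assert bin_trials(pd.DataFrame(columns=["participant_id"])) == {}


class TestAnalyzeParticipant:
    def test_recovery_and_detection(self):
        """Thresholds 92/86 are recovered within 2 dilution points and the
        individual-level comparison flags the difference."""
        detected = 0
        n_runs = 6
        for seed in range(n_runs):
            records = _two_condition_participant(92.0, 86.0, seed=100 + seed)
            rep = analyze_participant(
                records, AnalysisSettings(n_sims=300, seed=seed)
            )
            assert rep.thresholds["happy"] == pytest.approx(92.0, abs=2.0)
            assert rep.thresholds["fear"] == pytest.approx(86.0, abs=2.0)
            detected += rep.comparison.p_value < 0.05
        assert detected >= n_runs - 1

    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        n_runs = 12
        for seed in range(n_runs):
            records = _two_condition_participant(89.0, 89.0, seed=300 + seed)
            rep = analyze_participant(
                records, AnalysisSettings(n_sims=200, seed=seed)
            )
            rejections += rep.comparison.p_value < 0.05
        assert rejections <= 3  # ~5% nominal; generous binomial bound on 12 runs

    def test_unfittable_face_flagged(self):
        """A face far less discriminable than the rest never reaches 75%
        at the offered levels: flagged per face, others still reported."""
        offsets = {"FF1": 6.0, "FF2": -30.0, "FF3": 6.0, "MF1": 6.0, "MF2": 6.0, "MF3": 6.0}
        records = _two_condition_participant(90.0, 88.0, seed=7, offsets=offsets)
        rep = analyze_participant(
            records, AnalysisSettings(n_sims=100, seed=1, per_face=True)
        )
        assert any(key.startswith("happy/FF2") for key in rep.unfittable)
        assert ("happy", "FF1") in rep.face_thresholds
        # pooled fits survive
        assert "happy" in rep.thresholds and "fear" in rep.thresholds

    def test_retest_comparisons_run(self):
        cfg = {
            "participants": 1,
            "sessions": 2,
            "conditions": {
                "happy": {"threshold_mean": 92.0, "threshold_sd": 0.0, "beta": 0.3},
                "fear": {"threshold_mean": 86.0, "threshold_sd": 0.0, "beta": 0.3},
            },
            "repeats_per_face": 10,
        }
        records = make_synthetic_study(cfg, seed=4)
        rep = analyze_participant(records, AnalysisSettings(n_sims=100, seed=2))
        assert set(rep.session_comparisons) == {"happy", "fear"}
        # a stable observer rarely shows a session difference
        assert all(c.p_value > 0.05 for c in rep.session_comparisons.values())

    def test_requires_two_conditions(self):
        records = _two_condition_participant(92.0, 86.0, seed=5)
        happy_only = [r for r in records if r.condition == "happy"]
        with pytest.raises(ValueError, match="2 conditions"):
            analyze_participant(happy_only)


class TestGroupCurve:
    def _fit(self, thr):
        params = PsychometricParams(alpha=100.0 - thr, beta=0.3)
        return FitResult(params=params, log_likelihood=-1.0, n_levels_used=7)

    def test_identical_participants_zero_sem(self):
        fits = {f"P{i}": self._fit(90.0) for i in range(5)}
        curve = group_curve(fits)
        assert np.allclose(curve["sem_pct"], 0.0)

    def test_single_participant_matches_direct_evaluation(self):
        fit = self._fit(88.0)
        curve = group_curve({"P1": fit})
        expected = predict_percent_correct(curve["dilution_pct"], fit.params)
        np.testing.assert_allclose(curve["mean_pct"], expected)

    def test_monotone_nonincreasing(self):
        fits = {f"P{i}": self._fit(86.0 + i) for i in range(4)}
        curve = group_curve(fits)
        assert np.all(np.diff(curve["mean_pct"]) <= 1e-9)
        assert curve["mean_pct"].between(50.0, 100.0).all()


class TestPairedTest:
    @pytest.mark.parametrize(
        "t, df, expected_r",
        [(5.06, 10, 0.85), (5.96, 8, 0.90)],
    )
    def test_effect_size_from_t(self, t, df, expected_r):
        r = np.sqrt(t * t / (t * t + df))
        assert round(r, 2) == expected_r

    def test_on_real_vectors(self):
        rng = np.random.default_rng(0)
        a = rng.normal(92, 2, size=11)
        b = a - rng.normal(6, 1, size=11)
        res = paired_threshold_test(a, b)
        assert res.df == 10
        assert res.p < 0.001
        assert res.r == pytest.approx(
            np.sqrt(res.t**2 / (res.t**2 + res.df)), abs=1e-12
        )

    def test_identical_vectors(self):
        res = paired_threshold_test([90.0, 88.0, 86.0], [90.0, 88.0, 86.0])
        assert res.t == 0.0 and res.r == 0.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            paired_threshold_test([90.0], [88.0])


class TestAnalyzeStudy:
    def test_group_recovery(self):
        """Group means recovered close to the generating 92/86 on one study."""
        records = make_synthetic_study("exp1", seed=31)
        study = analyze_study(records, AnalysisSettings(n_sims=50, seed=1))
        g = study.group
        assert g.means["happy"] == pytest.approx(92.0, abs=2.0)
        assert g.means["fear"] == pytest.approx(86.0, abs=3.0)
        assert g.paired.df == 10
        assert set(g.curve["condition"]) == {"happy", "fear"}

    def test_determinism(self):
        records = records_to_frame(make_synthetic_study("exp1", seed=8)[:3360])
        s1 = analyze_study(records, AnalysisSettings(n_sims=50, seed=9))
        s2 = analyze_study(records, AnalysisSettings(n_sims=50, seed=9))
        assert s1.summary() == s2.summary()

    def test_exclusion_bookkeeping(self):
        records = make_synthetic_study(
            dict(preset_config("exp1"), participants=4), seed=2
        )
        df = records_to_frame(records)
        # ruin one participant's fear condition: every response a coin flip
        rng = np.random.default_rng(0)
        mask = (df["participant_id"] == "P02") & (df["condition"] == "fear")
        flips = rng.integers(1, 3, size=int(mask.sum()))
        df.loc[mask, "response_interval"] = flips
        df.loc[mask, "correct"] = (
            df.loc[mask, "response_interval"] == df.loc[mask, "test_interval"]
        )
        study = analyze_study(df, AnalysisSettings(n_sims=50, seed=3))
        assert "P02" in study.group.excluded
        assert len(study.group.thresholds) + len(study.group.excluded) == 4
        skipped = [r for r in study.participants if r.participant_id == "P02"]
        assert skipped[0].comparison is None
        assert skipped[0].comparison_skipped
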
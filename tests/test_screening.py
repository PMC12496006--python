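"""Screening: sensitivity evaluation, per-person screens, cure draws, trial engine."""

import math

import numpy as np
import pytest

import lungscreensim as ls
from lungscreensim.errors import ConfigurationError, ValidationError
from lungscreensim.natural_history import HISTOLOGIES, STAGES
from lungscreensim.screening import NaturalHistories, replay_screening

from conftest import make_person


class TestSensitivity:
    def test_fitted_table_values(self, nelson_sens):
        assert ls.sensitivity(nelson_sens, "IA", "adenocarcinoma", False) == 0.410
        assert ls.sensitivity(nelson_sens, "IA", "adenocarcinoma", True) == pytest.approx(0.709)
        assert ls.sensitivity(nelson_sens, "IB", "other_nsclc", False) == pytest.approx(0.264)

    def test_zero_boost_rows_equal_exactly(self, nelson_sens):
        for h in ("squamous", "other_nsclc", "sclc"):
            for s in STAGES:
                assert ls.sensitivity(nelson_sens, s, h, True) == \
                    ls.sensitivity(nelson_sens, s, h, False)

    def test_parametric_zero_beta_is_exact(self):
        base = {(s, h): 0.3 for s in STAGES for h in HISTOLOGIES}
        sp = ls.SensitivityParams("parametric", base=base, beta={"adenocarcinoma": 0.0})
        assert sp.value("IA", "adenocarcinoma", True) == 0.3

    def test_parametric_boost_monotone_to_one(self):
        base = {("IA", "adenocarcinoma"): 0.41}
        prev = 0.41
        for bh in (0.5, 1.0, 2.0, 5.0, 20.0):
            sp = ls.SensitivityParams("parametric", base=base,
                                      beta={"adenocarcinoma": bh})
            v = sp.value("IA", "adenocarcinoma", True)
            assert v > prev
            prev = v
        assert prev == pytest.approx(1.0, abs=1e-6)

    def test_missing_entry_raises(self, nelson_sens):
        with pytest.raises(ConfigurationError):
            nelson_sens.value("IA", "carcinoid", False)

    def test_percent_validation(self):
        import pandas as pd
        bad = pd.DataFrame(dict(stage=["IA"], histology=["adenocarcinoma"],
                                baseline=[120.0], repeat=[50.0]))
        with pytest.raises(ValidationError):
            ls.SensitivityParams.from_percent_frame(bad)


def preclinical_history(person, stage="IA", histology="adenocarcinoma",
                        onset=58.0, dx_age=70.0, oc=90.0, lc=None):
    """Hand-built life history holding one preclinical cancer."""
    idx = STAGES.index(stage)
    entries = [(s, onset + 0.1 * i) for i, s in enumerate(STAGES[:idx + 1])]
    sched = ls.StageSchedule(onset, entries, (dx_age, stage))
    return ls.LifeHistory(person=person, oc_death_age=oc, schedule=sched,
                          histology=histology, lc_death_age=lc)


class TestScreenPerson:
    def test_no_cancer_no_detection(self, nelson_sens, person):
        lh = ls.LifeHistory(person=person, oc_death_age=90.0)
        protocol = ls.ScreeningProtocol()
        for r in range(4):
            assert ls.screen_person(lh, r, protocol, nelson_sens, seed=0,
                                    attended=True) is None

    def test_onset_after_screen_time_is_invisible(self, nelson_sens, person):
        lh = preclinical_history(person, onset=person.age_at_randomization + 2.0)
        protocol = ls.ScreeningProtocol()
        assert ls.screen_person(lh, 0, protocol, nelson_sens, seed=0,
                                attended=True) is None

    def test_perfect_sensitivity_detects_first_round_after_onset(self, person):
        sens = ls.SensitivityParams.constant(1.0)
        protocol = ls.ScreeningProtocol()
        lh = preclinical_history(person, onset=person.age_at_randomization + 0.5)
        hits = [ls.screen_person(lh, r, protocol, sens, seed=0, attended=True)
                for r in range(4)]
        assert hits[0] is None          # round at t=0: before onset
        assert hits[1] == "IA"          # t=1: first round after onset

    def test_repeat_screen_detection_fraction(self, nelson_sens, person):
        """Prevalent IA adenocarcinoma at repeat screens: ~70.9% detected."""
        lh = preclinical_history(person)
        protocol = ls.ScreeningProtocol()
        rng = np.random.default_rng(10)
        n = 20000
        hits = sum(
            ls.screen_person(lh, 1, protocol, nelson_sens, rng, attended=True) == "IA"
            for _ in range(n)
        )
        p = 0.709
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_not_attending_returns_none(self, nelson_sens, person):
        lh = preclinical_history(person)
        protocol = ls.ScreeningProtocol()
        assert ls.screen_person(lh, 1, protocol, nelson_sens, seed=0,
                                attended=False) is None


class TestMortalityPrevention:
    def test_certain_cure_cancels_all_deaths(self, person):
        cure = ls.CureProbs.constant(1.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            lh = preclinical_history(person, lc=75.0)
            ls.apply_mortality_prevention(lh, "IA", cure, rng)
            assert lh.lc_death_age is None and lh.prevented

    def test_zero_cure_changes_nothing(self, person):
        cure = ls.CureProbs.constant(0.0)
        lh = preclinical_history(person, lc=75.0)
        ls.apply_mortality_prevention(lh, "IA", cure, seed=1)
        assert lh.lc_death_age == 75.0 and not lh.prevented

    def test_no_scheduled_death_untouched(self, person):
        cure = ls.CureProbs.constant(1.0)
        lh = preclinical_history(person, lc=None)
        ls.apply_mortality_prevention(lh, "IA", cure, seed=2)
        assert lh.lc_death_age is None and not lh.prevented

    def test_prevented_fraction_near_cure_probability(self, person):
        d = 0.83
        cure = ls.CureProbs({s: d for s in STAGES})
        rng = np.random.default_rng(3)
        n = 20000
        prevented = 0
        for _ in range(n):
            lh = preclinical_history(person, lc=75.0)
            ls.apply_mortality_prevention(lh, "IA", cure, rng)
            prevented += lh.prevented
        assert abs(prevented / n - d) < 3 * math.sqrt(d * (1 - d) / n)


def toy_histories():
    """Three hand-built screen-arm persons with known courses.

    A: onset 0.5 y after entry, slow IA cancer, clinical dx at year 8.
       -> detectable from round 2 (t=1); detected there in IA with sens 1.
    B: IA entered before baseline, progresses to IB at t=2, dx at t=4.
       -> detected at baseline (t=0) in IA.
    C: no cancer.
    """
    age0 = np.array([60.0, 55.0, 65.0])
    n = 3
    entry = np.full((n, 6), np.nan)
    entry[0, 0] = 60.5                      # A: IA from t=0.5
    entry[1, 0] = 54.0                      # B: IA from t=-1
    entry[1, 1] = 57.0                      # B: IB from t=2
    dx_age = np.array([68.0, 59.0, np.inf])
    dx_stage = np.array([0, 1, -1])
    return NaturalHistories(
        age0=age0,
        sex=np.zeros(n, dtype=int),
        screen_arm=np.ones(n, dtype=bool),
        oc_age=np.array([90.0, 90.0, 90.0]),
        onset=np.array([60.5, 54.0, np.nan]),
        hist=np.array([0, 0, -1]),
        u_soj=np.zeros((n, 6)), u_det=np.zeros((n, 6)),
        u_cure_frac=np.ones(n), e_surv=np.ones(n),
        u_screen=np.zeros((n, 4)), u_cure_screen=np.ones(n),
        attendance=np.ones((n, 4), dtype=bool),
        entry=entry, dx_age=dx_age, dx_stage=dx_stage,
        lc_death=np.array([70.5, 62.0, np.nan]),
    )


class TestReplayToyCohort:
    def test_hand_enumerated_detections(self):
        nh = toy_histories()
        protocol = ls.ScreeningProtocol()
        result = replay_screening(nh, protocol, ls.SensitivityParams.constant(1.0),
                                  ls.CureProbs.constant(0.0))
        # B detected at round 1 in IA; A at round 2 in IA; C never.
        assert result.screen_detected.sum() == 2
        assert result.screen_detected[0, 0, 0] == 1  # round 1, IA, adeno (B)
        assert result.screen_detected[1, 0, 0] == 1  # round 2, IA, adeno (A)
        # attended screens: round 1 = 3 alive undiagnosed; afterwards only C
        assert list(result.n_attended) == [3, 2, 1, 1]
        assert result.negatives.tolist() == [2, 1, 1, 1]

    def test_person_years_match_hand_sum(self):
        nh = toy_histories()
        protocol = ls.ScreeningProtocol()
        result = replay_screening(nh, protocol, ls.SensitivityParams.constant(1.0),
                                  ls.CureProbs.constant(0.0))
        # A: detected at t=1 (age 61), LC death at 70.5 beyond follow-up (age 70) -> py = 9
        # B: detected at t=0 (age 55), LC death 62 -> py = 7
        assert result.py_after_detection[0] == pytest.approx(9.0 + 7.0)
        assert result.lc_deaths_after_detection[0] == 1  # B dies within follow-up

    def test_full_cure_cancels_deaths(self):
        nh = toy_histories()
        nh.u_cure_screen = np.zeros(3)  # force success
        protocol = ls.ScreeningProtocol()
        result = replay_screening(nh, protocol, ls.SensitivityParams.constant(1.0),
                                  ls.CureProbs.constant(1.0))
        assert result.lc_deaths_after_detection.sum() == 0
        assert result.lc_deaths_by_arm.tolist() == [0, 0]


class TestRunTrial:
    def test_zero_attendance_yields_no_screens(self, small_cohort, model_params,
                                               nelson_sens, nelson_cure):
        protocol = ls.ScreeningProtocol(
            attendance=ls.AttendanceModel((0.0, 0.0, 0.0, 0.0)))
        result = ls.run_trial(small_cohort, protocol, model_params, nelson_sens,
                              nelson_cure, seed=20)
        assert result.n_attended.sum() == 0
        assert result.screen_detected.sum() == 0

    def test_conservation_of_cancers(self, small_trial, model_params, nelson_sens,
                                     nelson_cure):
        """Every screen-arm cancer is exactly one of: screen-detected,
        clinically diagnosed within follow-up, diagnosed after follow-up,
        or latent at death."""
        nh, _, protocol = small_trial
        result, detail = replay_screening(nh, protocol, nelson_sens, nelson_cure,
                                          return_detail=True)
        arm = nh.screen_arm
        has = arm & ~np.isnan(nh.onset)
        detected = detail["detected"] & arm
        tau = nh.dx_age - nh.age0
        clin_in_fu = has & ~detected & (nh.dx_age < nh.oc_age) & (tau < protocol.followup_end)
        after_fu = has & ~detected & (nh.dx_age < nh.oc_age) & (tau >= protocol.followup_end)
        latent = has & ~detected & (nh.dx_age >= nh.oc_age)
        assert int(detected.sum()) == int(result.screen_detected.sum())
        assert int(clin_in_fu.sum()) == int(result.screened_arm_clinical.sum())
        # exact partition of screen-arm cancers
        assert int(has.sum()) == (int(detected.sum()) + int(clin_in_fu.sum())
                                  + int(after_fu.sum()) + int(latent.sum()))
        # categories are mutually exclusive by construction
        assert not np.any(detected & clin_in_fu)
        assert not np.any(clin_in_fu & after_fu)

    def test_person_years_match_brute_force(self, small_trial, nelson_sens,
                                            nelson_cure):
        """py_after_detection equals a per-person python-loop sum."""
        nh, _, protocol = small_trial
        result, detail = replay_screening(nh, protocol, nelson_sens, nelson_cure,
                                          return_detail=True)
        expected = np.zeros(len(STAGES))
        for i in np.flatnonzero(detail["detected"]):
            lc = detail["lc_final"][i]
            death = nh.oc_age[i] if np.isnan(lc) else min(lc, nh.oc_age[i])
            end = min(death, nh.age0[i] + protocol.followup_end)
            expected[detail["det_stage"][i]] += max(end - detail["det_age"][i], 0.0)
        np.testing.assert_allclose(result.py_after_detection, expected, rtol=1e-12)

    def test_stage_shift_toward_early_detection(self, small_trial):
        nh, result, protocol = small_trial
        det_by_stage = result.screen_detected.sum(axis=(0, 2)).astype(float)
        ctrl_by_stage = np.zeros(len(STAGES))
        arm = ~nh.screen_arm
        tau = nh.dx_age - nh.age0
        obs = arm & (nh.dx_age < nh.oc_age) & (tau >= 0) & (tau < protocol.followup_end)
        for i in range(len(STAGES)):
            ctrl_by_stage[i] = np.sum(obs & (nh.dx_stage == i))
        mean_stage_screen = np.average(np.arange(6), weights=det_by_stage)
        mean_stage_ctrl = np.average(np.arange(6), weights=ctrl_by_stage)
        assert mean_stage_screen < mean_stage_ctrl

    def test_overdiagnosis_bookkeeping(self, small_trial, small_cohort,
                                       model_params, nelson_cure):
        nh, result, protocol = small_trial
        assert result.overdiagnosed >= 0
        null = ls.run_trial(small_cohort, protocol, model_params,
                            ls.SensitivityParams.constant(0.0), nelson_cure,
                            seed=12, histories=nh)
        assert null.overdiagnosed == 0
        assert null.screen_detected.sum() == 0

    def test_null_sensitivity_equalizes_arm_mortality(self, small_trial,
                                                      small_cohort, model_params,
                                                      nelson_cure):
        nh, result, protocol = small_trial
        null = ls.run_trial(small_cohort, protocol, model_params,
                            ls.SensitivityParams.constant(0.0), nelson_cure,
                            seed=12, histories=nh)
        deaths = null.lc_deaths_by_arm
        n = null.n_by_arm
        from scipy.stats import chi2_contingency
        table = np.array([[deaths[0], n[0] - deaths[0]],
                          [deaths[1], n[1] - deaths[1]]])
        _, p, *_ = chi2_contingency(table)
        assert p > 0.01

    def test_seed_reproducibility(self, small_cohort, model_params, nelson_sens,
                                  nelson_cure):
        protocol = ls.ScreeningProtocol()
        a = ls.run_trial(small_cohort, protocol, model_params, nelson_sens,
                         nelson_cure, seed=33)
        b = ls.run_trial(small_cohort, protocol, model_params, nelson_sens,
                         nelson_cure, seed=33)
        assert np.array_equal(a.screen_detected, b.screen_detected)
        assert np.array_equal(a.control_incidence, b.control_incidence)


class TestAllScreenAverage:
    def _result_with_counts(self, detected, detectable):
        sd = np.zeros((4, 6, 4), dtype=int)
        dp = np.zeros((4, 6, 4), dtype=int)
        for r in range(4):
            sd[r, 0, 0] = detected[r]
            dp[r, 0, 0] = detectable[r]
        return ls.TrialResult(
            round_times=(0.0, 1.0, 3.0, 5.5), followup_end=10.0, replication=1,
            screen_detected=sd, detectable=dp,
            n_attended=np.array([1000] * 4),
            interval_cancers=np.zeros((4, 6), dtype=int),
            control_incidence=np.zeros(10, dtype=int),
            screened_arm_clinical=np.zeros(10, dtype=int),
            py_after_detection=np.zeros(6),
            lc_deaths_after_detection=np.zeros(6, dtype=int),
            lc_deaths_by_arm=np.zeros(2, dtype=int),
            n_by_arm=np.array([2000, 2000]), overdiagnosed=0,
        )

    def test_direct_ratio(self):
        result = self._result_with_counts([41, 71, 71, 71], [100, 100, 100, 100])
        avg = ls.all_screen_average_sensitivity(result)
        row = avg[(avg.stage == "IA") & (avg.histology == "adenocarcinoma")]
        assert row.all_screen_average.iloc[0] == pytest.approx(63.5)

    def test_equal_round_sensitivities_average_unchanged(self):
        result = self._result_with_counts([30, 60, 15, 45], [100, 200, 50, 150])
        avg = ls.all_screen_average_sensitivity(result)
        row = avg[(avg.stage == "IA") & (avg.histology == "adenocarcinoma")]
        assert row.all_screen_average.iloc[0] == pytest.approx(30.0)

    def test_empty_pool_reported_absent(self):
        result = self._result_with_counts([0, 0, 0, 0], [0, 0, 0, 0])
        avg = ls.all_screen_average_sensitivity(result)
        row = avg[(avg.stage == "IA") & (avg.histology == "adenocarcinoma")]
        assert np.isnan(row.all_screen_average.iloc[0])

    def test_simulated_average_between_baseline_and_repeat(self, small_trial):
        nh, result, protocol = small_trial
        avg = ls.all_screen_average_sensitivity(result)
        row = avg[(avg.stage == "IA") & (avg.histology == "adenocarcinoma")].iloc[0]
        if row.detectable >= 50:
            assert 30.0 < row.all_screen_average < 85.0
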
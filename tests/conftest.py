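import numpy as np
import pytest

import lungscreensim as ls


@pytest.fixture(scope="session")
def model_params():
    return ls.default_model_params()


@pytest.fixture(scope="session")
def nelson_sens():
    return ls.SensitivityParams.nelson_fitted()


@pytest.fixture(scope="session")
def nelson_cure():
    return ls.CureProbs.nelson_fitted()


@pytest.fixture(scope="session")
def small_cohort():
    """A 6,000-person cohort (seeded) shared across aggregate tests."""
    return ls.generate_cohort(4000, 1000, 1, seed=11)


@pytest.fixture(scope="session")
def small_trial(small_cohort, model_params, nelson_sens, nelson_cure):
    """One seeded trial run on the shared cohort, with its histories."""
    protocol = ls.ScreeningProtocol()
    nh = ls.simulate_natural_histories(small_cohort, model_params, seed=12)
    result = ls.run_trial(small_cohort, protocol, model_params, nelson_sens,
                          nelson_cure, seed=12, histories=nh)
    return nh, result, protocol


def make_person(sex="male", age=60.0, cpd=20.0, start=17.0, quit_age=None, pid=0,
                arm="screen"):
    end = age if quit_age is None else quit_age
    smoking = ls.SmokingHistory(start, ((start, end, cpd),), quit_age)
    return ls.Person(id=pid, sex=sex, birth_year=int(2003 - age), arm=arm,
                     age_at_randomization=age, smoking=smoking)


@pytest.fixture
def person():
    return make_person()


RECOVERY_FREE = [
    ls.FreeParameter("sens:IA:adenocarcinoma:baseline", (0.05, 0.95)),
    ls.FreeParameter("sens:IA:adenocarcinoma:repeat", (0.05, 0.95)),
]


@pytest.fixture(scope="session")
def recovery_setup():
    """Self-calibration world at full trial size: targets simulated at known
    parameters with 50-fold replication (shared across suites)."""
    from lungscreensim.screening import replay_screening

    cohort = ls.generate_cohort(12474, 2382, 50, seed=101)
    params = ls.default_model_params()
    protocol = ls.ScreeningProtocol()
    truth_sens = ls.SensitivityParams.nelson_fitted()
    cure = ls.CureProbs.nelson_fitted()
    nh = ls.simulate_natural_histories(cohort, params, seed=102)
    truth_result = replay_screening(nh, protocol, truth_sens, cure,
                                    replication=cohort.replication_factor)
    targets = ls.CalibrationTargets.from_trial_result(truth_result)
    return cohort, params, protocol, truth_sens, cure, nh, targets


@pytest.fixture(scope="session")
def fitted_recovery(recovery_setup):
    cohort, params, protocol, sens, cure, nh, targets = recovery_setup
    return ls.calibrate(
        cohort, protocol, params, sens, cure, RECOVERY_FREE, targets,
        settings=ls.DESettings(np_=8, generations=40, stagnation=15),
        seed=105, histories=nh,
    )
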
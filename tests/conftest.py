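import numpy as np
import pytest

import lznpk as L


@pytest.fixture(scope="session")
def default_model() -> L.PopulationModel:
    return L.PopulationModel()


@pytest.fixture(scope="session")
def synthetic_cohort() -> L.Cohort:
    """One default synthetic cohort, shared across tests (seed fixed)."""
    return L.generate_cohort(L.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(synthetic_cohort, default_model):
    """FOCE-I fit of the shared synthetic cohort."""
    cohort = synthetic_cohort.fit_subset()
    return cohort, L.foce_fit(cohort, default_model)


@pytest.fixture()
def two_patient_cohort() -> L.Cohort:
    """A tiny hand-built cohort for I/O round-trips."""
    doses = [L.DoseEvent(time=12.0 * j, amount=600.0, duration=1.0)
             for j in range(8)]
    obs = [
        L.Observation(time=71.75, concentration=4.25, kind="trough"),
        L.Observation(time=73.1, concentration=12.5, kind="peak"),
    ]
    hema = L.Hematology(baseline_plt=232.0, nadir_plt=120.0,
                        baseline_hb=99.0, nadir_hb=95.0,
                        baseline_anc=4000.0, baseline_tbil_xuln=1.0)
    p1 = L.PatientRecord(id=1, sex=L.Sex.MALE, age=55.0, weight=70.0,
                         height=172.0, scr=90.0, crcl=80.0, doses=doses,
                         observations=obs, hematology=hema,
                         outcome=L.Outcome.THROMBOCYTOPENIA,
                         event_time=9.0, censored=False)
    p2 = L.PatientRecord(id=2, sex=L.Sex.FEMALE, age=70.0, weight=55.0,
                         height=158.0, scr=120.0, crcl=35.0,
                         doses=doses[:6],
                         observations=[L.Observation(time=59.9,
                                                     concentration=7.8,
                                                     kind="trough")],
                         hematology=None, outcome=L.Outcome.NONE,
                         event_time=3.0, censored=True)
    return L.Cohort([p1, p2])


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
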
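import numpy as np
import pytest

from hematotox.cohort import (BaselineLabs, Cohort, Covariates, InfectionEvent,
                              LabSeries, OutcomeRecord, PatientRecord)


def make_baseline(anc=2.5, hb=12.0, plt=200.0, crp=1.0, ferritin=300.0, day=0):
    return BaselineLabs(
        anc=anc, anc_day=day, hemoglobin=hb, hemoglobin_day=day,
        platelets=plt, platelets_day=day, crp=crp, crp_day=day,
        ferritin=ferritin, ferritin_day=day,
    )


def make_record(patient_id="P1", anc=None, platelets=None, hemoglobin=None,
                baseline=None, infections=(), outcome=None, prbc_days=(),
                plt_tx_days=(), covariates=None, candidates=None):
    """Build a PatientRecord from (day, value) pair lists."""
    def series(pairs):
        if pairs is None:
            return None
        pairs = sorted(pairs)
        return LabSeries(tuple(d for d, _ in pairs), tuple(v for _, v in pairs))

    return PatientRecord(
        patient_id=patient_id,
        baseline=baseline or make_baseline(),
        baseline_candidates=candidates or {},
        anc_series=series(anc),
        platelet_series=series(platelets),
        hemoglobin_series=series(hemoglobin),
        prbc_transfusion_days=tuple(prbc_days),
        platelet_transfusion_days=tuple(plt_tx_days),
        infections=tuple(infections),
        outcome=outcome,
        covariates=covariates or Covariates(),
    )


def make_outcome(pfs_time=12.0, pfs_event=0, os_time=12.0, os_event=0,
                 death_cause="none", response="PR"):
    return OutcomeRecord(pfs_time=pfs_time, pfs_event=pfs_event,
                         os_time=os_time, os_event=os_event,
                         death_cause=death_cause, response=response)


def event(day, category="bacterial", grade=2, source="bloodstream"):
    return InfectionEvent(onset_day=day, category=category, source=source,
                          grade=grade)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 200-patient synthetic cohort shared across tests."""
    from hematotox.simulate import GeneratorConfig, generate_cohort
    return generate_cohort(GeneratorConfig(n_patients=200), seed=20240901)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
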
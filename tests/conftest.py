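import numpy as np
import pandas as pd
import pytest

from mthetero import load_annotation
from mthetero.calling import call_mtsnvs, records_from_frame
from mthetero.simulate import SimulationConfig, simulate_cohort, outcomes_frame
from mthetero.stats import build_feature_matrix


@pytest.fixture(scope="session")
def annotation():
    return load_annotation()


def call_cohort(cohort, annotation, **kwargs):
    """Run the caller on every simulated patient; returns calls by patient."""
    calls = {}
    for p in cohort.patients:
        calls[p.patient_id] = call_mtsnvs(
            records_from_frame(cohort.tumor_tables[p.patient_id]),
            records_from_frame(cohort.normal_tables[p.patient_id]),
            p.cellularity, annotation, **kwargs)
    return calls


@pytest.fixture(scope="session")
def small_cohort(annotation):
    """Noise-free 80-patient cohort with calls, feature matrix and outcomes."""
    config = SimulationConfig(n_patients=80, seed=5, noise_sd=0.0,
                              censoring_rate=0.1)
    cohort = simulate_cohort(config, annotation)
    calls = call_cohort(cohort, annotation)
    mcn_by_patient = {p.patient_id: p.true_mcn_tumor for p in cohort.patients}
    matrix = build_feature_matrix(calls, annotation, nuclear=cohort.nuclear,
                                  clinical=cohort.clinical,
                                  mcn_by_patient=mcn_by_patient)
    outcomes = outcomes_frame(cohort.patients)
    return cohort, calls, matrix, outcomes
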
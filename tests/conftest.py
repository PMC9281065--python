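import numpy as np
import pandas as pd
import pytest

import hemodyn as h


@pytest.fixture(scope="session")
def registry():
    return h.default_registry()


@pytest.fixture(scope="session")
def cohort400():
    """Moderate synthetic cohort under the default study conditions."""
    return h.generate_cohort(h.GeneratorConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def labels400(cohort400):
    segments = h.annotate_interventions(cohort400.interventions)
    return h.label_cohort(cohort400.patients, segments)


@pytest.fixture(scope="session")
def samples400(cohort400, labels400, registry):
    lab = labels400[labels400["group"].isin(["stable", "unstable"])]
    return h.build_sample_matrix(lab, cohort400.observations, registry)


@pytest.fixture(scope="session")
def split400(labels400):
    lab = labels400[labels400["group"].isin(["stable", "unstable"])]
    return h.split_patients(lab["patient_id"], 0.5, seed=7)


@pytest.fixture(scope="session")
def model400(samples400, split400):
    from hemodyn.features import SampleMatrix

    train_ids, _ = split400
    frame = samples400.frame
    train = frame[frame["patient_id"].astype(str).isin(train_ids)]
    return h.train_reference_model(
        SampleMatrix(train.reset_index(drop=True), samples400.registry), seed=7
    )


def make_obs(rows, pid="P1"):
    """observations frame from (time, variable, value) triples."""
    return pd.DataFrame(
        {
            "patient_id": pid,
            "time": [r[0] for r in rows],
            "variable": [r[1] for r in rows],
            "value": [r[2] for r in rows],
            "source": "test",
        }
    )


def make_interventions(rows, pid="P1"):
    """interventions frame from (time, category, agent, volume, dose)."""
    return pd.DataFrame(
        {
            "patient_id": pid,
            "time": [r[0] for r in rows],
            "category": [r[1] for r in rows],
            "agent": [r[2] for r in rows],
            "volume_cc": [r[3] for r in rows],
            "dose": [r[4] for r in rows],
        }
    )
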
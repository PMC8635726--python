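import datetime as dt

import numpy as np
import pytest

from serialcox import (
    Cohort,
    ModelConfig,
    PatientRecord,
    Report,
    SerialCoxModel,
    SurvivalOutcome,
    SynthConfig,
    generate_cohort,
    split_cohort,
)


def make_record(pid, texts, time, event, start="2014-01-01"):
    d0 = dt.date.fromisoformat(start)
    reports = tuple(
        Report(pid, d0 + dt.timedelta(days=90 * i), t) for i, t in enumerate(texts)
    )
    return PatientRecord(pid, reports, SurvivalOutcome(time=time, event=event))


@pytest.fixture
def tiny_cohort():
    """Six handwritten patients, mixed report counts and outcomes."""
    return Cohort(
        (
            make_record("a", ["t3 tumour with crm threatening"], 10.0, 1),
            make_record("b", ["no adverse findings", "stable appearance"], 60.0, 0),
            make_record("c", ["mesorectal fat infiltration seen"], 18.0, 1),
            make_record("d", ["unremarkable study"], 72.0, 0),
            make_record("e", ["t3 lesion", "t3 lesion persists", "enlarged node"], 14.0, 1),
            make_record("f", ["normal post-operative appearance"], 48.0, 0),
        ),
        name="tiny",
    )


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic cohort with the default planted hazard structure."""
    return generate_cohort(SynthConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def small_fit(small_synth):
    """A quickly trained model on the small synthetic cohort."""
    train, test = split_cohort(small_synth, 0.25, seed=11)
    config = ModelConfig(embed_dim=16, attn_dim=16, hidden_dim=16)
    results = SerialCoxModel(train, config=config).fit(seed=11, epochs=25)
    return results, train, test
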
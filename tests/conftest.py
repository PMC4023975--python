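import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hepamark as hm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (280 animals, all four platforms)."""
    study, truth = hm.generate_study(hm.default_config(seed=1))
    return study, truth


@pytest.fixture(scope="session")
def default_analysis(default_study):
    """Centered deltas and class labels for the default study."""
    study, truth = default_study
    deltas = hm.center_study(study)
    classes = hm.classify_study(study, deltas["clinical_chemistry"])
    return study, truth, deltas, classes


@pytest.fixture()
def tiny_study():
    """A hand-built two-treatment study small enough to reason about."""
    samples = [
        hm.SampleRecord("v1", "S1", "vehicle", 0.0, "mg/kg", "p.o.", 24.0),
        hm.SampleRecord("v2", "S1", "vehicle", 0.0, "mg/kg", "p.o.", 24.0),
        hm.SampleRecord("t1", "S1", "drugA", 10.0, "mg/kg", "p.o.", 24.0),
        hm.SampleRecord("t2", "S1", "drugA", 10.0, "mg/kg", "p.o.", 24.0),
    ]
    histopath = [
        hm.HistopathReport("v1"),
        hm.HistopathReport("v2"),
        hm.HistopathReport("t1", frozenset({"necrosis"})),
        hm.HistopathReport("t2", observations=("glycogen content",)),
    ]
    values = pd.DataFrame(
        {
            "v1": [16.0, 2.0, 4.0],
            "v2": [64.0, 8.0, 4.0],
            "t1": [128.0, 4.0, 16.0],
            "t2": [2.0, np.nan, 4.0],
        },
        index=pd.Index(["ALT", "AST", "Bilirubin"], name="parameter_id"),
    )
    matrix = hm.MeasurementMatrix("clinical_chemistry", "raw", values)
    return hm.Study(
        samples=tuple(samples),
        histopath=tuple(histopath),
        matrices={"clinical_chemistry": matrix},
    )
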
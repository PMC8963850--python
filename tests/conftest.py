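import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sorasig.cohort import CohortAnnotation, PatientRecord, Platform, Recist
from sorasig.normalization import ExpressionMatrix

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_annotation(n_resp: int, n_poor: int, platform=Platform.MICROARRAY) -> CohortAnnotation:
    records = [
        PatientRecord(f"R{i:02d}", Recist.PR, age=50 + i, sex="female")
        for i in range(n_resp)
    ] + [
        PatientRecord(f"P{i:02d}", Recist.PD, age=60 + i, sex="male")
        for i in range(n_poor)
    ]
    return CohortAnnotation(records, platform=platform)


def make_matrix(values, genes, samples, platform=Platform.MICROARRAY, normalized=True):
    data = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(data, platform=platform, normalized=normalized)


@pytest.fixture
def annotation_3v3():
    return make_annotation(3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
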
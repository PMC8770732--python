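import numpy as np
import pytest

from pyroclock import (
    ClockModel,
    ClockTerm,
    CpGSite,
    Direction,
    PredictionRecord,
    Sample,
    Sex,
)


@pytest.fixture
def demo_panel():
    return [
        CpGSite("ELOVL2_6", "ELOVL2", Direction.INCREASES, aliases=("ELOVL26",)),
        CpGSite("ASPA_1", "ASPA", Direction.DECREASES, aliases=("ASPA1",)),
        CpGSite("EDARADD_1", "EDARADD", Direction.DECREASES),
        CpGSite("PDE4C_1", "PDE4C", Direction.INCREASES),
    ]


@pytest.fixture
def identity_model():
    """Predicted age equals methylation at S1 — handy for exact pipelines."""
    return ClockModel(model_id="ident", intercept=0.0, terms=(ClockTerm("S1", 1.0),))


def make_sample(sample_id="s1", sex=Sex.FEMALE, age=40.0, **meth):
    return Sample(sample_id=sample_id, sex=sex, age=age, methylation=dict(meth))


def make_records(ages, preds, sexes=None, groups=None, model_id="m"):
    n = len(ages)
    sexes = sexes or [Sex.FEMALE] * n
    groups = groups or [""] * n
    return [
        PredictionRecord.build(
            sample_id=f"s{i}",
            sex=sexes[i],
            age=float(ages[i]),
            predicted_age=float(preds[i]),
            age_group=groups[i],
            model_id=model_id,
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
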
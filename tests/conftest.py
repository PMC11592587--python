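import numpy as np
import pytest

from diafib.cohort import Cohort, PatientRecord
from diafib.simulate import default_spec, simulate


def make_record(rid="r1", **overrides) -> PatientRecord:
    base = dict(
        id=rid, age=55.0, sex="female", bmi=29.0, platelets=210.0, ast=55.0,
        alt=70.0, albumin=4.3, triglycerides=160.0, hdl=47.0, glucose=130.0,
        hypertension=True, on_diabetes_meds=False, alcohol_g_per_week=20.0,
        waist=95.0, ldl=120.0, hba1c=6.8, fibrosis_stage=2,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Mid-sized default-spec cohort shared across read-only tests."""
    return simulate(default_spec(), 800, seed=20240)


@pytest.fixture(scope="session")
def large_cohort():
    """n=5000 default-spec cohort for moment-fidelity checks."""
    return simulate(default_spec(), 5000, seed=77)


def labeled_cohort(scores_pos, scores_neg, var="ast") -> Cohort:
    """Toy cohort where one variable carries the given scores and the
    fibrosis stage encodes class membership."""
    recs = []
    for i, v in enumerate(scores_pos):
        recs.append(make_record(f"p{i}", **{var: float(v)}, fibrosis_stage=3))
    for i, v in enumerate(scores_neg):
        recs.append(make_record(f"n{i}", **{var: float(v)}, fibrosis_stage=1))
    return Cohort(recs, "toy")


@pytest.fixture
def toy_cohort_factory():
    return labeled_cohort


def brute_force_auc(scores, labels) -> float:
    """Independent oracle: exhaustive pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
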
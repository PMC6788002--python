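import numpy as np
import pytest

from patsim.cohort import Cohort, Patient
from patsim.icd import CCSMapping, parse_icd_code


def make_patient(pid, age, sex, codes, labs, label=None):
    return Patient(
        id=pid,
        age=age,
        sex=sex,
        diagnoses=frozenset(parse_icd_code(c) for c in codes),
        labs=np.asarray(labs, dtype=float),
        label=label,
    )


@pytest.fixture
def mapping():
    return CCSMapping.bundled()


@pytest.fixture
def hand_pool():
    """Five hand-built labeled patients with a 2-item lab panel."""
    patients = [
        make_patient("p1", 60.0, "male", ["E109", "I251"], [1.0, 2.0], 1),
        make_patient("p2", 60.0, "male", ["E119"], [1.5, 2.5], 1),
        make_patient("p3", 30.0, "female", ["A011"], [-1.0, 0.0], 0),
        make_patient("p4", 45.0, "male", ["I251", "K219"], [0.0, 1.0], 0),
        make_patient("p5", 75.0, "female", ["E109", "N189"], [2.0, 3.0], 1),
    ]
    return Cohort(patients, ["lab_a", "lab_b"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
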
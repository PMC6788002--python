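"""Feature similarities (age, sex, labs, diagnoses) and their weighted combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patsim.cohort import Cohort
from patsim.icd import ICDCode, ccs_vector, code_similarity, parse_icd_code
from patsim.similarity import (
    PatientSimilarity,
    SimilarityWeights,
    fs_age,
    fs_d1,
    fs_d2,
    fs_lab_batch,
    fs_sex,
    lab_distance,
    normalize_labs,
    patient_similarity,
    similarity_profile,
)

from conftest import make_patient


# --- independent oracle: literal double-loop evaluation of the set formula ---
def fs_d1_oracle(X, Y):
    d = lambda a, b: 1.0 - code_similarity(a, b)
    total = 0.0
    for x in X:
        if x not in Y:
            total += sum(d(x, y) for y in Y) / len(Y)
    for y in Y:
        if y not in X:
            total += sum(d(y, x) for x in X) / len(X)
    return 1.0 - total / len(X | Y)


# a 30-code universe over 3 chapters exercising all prefix-sharing depths
UNIVERSE = [
    ICDCode(c)
    for c in (
        [f"E10{i}" for i in range(4)]
        + [f"E11{i}" for i in range(4)]
        + ["E142", "E039", "E669", "E780"]
        + [f"I25{i}" for i in range(4)]
        + ["I209", "I509", "I639", "I10"]
        + [f"K21{i}" for i in range(4)]
        + ["K739", "K769", "K2", "E1", "I", "K760"]
    )
]
assert len(set(UNIVERSE)) == 30


class TestFeatureSimilarities:
    def test_fs_age(self):
        assert fs_age(50, 50) == 1.0
        assert fs_age(30, 60) == 0.5
        assert fs_age(63, 57) == pytest.approx(57 / 63)
        assert fs_age(60, 30) == fs_age(30, 60)
        with pytest.raises(ValueError):
            fs_age(0, 10)

    def test_fs_sex(self):
        assert fs_sex("male", "male") == 1
        assert fs_sex("male", "female") == 0
        assert fs_sex("female", "female") == 1

    def test_normalize_labs_roundtrip(self):
        M = np.array([[1.0, 5.0], [2.0, 7.0], [3.0, 9.0]])
        Z, means, sds = normalize_labs(M)
        assert np.allclose(Z.mean(axis=0), 0) and np.allclose(Z.std(axis=0), 1)
        # a test value equal to the training mean maps to 0
        assert np.allclose((means - means) / sds, 0)

    def test_normalize_labs_zero_variance_named(self):
        M = np.array([[1.0, 5.0], [1.0, 7.0]])
        with pytest.raises(ValueError, match="glucose"):
            normalize_labs(M, lab_names=["glucose", "sodium"])

    def test_lab_distance(self):
        assert lab_distance([0, 0], [3, 4]) == 5.0
        assert lab_distance([1, 2], [1, 2]) == 0.0
        with pytest.raises(ValueError):
            lab_distance([1], [1, 2])

    def test_fs_lab_batch_minmax(self):
        pool = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(fs_lab_batch(np.array([0.0]), pool), [1.0, 0.5, 0.0])
        np.testing.assert_allclose(
            fs_lab_batch(np.array([0.0]), np.array([[0.0], [7.0]])), [1.0, 0.0]
        )
        # degenerate batch: all distances equal -> all ones
        np.testing.assert_allclose(
            fs_lab_batch(np.array([0.0]), np.array([[3.0], [3.0]])), [1.0, 1.0]
        )

    def test_fs_d1_examples(self):
        e109 = frozenset([parse_icd_code("E109")])
        e119 = frozenset([parse_icd_code("E119")])
        a011 = frozenset([parse_icd_code("A011")])
        assert fs_d1(e109, e109) == 1.0
        assert fs_d1(e109, e119) == pytest.approx(0.5)
        assert fs_d1(e109, a011) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            fs_d1(e109, frozenset())

    def test_fs_d2_examples(self):
        v = np.zeros(259)
        v[48] = v[49] = 1
        w = np.zeros(259)
        w[48] = w[100] = 1
        assert fs_d2(v, v) == pytest.approx(1.0)
        assert fs_d2(v, w) == pytest.approx(0.5)
        disjoint = np.zeros(259)
        disjoint[200] = 1
        assert fs_d2(v, disjoint) == 0.0
        assert fs_d2(v, np.zeros(259)) == 0.0

    def test_patient_similarity_combination(self):
        w = SimilarityWeights()
        assert patient_similarity(1, 1, 1, 1, w) == pytest.approx(1.0)
        assert patient_similarity(0.5, 0.5, 1, 1, w) == pytest.approx(0.6)
        assert patient_similarity(0, 0, 0, 0, w) == 0.0

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            SimilarityWeights(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            SimilarityWeights(-0.1, 0.5, 0.3, 0.3)


sets_st = st.sets(st.sampled_from(UNIVERSE), min_size=1, max_size=6).map(frozenset)


@settings(max_examples=200, derandomize=True)
@given(sets_st, sets_st)
def test_fs_d1_matches_double_loop_oracle(X, Y):
    assert fs_d1(X, Y) == pytest.approx(fs_d1_oracle(X, Y), abs=1e-12)
    assert fs_d1(X, Y) == pytest.approx(fs_d1(Y, X), abs=1e-12)
    assert 0.0 <= fs_d1(X, Y) <= 1.0 + 1e-12


@settings(max_examples=50, derandomize=True)
@given(sets_st, sets_st)
def test_pooled_fs_d1_path_matches_oracle(X, Y):
    """The cached-matrix batch path agrees with the literal formula."""
    pool = [make_patient("a", 50, "male", [c.text for c in Y], [0.0, 0.0], 0)]
    est = PatientSimilarity(scheme="icd").fit(
        Cohort(pool + [make_patient("b", 50, "male", ["E109"], [1.0, 1.0], 1)], ["x", "y"])
    )
    query = make_patient("q", 50, "male", [c.text for c in X], [0.0, 0.0])
    row = est._fs_diag_row(query)
    assert row[0] == pytest.approx(fs_d1_oracle(X, Y), abs=1e-12)


class TestProfile:
    def test_identical_patient_ranks_first_with_ps_one(self, hand_pool):
        query = make_patient("q", 60.0, "male", ["E109", "I251"], [1.0, 2.0])
        prof = similarity_profile(query, hand_pool, scheme="icd")
        assert prof.entries[0][0] == "p1"
        assert prof.entries[0][1] == pytest.approx(1.0)
        ps_vals = [v for _, v in prof.entries]
        assert ps_vals == sorted(ps_vals, reverse=True)
        assert all(0 <= v <= 1 for v in ps_vals)

    def test_single_patient_pool(self, hand_pool):
        pool = Cohort(hand_pool.patients[:1], hand_pool.lab_names)
        query = make_patient("q", 50.0, "female", ["E119"], [0.5, 0.5])
        prof = similarity_profile(query, pool, scheme="icd")
        assert len(prof.entries) == 1
        assert 0 <= prof.entries[0][1] <= 1

    def test_profile_matches_hand_computation(self, hand_pool, mapping):
        """Brute-force re-evaluation of every formula on the 5-patient pool."""
        query = make_patient("q", 50.0, "male", ["E109", "K219"], [0.8, 1.8])
        pool = hand_pool.patients
        labs = np.vstack([p.labs for p in pool])
        means, sds = labs.mean(axis=0), labs.std(axis=0)
        zq = (query.labs - means) / sds
        d = [np.linalg.norm(zq - (p.labs - means) / sds) for p in pool]
        lo, hi = min(d), max(d)
        fs_l = [1 - (x - lo) / (hi - lo) for x in d]
        for scheme in ("icd", "ccs"):
            expected = {}
            for p, fl in zip(pool, fs_l):
                if scheme == "icd":
                    fd = fs_d1_oracle(query.diagnoses, p.diagnoses)
                else:
                    fd = fs_d2(
                        ccs_vector(query.diagnoses, mapping),
                        ccs_vector(p.diagnoses, mapping),
                    )
                expected[p.id] = (
                    0.4 * fd
                    + 0.4 * fl
                    + 0.1 * fs_age(query.age, p.age)
                    + 0.1 * fs_sex(query.sex, p.sex)
                )
            prof = similarity_profile(query, hand_pool, scheme=scheme, mapping=mapping)
            for pid, ps in prof.entries:
                assert ps == pytest.approx(expected[pid], abs=1e-12)

    def test_tie_break_by_ascending_id(self):
        # two pool patients identical in every feature -> tied PS, id order
        twin = lambda pid: make_patient(pid, 50, "male", ["E109"], [1.0], 1)
        pool = Cohort(
            [twin("b"), twin("a"), make_patient("c", 20, "female", ["A011"], [9.0], 0)],
            ["lab"],
        )
        query = make_patient("q", 50, "male", ["E109"], [1.0])
        prof = similarity_profile(query, pool, scheme="icd")
        assert [pid for pid, _ in prof.entries[:2]] == ["a", "b"]

    def test_ps_monotone_in_each_feature(self):
        w = SimilarityWeights()
        base = patient_similarity(0.5, 0.5, 0.5, 0.5, w)
        for i in range(4):
            fs = [0.5] * 4
            fs[i] = 0.9
            assert patient_similarity(*fs, w) > base


def test_similarity_matrix_export(tmp_path, hand_pool):
    import pandas as pd

    from patsim.similarity import export_similarity_matrix

    est = PatientSimilarity(scheme="icd").fit(hand_pool)
    queries = [make_patient("q1", 50, "male", ["E109"], [1.0, 2.0])]
    out = tmp_path / "ps.csv"
    export_similarity_matrix(queries, est, out)
    df = pd.read_csv(out, index_col="query_id")
    assert list(df.columns) == [p.id for p in hand_pool]
    assert df.loc["q1"].between(0, 1).all()
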
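"""Training-subset selection, feature assembly and the three classifiers."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from patsim.cohort import Cohort
from patsim.icd import parse_icd_code
from patsim.models import (
    KNNProportionClassifier,
    ModelSpec,
    PersonalizedClassifier,
    build_feature_vectors,
    derive_seed,
    knn_predict_proba,
    personalized_predict,
    select_random,
    select_top_k,
    train_model,
)
from patsim.similarity import SimilarityProfile
from patsim.synth import SyntheticConfig, generate_cohort

from conftest import make_patient


class TestSelection:
    def test_top_k_contract(self):
        prof = SimilarityProfile(
            "q", "icd", [("a", 0.9), ("b", 0.8), ("c", 0.8), ("d", 0.1)]
        )
        assert select_top_k(prof, 4) == ["a", "b", "c", "d"]
        assert select_top_k(prof, 1) == ["a"]
        assert select_top_k(prof, 3) == ["a", "b", "c"]  # tie kept in id order
        with pytest.raises(ValueError):
            select_top_k(prof, 5)

    def test_random_reproducible_and_uniform(self):
        ids = [f"p{i}" for i in range(10)]
        assert select_random(ids, 4, seed=11) == select_random(ids, 4, seed=11)
        assert sorted(select_random(ids, 10, seed=3)) == sorted(ids)
        counts = {i: 0 for i in ids}
        for rep in range(2000):
            counts[select_random(ids, 1, seed=derive_seed(0, rep))[0]] += 1
        freqs = np.array(list(counts.values())) / 2000
        assert np.all(np.abs(freqs - 0.1) < 0.03)


class TestFeatureVectors:
    def test_column_layout_against_hand_built(self):
        screened = [parse_icd_code("I251"), parse_icd_code("E780")]
        p = make_patient("a", 61.0, "male", ["I251", "N189"], [10.0, 20.0], 1)
        X, y = build_feature_vectors(
            [p], screened, np.array([8.0, 18.0]), np.array([2.0, 4.0])
        )
        # columns: age, male, E780, I251 (sorted), z-scored labs
        np.testing.assert_allclose(X[0], [61.0, 1.0, 0.0, 1.0, 1.0, 0.5])
        assert y.tolist() == [1]

    def test_unknown_diagnoses_and_identical_rows(self):
        screened = [parse_icd_code("I251")]
        p = make_patient("a", 40.0, "female", ["K219"], [1.0], 0)
        X, _ = build_feature_vectors(
            [p, p], screened, np.array([0.0]), np.array([1.0])
        )
        assert X[0][2] == 0.0  # unscreened diagnosis -> absent indicator
        np.testing.assert_array_equal(X[0], X[1])


class TestKNN:
    def test_neighbor_proportion_examples(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.zeros(60, dtype=int)
        y[:47] = 1  # plant 47 positives among the 50 nearest of a central query
        d = np.linalg.norm(X, axis=1)
        order = np.argsort(d)
        y_sorted = np.zeros(60, dtype=int)
        y_sorted[order[:50]] = np.array([1] * 47 + [0] * 3)
        assert knn_predict_proba(X, y_sorted, np.zeros(3), k=50) == pytest.approx(0.94)
        assert knn_predict_proba(X, np.ones(60, dtype=int), np.zeros(3), k=50) == 1.0

    def test_zero_distance_neighbor_wins(self, rng):
        X = rng.normal(size=(20, 2))
        y = (rng.random(20) < 0.5).astype(int)
        assert knn_predict_proba(X, y, X[7], k=1) == float(y[7])

    def test_matches_sklearn_oracle(self, rng):
        """Cross-check against sklearn's kNN on tie-free random instances."""
        for trial in range(5):
            X = rng.normal(size=(50, 4))
            y = (rng.random(50) < 0.5).astype(int)
            Q = rng.normal(size=(10, 4))
            ours = KNNProportionClassifier(k=7).fit(X, y).predict_proba(Q)[:, 1]
            oracle = (
                KNeighborsClassifier(n_neighbors=7).fit(X, y).predict_proba(Q)[:, 1]
            )
            np.testing.assert_allclose(ours, oracle)

    def test_matches_full_sort_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        y = (rng.random(50) < 0.4).astype(int)
        q = rng.normal(size=3)
        d = np.linalg.norm(X - q, axis=1)
        expect = y[np.argsort(d, kind="stable")[:9]].mean()
        assert knn_predict_proba(X, y, q, k=9) == pytest.approx(expect)


class TestTrainModel:
    def test_lr_separable_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        y = np.array([0, 0, 1, 1])
        clf = train_model(X, y, ModelSpec(algorithm="lr"))
        assert (clf.predict(X) == y).all()

    def test_rf_deterministic_under_seed(self, rng):
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + rng.normal(scale=0.5, size=80) > 0).astype(int)
        spec = ModelSpec(algorithm="rf", seed=42)
        p1 = train_model(X, y, spec).predict_proba(X)[:, 1]
        p2 = train_model(X, y, spec).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p1, p2)

    def test_rf_perfect_single_feature(self, rng):
        X = np.column_stack([rng.integers(0, 2, 200), rng.normal(size=200)])
        y = X[:, 0].astype(int)
        clf = train_model(X[:100], y[:100], ModelSpec(algorithm="rf", seed=0))
        from patsim.evaluation import auc

        assert auc(y[100:], clf.predict_proba(X[100:])[:, 1]) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_model(np.zeros((5, 2)), np.ones(5, dtype=int), ModelSpec())


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SyntheticConfig(n_per_class=40), seed=13)


class TestPersonalized:
    def test_probabilities_in_unit_interval(self, cohort):
        pool = Cohort(cohort.patients[:60], cohort.lab_names)
        queries = cohort.patients[60:70]
        clf = PersonalizedClassifier(algorithm="knn", k=20, scheme="ccs").fit(pool)
        probs = clf.predict_proba(queries)[:, 1]
        assert np.all((0 <= probs) & (probs <= 1))

    def test_deterministic_under_seed(self, cohort):
        pool = Cohort(cohort.patients[:60], cohort.lab_names)
        queries = cohort.patients[60:65]
        kw = dict(algorithm="rf", k=30, scheme="icd", random_state=5)
        p1 = PersonalizedClassifier(**kw).fit(pool).predict_proba(queries)
        p2 = PersonalizedClassifier(**kw).fit(pool).predict_proba(queries)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("algorithm", ["knn", "lr", "rf"])
    def test_full_pool_equals_random_selection(self, cohort, algorithm):
        """At K = pool size, personalized and random selection coincide."""
        pool = Cohort(cohort.patients[:60], cohort.lab_names)
        queries = cohort.patients[60:70]
        kw = dict(algorithm=algorithm, k=60, scheme="ccs", random_state=3)
        p_sim = (
            PersonalizedClassifier(selection="similar", **kw)
            .fit(pool)
            .predict_proba(queries)[:, 1]
        )
        p_rand = (
            PersonalizedClassifier(selection="random", **kw)
            .fit(pool)
            .predict_proba(queries)[:, 1]
        )
        np.testing.assert_array_equal(p_sim, p_rand)

    def test_label_concordant_neighborhood(self, cohort):
        """A query whose top-K all share its label scores on the correct side."""
        pool = Cohort(cohort.patients[:60], cohort.lab_names)
        dm_query = next(p for p in cohort.patients[60:] if p.label == 1)
        p = personalized_predict(
            dm_query, pool, k=10, spec=ModelSpec(algorithm="knn"), scheme="ccs"
        )
        assert p > 0.5


def test_derive_seed_stable_and_bounded():
    assert derive_seed(1, "model", "rf") == derive_seed(1, "model", "rf")
    assert derive_seed(1, "a") != derive_seed(1, "b")
    assert 0 <= derive_seed(2**20, "x") < 2**31
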
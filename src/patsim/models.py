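"""Personalized (top-K similar cohort) predictive models.

For an index patient with unknown disease status, a *personalized*
model is trained only on the K training-pool patients most similar to
the index patient, then applied to the index patient — one model per
query. The reference comparison trains on K randomly selected pool
patients instead (a *traditional* model; at K = pool size the two
coincide).

Three classifier families are supported:

* ``knn`` — k-nearest-neighbor by Euclidean distance on the feature
  vector; the predicted probability is the proportion of positive
  labels among the k (default 50) nearest training patients.
* ``lr``  — logistic regression fitted by maximum likelihood
  (unpenalized by default; an optional ridge strength stabilizes
  collinear inputs).
* ``rf``  — random forest of 100 bootstrap-aggregated trees with
  random feature selection; probability = mean of tree votes.

Model input features are, in fixed column order: age, a male indicator,
one binary presence indicator per screened diagnosis code (codes sorted
lexicographically), and the m z-scored laboratory values — so the
dimensionality is 2 + |screened diagnoses| + m.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, Patient
from .icd import CCSMapping, ICDCode
from .similarity import PatientSimilarity, SimilarityProfile, SimilarityWeights

logger = logging.getLogger(__name__)

ALGORITHMS = ("knn", "lr", "rf")


def derive_seed(master: int, *parts) -> int:
    """Stable sub-seed < 2**31 from a master seed and context tokens.

    A single master seed drives every source of randomness; sub-seeds
    for independent draws (per-query random selections, per-replicate
    model fits) are derived by hashing the context so whole sweeps are
    bit-reproducible and individual cells are independently replayable.
    """
    token = repr((int(master),) + parts).encode()
    return int.from_bytes(hashlib.sha256(token).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family and its hyperparameters."""

    algorithm: str = "rf"
    knn_k: int = 50
    rf_trees: int = 100
    ridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.knn_k < 1 or self.rf_trees < 1:
            raise ValueError("knn_k and rf_trees must be >= 1")


# ---------------------------------------------------------------------------
# subset selection


def select_top_k(profile: SimilarityProfile, k: int) -> list[str]:
    """Ids of the K most similar pool patients (profile order, ties by id)."""
    return profile.top_k_ids(k)


def select_random(pool_ids: Sequence[str], k: int, seed: int) -> list[str]:
    """Uniform sample of K pool ids without replacement, reproducible."""
    if not 1 <= k <= len(pool_ids):
        raise ValueError(f"K={k} out of range [1, {len(pool_ids)}]")
    rng = np.random.default_rng(seed)
    return [pool_ids[i] for i in rng.choice(len(pool_ids), size=k, replace=False)]


# ---------------------------------------------------------------------------
# feature construction


def build_feature_vectors(
    patients: Sequence[Patient],
    screened: Sequence[ICDCode],
    lab_means: np.ndarray,
    lab_sds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Assemble the model feature matrix for a list of patients.

    ``screened`` is the retained diagnosis feature set; it is sorted
    internally so the column order is stable across train and test. Lab
    values are z-scored with the supplied *training* statistics. A
    diagnosis outside the screened set simply contributes no indicator.

    Returns (X, y); y is None if any patient is unlabeled.
    """
    codes = sorted(set(screened), key=lambda c: c.text)
    rows = []
    for p in patients:
        diag = [1.0 if c in p.diagnoses else 0.0 for c in codes]
        labs = (np.asarray(p.labs, dtype=float) - lab_means) / lab_sds
        rows.append(np.concatenate(([p.age, 1.0 if p.sex == "male" else 0.0], diag, labs)))
    X = np.vstack(rows)
    if any(p.label is None for p in patients):
        return X, None
    return X, np.array([p.label for p in patients], dtype=int)


# ---------------------------------------------------------------------------
# classifiers


class KNNProportionClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor classifier scoring by neighbor class proportion.

    The predicted positive-class probability for a query is the fraction
    of positive labels among its ``k`` nearest training rows by
    Euclidean distance. Distance ties at the k-th rank are resolved by
    ascending training-row order (the training id order), so predictions
    are fully deterministic.
    """

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X, y) -> "KNNProportionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not 1 <= self.k <= len(X):
            raise ValueError(f"k={self.k} out of range [1, {len(X)}]")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        probs = np.empty(len(X))
        for i, q in enumerate(X):
            d = np.linalg.norm(self.X_ - q, axis=1)
            # stable sort keeps ascending training order among equal distances
            nearest = np.argsort(d, kind="stable")[: self.k]
            probs[i] = self.y_[nearest].mean()
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def knn_predict_proba(
    train_X: np.ndarray, train_y: np.ndarray, query: np.ndarray, k: int
) -> float:
    """Positive-class probability of one query under neighbor-proportion kNN."""
    clf = KNNProportionClassifier(k=k).fit(train_X, train_y)
    return float(clf.predict_proba(np.atleast_2d(query))[0, 1])


class _ConstantProbability:
    """Degenerate scorer used when a training subset is single-class."""

    def __init__(self, p: float):
        self.p = float(p)
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X) -> np.ndarray:
        n = len(np.atleast_2d(X))
        return np.column_stack([np.full(n, 1.0 - self.p), np.full(n, self.p)])


def train_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec):
    """Fit one probability-scoring classifier per :class:`ModelSpec`.

    Raises :class:`ValueError` if only one class is present (callers
    that sweep very small K handle that case themselves).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset contains a single class")
    if spec.algorithm == "knn":
        return KNNProportionClassifier(k=min(spec.knn_k, len(y))).fit(X, y)
    if spec.algorithm == "lr":
        # C = inf is plain maximum likelihood; a positive ridge adds an L2
        # penalty of strength `ridge` for collinear or separable inputs
        C = 1.0 / spec.ridge if spec.ridge > 0 else np.inf
        return LogisticRegression(C=C, max_iter=2000).fit(X, y)
    return RandomForestClassifier(
        n_estimators=spec.rf_trees, random_state=spec.seed, n_jobs=1
    ).fit(X, y)


# ---------------------------------------------------------------------------
# the personalized estimator


class PersonalizedClassifier(BaseEstimator, ClassifierMixin):
    """Disease-status classifier trained per query on its top-K similar patients.

    ``fit`` takes the labeled training pool (a :class:`Cohort`): it fits
    the patient-similarity estimator, screens diagnosis features (< 1%
    prevalence dropped, then chi-squared association with the label at
    P < 0.05), and freezes the feature-column layout.

    ``predict_proba`` then, for each query patient, ranks the pool by
    similarity, selects its top-K (or, with ``selection="random"``, a
    fresh random K-subset per query), trains a classifier of the chosen
    family on that subset and scores the query. Training rows are always
    ordered by ascending patient id and the model seed does not depend
    on the query, so at K = pool size every query sees the identical
    model and the personalized and random modes coincide exactly.

    Parameters
    ----------
    algorithm : {"knn", "lr", "rf"}
    k : int
        Training subset size K (not the kNN neighbor count).
    selection : {"similar", "random"}
    weights, scheme, mapping
        Passed to :class:`PatientSimilarity`.
    knn_k, rf_trees, ridge
        Classifier hyperparameters (kNN neighbor count is clamped to the
        subset size).
    screen_min_prevalence, screen_alpha
        Diagnosis feature screen thresholds.
    random_state : int
        Master seed; per-query selection seeds are derived from it.
    """

    def __init__(
        self,
        algorithm: str = "rf",
        k: int = 100,
        selection: str = "similar",
        weights: SimilarityWeights | None = None,
        scheme: str = "icd",
        mapping: CCSMapping | None = None,
        knn_k: int = 50,
        rf_trees: int = 100,
        ridge: float = 0.0,
        screen_min_prevalence: float = 0.01,
        screen_alpha: float = 0.05,
        feature_exclude_prefixes: Sequence[str] = (),
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.k = k
        self.selection = selection
        self.weights = weights
        self.scheme = scheme
        self.mapping = mapping
        self.knn_k = knn_k
        self.rf_trees = rf_trees
        self.ridge = ridge
        self.screen_min_prevalence = screen_min_prevalence
        self.screen_alpha = screen_alpha
        self.feature_exclude_prefixes = feature_exclude_prefixes
        self.random_state = random_state

    def fit(self, pool: Cohort, y=None) -> "PersonalizedClassifier":
        from .cohort import screen_diagnosis_features

        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.selection not in ("similar", "random"):
            raise ValueError("selection must be 'similar' or 'random'")
        pool.labels  # validates that the pool is labeled
        if not 1 <= self.k <= len(pool):
            raise ValueError(f"K={self.k} out of range [1, {len(pool)}]")
        self.similarity_ = PatientSimilarity(
            weights=self.weights, scheme=self.scheme, mapping=self.mapping
        ).fit(pool)
        self.screened_ = sorted(
            (
                c
                for c in screen_diagnosis_features(
                    pool, self.screen_min_prevalence, self.screen_alpha
                )
                if not any(
                    c.text.startswith(pre) for pre in self.feature_exclude_prefixes
                )
            ),
            key=lambda c: c.text,
        )
        self.pool_ = pool
        self.pool_by_id_ = {p.id: p for p in pool}
        self.classes_ = np.array([0, 1])
        self.n_features_ = 2 + len(self.screened_) + pool.n_labs
        self._model_cache: dict[tuple, object] = {}
        return self

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            algorithm=self.algorithm,
            knn_k=self.knn_k,
            rf_trees=self.rf_trees,
            ridge=self.ridge,
            seed=derive_seed(self.random_state, "model", self.algorithm),
        )

    def _fit_subset(self, ids: Sequence[str]):
        """Train (with caching) on the id subset, rows ordered by id."""
        key = tuple(sorted(ids))
        model = self._model_cache.get(key)
        if model is not None:
            return model
        patients = [self.pool_by_id_[i] for i in key]
        X, y = build_feature_vectors(
            patients,
            self.screened_,
            self.similarity_.lab_means_,
            self.similarity_.lab_sds_,
        )
        spec = self._spec()
        if len(np.unique(y)) < 2:
            p = float(y.mean())
            logger.info(
                "single-class training subset (n=%d); constant probability %.2f",
                len(y),
                p,
            )
            model = _ConstantProbability(p)
        else:
            spec = ModelSpec(
                algorithm=spec.algorithm,
                knn_k=min(spec.knn_k, len(y)),
                rf_trees=spec.rf_trees,
                ridge=spec.ridge,
                seed=spec.seed,
            )
            model = train_model(X, y, spec)
        self._model_cache[key] = model
        return model

    def _select_ids(self, query: Patient) -> list[str]:
        if self.selection == "similar":
            return select_top_k(self.similarity_.profile(query), self.k)
        seed = derive_seed(self.random_state, "select", query.id)
        return select_random(self.similarity_.pool_ids_, self.k, seed)

    def predict_proba(self, queries: Cohort | Sequence[Patient]) -> np.ndarray:
        check_is_fitted(self, "pool_")
        queries = list(queries)
        probs = np.empty(len(queries))
        for i, q in enumerate(queries):
            ids = self._select_ids(q)
            model = self._fit_subset(ids)
            Xq, _ = build_feature_vectors(
                [q],
                self.screened_,
                self.similarity_.lab_means_,
                self.similarity_.lab_sds_,
            )
            probs[i] = model.predict_proba(Xq)[0, 1]
        return np.column_stack([1.0 - probs, probs])

    def predict(self, queries) -> np.ndarray:
        return (self.predict_proba(queries)[:, 1] >= 0.5).astype(int)


def personalized_predict(
    query: Patient,
    pool: Cohort,
    k: int,
    spec: ModelSpec | None = None,
    weights: SimilarityWeights | None = None,
    scheme: str = "icd",
    mapping: CCSMapping | None = None,
) -> float:
    """Positive-class probability for one query from its top-K similar cohort."""
    spec = spec or ModelSpec()
    clf = PersonalizedClassifier(
        algorithm=spec.algorithm,
        k=k,
        weights=weights,
        scheme=scheme,
        mapping=mapping,
        knn_k=spec.knn_k,
        rf_trees=spec.rf_trees,
        ridge=spec.ridge,
        random_state=spec.seed,
    )
    return float(clf.fit(pool).predict_proba([query])[0, 1])
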
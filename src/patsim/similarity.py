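"""Multi-dimensional patient similarity.

A patient is a point in a heterogeneous feature space — age, sex, a
panel of m continuous laboratory values and a set of ICD-10 diagnosis
codes. Similarity is computed per feature type and combined by a convex
weighted sum into a single patient similarity PS(i, j) in [0, 1]:

    PS = w_diag * FS_D + w_lab * FS_L + w_age * FS_A + w_sex * FS_S

with default weights (0.4, 0.4, 0.1, 0.1). The four feature
similarities are:

* ``FS_A`` — ratio of the smaller age to the larger.
* ``FS_S`` — 1 if same sex else 0.
* ``FS_L`` — 1 minus the min-max-normalized Euclidean distance between
  z-scored lab vectors, with the min and max taken over the query's
  distances to the whole training pool. FS_L is therefore *relative to
  the pool*: the closest pool patient scores 1, the farthest 0.
* ``FS_D`` — diagnosis-set similarity under one of two schemes:
  ``"icd"`` (hierarchical, from pairwise nearest-common-ancestor code
  similarity) or ``"ccs"`` (cosine similarity of 259-dimensional CCS
  indicator vectors).

The :class:`PatientSimilarity` estimator fits lab standardization on a
training pool and ranks pool patients for any query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, Patient
from .icd import CCSMapping, ICDCode, ccs_vector, code_similarity

logger = logging.getLogger(__name__)

SCHEMES = ("icd", "ccs")


@dataclass(frozen=True)
class SimilarityWeights:
    """The four convex weights (w1-w4) combining feature similarities."""

    w_diag: float = 0.4
    w_lab: float = 0.4
    w_age: float = 0.1
    w_sex: float = 0.1

    def __post_init__(self) -> None:
        ws = (self.w_diag, self.w_lab, self.w_age, self.w_sex)
        if any(not 0.0 <= w <= 1.0 for w in ws):
            raise ValueError(f"weights must lie in [0, 1]: {ws}")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(ws)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_diag, self.w_lab, self.w_age, self.w_sex])


@dataclass
class SimilarityProfile:
    """Ranked similarities of one query patient against a training pool.

    ``entries`` is sorted by PS descending; ties broken by pool patient
    id ascending so top-K selection is reproducible.
    """

    query_id: str
    scheme: str
    entries: list[tuple[str, float]]

    def top_k_ids(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.entries):
            raise ValueError(f"K={k} out of range [1, {len(self.entries)}]")
        return [pid for pid, _ in self.entries[:k]]


# ---------------------------------------------------------------------------
# feature-level similarities


def fs_age(age_i: float, age_j: float) -> float:
    """Age similarity: min(age_i, age_j) / max(age_i, age_j)."""
    if age_i <= 0 or age_j <= 0:
        raise ValueError("ages must be positive")
    return min(age_i, age_j) / max(age_i, age_j)


def fs_sex(sex_i: str, sex_j: str) -> int:
    """Sex similarity: 1 if equal, 0 otherwise."""
    return int(sex_i == sex_j)


def normalize_labs(
    matrix: np.ndarray, lab_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring of a training lab matrix.

    Returns the standardized matrix and the fitted (means, sds) so test
    patients can be transformed with *training* statistics (no leakage).
    A zero-variance column raises, naming the column.
    """
    matrix = np.asarray(matrix, dtype=float)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        name = lab_names[zero[0]] if lab_names is not None else f"#{zero[0]}"
        raise ValueError(f"lab column {name} has zero variance; cannot z-score")
    return (matrix - means) / sds, means, sds


def lab_distance(labs_i: np.ndarray, labs_j: np.ndarray) -> float:
    """Euclidean distance between two (standardized) lab vectors."""
    labs_i = np.asarray(labs_i, dtype=float)
    labs_j = np.asarray(labs_j, dtype=float)
    if labs_i.shape != labs_j.shape:
        raise ValueError(f"lab vector length mismatch: {labs_i.shape} vs {labs_j.shape}")
    return float(np.linalg.norm(labs_i - labs_j))


def fs_lab_batch(query_labs: np.ndarray, pool_labs: np.ndarray) -> np.ndarray:
    """Lab similarity of one query against a whole pool.

    Distances from the query to every pool patient are min-max scaled
    over the batch, then FS_L = 1 - d'. The closest pool patient gets 1,
    the farthest 0. If all distances are equal (degenerate batch) every
    FS_L is defined as 1 and the event is logged.
    """
    pool_labs = np.atleast_2d(np.asarray(pool_labs, dtype=float))
    d = np.linalg.norm(pool_labs - np.asarray(query_labs, dtype=float), axis=1)
    lo, hi = d.min(), d.max()
    if hi == lo:
        logger.info("degenerate lab-distance batch (all equal); FS_L set to 1")
        return np.ones_like(d)
    return 1.0 - (d - lo) / (hi - lo)


def fs_d1(X: frozenset[ICDCode], Y: frozenset[ICDCode]) -> float:
    """Hierarchical diagnosis-set similarity over ICD-10 codes.

    With pairwise code distance d(x, y) = 1 - S(x, y):

        FS_D1 = 1 - (1/|X u Y|) * ( sum_{x in X\\Y} mean_{y in Y} d(x, y)
                                  + sum_{y in Y\\X} mean_{x in X} d(y, x) )

    Identical sets score 1 (both difference sums vanish); fully
    cross-chapter disjoint sets score 0.
    """
    if not X or not Y:
        raise ValueError("diagnosis sets must be non-empty")
    union = len(X | Y)
    total = 0.0
    for x in X - Y:
        total += sum(1.0 - code_similarity(x, y) for y in Y) / len(Y)
    for y in Y - X:
        total += sum(1.0 - code_similarity(y, x) for x in X) / len(X)
    return 1.0 - total / union


def fs_d2(vx: np.ndarray, vy: np.ndarray) -> float:
    """Cosine similarity between two 259-dimensional CCS 0/1 vectors.

    An all-zero vector cannot be cosine-normalized; the similarity is
    defined as 0 in that case, with a logged warning.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError("CCS vectors must have equal length")
    nx, ny = np.linalg.norm(vx), np.linalg.norm(vy)
    if nx == 0 or ny == 0:
        logger.warning("all-zero CCS vector in cosine similarity; returning 0")
        return 0.0
    return float(vx @ vy / (nx * ny))


def patient_similarity(
    fs_d: float, fs_l: float, fs_a: float, fs_s: float, w: SimilarityWeights
) -> float:
    """Weighted patient similarity PS = w1*FS_D + w2*FS_L + w3*FS_A + w4*FS_S."""
    fs = np.array([fs_d, fs_l, fs_a, fs_s], dtype=float)
    if ((fs < -1e-12) | (fs > 1 + 1e-12)).any():
        raise ValueError(f"feature similarities must lie in [0, 1]: {fs}")
    return float(w.as_array() @ fs)


# ---------------------------------------------------------------------------
# pool-level estimator


class PatientSimilarity(BaseEstimator, TransformerMixin):
    """Rank a training pool by similarity to query patients.

    Fitting stores the pool, z-scores its lab panel (training-only
    statistics) and precomputes the per-patient diagnosis representation
    for the chosen scheme. ``transform`` maps query patients to a
    (n_queries, n_pool) PS matrix; ``profile`` returns the ranked
    :class:`SimilarityProfile` for one query.

    Parameters
    ----------
    weights : SimilarityWeights
        Convex combination weights; default (0.4, 0.4, 0.1, 0.1).
    scheme : {"icd", "ccs"}
        Diagnosis similarity scheme: hierarchical code-set similarity or
        cosine over CCS category indicator vectors.
    mapping : CCSMapping, optional
        ICD-10 -> CCS crosswalk; required for the "ccs" scheme (the
        bundled fixture crosswalk is used when omitted).
    """

    def __init__(
        self,
        weights: SimilarityWeights | None = None,
        scheme: str = "icd",
        mapping: CCSMapping | None = None,
    ):
        self.weights = weights
        self.scheme = scheme
        self.mapping = mapping

    def _validated(self) -> tuple[SimilarityWeights, str]:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        return self.weights or SimilarityWeights(), self.scheme

    def fit(self, pool: Cohort | Sequence[Patient], y=None) -> "PatientSimilarity":
        weights, scheme = self._validated()
        patients = list(pool)
        if not patients:
            raise ValueError("training pool must be non-empty")
        if any(not p.diagnoses for p in patients):
            raise ValueError("every pool patient must carry >= 1 diagnosis code")
        self.pool_ = patients
        self.pool_ids_ = [p.id for p in patients]
        labs = np.vstack([p.labs for p in patients])
        if len(patients) == 1:
            # z-scoring is ill-posed on a single patient; center only
            self.lab_means_, self.lab_sds_ = labs[0].copy(), np.ones(labs.shape[1])
            self.pool_labs_ = np.zeros_like(labs)
        else:
            self.pool_labs_, self.lab_means_, self.lab_sds_ = normalize_labs(labs)
        self.pool_ages_ = np.array([p.age for p in patients], dtype=float)
        self.pool_male_ = np.array([p.sex == "male" for p in patients])
        if scheme == "ccs":
            mapping = self.mapping or CCSMapping.bundled()
            self.ccs_matrix_ = np.vstack(
                [ccs_vector(p.diagnoses, mapping) for p in patients]
            ).astype(float)
            norms = np.linalg.norm(self.ccs_matrix_, axis=1)
            self.ccs_norms_ = norms
        else:
            # cache pairwise code similarity over the observed universe so
            # FS_D1 against a large pool indexes a matrix instead of
            # recomputing NCAs
            universe = sorted(
                {c for p in patients for c in p.diagnoses}, key=lambda c: c.text
            )
            self.code_index_ = {c: i for i, c in enumerate(universe)}
            n = len(universe)
            S = np.empty((n, n))
            for i, x in enumerate(universe):
                for j, y in enumerate(universe):
                    S[i, j] = code_similarity(x, y) if j >= i else S[j, i]
            self.code_sim_ = S
            self.pool_code_idx_ = [
                np.array(sorted(self.code_index_[c] for c in p.diagnoses))
                for p in patients
            ]
        return self

    def standardize(self, labs: np.ndarray) -> np.ndarray:
        """Apply the pool's fitted lab z-scoring to raw lab values."""
        check_is_fitted(self, "lab_means_")
        return (np.asarray(labs, dtype=float) - self.lab_means_) / self.lab_sds_

    def _code_indices(self, codes: frozenset[ICDCode]) -> np.ndarray:
        """Universe indices of a query's codes, extending the cache on demand."""
        new = [c for c in codes if c not in self.code_index_]
        if new:
            universe = sorted(self.code_index_, key=lambda c: c.text)
            n_old = len(universe)
            for c in sorted(new, key=lambda c: c.text):
                self.code_index_[c] = len(universe)
                universe.append(c)
            n = len(universe)
            S = np.empty((n, n))
            S[:n_old, :n_old] = self.code_sim_
            for i in range(n_old, n):
                for j in range(n):
                    S[i, j] = S[j, i] = code_similarity(universe[i], universe[j])
            self.code_sim_ = S
        return np.array(sorted(self.code_index_[c] for c in codes))

    def _fs_diag_row(self, query: Patient) -> np.ndarray:
        """FS_D of the query against every pool patient, per scheme."""
        if self.scheme == "ccs":
            mapping = self.mapping or CCSMapping.bundled()
            vq = ccs_vector(query.diagnoses, mapping).astype(float)
            nq = np.linalg.norm(vq)
            if nq == 0:
                logger.warning(
                    "query %s has an all-zero CCS vector; FS_D2 = 0", query.id
                )
                return np.zeros(len(self.pool_))
            dots = self.ccs_matrix_ @ vq
            out = np.zeros(len(self.pool_))
            ok = self.ccs_norms_ > 0
            out[ok] = dots[ok] / (self.ccs_norms_[ok] * nq)
            return out
        if not query.diagnoses:
            raise ValueError(f"query {query.id}: empty diagnosis set")
        xi = self._code_indices(query.diagnoses)
        D = 1.0 - self.code_sim_
        x_set = set(xi.tolist())
        out = np.empty(len(self.pool_))
        for j, yi in enumerate(self.pool_code_idx_):
            y_set = set(yi.tolist())
            union = len(x_set | y_set)
            x_only = np.array(sorted(x_set - y_set), dtype=int)
            y_only = np.array(sorted(y_set - x_set), dtype=int)
            total = 0.0
            if x_only.size:
                total += D[np.ix_(x_only, yi)].mean(axis=1).sum()
            if y_only.size:
                total += D[np.ix_(y_only, xi)].mean(axis=1).sum()
            out[j] = 1.0 - total / union
        return out

    def transform(self, queries: Cohort | Sequence[Patient]) -> np.ndarray:
        """PS matrix of shape (n_queries, n_pool)."""
        check_is_fitted(self, "pool_")
        weights, _ = self._validated()
        queries = list(queries)
        q_labs = self.standardize(np.vstack([p.labs for p in queries]))
        dist = cdist(q_labs, self.pool_labs_)
        lo = dist.min(axis=1, keepdims=True)
        hi = dist.max(axis=1, keepdims=True)
        span = hi - lo
        degenerate = (span == 0).ravel()
        if degenerate.any():
            logger.info(
                "%d queries with degenerate lab-distance batches; FS_L = 1",
                int(degenerate.sum()),
            )
        span[span == 0] = 1.0
        fs_l = 1.0 - (dist - lo) / span
        fs_l[degenerate, :] = 1.0

        q_ages = np.array([p.age for p in queries], dtype=float)[:, None]
        fs_a = np.minimum(q_ages, self.pool_ages_) / np.maximum(
            q_ages, self.pool_ages_
        )
        q_male = np.array([p.sex == "male" for p in queries])[:, None]
        fs_s = (q_male == self.pool_male_).astype(float)
        fs_d = np.vstack([self._fs_diag_row(q) for q in queries])
        return (
            weights.w_diag * fs_d
            + weights.w_lab * fs_l
            + weights.w_age * fs_a
            + weights.w_sex * fs_s
        )

    def profile(self, query: Patient) -> SimilarityProfile:
        """Ranked similarity profile of one query against the pool."""
        ps = self.transform([query])[0]
        order = sorted(range(len(ps)), key=lambda i: (-ps[i], self.pool_ids_[i]))
        entries = [(self.pool_ids_[i], float(ps[i])) for i in order]
        return SimilarityProfile(query.id, self.scheme, entries)


def similarity_profile(
    query: Patient,
    pool: Cohort | Sequence[Patient],
    weights: SimilarityWeights | None = None,
    scheme: str = "icd",
    mapping: CCSMapping | None = None,
) -> SimilarityProfile:
    """One-shot ranked profile of ``query`` against ``pool`` (fits + profiles)."""
    est = PatientSimilarity(weights=weights, scheme=scheme, mapping=mapping)
    return est.fit(pool).profile(query)


def export_similarity_matrix(
    queries: Cohort | Sequence[Patient],
    estimator: PatientSimilarity,
    path: str | Path,
) -> None:
    """Write a PS matrix as delimited text: rows = query ids, cols = pool ids."""
    import pandas as pd

    ps = estimator.transform(queries)
    df = pd.DataFrame(
        ps, index=[p.id for p in queries], columns=estimator.pool_ids_
    )
    df.to_csv(path, index_label="query_id")
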
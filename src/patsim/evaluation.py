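"""Evaluation harness: hold-out split, AUC-vs-K sweeps, curve comparison.

The study design: split a labeled cohort into a class-balanced training
pool and test set; for a grid of training-subset sizes K, train each
classifier either on every test patient's top-K most-similar pool
patients (personalized) or on a randomly selected K-subset
(traditional), and score the whole test set by AUC. Personalized curves
are expected to dominate at small K and converge to the traditional
curves as K approaches the full pool. Curves are summarized by a cubic
polynomial trend and compared by a Bonferroni-adjusted two-sided
Mann-Whitney U test over the per-K AUC values.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from .cohort import Cohort, screen_diagnosis_features
from .icd import CCSMapping
from .models import (
    ALGORITHMS,
    ModelSpec,
    _ConstantProbability,
    build_feature_vectors,
    derive_seed,
    select_random,
    train_model,
)
from .similarity import PatientSimilarity, SimilarityWeights

logger = logging.getLogger(__name__)

#: ICD-10 prefixes excluded from *model features* by default when the
#: prediction target is diabetes: the E10-E14 block defines the label, so
#: using it as an input feature would be circular. The block still
#: participates fully in the similarity computation.
DM_FEATURE_EXCLUDE = ("E10", "E11", "E12", "E13", "E14")


def holdout_split(
    cohort: Cohort, train_per_class: int, seed: int
) -> tuple[Cohort, Cohort]:
    """Class-balanced random split into disjoint (training pool, test set).

    ``train_per_class`` patients of each class go to the pool; the rest
    form the test set. Reproducible under ``seed``.
    """
    y = cohort.labels
    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    for cls in (0, 1):
        ids = [p.id for p, lab in zip(cohort.patients, y) if lab == cls]
        if len(ids) < train_per_class + 1:
            raise ValueError(
                f"class {cls} has {len(ids)} patients; needs >= {train_per_class + 1}"
            )
        train_ids.update(rng.choice(ids, size=train_per_class, replace=False))
    train = cohort.subset([p.id for p in cohort.patients if p.id in train_ids])
    test = cohort.subset([p.id for p in cohort.patients if p.id not in train_ids])
    return train, test


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based area under the ROC curve (ties get midrank treatment)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes among the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def fit_trend(
    k_values: Sequence[float], aucs: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic trend of AUC against K.

    Returns (coefficients in ascending degree order, fitted values).
    Requires at least 4 distinct K values.
    """
    k = np.asarray(k_values, dtype=float)
    a = np.asarray(aucs, dtype=float)
    if len(np.unique(k)) < 4:
        raise ValueError("cubic trend fit needs >= 4 distinct K values")
    coefs = np.polynomial.polynomial.polyfit(k, a, deg=3)
    return coefs, np.polynomial.polynomial.polyval(k, coefs)


def compare_curves(
    aucs_a: Sequence[float], aucs_b: Sequence[float], n_comparisons: int = 1
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two per-K AUC samples.

    The exact null distribution is used when both samples have <= 12
    values and no ties straddle the groups; the tie-corrected normal
    approximation otherwise. The P value is Bonferroni-adjusted by
    ``n_comparisons`` and capped at 1.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired K grids required: sample sizes differ")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "asymptotic"
    stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(min(1.0, p * n_comparisons))


class _SubsetTrainer:
    """Fits classifiers on id-subsets of the pool, with caching.

    Training rows are always ordered by ascending patient id and the
    model seed is independent of which query requested the subset, so
    identical subsets yield identical models — in particular the
    personalized and random arms coincide exactly at K = pool size.
    """

    def __init__(self, X_pool, y_pool, id_to_row, algorithm, model_seed, knn_k, rf_trees, ridge):
        self.X_pool = X_pool
        self.y_pool = y_pool
        self.id_to_row = id_to_row
        self.algorithm = algorithm
        self.model_seed = model_seed
        self.knn_k = knn_k
        self.rf_trees = rf_trees
        self.ridge = ridge
        self._cache: dict[tuple, object] = {}

    def fit(self, ids: Sequence[str]):
        key = tuple(sorted(ids))
        model = self._cache.get(key)
        if model is not None:
            return model
        rows = [self.id_to_row[i] for i in key]
        X = self.X_pool[rows]
        y = self.y_pool[rows]
        if len(np.unique(y)) < 2:
            model = _ConstantProbability(float(y.mean()))
        else:
            spec = ModelSpec(
                algorithm=self.algorithm,
                knn_k=min(self.knn_k, len(y)),
                rf_trees=self.rf_trees,
                ridge=self.ridge,
                seed=self.model_seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # LBFGS on separable subsets
                model = train_model(X, y, spec)
        self._cache[key] = model
        return model


def sweep_training_size(
    pool: Cohort,
    test: Cohort,
    k_grid: Sequence[int],
    algorithms: Sequence[str] = ALGORITHMS,
    schemes: Sequence[str] = ("ccs",),
    weights: SimilarityWeights | None = None,
    mapping: CCSMapping | None = None,
    master_seed: int = 0,
    n_replicates: int = 5,
    knn_k: int = 50,
    rf_trees: int = 100,
    ridge: float = 0.0,
    exclude_prefixes: Sequence[str] = DM_FEATURE_EXCLUDE,
) -> pd.DataFrame:
    """AUC versus training-subset size, personalized vs random selection.

    For every (scheme, replicate, algorithm, K): the *similar* arm
    trains one model per test patient on that patient's top-K most
    similar pool patients; the *random* arm trains a single model on a
    fresh random K-subset (shared across algorithms within a
    replicate); both are scored by AUC over the whole test set.

    Returns a tidy DataFrame with columns
    ``algorithm, scheme, mode, K, replicate, seed, auc``.
    """
    k_grid = list(k_grid)
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("K grid must be strictly increasing")
    if k_grid[0] < 1 or k_grid[-1] > len(pool):
        raise ValueError(f"K grid must lie within [1, {len(pool)}]")
    y_test = test.labels

    screened = [
        c
        for c in screen_diagnosis_features(pool)
        if not any(c.text.startswith(p) for p in exclude_prefixes)
    ]
    screened = sorted(screened, key=lambda c: c.text)
    logger.info("screened diagnosis features retained: %d", len(screened))

    rows_out: list[dict] = []
    for scheme in schemes:
        sim = PatientSimilarity(weights=weights, scheme=scheme, mapping=mapping)
        sim.fit(pool)
        lab_means, lab_sds = sim.lab_means_, sim.lab_sds_
        X_pool, y_pool = build_feature_vectors(
            sim.pool_, screened, lab_means, lab_sds
        )
        id_to_row = {pid: i for i, pid in enumerate(sim.pool_ids_)}
        X_test, _ = build_feature_vectors(test.patients, screened, lab_means, lab_sds)

        ps = sim.transform(test)
        ids_arr = np.array(sim.pool_ids_)
        id_rank = np.argsort(ids_arr, kind="stable")
        # rank pool per query: PS descending, ties by ascending id
        top_ids: list[np.ndarray] = []
        for q in range(ps.shape[0]):
            order = id_rank[np.argsort(-ps[q, id_rank], kind="stable")]
            top_ids.append(ids_arr[order])

        for rep in range(n_replicates):
            rep_seed = derive_seed(master_seed, "rep", rep)
            random_subsets = {
                k: select_random(
                    list(ids_arr), k, derive_seed(rep_seed, "randsel", k)
                )
                for k in k_grid
            }
            for algo in algorithms:
                model_seed = derive_seed(rep_seed, "model", algo)
                trainer = _SubsetTrainer(
                    X_pool, y_pool, id_to_row, algo, model_seed, knn_k, rf_trees, ridge
                )
                for k in k_grid:
                    scores = np.empty(len(test))
                    for q in range(len(test)):
                        model = trainer.fit(top_ids[q][:k])
                        scores[q] = model.predict_proba(X_test[q : q + 1])[0, 1]
                    rows_out.append(
                        dict(
                            algorithm=algo,
                            scheme=scheme,
                            mode="similar",
                            K=k,
                            replicate=rep,
                            seed=model_seed,
                            auc=auc(y_test, scores),
                        )
                    )
                    model = trainer.fit(random_subsets[k])
                    scores = model.predict_proba(X_test)[:, 1]
                    rows_out.append(
                        dict(
                            algorithm=algo,
                            scheme=scheme,
                            mode="random",
                            K=k,
                            replicate=rep,
                            seed=derive_seed(rep_seed, "randsel", k),
                            auc=auc(y_test, scores),
                        )
                    )
    return pd.DataFrame(rows_out)


def write_sweep(df: pd.DataFrame, path: str | Path) -> None:
    """Write sweep results as tidy CSV."""
    df.to_csv(path, index=False)


def plot_sweep(df: pd.DataFrame, path: str | Path) -> None:
    """Render AUC-vs-K curves per algorithm and selection mode (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    grouped = df.groupby(["algorithm", "scheme", "mode"])
    for (algo, scheme, mode), g in grouped:
        curve = g.groupby("K")["auc"].mean()
        style = "-" if mode == "similar" else "--"
        ax.plot(curve.index, curve.values, style, label=f"{algo}/{scheme}/{mode}")
    ax.set_xlabel("training subset size K")
    ax.set_ylabel("AUC")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
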
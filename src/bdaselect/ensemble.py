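"""Bootstrap-ensemble wrapper selection and the baseline-classifier harness.

The outer loop draws ``m`` stratified bootstrap replicates of the dataset,
runs one full binary-dragonfly search per replicate against the
CV-error x feature-count objective, scores each replicate's best mask by
K-fold CV accuracy ``Sc_m``, and combines the per-replicate masks by
accuracy-weighted voting::

    SV_i = sum_m Sc_m * mask_m[i]

The final selection keeps the ``M`` top-voted features, with
``M = round(mean_m |mask_m|)`` so no extra hyperparameter is introduced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bda import optimize
from .classifier import ClassifierSpec, cv_error, stratified_folds, _standardize
from .data_io import FeatureTable, RunConfig, SelectionReport
from .objective import ObjectiveFunction

logger = logging.getLogger(__name__)

__all__ = ["bootstrap_subdatasets", "weighted_vote", "top_m",
           "select_features", "run_baselines", "BASELINE_ALGORITHMS"]

_SEED_MAX = 2**31 - 1


def _bootstrap_indices(table: FeatureTable, m: int,
                       seed: int) -> list[np.ndarray]:
    if m < 1:
        raise ValueError("m must be >= 1")
    if not table.has_both_classes():
        raise ValueError("table must contain both classes")
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(table.y == c) for c in (-1, 1)]
    return [np.sort(np.concatenate(
        [rng.choice(idx, size=len(idx), replace=True) for idx in class_idx]))
        for _ in range(m)]


def bootstrap_subdatasets(table: FeatureTable, m: int,
                          seed: int) -> list[FeatureTable]:
    """Draw ``m`` stratified bootstrap replicates of size n.

    Sampling is with replacement within each class, so every replicate
    preserves the class counts exactly (a plain bootstrap could produce
    single-class replicates when the minority class is small).
    """
    return [table.take_rows(rows)
            for rows in _bootstrap_indices(table, m, seed)]


def weighted_vote(masks: list[np.ndarray],
                  accuracies: list[float]) -> np.ndarray:
    """SV_i = sum_m Sc_m * mask_m[i]."""
    if len(masks) != len(accuracies):
        raise ValueError("masks and accuracies must have equal length")
    stack = np.asarray(masks, dtype=float)
    acc = np.asarray(accuracies, dtype=float)
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    return stack.T @ acc


def top_m(votes: np.ndarray, m: int) -> np.ndarray:
    """Mask of the ``m`` highest-voted features; ties at the cutoff go to
    the smaller feature index."""
    votes = np.asarray(votes, dtype=float)
    p = votes.size
    if not 1 <= m <= p:
        raise ValueError("m out of range")
    order = np.lexsort((np.arange(p), -votes))
    mask = np.zeros(p, dtype=np.int8)
    mask[order[:m]] = 1
    return mask


def _score_replicate(table: FeatureTable, sub: FeatureTable,
                     rows: np.ndarray, mask: np.ndarray,
                     spec: ClassifierSpec, config: RunConfig,
                     seed: int) -> float:
    """Replicate accuracy Sc_m: K-fold CV on the replicate's own
    sub-dataset (the stated procedure), or — optionally — accuracy on the
    out-of-bag rows, which avoids the in-bag optimism."""
    if config.oob_accuracy:
        oob = np.setdiff1d(np.arange(table.n_samples), rows)
        if oob.size and len(np.unique(table.y[oob])) == 2:
            cols = np.flatnonzero(mask)
            Xtr, Xte = _standardize(sub.X[:, cols], table.X[oob][:, cols])
            model = spec.make()
            model.fit(Xtr, sub.y)
            return float(np.mean(model.predict(Xte) == table.y[oob]))
        logger.warning("degenerate out-of-bag set; falling back to in-bag CV")
    return cv_error(sub, mask, spec, config.cv_folds, seed).mean_accuracy


def select_features(table: FeatureTable,
                    config: RunConfig) -> SelectionReport:
    """Run the full ensemble selector; byte-identical under a fixed seed.

    One master generator (from ``config.rng_seed``) expands into named
    sub-seeds: the bootstrap draw, then per replicate a swarm seed, an
    objective CV-fold seed, and a scoring CV-fold seed, so each stage is
    independently reproducible.  Replicate scoring uses fresh folds on the
    replicate's own sub-dataset (optionally on out-of-bag rows instead).
    """
    if not table.has_both_classes():
        raise ValueError("table must contain both classes")
    master = np.random.default_rng(config.rng_seed)
    boot_seed = int(master.integers(_SEED_MAX))
    rep_seeds = master.integers(_SEED_MAX, size=(config.n_replicates, 3))

    spec = ClassifierSpec(penalty=config.penalty, kernel=config.kernel)
    boot_rows = _bootstrap_indices(table, config.n_replicates, boot_seed)

    masks, accs, traces = [], [], []
    for rep, rows in enumerate(boot_rows):
        sub = table.take_rows(rows)
        swarm_seed, obj_seed, score_seed = (int(s) for s in rep_seeds[rep])
        objective = ObjectiveFunction(sub, spec, config.cv_folds,
                                      config.penalty_sign, obj_seed)
        result = optimize(objective, table.n_features, config,
                          rng=np.random.default_rng(swarm_seed))
        sc = _score_replicate(table, sub, rows, result.best_mask, spec,
                              config, score_seed)
        masks.append(result.best_mask)
        accs.append(sc)
        traces.append(result.trace)
        logger.debug("replicate %d: |S|=%d acc=%.3f", rep,
                     int(result.best_mask.sum()), sc)

    mean_size = float(np.mean([m.sum() for m in masks]))
    m_sel = int(np.clip(config.round_m(mean_size), 1, table.n_features))
    votes = weighted_vote(masks, accs)
    final = top_m(votes, m_sel)
    return SelectionReport(
        feature_names=list(table.feature_names),
        replicate_masks=masks,
        replicate_accuracies=accs,
        votes=votes,
        m_selected=m_sel,
        final_mask=final,
        config=config.to_dict(),
        seed=config.rng_seed,
        traces=traces,
    )


def _baseline_models(seed: int, spec: ClassifierSpec) -> dict:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, RidgeClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.tree import DecisionTreeClassifier

    # library-default hyperparameters throughout; seeded where stochastic
    return {
        "k_nearest_neighbor": KNeighborsClassifier(),
        "logistic_regression": LogisticRegression(max_iter=1000),
        "lasso_logistic": LogisticRegression(
            solver="liblinear", l1_ratio=1.0, max_iter=1000),
        "elastic_net": LogisticRegression(
            solver="saga", l1_ratio=0.5, max_iter=5000),
        "ridge": RidgeClassifier(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "svm": spec.make(),
    }


BASELINE_ALGORITHMS = tuple(_baseline_models(0, ClassifierSpec()).keys())


def run_baselines(table: FeatureTable, mask: np.ndarray | None,
                  seed: int,
                  spec: ClassifierSpec | None = None,
                  k: int = 10) -> pd.DataFrame:
    """K-fold CV accuracy of standard classifiers on the masked features.

    Uses the same stratified folds and per-fold standardization as
    :func:`bdaselect.classifier.cv_error`, so the ``svm`` row equals
    ``1 - cv_error(...).mean_error`` for the same seed.
    """
    spec = spec or ClassifierSpec()
    if mask is None:
        mask = np.ones(table.n_features, dtype=np.int8)
    cols = np.flatnonzero(np.asarray(mask))
    if cols.size == 0:
        raise ValueError("mask selects no features")
    X, y = table.X[:, cols], table.y
    folds = stratified_folds(y, k, seed)
    rows = []
    for name, model in _baseline_models(seed, spec).items():
        accs = []
        for tr, te in folds:
            Xtr, Xte = _standardize(X[tr], X[te])
            model.fit(Xtr, y[tr])
            accs.append(float(np.mean(model.predict(Xte) == y[te])))
        rows.append({"algorithm": name,
                     "mean_cv_accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
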
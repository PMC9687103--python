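"""Selection objective: cross-validated error times a feature-count factor.

For a candidate mask S over the universe O of features,

    value = mean_CV_error(S) * exp(penalty_sign * |S| / |O|)

With ``penalty_sign = +1`` (the default) larger feature sets are penalized,
matching the method's stated goal of selecting as few features as possible.
``penalty_sign = -1`` reproduces the formula exactly as printed in the
source method description, where the exponential factor instead *rewards*
larger sets; both modes are first-class and the sign used is recorded in
every report.  An empty mask is infeasible and is valued ``+inf`` so the
optimizer can never prefer it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierSpec, cv_error
from .data_io import FeatureTable

__all__ = ["ObjectiveValue", "evaluate", "ObjectiveFunction"]


@dataclass(frozen=True)
class ObjectiveValue:
    value: float
    mean_error: float
    n_selected: int
    n_total: int
    penalty_sign: int


def evaluate(table: FeatureTable, mask: np.ndarray, spec: ClassifierSpec,
             k: int, penalty_sign: int, seed: int) -> ObjectiveValue:
    """Evaluate the objective for one mask (empty mask -> +inf sentinel)."""
    if penalty_sign not in (1, -1):
        raise ValueError("penalty_sign must be +1 or -1")
    mask = np.asarray(mask)
    n_total = table.n_features
    n_sel = int(mask.sum())
    if n_sel == 0:
        return ObjectiveValue(math.inf, math.nan, 0, n_total, penalty_sign)
    err = cv_error(table, mask, spec, k, seed).mean_error
    value = err * math.exp(penalty_sign * n_sel / n_total)
    return ObjectiveValue(value, err, n_sel, n_total, penalty_sign)


class ObjectiveFunction:
    """Memoizing mask -> objective-value callable handed to the optimizer.

    Swarm trajectories revisit masks heavily; caching by mask bytes makes
    repeat evaluations free while keeping results identical (the CV seed is
    fixed per instance, so a mask always maps to one value).
    """

    def __init__(self, table: FeatureTable, spec: ClassifierSpec, k: int,
                 penalty_sign: int, seed: int):
        self.table = table
        self.spec = spec
        self.k = k
        self.penalty_sign = penalty_sign
        self.seed = seed
        self._cache: dict[bytes, ObjectiveValue] = {}
        self.n_cv_evals = 0

    def detailed(self, mask: np.ndarray) -> ObjectiveValue:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        hit = self._cache.get(key)
        if hit is None:
            hit = evaluate(self.table, mask, self.spec, self.k,
                           self.penalty_sign, self.seed)
            self._cache[key] = hit
            self.n_cv_evals += 1
        return hit

    def __call__(self, mask: np.ndarray) -> float:
        return self.detailed(mask).value
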
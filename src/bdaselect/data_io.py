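"""Tabular data loading, run configuration, and selection-report I/O.

A :class:`FeatureTable` is the in-memory container used throughout the
package: an ``n_samples x n_features`` numeric matrix with named columns and
a binary label vector coded ``{-1, +1}``.  CSV is the only input format;
selection reports round-trip through JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "RunConfig",
    "SelectionReport",
    "load_table",
    "write_report",
    "read_report",
]


class DataError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class FeatureTable:
    """Samples-by-features matrix with a binary label vector.

    Parameters
    ----------
    feature_names
        Unique column identifiers; ``len(feature_names) == X.shape[1]``.
    X
        Numeric matrix, shape ``(n_samples, n_features)``.
    y
        Labels in ``{-1, +1}``, shape ``(n_samples,)``.
    encodings
        Recorded integer encodings for categorical columns (name -> mapping
        from original value to code).
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    encodings: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise DataError("X must be 2-dimensional")
        if len(self.feature_names) != self.X.shape[1]:
            raise DataError("feature_names length must match X columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature_names must be unique")
        if self.y.shape != (self.X.shape[0],):
            raise DataError("y length must match X rows")
        if np.isnan(self.X).any():
            raise DataError("X contains missing values")
        if not np.isin(self.y, (-1, 1)).all():
            raise DataError("y must be coded in {-1, +1}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        """Size of the candidate-feature universe |O|."""
        return self.X.shape[1]

    def has_both_classes(self) -> bool:
        return len(np.unique(self.y)) == 2

    def take_rows(self, idx: np.ndarray) -> "FeatureTable":
        """New table with rows ``idx`` (bootstrap / fold subsetting)."""
        return FeatureTable(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            encodings=dict(self.encodings),
        )

    def feature_summary(self) -> pd.DataFrame:
        """Per-feature mean/SD of the full table (reference metadata only;
        model fitting re-estimates scaling on training folds)."""
        return pd.DataFrame(
            {"mean": self.X.mean(axis=0), "sd": self.X.std(axis=0)},
            index=self.feature_names,
        )


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class RunConfig:
    """Configuration for the ensemble feature selector.

    Defaults follow the method's reference settings: a swarm of 10
    dragonflies run for up to 150 iterations per bootstrap replicate,
    100 replicates, 10-fold cross-validation inside the objective, SVM
    penalty ``C = 1``, five behaviour weights of 0.2 each, and personal /
    group learning rates 0.4 / 0.7 applied inside the attraction term.
    """

    swarm_size: int = 10
    max_iter: int = 150          # KK, iteration threshold
    objective_threshold: float = 0.0  # EE, early stop when objective <= EE
    n_replicates: int = 100      # m, bootstrap replicates
    cv_folds: int = 10           # K
    penalty: float = 1.0         # SVM C
    kernel: str = "rbf"
    behavior_weights: tuple[float, float, float, float, float] = (
        0.2, 0.2, 0.2, 0.2, 0.2)
    personal_rate: float = 0.4
    group_rate: float = 0.7
    use_learning_rates: bool = True
    penalty_sign: int = 1        # +1 penalizes large sets; -1 is literal form
    cohesion_convention: str = "printed"     # or "standard"
    distraction_convention: str = "printed"  # or "standard"
    m_rounding: str = "half_away"            # or "floor" / "ceil"
    oob_accuracy: bool = False   # score replicates on out-of-bag rows
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("swarm_size", "max_iter", "n_replicates", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.penalty_sign not in (1, -1):
            raise ValueError("penalty_sign must be +1 or -1")
        if not all(np.isfinite(self.behavior_weights)):
            raise ValueError("behavior_weights must be finite")
        if self.cohesion_convention not in ("printed", "standard"):
            raise ValueError("unknown cohesion_convention")
        if self.distraction_convention not in ("printed", "standard"):
            raise ValueError("unknown distraction_convention")
        if self.m_rounding not in ("half_away", "floor", "ceil"):
            raise ValueError("unknown m_rounding")

    def round_m(self, mean_size: float) -> int:
        if self.m_rounding == "floor":
            return int(np.floor(mean_size))
        if self.m_rounding == "ceil":
            return int(np.ceil(mean_size))
        return _round_half_away(mean_size)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["behavior_weights"] = list(self.behavior_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "behavior_weights" in d:
            d["behavior_weights"] = tuple(d["behavior_weights"])
        return cls(**d)


@dataclass
class SelectionReport:
    """Output of the ensemble selector.

    ``votes[i] = sum_m accuracies[m] * masks[m][i]`` and ``final_mask`` has
    exactly ``m_selected`` ones at the top-voted positions.
    """

    feature_names: list[str]
    replicate_masks: list[np.ndarray]
    replicate_accuracies: list[float]
    votes: np.ndarray
    m_selected: int
    final_mask: np.ndarray
    config: dict
    seed: int
    traces: list[list[float]] = field(default_factory=list)

    @property
    def selected_features(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.final_mask) if b]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "replicates": [
                {"mask": np.asarray(m).astype(int).tolist(),
                 "accuracy": float(a)}
                for m, a in zip(self.replicate_masks,
                                self.replicate_accuracies)
            ],
            "votes": np.asarray(self.votes, dtype=float).tolist(),
            "m_selected": int(self.m_selected),
            "final_mask": np.asarray(self.final_mask).astype(int).tolist(),
            "selected_features": self.selected_features,
            "config": self.config,
            "seed": int(self.seed),
            "traces": [[float(v) for v in t] for t in self.traces],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionReport":
        return cls(
            feature_names=list(d["feature_names"]),
            replicate_masks=[np.asarray(r["mask"], dtype=np.int8)
                             for r in d["replicates"]],
            replicate_accuracies=[float(r["accuracy"])
                                  for r in d["replicates"]],
            votes=np.asarray(d["votes"], dtype=float),
            m_selected=int(d["m_selected"]),
            final_mask=np.asarray(d["final_mask"], dtype=np.int8),
            config=dict(d["config"]),
            seed=int(d["seed"]),
            traces=[list(t) for t in d.get("traces", [])],
        )


def load_table(
    path: str | Path,
    label_column: str,
    positive_label,
    categorical: Mapping[str, Sequence] | None = None,
) -> FeatureTable:
    """Load a CSV into a :class:`FeatureTable`.

    Rows containing any missing value are dropped (and counted in the log);
    the label column must contain exactly two distinct values, of which
    ``positive_label`` is mapped to +1 and the other to -1.

    Parameters
    ----------
    categorical
        Mapping from column name to its ordered category levels.  Declared
        columns are integer-encoded by rank (so ordered scales such as
        education levels keep their ordering and unordered binaries become
        0/1); the encoding is recorded on the returned table.  A non-numeric
        column that is not declared here is an error.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise DataError(f"label column {label_column!r} not found")

    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning("dropped %d row(s) with missing values", n0 - len(df))

    labels = df[label_column]
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise DataError(
            f"label column must have exactly 2 distinct values, got {len(uniq)}")
    if positive_label not in set(uniq):
        raise DataError(f"positive label {positive_label!r} not present")
    y = np.where(labels == positive_label, 1, -1).astype(np.int8)

    feats = df.drop(columns=[label_column])
    encodings: dict[str, dict] = {}
    categorical = dict(categorical or {})
    for col in feats.columns:
        if col in categorical:
            levels = list(categorical[col])
            mapping = {lv: i for i, lv in enumerate(levels)}
            unknown = set(feats[col]) - set(levels)
            if unknown:
                raise DataError(
                    f"column {col!r} has values outside declared levels: "
                    f"{sorted(map(str, unknown))}")
            feats[col] = feats[col].map(mapping)
            encodings[col] = {str(k): v for k, v in mapping.items()}
        else:
            coerced = pd.to_numeric(feats[col], errors="coerce")
            if coerced.isna().any():
                raise DataError(
                    f"column {col!r} is non-numeric and not declared categorical")
            feats[col] = coerced

    X = feats.to_numpy(dtype=float)
    constant = [c for c, s in zip(feats.columns, X.std(axis=0)) if s == 0]
    if constant:
        logger.warning("constant feature column(s) retained: %s", constant)

    return FeatureTable(
        feature_names=list(feats.columns), X=X, y=y, encodings=encodings)


def write_report(report: SelectionReport, path: str | Path) -> None:
    """Serialize a complete report to JSON (lossless round-trip)."""
    if len(report.replicate_masks) == 0:
        raise ValueError("report has no replicates")
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def read_report(path: str | Path) -> SelectionReport:
    with open(path) as fh:
        return SelectionReport.from_dict(json.load(fh))
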
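"""Synthetic questionnaire cohorts with known ground truth.

Real clinical questionnaire data for this problem are private, so testing
relies on generated cohorts that copy the *shape* of such data: three
groups (mood disorder with self-injury, mood disorder without, typical
development), ~25 bounded integer scale scores (anxiety and depression
totals, personality-disorder subscales, childhood-trauma subscales,
emotion-regulation subscales, simple demographics), a subset of features
carrying known group mean shifts, a single latent severity factor inducing
correlation between loaded scales, and pure-noise features.

The model per subject i in group g and scale f:

    latent_i  = mu_g + N(0, 1)
    raw_{i,f} = load_f * latent_i + shift_{g,f} * s_f + N(0, 1),
                s_f = sqrt(load_f^2 + 1)
    value     = clip(round(mid_f + (raw / s_f) * width_f / 6), low_f, high_f)

so ``shift_{g,f}`` is a *standardized* mean shift (in SDs of the feature)
and each scale is a clipped, rounded affine map of the latent-plus-noise
score into its declared integer range.  Features with zero loading and
zero shift are independent of group membership.

The module also ships verbatim demographic contingency-table fixtures for
the published three-group cohort (n = 137/49/96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import FeatureTable
from .stats import ContingencyTable

__all__ = ["ScaleDef", "CohortSpec", "GroundTruth", "generate_cohort",
           "binary_view", "default_cohort_spec", "planted_cohort_spec",
           "fixture_table1"]


@dataclass(frozen=True)
class ScaleDef:
    """A bounded integer questionnaire score."""

    name: str
    low: int
    high: int

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise ValueError("empty score range")


@dataclass
class CohortSpec:
    """Generator parameters for a three-group cohort.

    ``informative`` maps a scale name to its per-group standardized mean
    shifts (one per group, in feature SDs); ``loadings`` maps a scale name
    to its loading on the shared latent severity factor;
    ``latent_group_shift`` moves the latent factor itself by group, which
    separates every loaded scale at once.
    """

    scales: list[ScaleDef]
    n_per_group: tuple[int, int, int] = (137, 49, 96)
    group_names: tuple[str, str, str] = ("with_nssi", "without_nssi", "td")
    informative: dict[str, tuple[float, float, float]] = field(
        default_factory=dict)
    loadings: dict[str, float] = field(default_factory=dict)
    latent_group_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.name for s in self.scales]
        if len(set(names)) != len(names):
            raise ValueError("scale names must be unique")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("every group must be nonempty")
        unknown = set(self.informative) - set(names)
        if unknown:
            raise ValueError(f"informative features not in scales: {unknown}")
        if not all(np.isfinite(np.ravel(list(self.informative.values()) or [0.0]))):
            raise ValueError("shifts must be finite")


@dataclass
class GroundTruth:
    informative: list[str]
    group_labels: np.ndarray


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort table (features + ``group`` column) and its truth.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = np.repeat(np.arange(3), spec.n_per_group)
    n = len(groups)
    latent = np.asarray(spec.latent_group_shift)[groups] + rng.normal(size=n)

    data = {}
    for scale in spec.scales:
        load = spec.loadings.get(scale.name, 0.0)
        shifts = np.asarray(spec.informative.get(scale.name, (0.0,) * 3))
        s_f = np.sqrt(load * load + 1.0)
        raw = (load * latent + shifts[groups] * s_f
               + rng.normal(size=n))
        width = scale.high - scale.low
        mid = (scale.high + scale.low) / 2.0
        vals = np.round(mid + (raw / s_f) * (width / 6.0))
        data[scale.name] = np.clip(vals, scale.low, scale.high).astype(int)

    df = pd.DataFrame(data)
    df["group"] = np.asarray(spec.group_names)[groups]
    truth = GroundTruth(
        informative=sorted(
            {name for name, sh in spec.informative.items()
             if len(set(sh)) > 1}
            | {s.name for s in spec.scales
               if spec.loadings.get(s.name, 0.0) != 0.0
               and len(set(spec.latent_group_shift)) > 1}),
        group_labels=groups.copy(),
    )
    return df, truth


def binary_view(cohort: pd.DataFrame, positive_groups: list[str],
                negative_groups: list[str],
                group_column: str = "group") -> FeatureTable:
    """Collapse a three-group cohort to a binary classification table.

    Rows outside the named groups are dropped; the group column never
    appears among the features.  Swapping positive and negative groups
    flips every label exactly.
    """
    pos, neg = set(positive_groups), set(negative_groups)
    if pos & neg:
        raise ValueError("positive and negative groups overlap")
    keep = cohort[cohort[group_column].isin(pos | neg)]
    y = np.where(keep[group_column].isin(pos), 1, -1).astype(np.int8)
    feats = keep.drop(columns=[group_column])
    return FeatureTable(feature_names=list(feats.columns),
                        X=feats.to_numpy(dtype=float), y=y)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-shaped cohort: 137/49/96 subjects, instrument-like scales.

    Shift magnitudes are plausible standardized group differences for a
    clinical vs. typically-developing contrast (largest for depression /
    anxiety / borderline traits, null for sexual abuse and ethnicity);
    mood-symptom scales share a latent severity factor.
    """
    scales = [
        ScaleDef("gad7", 0, 21), ScaleDef("phq9", 0, 27),
        ScaleDef("pdq_paranoid", 0, 8), ScaleDef("pdq_borderline", 0, 8),
        ScaleDef("pdq_histrionic", 0, 8), ScaleDef("pdq_avoidant", 0, 8),
        ScaleDef("pdq_obsessive", 0, 8),
        ScaleDef("ctq_physical_abuse", 5, 25),
        ScaleDef("ctq_emotional_abuse", 5, 25),
        ScaleDef("ctq_sexual_abuse", 5, 25),
        ScaleDef("ctq_physical_neglect", 5, 25),
        ScaleDef("ctq_emotional_neglect", 5, 25),
        ScaleDef("ders_awareness", 6, 30), ScaleDef("ders_clarity", 5, 25),
        ScaleDef("ders_nonacceptance", 6, 30),
        ScaleDef("ders_impulse", 6, 30), ScaleDef("ders_goals", 5, 25),
        ScaleDef("ders_strategies", 8, 40), ScaleDef("ders_total", 36, 180),
        ScaleDef("gender", 0, 1), ScaleDef("ethnicity", 0, 1),
        ScaleDef("education", 0, 2), ScaleDef("age", 12, 25),
    ]
    informative = {
        "gad7": (1.9, 1.6, 0.0), "phq9": (2.3, 1.8, 0.0),
        "pdq_paranoid": (1.0, 0.5, 0.0), "pdq_borderline": (1.9, 1.3, 0.0),
        "pdq_histrionic": (0.6, 0.5, 0.0), "pdq_avoidant": (1.4, 1.2, 0.0),
        "pdq_obsessive": (1.0, 0.7, 0.0),
        "ctq_physical_abuse": (0.7, 0.4, 0.0),
        "ctq_emotional_abuse": (1.5, 1.1, 0.0),
        "ctq_physical_neglect": (0.4, 0.15, 0.0),
        "ctq_emotional_neglect": (0.95, 0.6, 0.0),
        "ders_awareness": (0.5, 0.0, 0.0), "ders_clarity": (1.1, 0.6, 0.0),
        "ders_nonacceptance": (1.25, 1.0, 0.0),
        "ders_impulse": (1.45, 0.9, 0.0), "ders_goals": (1.4, 1.15, 0.0),
        "ders_strategies": (1.65, 1.25, 0.0), "ders_total": (1.8, 1.25, 0.0),
        "gender": (-0.35, 0.05, 0.0), "education": (-0.9, -0.45, 0.0),
        "age": (-1.3, -0.8, 0.0),
    }
    loadings = {name: 0.6 for name in
                ("gad7", "phq9", "pdq_borderline", "ders_clarity",
                 "ders_impulse", "ders_strategies", "ders_total")}
    return CohortSpec(scales=scales, informative=informative,
                      loadings=loadings, seed=seed)


def planted_cohort_spec(n_features: int = 25, n_informative: int = 5,
                        effect_size: float = 1.0,
                        n_per_group: tuple[int, int, int] = (100, 100, 100),
                        seed: int = 0) -> CohortSpec:
    """Generic planted-truth cohort for recovery experiments.

    The first ``n_informative`` scales carry a standardized shift of
    ``effect_size`` in both clinical groups (0 in the comparison group);
    the remainder are pure noise.  All features are independent.
    """
    if not 0 <= n_informative <= n_features:
        raise ValueError("n_informative out of range")
    scales = [ScaleDef(f"score_{i:02d}", 0, 40) for i in range(n_features)]
    informative = {f"score_{i:02d}": (effect_size, effect_size, 0.0)
                   for i in range(n_informative)}
    return CohortSpec(scales=scales, n_per_group=n_per_group,
                      informative=informative, seed=seed)


def fixture_table1() -> dict[str, ContingencyTable]:
    """Published demographic contingency tables, counts verbatim.

    Rows are the three groups (with NSSI, without NSSI, TD).  Note the
    published TD education row sums to 97 against a stated group size of
    96; the counts are kept exactly as printed.
    """
    groups = ["with_nssi", "without_nssi", "td"]

    def ct(counts, cols):
        return ContingencyTable(np.array(counts), list(groups), cols)

    return {
        "gender": ct([[27, 110], [18, 31], [32, 64]], ["male", "female"]),
        "ethnicity": ct([[117, 20], [46, 3], [93, 3]], ["han", "other"]),
        "adolescent_education": ct(
            [[5, 55, 77], [1, 12, 36], [4, 6, 87]],
            ["<=middle_school", "high_school", ">=college"]),
        "mother_education": ct(
            [[64, 42, 31], [18, 17, 14], [50, 25, 21]],
            ["<=middle_school", "high_school", ">=college"]),
        "father_education": ct(
            [[56, 43, 38], [18, 16, 15], [40, 33, 23]],
            ["<=middle_school", "high_school", ">=college"]),
    }
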
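"""Split-half reliability, between-subject consistency, and model-behavior fits.

The estimators follow a common scheme: per iteration, each item's trials
(items = images or morph levels) are split into two random halves; the
half-mean vectors v1, v2 over items are compared by squared Pearson
correlation (R^2).  Repeating over iterations yields a distribution of fits
rather than a single point estimate, which keeps within- and between-subject
comparisons equally powered.  For the between-subject variant v1 comes from
one subject's random half and v2 from the other's.

The empirical percentile test locates a model's fit-to-behavior within a
between-subject reference distribution: a model is "subject-like" at a given
resolution when its percentile is not extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import rng_for
from .behavior import ChoiceTable
from .stats import StatResult, ols_slope

__all__ = [
    "ReliabilityDistribution",
    "split_half_reliability",
    "between_subject_consistency",
    "fit_model_to_behavior",
    "empirical_percentile",
    "compare_groups",
]


@dataclass
class ReliabilityDistribution:
    """Per-iteration split-half R^2 values for one subject pair (i = j within)."""

    values: np.ndarray
    level: str  # "image" | "morph"
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("squared-Pearson fits must lie in [0, 1]")

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def __len__(self) -> int:
        return len(self.values)


def _item_trials(choices: ChoiceTable, level: str, min_reps: int | None) -> dict:
    """item id -> array of trial responses; enforces the repetition floor."""
    if level not in ("image", "morph"):
        raise ValueError("level must be 'image' or 'morph'")
    key = "image_id" if level == "image" else "morph_level_pct"
    groups = {k: g["response"].to_numpy() for k, g in choices.df.groupby(key)}
    if len(groups) < 3:
        raise ValueError("need at least 3 items")
    floor = 2 if min_reps is None else max(min_reps, 2)
    for item, trials in groups.items():
        if len(trials) < floor:
            raise ValueError(
                f"item {item!r} has {len(trials)} trials; "
                f"{floor} are required — insufficient repetitions for a {level}-level analysis"
            )
    return groups


def _half_means(groups: dict, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random half-split per item; odd counts give the extra trial to a random half."""
    v1, v2 = [], []
    for item in sorted(groups, key=str):
        trials = groups[item]
        n = len(trials)
        perm = rng.permutation(n)
        cut = n // 2 if (n % 2 == 0 or rng.random() < 0.5) else n - n // 2
        v1.append(trials[perm[:cut]].mean())
        v2.append(trials[perm[cut:]].mean())
    return np.array(v1), np.array(v2)


def _squared_pearson(v1: np.ndarray, v2: np.ndarray) -> float:
    if np.ptp(v1) == 0 and np.ptp(v2) == 0 and np.allclose(v1, v2):
        return 1.0  # deterministic behavior: halves identical
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return 0.0
    return float(np.corrcoef(v1, v2)[0, 1] ** 2)


def split_half_reliability(
    choices: ChoiceTable,
    level: str = "image",
    n_iter: int = 100,
    seed: int = 0,
    min_reps: int | None = 8,
) -> ReliabilityDistribution:
    """Within-subject split-half reliability of one subject's choice behavior.

    ``min_reps`` (default 8 at image level, mirroring the exclusion of
    under-repeated experiments) can be lowered for simulation studies.
    """
    groups = _item_trials(choices, level, min_reps if level == "image" else 2)
    subject = choices.df["subject_id"].iloc[0] if len(choices.df) else "?"
    rng = rng_for(seed, "split-half", subject, level)
    values = np.zeros(n_iter)
    for it in range(n_iter):
        v1, v2 = _half_means(groups, rng)
        values[it] = _squared_pearson(v1, v2)
    return ReliabilityDistribution(values=values, level=level, pair=(str(subject), str(subject)))


def between_subject_consistency(
    choices_i: ChoiceTable,
    choices_j: ChoiceTable,
    level: str = "image",
    n_iter: int = 100,
    seed: int = 0,
    min_reps: int | None = 8,
) -> ReliabilityDistribution:
    """Between-subject consistency: subject i's random half vs subject j's.

    Each subject contributes one random half per iteration (the same protocol
    as the within-subject measure), so both measures are equally powered.
    The split template is replayed for both subjects: v1 is subject i's first
    half and v2 is subject j's second half, so when trial counts match the
    two halves partition the trial indices — and a subject compared with an
    exact copy of itself reproduces the within-subject distribution.
    """
    key = "image_id" if level == "image" else "morph_level_pct"
    floor = min_reps if level == "image" else 2
    gi = _item_trials(choices_i, level, floor)
    gj = _item_trials(choices_j, level, floor)
    shared = sorted(set(gi) & set(gj), key=str)
    if not shared:
        raise ValueError(f"subjects share no items on {key}")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared items")
    gi = {k: gi[k] for k in shared}
    gj = {k: gj[k] for k in shared}
    si = choices_i.df["subject_id"].iloc[0]
    sj = choices_j.df["subject_id"].iloc[0]
    values = np.zeros(n_iter)
    for it in range(n_iter):
        # identical streams replay the same split template on both subjects
        rng_i = rng_for(seed, "between", level, it)
        rng_j = rng_for(seed, "between", level, it)
        v1, _ = _half_means(gi, rng_i)
        _, v2 = _half_means(gj, rng_j)
        values[it] = _squared_pearson(v1, v2)
    return ReliabilityDistribution(values=values, level=level, pair=(str(si), str(sj)))


def fit_model_to_behavior(model_values, behavior_values, level: str | None = None) -> StatResult:
    """OLS of behavior on model per-item values; slope t-test with df n - 2.

    Returns a StatResult whose ``r_squared`` is the coefficient of
    determination and whose ``beta`` is the regression slope.
    """
    model_values = np.asarray(model_values, dtype=float)
    behavior_values = np.asarray(behavior_values, dtype=float)
    if model_values.shape != behavior_values.shape:
        raise ValueError("model and behavior vectors must be aligned")
    if model_values.size < 3:
        raise ValueError("need at least 3 items")
    if np.ptp(model_values) == 0:
        raise ValueError("model values have zero variance")
    return ols_slope(model_values, behavior_values, statistic="t")


def empirical_percentile(model_fit, reference: ReliabilityDistribution | np.ndarray) -> float:
    """Fraction of reference values <= model_fit.

    ``model_fit`` may be a scalar or a vector of per-iteration model fits; for
    a vector, the median percentile over iterations is reported.
    """
    ref = reference.values if isinstance(reference, ReliabilityDistribution) else np.asarray(reference, float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    fits = np.atleast_1d(np.asarray(model_fit, dtype=float))
    percentiles = np.array([np.mean(ref <= f) for f in fits])
    return float(np.median(percentiles))


def compare_groups(curve_a: pd.DataFrame, curve_b: pd.DataFrame) -> StatResult:
    """Association between two groups' (experiment, morph level) mean curves.

    OLS of group-b means on group-a means with intercept; F-test of the slope
    with df (1, n - 2).  Points must align exactly.
    """
    keys = [c for c in ("experiment_id", "morph_level_pct") if c in curve_a.columns]
    if not keys:
        raise ValueError("curves need experiment_id and/or morph_level_pct columns")
    a = curve_a.set_index(keys)["prop_dog"] if "prop_dog" in curve_a.columns else curve_a.set_index(keys).iloc[:, 0]
    b = curve_b.set_index(keys)["prop_dog"] if "prop_dog" in curve_b.columns else curve_b.set_index(keys).iloc[:, 0]
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("group curves cover different (experiment, morph level) points")
        b = b.reindex(a.index)
    return ols_slope(a.to_numpy(), b.to_numpy(), statistic="F")
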
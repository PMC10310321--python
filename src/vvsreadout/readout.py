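"""L2-regularized linear category readouts from image features.

The readout is a logistic regression predicting the binary category (dog = 1,
cat = 0) from per-image feature vectors.  Two train/test regimes are
implemented:

* ``random`` — repeated random 4/5 train, 1/5 test splits (default 100
  iterations, stratified by morph level), recording each iteration's held-out
  predictions;
* ``sequence_holdout`` — the conservative leave-one-morph-sequence-out
  rotation (train on all other sequences, test on the held-out one), which
  removes the within-sequence pixel colinearity that trivial readouts can
  exploit.

Held-out predictions are aggregated per image and per morph level into the
morph-level performance curve compared against observer behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._linalg import gram_reduce
from ._rng import rng_for
from .behavior import ChoiceTable
from .encoders import FeatureMatrix
from .stimuli import StimulusSet

__all__ = [
    "ReadoutConfig",
    "FittedReadout",
    "train_readout",
    "CategoryReadout",
    "ReadoutResults",
    "evaluate_random_splits",
    "evaluate_sequence_holdout",
    "aggregate_morph_level",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadoutConfig:
    """Configuration of the linear readout evaluation.

    ``c_grid`` defaults to nine log-spaced inverse-regularization strengths
    from 1e-5 to 1e5; the optimal C is chosen by inner fivefold CV on the
    training data only.
    """

    c_grid: tuple = tuple(np.logspace(-5, 5, 9))
    inner_folds: int = 5
    n_iterations: int = 100
    train_fraction: float = 0.8
    split_mode: str = "random"  # "random" | "sequence_holdout"
    stratify_by_level: bool = True
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.c_grid)
        if not grid or any(c <= 0 for c in grid) or list(grid) != sorted(grid):
            raise ValueError("c_grid must be nonempty, strictly positive and sorted")
        object.__setattr__(self, "c_grid", grid)
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.split_mode not in ("random", "sequence_holdout"):
            raise ValueError("split_mode must be 'random' or 'sequence_holdout'")


@dataclass
class FittedReadout:
    """Weights, intercept and the inner-CV-selected C of one trained readout."""

    coef: np.ndarray
    intercept: float
    C: float
    classes: np.ndarray

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        # ties at exactly 0.5 go to 1
        return (self.predict_prob(X) >= 0.5).astype(int)


def _select_c(X: np.ndarray, y: np.ndarray, config: ReadoutConfig, rng_seed: int) -> float:
    """Inner stratified K-fold accuracy over the C grid; ties -> largest C
    (the least regularized of the equally scoring values, so separable data
    is fit sharply)."""
    n_splits = min(config.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return config.c_grid[len(config.c_grid) // 2]
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed % (2**32))
    scores = np.zeros(len(config.c_grid))
    for train, test in folds.split(X, y):
        for ci, c in enumerate(config.c_grid):
            clf = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)
            clf.fit(X[train], y[train])
            scores[ci] += clf.score(X[test], y[test])
    best = len(scores) - 1 - int(np.argmax(scores[::-1]))
    return config.c_grid[best]


def train_readout(
    features: np.ndarray, labels: np.ndarray, config: ReadoutConfig | None = None, seed: int | None = None
) -> FittedReadout:
    """Fit the L2 logistic readout; C chosen by inner CV, then refit on all data."""
    config = config or ReadoutConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    present = set(np.unique(y))
    for cls, name in ((0, "cat (0)"), (1, "dog (1)")):
        if cls not in present:
            raise ValueError(f"training set lacks the {name} class")
    c = _select_c(X, y, config, config.seed if seed is None else seed)
    clf = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    return FittedReadout(coef=clf.coef_.ravel(), intercept=float(clf.intercept_[0]), C=c, classes=clf.classes_)


class CategoryReadout:
    """Model object: features + category labels + morph metadata.

    Use :meth:`from_stimuli` to build from a FeatureMatrix and the
    StimulusSet it was extracted from; :meth:`fit` runs the split regime
    named in the config and returns :class:`ReadoutResults`.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels: np.ndarray,
        morph_levels: np.ndarray,
        sequence_ids: np.ndarray | None = None,
        config: ReadoutConfig | None = None,
    ):
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        self.morph_levels = np.asarray(morph_levels, dtype=int)
        self.sequence_ids = None if sequence_ids is None else np.asarray(sequence_ids)
        self.config = config or ReadoutConfig()
        if len(self.labels) != features.n_images or len(self.morph_levels) != features.n_images:
            raise ValueError("labels and morph levels must align with feature rows")
        X = features.matrix
        if self.config.standardize:
            # z-score each feature over the stimulus set (a label-free, fixed
            # preprocessing step; encoder layers have wildly heterogeneous
            # per-dimension scales that an L2 penalty would otherwise conflate)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        # exact Gram-preserving reduction: predictions unchanged, fits much faster
        self._X = gram_reduce(X)

    @classmethod
    def from_stimuli(
        cls, features: FeatureMatrix, stimuli: StimulusSet, config: ReadoutConfig | None = None
    ) -> "CategoryReadout":
        if list(features.image_ids) != list(stimuli.image_ids):
            raise ValueError("feature rows must align with stimulus iteration order")
        return cls(
            features=features,
            labels=stimuli.labels(),
            morph_levels=stimuli.morph_levels(),
            sequence_ids=stimuli.sequence_ids(),
            config=config,
        )

    # -- split regimes -------------------------------------------------------
    def fit(self) -> "ReadoutResults":
        if self.config.split_mode == "random":
            return self._fit_random()
        return self._fit_sequence_holdout()

    def _one_random_split(self, iteration: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(self.features.n_images)
        strat = self.morph_levels if self.config.stratify_by_level else None
        if strat is not None and np.bincount(np.unique(strat, return_inverse=True)[1]).min() < 2:
            logger.info("stratification impossible (a morph level has < 2 images); falling back")
            strat = None
        seed = rng_for(self.config.seed, "split", iteration).integers(2**31)
        try:
            train, test = train_test_split(
                idx, train_size=self.config.train_fraction, random_state=int(seed), stratify=strat
            )
        except ValueError:
            # stratification impossible (e.g. more levels than test slots)
            logger.info("stratified split infeasible; falling back to unstratified")
            train, test = train_test_split(
                idx, train_size=self.config.train_fraction, random_state=int(seed), stratify=None
            )
        return np.sort(train), np.sort(test)

    def _fit_random(self) -> "ReadoutResults":
        if self.features.n_images < 10:
            raise ValueError("need at least 10 images for random-split evaluation")
        records = []
        held_out_ever = np.zeros(self.features.n_images, dtype=bool)
        iteration = 0
        total = self.config.n_iterations
        while iteration < total:
            train, test = self._one_random_split(iteration)
            self._record_iteration(iteration, train, test, records)
            held_out_ever[test] = True
            iteration += 1
            # coverage contract: every image must be held out at least once
            if iteration == total and not held_out_ever.all():
                logger.info("re-drawing extra splits until every image is held out")
                total += 1
        return ReadoutResults(self, pd.DataFrame(records))

    def _fit_sequence_holdout(self) -> "ReadoutResults":
        if self.sequence_ids is None:
            raise ValueError("sequence ids are required for sequence_holdout")
        sequences = pd.unique(self.sequence_ids)
        if len(sequences) < 2:
            raise ValueError("sequence_holdout needs at least 2 sequences")
        records = []
        for k, seq in enumerate(sequences):
            test = np.flatnonzero(self.sequence_ids == seq)
            train = np.flatnonzero(self.sequence_ids != seq)
            self._record_iteration(k, train, test, records)
        return ReadoutResults(self, pd.DataFrame(records))

    def _record_iteration(self, iteration, train, test, records) -> None:
        assert len(np.intersect1d(train, test)) == 0
        seed = int(rng_for(self.config.seed, "inner-cv", iteration).integers(2**31))
        fitted = train_readout(self._X[train], self.labels[train], self.config, seed=seed)
        probs = fitted.predict_prob(self._X[test])
        labels = (probs >= 0.5).astype(int)
        ids = self.features.image_ids
        for j, prob, lab in zip(test, probs, labels):
            records.append(
                {
                    "iteration": iteration,
                    "image_id": ids[j],
                    "in_test": True,
                    "predicted_prob": float(prob),
                    "predicted_label": int(lab),
                    "true_label": int(self.labels[j]),
                    "morph_level_pct": int(self.morph_levels[j]),
                    "chosen_C": fitted.C,
                }
            )


@dataclass
class ReadoutResults:
    """Held-out predictions across split iterations, with aggregates."""

    model: CategoryReadout
    per_iteration: pd.DataFrame
    _per_image: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        g = self.per_iteration.groupby("image_id")
        self._per_image = g.agg(
            mean_predicted_label=("predicted_label", "mean"),
            mean_predicted_prob=("predicted_prob", "mean"),
            n_held_out=("iteration", "size"),
            true_label=("true_label", "first"),
            morph_level_pct=("morph_level_pct", "first"),
        ).reset_index()

    @property
    def n_iterations(self) -> int:
        return int(self.per_iteration["iteration"].nunique())

    @property
    def per_image(self) -> pd.DataFrame:
        return self._per_image

    def morph_curve(self) -> pd.DataFrame:
        """morph_level_pct -> mean proportion predicted 'dog', SD across iterations."""
        return aggregate_morph_level(self.per_iteration)

    def accuracy(self, levels: list[int] | None = None) -> float:
        df = self.per_iteration
        if levels is not None:
            df = df[df["morph_level_pct"].isin(levels)]
        if len(df) == 0:
            raise ValueError("no held-out predictions at the requested levels")
        return float((df["predicted_label"] == df["true_label"]).mean())

    def summary(self) -> pd.DataFrame:
        curve = self.morph_curve()
        curve["accuracy"] = [
            self.accuracy(levels=[lev]) for lev in curve["morph_level_pct"]
        ]
        return curve

    def plot_morph_curve(self, ax=None, label: str | None = None, color="k"):
        """Proportion predicted 'dog' per morph level, +/- SD across iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        curve = self.morph_curve()
        ax.errorbar(curve["morph_level_pct"], curve["prop_dog"], yerr=curve["sd"],
                    color=color, marker="o", ms=3, capsize=2, label=label)
        ax.set_xlabel("morph level (% dog)")
        ax.set_ylabel("proportion predicted 'dog'")
        ax.set_ylim(-0.05, 1.05)
        if label:
            ax.legend(frameon=False)
        return ax


def evaluate_random_splits(
    features: FeatureMatrix, stimuli: StimulusSet, config: ReadoutConfig | None = None
) -> ReadoutResults:
    config = replace(config or ReadoutConfig(), split_mode="random")
    return CategoryReadout.from_stimuli(features, stimuli, config).fit()


def evaluate_sequence_holdout(
    features: FeatureMatrix, stimuli: StimulusSet, config: ReadoutConfig | None = None
) -> ReadoutResults:
    config = replace(config or ReadoutConfig(), split_mode="sequence_holdout")
    return CategoryReadout.from_stimuli(features, stimuli, config).fit()


def aggregate_morph_level(data, value_column: str | None = None) -> pd.DataFrame:
    """Per-morph-level mean proportion 'dog' with SD across iterations/subjects.

    Accepts a ChoiceTable (uses ``response``, SD across subjects), a readout
    per-iteration frame (uses ``predicted_label``, SD across iterations), or
    any frame with ``morph_level_pct`` plus an explicit ``value_column``.
    Missing levels are absent, never imputed.
    """
    if isinstance(data, ChoiceTable):
        df, col, unit = data.df, "response", "subject_id"
    elif isinstance(data, ReadoutResults):
        df, col, unit = data.per_iteration, "predicted_label", "iteration"
    else:
        df = data
        if value_column is not None:
            col = value_column
        elif "predicted_label" in df.columns:
            col = "predicted_label"
        elif "response" in df.columns:
            col = "response"
        else:
            raise ValueError("cannot infer the value column; pass value_column")
        unit = "iteration" if "iteration" in df.columns else "subject_id"
    if len(df) == 0:
        raise ValueError("empty input")
    if "morph_level_pct" not in df.columns:
        raise ValueError("input lacks morph_level_pct")
    overall = df.groupby("morph_level_pct")[col].mean()
    if unit in df.columns and df[unit].nunique() > 1:
        per_unit = df.groupby(["morph_level_pct", unit])[col].mean().unstack()
        sd = per_unit.std(axis=1, ddof=0)
    else:
        sd = overall * 0.0
    out = pd.DataFrame(
        {
            "morph_level_pct": overall.index.to_numpy(),
            "prop_dog": overall.to_numpy(),
            "sd": sd.reindex(overall.index).to_numpy(),
            "n": df.groupby("morph_level_pct")[col].size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)
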
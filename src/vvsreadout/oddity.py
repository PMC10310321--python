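"""Leave-one-out pseudo-oddity performance estimation.

A three-alternative oddity trial shows two views of one object and one view of
another (the "oddity"); the task is to pick the slot holding the oddity.  For
a held-out sample trial over objects (i, j), performance is estimated by
synthesizing "pseudo oddity experiments": sets of training trials drawn from
the remaining views of the two objects (excluding the sample's three images),
training an L2-regularized linear classifier over slot-concatenated feature
blocks to report the oddity slot, and testing it on the sample trial.  The
binarized outcome, averaged over pseudo-experiment draws, is the trial's
performance; object-level performance averages over all partner objects.

The protocol is feature-source agnostic: encoder layers, raw pixels, or
simulated neural population responses all run through the same entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import rng_for
from .encoders import FeatureMatrix
from .stats import StatResult, one_sample_t, ols_slope
from .stimuli import StimulusSet

__all__ = [
    "OddityTrial",
    "PerformanceVector",
    "sample_trial",
    "build_pseudo_experiments",
    "estimate_trial_outcome",
    "aggregate_objects",
    "compare_performance_vectors",
    "synthetic_object_features",
    "OddityModel",
    "OddityResults",
]


@dataclass(frozen=True)
class OddityTrial:
    """Three image ids in slot order; ``oddity_pos`` indexes the odd one out."""

    image_ids: tuple[str, str, str]
    oddity_pos: int

    def __post_init__(self) -> None:
        if self.oddity_pos not in (0, 1, 2):
            raise ValueError("oddity_pos must be 0, 1 or 2")
        if len(set(self.image_ids)) != 3:
            raise ValueError("a trial needs three distinct images")

    def validate(self, index: dict[str, tuple]) -> None:
        objects = [index[iid][0] for iid in self.image_ids]
        odd = objects[self.oddity_pos]
        pair = [o for k, o in enumerate(objects) if k != self.oddity_pos]
        if pair[0] != pair[1] or odd == pair[0]:
            raise ValueError("exactly one image's object must differ from the other two")

    def pair_object(self, index: dict[str, tuple]) -> str:
        k = (self.oddity_pos + 1) % 3
        return index[self.image_ids[k]][0]

    def oddity_object(self, index: dict[str, tuple]) -> str:
        return index[self.image_ids[self.oddity_pos]][0]


@dataclass
class PerformanceVector:
    """Per-object mean oddity accuracy."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for obj, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"performance for {obj} outside [0, 1]")

    @property
    def n_objects(self) -> int:
        return len(self.values)

    @property
    def objects(self) -> list[str]:
        return sorted(self.values)

    def as_array(self, objects: list[str] | None = None) -> np.ndarray:
        objects = objects or self.objects
        return np.array([self.values[o] for o in objects])


def _views_of(index: dict[str, tuple], obj: str) -> list[str]:
    return [iid for iid, info in index.items() if info[0] == obj]


def sample_trial(
    pool: "StimulusSet | dict", object_i: str, object_j: str, seed: int = 0
) -> OddityTrial:
    """Draw one oddity trial: two views of ``object_i``, one of ``object_j``."""
    index = pool.index if isinstance(pool, StimulusSet) else dict(pool)
    rng = rng_for(seed, "sample-trial", object_i, object_j)
    vi = sorted(_views_of(index, object_i))
    vj = sorted(_views_of(index, object_j))
    a, b = rng.choice(len(vi), size=2, replace=False)
    c = int(rng.integers(len(vj)))
    pos = int(rng.integers(3))
    ids = [vi[a], vi[b]]
    ids.insert(pos, vj[c])
    return OddityTrial(image_ids=tuple(ids), oddity_pos=pos)


def build_pseudo_experiments(
    sample: OddityTrial,
    pool: "StimulusSet | dict",
    n_trials: int = 52,
    seed: int = 0,
    balance_roles: bool = False,
) -> list[OddityTrial]:
    """Synthesize ``n_trials`` training trials from the two objects' remaining views.

    The sample's three images are excluded from the pool.  By default every
    pseudo trial mirrors the sample's structure — two views of the sample's
    typical object and one view of its oddity object — with the oddity's slot
    randomized uniformly.  (A linear slot classifier cannot learn anything
    from role-balanced trials: "which slot differs" is a relational, XOR-like
    target when either object may be the oddity, so the roles are kept fixed;
    ``balance_roles=True`` is available for comparison.)
    """
    index = pool.index if isinstance(pool, StimulusSet) else dict(pool)
    sample.validate(index)
    obj_i = sample.pair_object(index)
    obj_j = sample.oddity_object(index)
    excluded = set(sample.image_ids)
    avail = {o: sorted(set(_views_of(index, o)) - excluded) for o in (obj_i, obj_j)}
    for o, views in avail.items():
        if len(views) < 4:
            raise ValueError(
                f"object {o!r} has only {len(views)} views beyond the sample; "
                "need at least 4 (two pair views and an oddity view in either role)"
            )
    rng = rng_for(seed, "pseudo", *sorted(excluded))
    if balance_roles:
        half = n_trials // 2
        roles = [obj_j] * half + [obj_i] * (n_trials - half)
        rng.shuffle(roles)
    else:
        roles = [obj_j] * n_trials
    trials = []
    for odd_obj in roles:
        pair_obj = obj_i if odd_obj == obj_j else obj_j
        pv = rng.choice(len(avail[pair_obj]), size=2, replace=False)
        ov = int(rng.integers(len(avail[odd_obj])))
        pos = int(rng.integers(3))
        ids = [avail[pair_obj][pv[0]], avail[pair_obj][pv[1]]]
        ids.insert(pos, avail[odd_obj][ov])
        trials.append(OddityTrial(image_ids=tuple(ids), oddity_pos=pos))
    return trials


def _trial_design(trials: list[OddityTrial], features: FeatureMatrix):
    """Slot-concatenated feature blocks; target = oddity slot index."""
    X = np.stack([np.concatenate(list(features.rows(list(t.image_ids)))) for t in trials])
    y = np.array([t.oddity_pos for t in trials])
    return X, y


def estimate_trial_outcome(
    sample: OddityTrial,
    features: FeatureMatrix,
    pool: "StimulusSet | dict",
    n_pseudo: int = 100,
    n_trials: int = 52,
    C: float = 1.0,
    seed: int = 0,
) -> float:
    """Mean binarized outcome over ``n_pseudo`` pseudo-experiment draws.

    Each draw trains a fresh multinomial L2 logistic classifier (fixed C) on
    its pseudo-experiment and predicts the sample trial's oddity slot; the
    prediction is binarized correct/incorrect and averaged across draws.
    """
    X_sample = np.concatenate(list(features.rows(list(sample.image_ids))))[None, :]
    outcomes = np.zeros(n_pseudo)
    for p in range(n_pseudo):
        pseudo_seed = rng_for(seed, "pseudo-draw", p).integers(2**31)
        trials = build_pseudo_experiments(sample, pool, n_trials=n_trials, seed=int(pseudo_seed))
        X, y = _trial_design(trials, features)
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        clf.fit(X, y)
        outcomes[p] = float(clf.predict(X_sample)[0] == sample.oddity_pos)
    return float(outcomes.mean())


def aggregate_objects(outcomes: pd.DataFrame) -> PerformanceVector:
    """Per-object mean over all partner oddities.

    ``outcomes`` has columns (object_i, object_j, outcome), with object_i the
    paired (non-oddity) identity.  Every object must appear as object_i.
    """
    if len(outcomes) == 0:
        raise ValueError("no trial outcomes to aggregate")
    means = outcomes.groupby("object_i")["outcome"].mean()
    all_objects = set(outcomes["object_i"]) | set(outcomes["object_j"])
    missing = sorted(all_objects - set(means.index))
    if missing:
        raise ValueError(f"objects never appear as the paired identity: {missing}")
    return PerformanceVector(values={str(o): float(v) for o, v in means.items()})


def compare_performance_vectors(
    a: PerformanceVector, b: PerformanceVector, mode: str = "slope"
) -> StatResult:
    """Compare two per-object performance vectors.

    ``slope``: OLS of b on a with intercept, F-test of the slope, df (1, n-2).
    ``paired_difference``: mean(b - a) with a one-sample t-test, df n-1.
    """
    if set(a.values) != set(b.values):
        raise ValueError("performance vectors cover different object sets")
    objects = a.objects
    if len(objects) < 3:
        raise ValueError("need at least 3 objects")
    va, vb = a.as_array(objects), b.as_array(objects)
    if mode == "slope":
        return ols_slope(va, vb, statistic="F")
    if mode == "paired_difference":
        return one_sample_t(vb - va)
    raise ValueError("mode must be 'slope' or 'paired_difference'")


def synthetic_object_features(
    n_objects: int = 6,
    n_views: int = 12,
    dim: int = 16,
    separation: float = 2.0,
    seed: int = 0,
) -> tuple[dict, FeatureMatrix]:
    """Synthetic feature-space oddity fixture with known object structure.

    Each object is a unit-norm prototype direction; each view is the
    prototype scaled by ``separation`` plus unit isotropic noise.
    ``separation = 0`` gives structure-free features (chance performance is
    1/3); large separation makes the task easy.  Returns an (index, features)
    pair usable anywhere a rendered pool is: the index maps image_id ->
    (object_id, view_id).
    """
    if n_objects < 2 or n_views < 4:
        raise ValueError("need n_objects >= 2 and n_views >= 4")
    index: dict[str, tuple] = {}
    rows, ids = [], []
    for o in range(n_objects):
        org = rng_for(seed, "synth-obj", o)
        mu = org.normal(0.0, 1.0, dim)
        mu /= np.linalg.norm(mu)
        for w in range(n_views):
            vrg = rng_for(seed, "synth-view", o, w)
            iid = f"o{o:02d}_v{w:02d}"
            index[iid] = (f"o{o:02d}", f"v{w:02d}")
            rows.append(separation * mu + vrg.normal(0.0, 1.0, dim))
            ids.append(iid)
    return index, FeatureMatrix(np.array(rows), ids, f"synthetic-objects(sep={separation})")


class OddityModel:
    """Full pseudo-oddity protocol over an image pool and a feature source."""

    def __init__(self, features: FeatureMatrix, pool: "StimulusSet | dict"):
        if isinstance(pool, StimulusSet) and pool.kind != "oddity":
            raise ValueError("pool must be an oddity StimulusSet")
        index = pool.index if isinstance(pool, StimulusSet) else dict(pool)
        missing = set(index) - set(features.image_ids)
        if missing:
            raise KeyError(f"feature rows missing for image ids: {sorted(missing)}")
        self.features = features
        self.pool = pool
        self.index = index
        self.objects = sorted({info[0] for info in index.values()})
        if len(self.objects) < 2:
            raise ValueError("need at least 2 objects")

    def fit(
        self, n_trials: int = 52, n_pseudo: int = 100, C: float = 1.0, seed: int = 0
    ) -> "OddityResults":
        rows = []
        for oi in self.objects:
            for oj in self.objects:
                if oi == oj:
                    continue
                trial_seed = int(rng_for(seed, "pair", oi, oj).integers(2**31))
                sample = sample_trial(self.pool, oi, oj, seed=trial_seed)
                outcome = estimate_trial_outcome(
                    sample, self.features, self.pool,
                    n_pseudo=n_pseudo, n_trials=n_trials, C=C, seed=trial_seed,
                )
                rows.append({"object_i": oi, "object_j": oj, "outcome": outcome})
        outcomes = pd.DataFrame(rows)
        return OddityResults(model=self, pairwise=outcomes, performance=aggregate_objects(outcomes))


@dataclass
class OddityResults:
    model: OddityModel
    pairwise: pd.DataFrame
    performance: PerformanceVector

    def mean_performance(self) -> float:
        return float(self.performance.as_array().mean())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object_id": self.performance.objects,
                "mean_accuracy": self.performance.as_array(),
            }
        )
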
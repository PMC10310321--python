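"""Cross-validated linear maps from encoder layers to electrode responses.

For each (layer, electrode) pair a ridge-regularized linear map is fitted and
evaluated out-of-fold; the concatenated held-out predictions are correlated
with the held-out mean responses (Pearson r).  Raw fits are noise-corrected by
the electrode's split-half reliability ceiling, r_corrected = r / sqrt(rel),
with the reliability estimated by Spearman-Brown-corrected random half-splits
over repetitions.  Layer-order contrasts (first vs second half of the
encoder's declared layer order) and peak-layer selection summarise the layer
profile per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold

from ._linalg import gram_reduce
from ._rng import rng_for
from .electrodes import ElectrodeSet
from .encoders import FeatureMatrix
from .stats import StatResult, unpaired_t

__all__ = [
    "DEFAULT_RIDGE_GRID",
    "LayerFitResult",
    "fit_electrode_map",
    "estimate_reliability",
    "noise_correct",
    "contrast_layer_halves",
    "select_peak_layer",
    "NeuralEncodingModel",
    "NeuralEncodingResults",
]

DEFAULT_RIDGE_GRID = tuple(np.logspace(-4, 4, 9))


@dataclass
class LayerFitResult:
    """Per-electrode fits of one layer to one region's electrodes."""

    layer: str
    region_label: str
    per_electrode_r: np.ndarray
    per_electrode_r_corrected: np.ndarray
    reliability: np.ndarray
    reliability_floor: float = 0.1

    @property
    def included(self) -> np.ndarray:
        """Electrodes whose reliability clears the floor and whose r is defined."""
        return (self.reliability >= self.reliability_floor) & np.isfinite(self.per_electrode_r)

    @property
    def median_r_corrected(self) -> float:
        vals = self.per_electrode_r_corrected[self.included]
        return float(np.median(vals)) if vals.size else float("nan")

    @property
    def dispersion(self) -> float:
        vals = self.per_electrode_r_corrected[self.included]
        return float(np.std(vals)) if vals.size else float("nan")

    @property
    def n_exceeding_unity(self) -> int:
        """Corrected fits above 1 are possible at low reliability; flagged, not clipped."""
        return int(np.sum(self.per_electrode_r_corrected[self.included] > 1.0))


def fit_electrode_map(
    features: FeatureMatrix | np.ndarray,
    responses: np.ndarray,
    n_folds: int = 5,
    ridge_grid=DEFAULT_RIDGE_GRID,
    seed: int = 0,
    return_predictions: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Raw cross-validated Pearson r per electrode.

    ``responses``: n_images x n_electrodes, already averaged over repetitions.
    Out-of-fold predictions come from a ridge map whose penalty is selected by
    nested (leave-one-out generalized) CV within each training fold; held-out
    responses are never seen by the fit.  Electrodes with constant held-out
    responses get NaN (recorded as missing, excluded from medians).
    """
    X = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    responses = np.atleast_2d(np.asarray(responses, dtype=np.float64))
    if responses.shape[0] != X.shape[0]:
        responses = responses.T
    n_images, n_electrodes = responses.shape
    if n_electrodes == 0:
        raise ValueError("empty electrode set: nothing to fit")
    if n_images < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} images for {n_folds}-fold CV")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    Z = gram_reduce(X)
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    preds = np.zeros_like(responses)
    for train, test in folds.split(Z):
        for e in range(n_electrodes):
            model = RidgeCV(alphas=np.asarray(ridge_grid), fit_intercept=True)
            model.fit(Z[train], responses[train, e])
            preds[test, e] = model.predict(Z[test])

    r = np.full(n_electrodes, np.nan)
    for e in range(n_electrodes):
        y = responses[:, e]
        if np.ptp(y) == 0 or np.ptp(preds[:, e]) == 0:
            continue  # undefined correlation -> missing
        r[e] = sps.pearsonr(preds[:, e], y).statistic
    if return_predictions:
        return r, preds
    return r


def estimate_reliability(
    responses: np.ndarray, n_iter: int = 100, seed: int = 0
) -> np.ndarray | float:
    """Spearman-Brown-corrected split-half reliability per electrode.

    ``responses``: n_images x n_reps (single electrode) or n_images x
    n_electrodes x n_reps.  Each iteration splits the repetitions at random
    into two halves (odd counts: the extra repetition goes to a random half),
    correlates the half-mean vectors over images, and the mean correlation is
    mapped through Spearman-Brown 2r / (1 + r).
    """
    responses = np.asarray(responses, dtype=np.float64)
    single = responses.ndim == 2
    if single:
        responses = responses[:, None, :]
    n_images, n_electrodes, n_reps = responses.shape
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions per image")
    if n_images < 2:
        raise ValueError("need at least 2 images to correlate split halves")

    rng = rng_for(seed, "reliability")
    out = np.zeros(n_electrodes)
    for e in range(n_electrodes):
        rs = np.zeros(n_iter)
        for it in range(n_iter):
            perm = rng.permutation(n_reps)
            cut = n_reps // 2 if (n_reps % 2 == 0 or rng.random() < 0.5) else n_reps - n_reps // 2
            a = responses[:, e, perm[:cut]].mean(axis=1)
            b = responses[:, e, perm[cut:]].mean(axis=1)
            if np.ptp(a) == 0 and np.ptp(b) == 0 and np.allclose(a, b):
                rs[it] = 1.0  # zero-noise degenerate case: halves identical
            elif np.ptp(a) == 0 or np.ptp(b) == 0:
                rs[it] = 0.0
            else:
                rs[it] = np.corrcoef(a, b)[0, 1]
        r = rs.mean()
        out[e] = 2 * r / (1 + r) if r > -1 else -1.0
    return float(out[0]) if single else out


def noise_correct(
    raw_r: np.ndarray | float, reliability: np.ndarray | float, floor: float = 0.1
) -> np.ndarray | float:
    """Corrected r = raw_r / sqrt(reliability).

    Electrodes below the reliability floor are excluded (NaN) rather than
    corrected — low ceilings make the correction explode.
    """
    raw = np.atleast_1d(np.asarray(raw_r, dtype=np.float64))
    rel = np.atleast_1d(np.asarray(reliability, dtype=np.float64))
    corrected = np.full_like(raw, np.nan)
    ok = rel >= max(floor, 1e-12)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} electrode(s) with reliability below {floor}",
            stacklevel=2,
        )
    corrected[ok] = raw[ok] / np.sqrt(rel[ok])
    return float(corrected[0]) if np.isscalar(raw_r) or np.ndim(raw_r) == 0 else corrected


def contrast_layer_halves(
    layer_medians: "pd.Series | dict[str, float]", layer_order: list[str] | None = None
) -> StatResult:
    """Unpaired t-test: per-layer median corrected fits, first vs second half.

    With L layers the halves contain floor(L/2) and ceil(L/2) layers and the
    test has L - 2 degrees of freedom.
    """
    if isinstance(layer_medians, dict):
        layer_medians = pd.Series(layer_medians)
    if layer_order is not None:
        layer_medians = layer_medians.loc[layer_order]
    values = layer_medians.to_numpy(dtype=float)
    half = len(values) // 2
    if half < 2 or len(values) - half < 2:
        raise ValueError("need at least 2 layers in each half")
    return unpaired_t(values[:half], values[half:])


def select_peak_layer(
    layer_medians: "pd.Series | dict[str, float]", layer_order: list[str] | None = None
) -> tuple[str, float, float | None]:
    """Layer with the largest median corrected fit; ties break earlier."""
    if isinstance(layer_medians, dict):
        layer_medians = pd.Series(layer_medians)
    if layer_order is not None:
        layer_medians = layer_medians.loc[layer_order]
    if len(layer_medians) == 0:
        raise ValueError("no fitted layers")
    values = layer_medians.to_numpy(dtype=float)
    best = int(np.nanargmax(values))  # argmax returns the first maximum -> earlier layer
    return str(layer_medians.index[best]), float(values[best]), None


class NeuralEncodingModel:
    """Layer-to-electrode encoding analysis for one region.

    Parameters
    ----------
    layer_features : mapping of layer name -> FeatureMatrix
        Insertion order defines the layer order (used for the early/late
        contrast and tie-breaks).
    electrodes : ElectrodeSet
    reliability_floor : float
        Electrodes with split-half reliability below this are excluded from
        noise correction and medians.
    """

    def __init__(
        self,
        layer_features: dict[str, FeatureMatrix],
        electrodes: ElectrodeSet,
        reliability_floor: float = 0.1,
    ):
        if electrodes.n_electrodes == 0:
            raise ValueError("empty electrode set: refusing to fit")
        for layer, fm in layer_features.items():
            if list(fm.image_ids) != list(electrodes.image_ids):
                raise ValueError(f"image ids of layer {layer!r} do not match the electrodes")
        self.layer_features = dict(layer_features)
        self.layer_order = list(layer_features)
        self.electrodes = electrodes
        self.reliability_floor = reliability_floor

    def fit(
        self,
        n_folds: int = 5,
        ridge_grid=DEFAULT_RIDGE_GRID,
        n_reliability_iter: int = 100,
        seed: int = 0,
    ) -> "NeuralEncodingResults":
        reliability = estimate_reliability(self.electrodes.responses, n_iter=n_reliability_iter, seed=seed)
        reliability = np.atleast_1d(reliability)
        mean_resp = self.electrodes.mean_over_repetitions()
        fits: dict[str, LayerFitResult] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for layer in self.layer_order:
                raw = fit_electrode_map(
                    self.layer_features[layer], mean_resp, n_folds=n_folds, ridge_grid=ridge_grid, seed=seed
                )
                corrected = noise_correct(raw, reliability, floor=self.reliability_floor)
                fits[layer] = LayerFitResult(
                    layer=layer,
                    region_label=self.electrodes.region_label,
                    per_electrode_r=raw,
                    per_electrode_r_corrected=np.atleast_1d(corrected),
                    reliability=reliability,
                    reliability_floor=self.reliability_floor,
                )
        return NeuralEncodingResults(model=self, layer_fits=fits)


@dataclass
class NeuralEncodingResults:
    model: NeuralEncodingModel
    layer_fits: dict[str, LayerFitResult]
    _medians: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self._medians = pd.Series(
            {layer: fit.median_r_corrected for layer, fit in self.layer_fits.items()},
            name="median_r_corrected",
        )

    @property
    def layer_medians(self) -> pd.Series:
        return self._medians

    def peak_layer(self) -> tuple[str, float, float]:
        layer, median, _ = select_peak_layer(self._medians, self.model.layer_order)
        return layer, median, self.layer_fits[layer].dispersion

    def contrast_layer_halves(self) -> StatResult:
        return contrast_layer_halves(self._medians, self.model.layer_order)

    def summary(self) -> pd.DataFrame:
        rows = []
        for layer in self.model.layer_order:
            fit = self.layer_fits[layer]
            rows.append(
                {
                    "layer": layer,
                    "region": fit.region_label,
                    "median_r_corrected": fit.median_r_corrected,
                    "sd": fit.dispersion,
                    "n_electrodes": int(fit.included.sum()),
                    "n_corrected_above_1": fit.n_exceeding_unity,
                }
            )
        return pd.DataFrame(rows)

    def plot_layer_profile(self, ax=None, color="k"):
        """Median noise-corrected fit per layer, +/- SD across electrodes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3))
        medians = [self.layer_fits[l].median_r_corrected for l in self.model.layer_order]
        sds = [self.layer_fits[l].dispersion for l in self.model.layer_order]
        x = np.arange(len(medians))
        ax.errorbar(x, medians, yerr=sds, color=color, marker="o", ms=3, capsize=2)
        ax.set_xticks(x, self.model.layer_order, rotation=45)
        ax.set_ylabel("median noise-corrected r")
        ax.set_xlabel("model layer")
        return ax

    def per_electrode_frame(self) -> pd.DataFrame:
        rows = []
        for layer in self.model.layer_order:
            fit = self.layer_fits[layer]
            for e, eid in enumerate(self.model.electrodes.electrode_ids):
                rows.append(
                    {
                        "layer": layer,
                        "electrode_id": eid,
                        "r_raw": fit.per_electrode_r[e],
                        "reliability": fit.reliability[e],
                        "r_corrected": fit.per_electrode_r_corrected[e],
                        "included": bool(fit.included[e]),
                    }
                )
        return pd.DataFrame(rows)
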
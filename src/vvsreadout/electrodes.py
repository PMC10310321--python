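"""Simulated electrodes: noisy linear mixtures of a known encoder layer.

Each electrode's expected response is a fixed random linear combination of the
generating layer's features; repetition noise is i.i.d. Gaussian.  With the
signal standardized to unit variance (the default), ``noise_sd`` is directly
interpretable in signal-SD units, which makes split-half reliabilities and
signal-attenuation predictions analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for
from .encoders import FeatureMatrix

__all__ = ["ElectrodeSet", "simulate_electrodes"]


@dataclass
class ElectrodeSet:
    """responses: n_images x n_electrodes x n_repetitions."""

    responses: np.ndarray
    image_ids: list[str]
    generating_layer: str
    mixing_weights: np.ndarray  # d x n_electrodes
    noise_sd: float
    region_label: str = "IT-like"
    electrode_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 3:
            raise ValueError("responses must be n_images x n_electrodes x n_repetitions")
        if self.responses.shape[0] != len(self.image_ids):
            raise ValueError("first axis must align with image_ids")
        if not self.electrode_ids:
            self.electrode_ids = [f"e{j:03d}" for j in range(self.n_electrodes)]

    @property
    def n_images(self) -> int:
        return self.responses.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.responses.shape[1]

    @property
    def n_repetitions(self) -> int:
        return self.responses.shape[2]

    def mean_over_repetitions(self) -> np.ndarray:
        return self.responses.mean(axis=2)

    def save(self, path: str | Path) -> Path:
        """Persist as ``<path>.npz`` plus a CSV manifest ``<path>_electrodes.csv``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path.with_suffix(".npz"),
            responses=self.responses,
            mixing_weights=self.mixing_weights,
            image_ids=np.array(self.image_ids),
            generating_layer=self.generating_layer,
            noise_sd=self.noise_sd,
            region_label=self.region_label,
        )
        pd.DataFrame({"electrode_id": self.electrode_ids, "region_label": self.region_label}).to_csv(
            path.with_name(path.stem + "_electrodes.csv"), index=False
        )
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ElectrodeSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz"), allow_pickle=False) as data:
            obj = cls(
                responses=data["responses"],
                image_ids=[str(s) for s in data["image_ids"]],
                generating_layer=str(data["generating_layer"]),
                mixing_weights=data["mixing_weights"],
                noise_sd=float(data["noise_sd"]),
                region_label=str(data["region_label"]),
            )
        manifest = path.with_name(path.stem + "_electrodes.csv")
        if manifest.exists():
            obj.electrode_ids = pd.read_csv(manifest)["electrode_id"].astype(str).tolist()
        return obj


def simulate_electrodes(
    features: FeatureMatrix,
    n_electrodes: int,
    n_repetitions: int,
    noise_sd: float,
    seed: int = 0,
    region_label: str = "IT-like",
    mixing: str = "pca",
    n_components: int = 10,
    normalize_signal: bool = True,
) -> ElectrodeSet:
    """response[i, e, r] = w_e . features[i] + Normal(0, noise_sd).

    Mixing weights are drawn once per electrode from its own seed stream, so
    adding electrodes never changes existing ones.  Two mixing models:

    * ``pca`` (default): w_e is a random combination of the generating
      layer's top ``n_components`` principal directions.  Population activity
      recorded by an electrode reflects the shared (low-rank) covariance of
      nearby neurons, so the simulated signal lives in the layer's dominant
      variance subspace — which is also what makes the generating layer
      identifiable by encoding-model fits.
    * ``dense``: w_e is i.i.d. Gaussian over all feature dimensions.

    With ``normalize_signal`` each electrode's noiseless signal is
    standardized to mean 0, SD 1 across images, so ``noise_sd`` is in
    signal-SD units and split-half reliabilities are analytic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_repetitions < 2:
        raise ValueError("n_repetitions must be >= 2 (needed for noise-ceiling estimation)")
    if n_electrodes < 0:
        raise ValueError("n_electrodes must be >= 0")
    if mixing not in ("pca", "dense"):
        raise ValueError("mixing must be 'pca' or 'dense'")

    X = features.matrix
    n_images, d = X.shape
    basis = None
    if mixing == "pca" and n_electrodes > 0:
        Xc = X - X.mean(axis=0)
        k = min(n_components, n_images - 1, d)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        basis = vt[:k].T  # d x k principal directions
    responses = np.zeros((n_images, n_electrodes, n_repetitions))
    weights = np.zeros((d, n_electrodes))
    for e in range(n_electrodes):
        erng = rng_for(seed, "electrode", e)
        if mixing == "pca":
            w = basis @ erng.normal(0.0, 1.0, basis.shape[1])
        else:
            w = erng.normal(0.0, 1.0 / np.sqrt(d), d)
        signal = (X - X.mean(axis=0)) @ w
        if normalize_signal:
            sd = signal.std()
            if sd > 0:
                signal = signal / sd
                w = w / sd  # keep the stored weights consistent with the signal scale
        noise = erng.normal(0.0, noise_sd, (n_images, n_repetitions)) if noise_sd > 0 else 0.0
        responses[:, e, :] = signal[:, None] + noise
        weights[:, e] = w
    return ElectrodeSet(
        responses=responses,
        image_ids=list(features.image_ids),
        generating_layer=features.source,
        mixing_weights=weights,
        noise_sd=noise_sd,
        region_label=region_label,
    )
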
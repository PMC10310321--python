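"""Image preprocessing, layer-indexed encoders, and feature matrices.

The encoder contract mirrors how convolutional networks are used as proxies
for the ventral visual stream: an ordered list of named layers, with
``encode(image, layer)`` returning a deterministic flat feature vector.  Three
encoders satisfy the contract:

* ``RandomConvEncoder`` — a seeded random-weight convolutional network
  (10 named layers, ``conv1`` ... ``fc6``); no downloads, fully deterministic.
* ``PixelEncoder`` / ``flatten_pixels`` — the vectorized-image baseline.
* ``TorchvisionEncoder`` — optional adapter for a locally available
  pretrained object-classification network (VGG-family layer names such as
  ``pool3``, ``conv5_1``, ``fc6``); import-guarded, never downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from ._rng import rng_for
from .stimuli import StimulusSet

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "preprocess_image",
    "ImageEncoder",
    "RandomConvEncoder",
    "PixelEncoder",
    "TorchvisionEncoder",
    "FeatureMatrix",
    "extract_features",
    "extract_feature_layers",
    "flatten_pixels",
    "get_encoder",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def preprocess_image(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Bilinear-resize to ``size`` x ``size`` and channel-normalize.

    Uses the standard computer-vision pipeline: per-channel subtraction of the
    mean (0.485, 0.456, 0.406) and division by the SD (0.229, 0.224, 0.225).
    Resize is bilinear (order-1 spline, edge-clamped, no anti-alias filter) —
    the convention matching common pretrained-model preprocessing.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    if image.shape[0] != size or image.shape[1] != size:
        image = _sk_resize(image, (size, size), order=1, mode="edge", anti_aliasing=False)
    return (image - IMAGENET_MEAN) / IMAGENET_STD


@dataclass
class FeatureMatrix:
    """Per-image feature vectors: rows aligned 1:1 with ``image_ids``."""

    matrix: np.ndarray
    image_ids: list[str]
    source: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.image_ids):
            raise ValueError("rows must align 1:1 with image_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_images(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def rows(self, image_ids: list[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.image_ids)}
        missing = [iid for iid in image_ids if iid not in lookup]
        if missing:
            raise KeyError(f"feature rows missing for image ids: {missing}")
        return self.matrix[[lookup[iid] for iid in image_ids]]

    def save(self, path: str | Path) -> Path:
        """Persist as ``<path>.npy`` plus a JSON sidecar ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path.with_suffix(".npy"), self.matrix)
        sidecar = {"source": self.source, "image_ids": list(self.image_ids)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path.with_suffix(".npy")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        matrix = np.load(path.with_suffix(".npy"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(matrix=matrix, image_ids=sidecar["image_ids"], source=sidecar["source"])

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(self.matrix, index=pd.Index(self.image_ids, name="image_id"))
        frame.to_csv(path)
        return path


class ImageEncoder:
    """Contract: named, ordered layers; deterministic ``encode``."""

    name: str = "encoder"
    layers: list[str] = []

    def encode(self, image: np.ndarray, layer: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def feature_dim(self, layer: str) -> int:
        probe = np.zeros((224, 224, 3))
        return self.encode(probe, layer).size

    def first_half_layers(self) -> list[str]:
        """The floor(L/2) earliest layers of the declared order."""
        return self.layers[: len(self.layers) // 2]

    def _check_layer(self, layer: str) -> None:
        if layer not in self.layers:
            raise ValueError(f"unknown layer {layer!r}; available layers: {self.layers}")


def _im2col_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: H x W x Cin, w: k x k x Cin x Cout -> relu(conv) via patch matmul."""
    k = w.shape[0]
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)), mode="constant")
    H, W, cin = x.shape
    out_h = (H - k) // stride + 1
    out_w = (W - k) // stride + 1
    s0, s1, s2 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(out_h, out_w, k, k, cin),
        strides=(s0 * stride, s1 * stride, s0, s1, s2),
        writeable=False,
    )
    cols = patches.reshape(out_h * out_w, k * k * cin)
    out = cols @ w.reshape(k * k * cin, -1) + b
    return np.maximum(out, 0.0).reshape(out_h, out_w, -1)


def _coarse_pool(x: np.ndarray, grid: int = 2) -> np.ndarray:
    """Adaptive grid x grid average pooling over space, channels preserved."""
    H, W, _ = x.shape
    hs = np.linspace(0, H, grid + 1).round().astype(int)
    ws = np.linspace(0, W, grid + 1).round().astype(int)
    cells = [
        x[hs[i]:hs[i + 1], ws[j]:ws[j + 1]].mean(axis=(0, 1))
        for i in range(grid)
        for j in range(grid)
    ]
    return np.concatenate(cells)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    H, W, C = x.shape
    x = x[: H - H % 2, : W - W % 2]
    return x.reshape(H // 2, 2, W // 2, 2, C).max(axis=(1, 3))


class RandomConvEncoder(ImageEncoder):
    """Seeded random-weight convolutional encoder with 10 named layers.

    Architecture (input 224 x 224 x 3, He-initialized weights, ReLU):
    conv1 (5x5/2, 8ch) -> pool1 -> conv2 (3x3, 16ch) -> pool2 -> conv3 (3x3,
    32ch) -> pool3 -> conv4 (3x3, 32ch) -> pool4 -> conv5 (3x3, 64ch) -> fc6
    (fully connected, 256 units, on 2x2 adaptive-average-pooled conv5).
    Untrained, but its pooled rectified filter responses expose local
    spatial-frequency structure (e.g. contour spikiness) in a
    position-tolerant way, which is what the synthetic category signal is
    made of; the coarse 2x2 pooling before fc6 keeps that tolerance while
    leaving enough spatial structure for encoding-model fits.
    """

    def __init__(self, seed: int = 0, fc_dim: int = 256):
        self.name = f"random-cnn-{seed}"
        self.seed = seed
        self.layers = [
            "conv1",
            "pool1",
            "conv2",
            "pool2",
            "conv3",
            "pool3",
            "conv4",
            "pool4",
            "conv5",
            "fc6",
        ]
        spec = [("conv1", 5, 3, 8, 2), ("conv2", 3, 8, 16, 1), ("conv3", 3, 16, 32, 1),
                ("conv4", 3, 32, 32, 1), ("conv5", 3, 32, 64, 1)]
        self._convs = {}
        for name, k, cin, cout, stride in spec:
            rng = rng_for(seed, "weights", name)
            w = rng.normal(0.0, np.sqrt(2.0 / (k * k * cin)), (k, k, cin, cout))
            self._convs[name] = (w, np.zeros(cout), stride)
        rng = rng_for(seed, "weights", "fc6")
        self._fc6_w = rng.normal(0.0, np.sqrt(2.0 / (4 * 64)), (4 * 64, fc_dim))

    def _forward(self, image: np.ndarray, upto: str) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64)
        if x.shape[:2] != (224, 224):
            raise ValueError("RandomConvEncoder expects preprocessed 224 x 224 x 3 input")
        pad = {"conv1": 2, "conv2": 1, "conv3": 1, "conv4": 1, "conv5": 1}
        for layer in self.layers:
            if layer.startswith("conv"):
                w, b, stride = self._convs[layer]
                x = _im2col_conv(x, w, b, stride, pad[layer])
            elif layer.startswith("pool"):
                x = _maxpool2(x)
            elif layer == "fc6":
                x = np.maximum(_coarse_pool(x, grid=2) @ self._fc6_w, 0.0)
            if layer == upto:
                return x
        raise AssertionError(upto)

    def encode(self, image: np.ndarray, layer: str) -> np.ndarray:
        self._check_layer(layer)
        return self._forward(image, layer).reshape(-1)

    def encode_layers(self, image: np.ndarray, layers: list[str]) -> dict[str, np.ndarray]:
        """All requested layers from a single forward pass."""
        for layer in layers:
            self._check_layer(layer)
        wanted = set(layers)
        out: dict[str, np.ndarray] = {}
        x = np.asarray(image, dtype=np.float64)
        if x.shape[:2] != (224, 224):
            raise ValueError("RandomConvEncoder expects preprocessed 224 x 224 x 3 input")
        pad = {"conv1": 2, "conv2": 1, "conv3": 1, "conv4": 1, "conv5": 1}
        for layer in self.layers:
            if layer.startswith("conv"):
                w, b, stride = self._convs[layer]
                x = _im2col_conv(x, w, b, stride, pad[layer])
            elif layer.startswith("pool"):
                x = _maxpool2(x)
            elif layer == "fc6":
                x = np.maximum(_coarse_pool(x, grid=2) @ self._fc6_w, 0.0)
            if layer in wanted:
                out[layer] = x.reshape(-1)
            if len(out) == len(wanted):
                break
        return out


class PixelEncoder(ImageEncoder):
    """The vectorized-image baseline, exposed under the encoder contract."""

    def __init__(self, resize_to: int | None = None):
        self.name = "pixels"
        self.layers = ["pixels"]
        self.resize_to = resize_to

    def encode(self, image: np.ndarray, layer: str = "pixels") -> np.ndarray:
        self._check_layer(layer)
        image = np.asarray(image, dtype=np.float64)
        if self.resize_to is not None and image.shape[:2] != (self.resize_to, self.resize_to):
            image = _sk_resize(image, (self.resize_to, self.resize_to), order=1,
                               mode="edge", anti_aliasing=False)
        return image.reshape(-1)


class TorchvisionEncoder(ImageEncoder):
    """Adapter for a locally installed pretrained VGG-family network.

    Requires ``torchvision`` and local weights; never downloads.  Provided for
    users replicating the analyses with a task-optimized network; the bundled
    random-weight encoder is the default fixture everywhere else.
    """

    def __init__(self, weights_path: str | None = None, arch: str = "vgg16"):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "TorchvisionEncoder needs torch/torchvision installed locally; "
                "use RandomConvEncoder or PixelEncoder otherwise"
            ) from exc
        raise NotImplementedError(
            "pretrained adapter is a replication path; supply weights locally and "
            "subclass ImageEncoder if your torchvision version differs"
        )


def extract_features(encoder: ImageEncoder, stimuli: StimulusSet, layer: str) -> FeatureMatrix:
    """Row i = encoder.encode(preprocess_image(image_i), layer), in stimulus order."""
    encoder._check_layer(layer)
    rows = [encoder.encode(preprocess_image(arr), layer) for _, arr in stimuli]
    return FeatureMatrix(
        matrix=np.vstack(rows),
        image_ids=stimuli.image_ids,
        source=f"{encoder.name}:{layer}",
    )


def extract_feature_layers(
    encoder: ImageEncoder, stimuli: StimulusSet, layers: list[str] | None = None
) -> dict[str, FeatureMatrix]:
    """FeatureMatrix per layer, sharing forward passes when the encoder allows."""
    layers = list(encoder.layers) if layers is None else layers
    if hasattr(encoder, "encode_layers"):
        per_layer: dict[str, list[np.ndarray]] = {layer: [] for layer in layers}
        for _, arr in stimuli:
            feats = encoder.encode_layers(preprocess_image(arr), layers)
            for layer in layers:
                per_layer[layer].append(feats[layer])
        return {
            layer: FeatureMatrix(np.vstack(rows), stimuli.image_ids, f"{encoder.name}:{layer}")
            for layer, rows in per_layer.items()
        }
    return {layer: extract_features(encoder, stimuli, layer) for layer in layers}


def flatten_pixels(stimuli: StimulusSet, resize_to: int | None = None) -> FeatureMatrix:
    """Flatten raw images row-major (optionally resized first); source 'pixels'."""
    enc = PixelEncoder(resize_to=resize_to)
    rows = [enc.encode(arr) for _, arr in stimuli]
    return FeatureMatrix(matrix=np.vstack(rows), image_ids=stimuli.image_ids, source="pixels")


def get_encoder(name: str, seed: int = 0) -> ImageEncoder:
    """Factory used by the CLI: {random-cnn | pixels | pretrained}."""
    if name == "random-cnn":
        return RandomConvEncoder(seed=seed)
    if name == "pixels":
        return PixelEncoder()
    if name == "pretrained":
        return TorchvisionEncoder()
    raise ValueError(f"unknown encoder {name!r}; choose random-cnn, pixels, or pretrained")
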
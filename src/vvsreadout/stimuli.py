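"""Synthetic morph-sequence and oddity stimuli with known ground truth.

The generators here stand in for a deposited psychophysics stimulus set: each
morph sequence is a discrete pixel-space interpolation between a sequence-
specific "cat" prototype and "dog" prototype shape, rendered on a noise
background.  Categories differ only in the amplitude of high-spatial-frequency
contour harmonics (smooth blob vs spiky blob); low-frequency shape, fill
intensity and enclosed area carry no category information, so a linear pixel
readout cannot exploit a trivial global cue.

``colinearity`` controls how much of a sequence's identity — its background
texture and position jitter — is shared across morph levels within the
sequence.  High colinearity makes images within a sequence linearly related in
pixel space (adjacent morph levels are highly similar), which is exactly the
property that lets naive pixel readouts succeed under random train/test splits
while failing when whole sequences are held out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from ._rng import rng_for

__all__ = ["StimulusSet", "generate_morph_stimuli", "generate_oddity_pool"]

# contour harmonics: low-frequency terms shape the blob identically for both
# categories; the high-frequency terms are the category-relevant signal
_LOW_K = (2, 3, 4, 5)
_HIGH_K = (9, 11, 13)
_ALL_K = _LOW_K + _HIGH_K


@dataclass
class StimulusSet:
    """Images indexed by (experiment, sequence, morph level) or (object, view).

    ``images`` fixes the iteration order all downstream feature extraction
    uses.  For morph stimuli the category rule is label 1 ("dog") iff
    ``morph_level_pct > 50``, label 0 ("cat") iff ``< 50``; images at exactly
    50 carry an explicit label assigned at generation time.
    """

    images: list[tuple[str, np.ndarray]]
    index: dict[str, tuple]
    kind: str = "morph"  # "morph" | "oddity"
    explicit_labels: dict[str, int] = field(default_factory=dict)

    # -- accessors -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.images)

    @property
    def image_ids(self) -> list[str]:
        return [iid for iid, _ in self.images]

    def image_array(self, image_id: str) -> np.ndarray:
        for iid, arr in self.images:
            if iid == image_id:
                return arr
        raise KeyError(image_id)

    def category_label(self, image_id: str) -> int:
        if self.kind != "morph":
            raise ValueError("category labels are defined for morph stimuli only")
        level = self.index[image_id][2]
        if level > 50:
            return 1
        if level < 50:
            return 0
        return self.explicit_labels[image_id]

    def labels(self) -> np.ndarray:
        return np.array([self.category_label(iid) for iid in self.image_ids])

    def morph_levels(self) -> np.ndarray:
        return np.array([self.index[iid][2] for iid in self.image_ids])

    def sequence_ids(self) -> np.ndarray:
        return np.array([self.index[iid][1] for iid in self.image_ids])

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "morph":
            rows = [
                {
                    "image_id": iid,
                    "experiment_id": self.index[iid][0],
                    "sequence_id": self.index[iid][1],
                    "morph_level_pct": self.index[iid][2],
                    "label": self.category_label(iid),
                }
                for iid in self.image_ids
            ]
        else:
            rows = [
                {"image_id": iid, "object_id": self.index[iid][0], "view_id": self.index[iid][1]}
                for iid in self.image_ids
            ]
        return pd.DataFrame(rows)

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        ids = self.image_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids")
        if set(ids) != set(self.index):
            raise ValueError("index and images disagree on image ids")
        shapes = {arr.shape for _, arr in self.images}
        if len(shapes) > 1:
            raise ValueError(f"images differ in shape: {shapes}")
        for _, arr in self.images:
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ValueError("images must be H x W x 3")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("pixel values must lie in [0, 1]")
        if self.kind == "morph":
            seqs: dict[tuple, list[int]] = {}
            for iid in ids:
                exp, seq, lev = self.index[iid]
                seqs.setdefault((exp, seq), []).append(lev)
            for key, levels in seqs.items():
                if any(b <= a for a, b in zip(levels, levels[1:])):
                    raise ValueError(f"morph levels not strictly increasing in {key}")
            for iid in ids:
                self.category_label(iid)  # raises if a 50% image lacks a label

    # -- I/O -----------------------------------------------------------------
    def to_dir(self, root: str | Path) -> Path:
        """Write PNGs as ``<root>/<experiment>/<sequence>/<level>.png`` (morph)
        or ``<root>/objects/<object_id>/<view_id>.png`` (oddity), plus an
        ``index.csv`` manifest preserving explicit midpoint labels."""
        root = Path(root)
        for iid, arr in self.images:
            if self.kind == "morph":
                exp, seq, lev = self.index[iid]
                path = root / str(exp) / str(seq) / f"{lev:03d}.png"
            else:
                obj, view = self.index[iid]
                path = root / "objects" / str(obj) / f"{view}.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(path)
        self.to_frame().to_csv(root / "index.csv", index=False)
        return root

    @classmethod
    def from_dir(cls, root: str | Path) -> "StimulusSet":
        root = Path(root)
        manifest = root / "index.csv"
        if not manifest.exists():
            raise FileNotFoundError(f"no index.csv manifest under {root}")
        frame = pd.read_csv(manifest)
        kind = "oddity" if "object_id" in frame.columns else "morph"
        images, index, explicit = [], {}, {}
        for row in frame.itertuples(index=False):
            if kind == "morph":
                path = root / str(row.experiment_id) / str(row.sequence_id) / f"{row.morph_level_pct:03d}.png"
                index[row.image_id] = (row.experiment_id, row.sequence_id, int(row.morph_level_pct))
                if int(row.morph_level_pct) == 50:
                    explicit[row.image_id] = int(row.label)
            else:
                path = root / "objects" / str(row.object_id) / f"{row.view_id}.png"
                index[row.image_id] = (row.object_id, row.view_id)
            arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
            images.append((row.image_id, arr))
        return cls(images=images, index=index, kind=kind, explicit_labels=explicit)


# ---------------------------------------------------------------------------
# rendering


def _render_blob(size, amps, phases, base_radius, center, rotation, color, background):
    """Render a star-polygon blob r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k)).

    The base radius is rescaled so the enclosed area is independent of the
    harmonic amplitudes (area of r(theta) integrates to pi R^2 (1 + sum a^2/2)),
    removing mean-luminance category cues.
    """
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    dx, dy = xx - center[0], yy - center[1]
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx) - rotation
    modulation = np.ones_like(rho)
    for k, a, phi in zip(_ALL_K, amps, phases):
        modulation += a * np.cos(k * theta + phi)
    radius = base_radius / np.sqrt(1.0 + 0.5 * float(np.sum(np.square(amps)))) * modulation
    edge = 1.5 * (2.0 / size)  # ~1.5 px soft edge for anti-aliasing
    mask = np.clip((radius - rho) / edge + 0.5, 0.0, 1.0)
    img = background * (1.0 - mask[..., None]) + color[None, None, :] * mask[..., None]
    return np.clip(img, 0.0, 1.0)


def _noise_texture(size: int, rng: np.random.Generator, sigma_frac: float = 1 / 16) -> np.ndarray:
    """Smooth zero-mean noise field, unit SD, replicated over RGB."""
    field2d = gaussian_filter(rng.standard_normal((size, size)), sigma=size * sigma_frac)
    sd = field2d.std()
    if sd > 0:
        field2d /= sd
    return field2d[..., None].repeat(3, axis=2)


def _sequence_label(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    label = ""
    i0 = i
    while True:
        label = chr(ord("A") + i0 % 26) + label
        i0 = i0 // 26 - 1
        if i0 < 0:
            return label


def generate_morph_stimuli(
    n_sequences: int = 7,
    n_levels: int = 11,
    image_size: int = 64,
    colinearity: float = 0.9,
    seed: int = 0,
    experiment_id: str = "exp1",
) -> StimulusSet:
    """Generate ``n_sequences`` discrete cat-to-dog morph sequences.

    Each sequence interpolates the contour-harmonic amplitudes of a smooth
    "cat" prototype toward a spiky "dog" prototype; morph level ``p`` blends
    with weight ``p/100``.  Deterministic given ``seed``.
    """
    if n_sequences < 1 or n_levels < 2 or image_size < 32:
        raise ValueError("need n_sequences >= 1, n_levels >= 2, image_size >= 32")
    if not 0.0 <= colinearity <= 1.0:
        raise ValueError("colinearity must lie in [0, 1]")

    levels = np.unique(np.round(np.linspace(0, 100, n_levels)).astype(int))
    images: list[tuple[str, np.ndarray]] = []
    index: dict[str, tuple] = {}
    explicit: dict[str, int] = {}

    for s in range(n_sequences):
        seq = _sequence_label(s)
        srng = rng_for(seed, "morph-seq", s)
        # low-frequency shape: same distribution for both prototypes (no
        # category signal); high-frequency spikes: the category signal
        cat_amps = np.concatenate([srng.normal(0.08, 0.02, len(_LOW_K)), np.full(len(_HIGH_K), 0.005)])
        dog_amps = np.concatenate([srng.normal(0.08, 0.02, len(_LOW_K)), srng.normal(0.22, 0.015, len(_HIGH_K))])
        phases = srng.uniform(0, 2 * np.pi, len(_ALL_K))
        base_radius = srng.uniform(0.43, 0.47)
        rotation = srng.uniform(0, 2 * np.pi)
        color = np.clip(0.82 + srng.normal(0, 0.01, 3), 0, 1)
        seq_offset = srng.normal(0.0, 0.09, 2)
        seq_texture = _noise_texture(image_size, srng)
        for lev in levels:
            irng = rng_for(seed, "morph-img", s, int(lev))
            t = lev / 100.0
            amps = (1 - t) * cat_amps + t * dog_amps
            img_offset = irng.normal(0.0, 0.09, 2)
            center = colinearity * seq_offset + (1 - colinearity) * img_offset
            img_texture = _noise_texture(image_size, irng)
            texture = np.sqrt(colinearity) * seq_texture + np.sqrt(1 - colinearity) * img_texture
            background = np.clip(0.45 + 0.10 * texture, 0, 1)
            arr = _render_blob(image_size, amps, phases, base_radius, center, rotation, color, background)
            iid = f"{experiment_id}_{seq}_{lev:03d}"
            images.append((iid, arr))
            index[iid] = (experiment_id, seq, int(lev))
            if lev == 50:
                explicit[iid] = s % 2  # alternating midpoint label per sequence
    out = StimulusSet(images=images, index=index, kind="morph", explicit_labels=explicit)
    out.validate()
    return out


def generate_oddity_pool(
    n_objects: int = 32,
    n_views: int = 20,
    image_size: int = 64,
    seed: int = 0,
) -> StimulusSet:
    """Render ``n_objects`` parametric shapes at ``n_views`` random in-plane
    rotations, each on an independently sampled noise background."""
    if n_objects < 2:
        raise ValueError("need at least 2 objects to define an oddity")
    if n_views < 4:
        raise ValueError("need at least 4 views per object")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")

    images: list[tuple[str, np.ndarray]] = []
    index: dict[str, tuple] = {}
    for o in range(n_objects):
        obj = f"obj{o:02d}"
        orng = rng_for(seed, "oddity-obj", o)
        amps = np.abs(orng.normal(0.0, 0.07, len(_ALL_K)))
        phases = orng.uniform(0, 2 * np.pi, len(_ALL_K))
        base_radius = orng.uniform(0.38, 0.52)
        color = np.clip(0.82 + orng.normal(0, 0.03, 3), 0, 1)
        for v in range(n_views):
            vrng = rng_for(seed, "oddity-view", o, v)
            rotation = vrng.uniform(0, 2 * np.pi)
            center = vrng.normal(0.0, 0.05, 2)
            background = np.clip(0.45 + 0.10 * _noise_texture(image_size, vrng), 0, 1)
            arr = _render_blob(image_size, amps, phases, base_radius, center, rotation, color, background)
            iid = f"{obj}_v{v:02d}"
            images.append((iid, arr))
            index[iid] = (obj, f"v{v:02d}")
    out = StimulusSet(images=images, index=index, kind="oddity")
    out.validate()
    return out
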
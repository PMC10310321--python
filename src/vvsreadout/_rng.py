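"""Counter-based seed derivation.

Every stochastic operation in this package takes a single integer seed and
derives independent streams for each logical entity (sequence, image,
electrode, subject, iteration ...) from ``(seed, stream labels)``.  Because
each entity owns its own stream, adding entities (more electrodes, more
subjects) never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["rng_for", "derive_seed"]


def _label_words(labels: tuple) -> list[int]:
    """Map arbitrary hashable labels to stable uint32 words via SHA-256."""
    words: list[int] = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            words.append(int(lab) & 0xFFFFFFFF)
        else:
            digest = hashlib.sha256(str(lab).encode("utf-8")).digest()
            words.append(int.from_bytes(digest[:4], "little"))
    return words


def rng_for(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *labels)``."""
    entropy = [int(seed) & 0x7FFFFFFF] + _label_words(labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *labels) -> int:
    """Derive a child integer seed (< 2**31) for a named stage."""
    payload = ":".join([str(int(seed))] + [str(lab) for lab in labels])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
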
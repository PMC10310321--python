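"""Exact Gram-preserving dimensionality reduction.

L2-penalized linear fits (ridge, logistic) depend on the training rows only
through inner products, and their predictions on any row in the common row
space are likewise inner-product functions.  Replacing an n x d feature
matrix (d >> n) by the n x r matrix U * S from its thin SVD therefore leaves
every fit and every prediction in this package numerically unchanged while
making the fits O(n^2) instead of O(n d).
"""

from __future__ import annotations

import numpy as np

__all__ = ["gram_reduce"]


def gram_reduce(X: np.ndarray, max_dim: int | None = None) -> np.ndarray:
    """Return Z with Z @ Z.T == X @ X.T (up to numerical precision).

    If d <= n (nothing to gain) the input is returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    limit = n if max_dim is None else min(n, max_dim)
    if d <= limit:
        return X
    gram = X @ X.T
    # symmetric eigendecomposition of the Gram matrix; clip tiny negatives
    vals, vecs = np.linalg.eigh(gram)
    vals = np.clip(vals[::-1], 0.0, None)
    vecs = vecs[:, ::-1]
    return vecs * np.sqrt(vals)[None, :]
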
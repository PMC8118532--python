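"""Principal-angle geometry between row spaces.

Used to quantify two facts about the shared embedding: the span of
``L @ D`` is stable across training seeds (despite the mixing ambiguity of
``L`` itself), and with a matched latent width it recovers the span of the
generative networks on synthetic data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["subspace_affinity", "random_subspace_affinity_null"]


def _orthonormal_rowspace(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) of the row space of ``M``."""
    M = np.asarray(M, dtype=float)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    return vt[:rank].T


def subspace_affinity(A: np.ndarray, B: np.ndarray) -> float:
    """Mean cosine of the principal angles between two row spaces.

    1.0 for identical subspaces; near ``sqrt(d/p)`` for random d-dim
    subspaces of an ambient p-dim space.
    """
    Qa = _orthonormal_rowspace(A)
    Qb = _orthonormal_rowspace(B)
    if Qa.shape[1] == 0 or Qb.shape[1] == 0:
        raise ValueError("zero-dimensional subspace")
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.mean(np.clip(s, 0.0, 1.0)))


def random_subspace_affinity_null(
    dim: int, ambient: int, n_draws: int = 200, seed: int = 0
) -> np.ndarray:
    """Null distribution of the affinity between independent random
    ``dim``-dimensional subspaces of an ``ambient``-dimensional space."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        A = rng.normal(size=(dim, ambient))
        B = rng.normal(size=(dim, ambient))
        out[i] = subspace_affinity(A, B)
    return out
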
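"""Shared k-means wrapper.

All clustering steps in the pipeline (expression rows k=7, accessibility
profiles k=3, hit rates k=2, motif similarity k=10) use the same rule:
Lloyd's algorithm with k-means++ initialization, best of ``restarts`` runs
by within-cluster sum of squares, deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans


def kmeans_rows(matrix, k: int, seed: int = 0, restarts: int = 10) -> np.ndarray:
    """Cluster matrix rows into k groups; returns integer labels."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    return km.fit_predict(X)
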
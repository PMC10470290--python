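"""Cross-method clustering agreement.

Subtype robustness is checked by re-clustering the scaled matrix with k-means
and Ward hierarchical clustering and quantifying agreement with the NMF
labels via unweighted Cohen's kappa after optimal (Hungarian) label
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = ["LabelAgreement", "cluster_baselines", "align_labels", "cohen_kappa"]


@dataclass
class LabelAgreement:
    aligned_confusion: np.ndarray
    observed_agreement: float
    expected_agreement: float
    kappa: float


def cluster_baselines(V_scaled, k: int, method: str = "kmeans", seed: int = 0) -> np.ndarray:
    """Partition samples (columns of ``V_scaled``) into k groups.

    ``kmeans`` uses 25 seeded restarts (re-seeded up to 5 times if a cluster
    comes back empty); ``hierarchical`` uses Euclidean distance with Ward
    linkage and is deterministic.
    """
    X = np.asarray(V_scaled, dtype=float).T  # samples × features
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    if method == "kmeans":
        for attempt in range(5):
            km = KMeans(n_clusters=k, n_init=25, random_state=seed + attempt)
            labels = km.fit_predict(X) + 1
            if np.unique(labels).size == k:
                return labels
        raise RuntimeError("k-means repeatedly produced an empty cluster")
    if method == "hierarchical":
        Z = linkage(X, method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(labels).size < k:
            raise ValueError(f"Ward cut produced fewer than {k} groups")
        return labels
    raise ValueError(f"unknown clustering method {method!r}")


def _confusion(a, b):
    la = np.unique(a)
    lb = np.unique(b)
    size = max(la.size, lb.size)
    conf = np.zeros((size, size), dtype=int)
    ia = {v: i for i, v in enumerate(la)}
    ib = {v: i for i, v in enumerate(lb)}
    for x, y in zip(a, b):
        conf[ia[x], ib[y]] += 1
    return conf, la, lb


def align_labels(a, b):
    """Relabel ``b`` to maximize agreement with ``a`` (optimal assignment).

    The confusion matrix is padded with zero rows/columns when the two
    labelings use different numbers of distinct labels. Returns the aligned
    copy of ``b``; equivalent to exhaustive search over permutations.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    conf, la, lb = _confusion(a, b)
    rows, cols = linear_sum_assignment(-conf)
    mapping = {}
    for r, c in zip(rows, cols):
        if c < lb.size:
            # map b's label lb[c] to a's label la[r] (or a fresh one if padded)
            mapping[lb[c]] = la[r] if r < la.size else lb[c]
    return np.asarray([mapping[x] for x in b])


def cohen_kappa(a, b_aligned) -> LabelAgreement:
    """Unweighted Cohen's kappa between two aligned label vectors.

    kappa = (p_o − p_e) / (1 − p_e) with p_o the observed agreement and p_e
    the chance agreement from the marginals. Two identical constant labelings
    have p_e = 1 and kappa is defined as 1 by convention.
    """
    a = np.asarray(a)
    b = np.asarray(b_aligned)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length label vectors with n >= 2")
    labels = np.unique(np.concatenate([a, b]))
    idx = {v: i for i, v in enumerate(labels)}
    conf = np.zeros((labels.size, labels.size), dtype=int)
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    n = a.size
    p_o = np.trace(conf) / n
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        kappa = 1.0
        p_e = 1.0 - np.finfo(float).eps  # keep the invariant field sane
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return LabelAgreement(
        aligned_confusion=conf,
        observed_agreement=float(p_o),
        expected_agreement=float(p_e),
        kappa=float(kappa),
    )


def agreement_with(a, b) -> LabelAgreement:
    """Convenience: align ``b`` to ``a`` then compute Cohen's kappa."""
    return cohen_kappa(a, align_labels(a, b))
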
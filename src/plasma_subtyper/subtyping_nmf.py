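"""Consensus non-negative matrix factorization subtyping.

The factorization V ≈ WH (V proteins × samples, entries ≥ 0) is fitted with
Brunet-style multiplicative updates for the generalized Kullback–Leibler
divergence D(V‖WH) = Σ V log(V/WH) − V + WH. Cluster stability over random
restarts is summarized by the consensus matrix (mean co-clustering indicator)
and its cophenetic correlation coefficient; the factorization rank is chosen
to maximize that coefficient over a candidate range. Representative
"metaproteins" per subtype are extracted with the Kim–Park entropy-based
feature score computed on the rows of W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import median_abs_deviation, pearsonr

__all__ = [
    "NMFFactors",
    "ConsensusNMFResult",
    "nmf_factorize",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
    "assign_subtypes",
    "metaprotein_scores",
]

_EPS = np.finfo(float).tiny


@dataclass
class NMFFactors:
    """One factorization: W (proteins × k), H (k × samples), KL objective trace."""

    W: np.ndarray
    H: np.ndarray
    divergence: float
    n_iter: int
    converged: bool
    divergence_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def sample_labels(self) -> np.ndarray:
        """Cluster label per sample: argmax over the columns of H (0-based)."""
        return np.argmax(self.H, axis=0)


@dataclass
class ConsensusNMFResult:
    """Full rank survey plus the final consensus fit."""

    rho_by_rank: dict                 # k -> cophenetic coefficient
    consensus_by_rank: dict           # k -> s×s consensus matrix
    selected_rank: int
    final_consensus: np.ndarray
    subtype_labels: pd.Series         # per sample, 1..k*
    metaproteins: pd.DataFrame        # protein_id, kim_park_score, subtype
    final_factors: NMFFactors


def _kl_divergence(V, WH):
    mask = V > 0
    div = np.sum(WH) - np.sum(V[mask])
    div += np.sum(V[mask] * np.log(V[mask] / WH[mask]))
    return float(div)


def nmf_factorize(
    V,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    check_every: int = 10,
    stall_limit: int = 40,
    init_W=None,
    init_H=None,
) -> NMFFactors:
    """Brunet multiplicative-update KL NMF with connectivity-stall stopping.

    W and H start uniform-random (seeded). Every ``check_every`` iterations the
    sample labels (argmax over H columns) are compared with the previous
    check; when they are unchanged for ``stall_limit`` consecutive checks the
    run stops, otherwise it caps at ``max_iter``. The KL divergence is
    recorded at each check and is non-increasing by construction of the
    updates.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if (V < 0).any() or np.isnan(V).any():
        raise ValueError("V must be nonnegative with no missing entries")
    f, s = V.shape
    if (V.sum(axis=1) == 0).any() or (V.sum(axis=0) == 0).any():
        raise ValueError("V must not contain all-zero rows or columns")
    if not (2 <= k < min(f, s)):
        raise ValueError(f"rank k={k} out of range [2, min(f, s))")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = np.array(init_W, dtype=float) if init_W is not None else rng.uniform(_EPS, 1.0, size=(f, k)) * scale
    H = np.array(init_H, dtype=float) if init_H is not None else rng.uniform(_EPS, 1.0, size=(k, s)) * scale
    if W.shape != (f, k) or H.shape != (k, s):
        raise ValueError("init_W/init_H shapes inconsistent with V and k")

    prev_labels = None
    stall = 0
    trace = []
    n_iter = 0
    converged = False
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        n_iter = it
        if it % check_every == 0 or it == max_iter:
            WH = np.maximum(W @ H, _EPS)
            trace.append(_kl_divergence(V, WH))
            labels = np.argmax(H, axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stall += 1
                if stall >= stall_limit:
                    converged = True
                    break
            else:
                stall = 0
            prev_labels = labels
    WH = np.maximum(W @ H, _EPS)
    return NMFFactors(
        W=W,
        H=H,
        divergence=_kl_divergence(V, WH),
        n_iter=n_iter,
        converged=converged,
        divergence_trace=np.asarray(trace),
    )


def consensus_matrix(V, k: int, n_restarts: int, base_seed: int = 0):
    """Mean co-clustering (connectivity) matrix over seeded random restarts.

    Restart ``i`` uses seed ``base_seed + i``. Restarts that hit the iteration
    cap without a stable connectivity are excluded with a warning; fewer than
    two usable restarts is an error. Returns ``(C, per_restart_labels)``.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be at least 2")
    V = np.asarray(V, dtype=float)
    s = V.shape[1]
    C = np.zeros((s, s))
    all_labels = []
    usable = 0
    for i in range(n_restarts):
        fit = nmf_factorize(V, k, seed=base_seed + i)
        if not fit.converged:
            warnings.warn(
                f"NMF restart {i} (k={k}) did not reach a stable connectivity; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        labels = fit.sample_labels
        all_labels.append(labels)
        C += (labels[:, None] == labels[None, :]).astype(float)
        usable += 1
    if usable < 2:
        raise RuntimeError(f"fewer than 2 usable NMF restarts at k={k}")
    C /= usable
    np.fill_diagonal(C, 1.0)
    return C, np.asarray(all_labels)


def cophenetic_coefficient(C) -> float:
    """Cophenetic correlation of the consensus-derived distance matrix.

    Average-linkage hierarchical clustering is run on the distances 1 − C; the
    coefficient is the Pearson correlation between the original off-diagonal
    distances and the dendrogram's cophenetic distances.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("consensus matrix must be symmetric with unit diagonal")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(np.clip(D, 0.0, None), checks=False)
    if np.allclose(d, d[0]):
        raise ValueError("constant distance matrix: cophenetic correlation undefined")
    Z = average(d)
    coph = cophenet(Z)
    if np.allclose(coph, coph[0]):
        # perfectly flat dendrogram cannot happen with non-constant d, guard anyway
        raise ValueError("degenerate dendrogram: cophenetic correlation undefined")
    rho = pearsonr(d, coph).statistic
    return float(rho)


def select_rank(V, k_range=range(2, 7), n_restarts: int = 50, base_seed: int = 0):
    """Survey ranks, pick the one maximizing the cophenetic coefficient.

    Ties break toward the smaller rank (parsimony). Returns
    ``(k_star, rho_by_rank, consensus_by_rank)``.
    """
    rho_by_rank = {}
    consensus_by_rank = {}
    for k in k_range:
        C, _ = consensus_matrix(V, k, n_restarts=n_restarts, base_seed=base_seed)
        consensus_by_rank[k] = C
        rho_by_rank[k] = cophenetic_coefficient(C)
    k_star = min(rho_by_rank, key=lambda k: (-rho_by_rank[k], k))
    return k_star, rho_by_rank, consensus_by_rank


def assign_subtypes(C, k: int, sample_ids=None) -> pd.Series:
    """Cut the average-linkage dendrogram of 1 − C into k subtype labels.

    Deterministic given the consensus matrix; labels are renumbered 1..k by
    first appearance. An empty group (cannot occur with maxclust on distinct
    heights, but guarded) raises.
    """
    C = np.asarray(C, dtype=float)
    d = squareform(np.clip(1.0 - C, 0.0, None), checks=False)
    Z = average(d)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if np.unique(raw).size < k:
        raise ValueError(f"average-linkage cut produced fewer than {k} groups; try a lower k")
    # stable renumber by first appearance
    order = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order) + 1
        labels[i] = order[r]
    index = sample_ids if sample_ids is not None else pd.RangeIndex(len(labels))
    return pd.Series(labels, index=index, name="subtype")


def kim_park_score(W) -> np.ndarray:
    """Entropy-based feature score on rows of W: 1 at degenerate, 0 at uniform.

    For row f with contributions q_a = W[f,a] / Σ_a W[f,a]:
    S(f) = 1 + (1/log2 k) Σ_a q_a log2 q_a, with 0·log 0 ≡ 0.
    """
    W = np.asarray(W, dtype=float)
    rowsum = W.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("all-zero W row: feature score undefined")
    q = W / rowsum[:, None]
    k = W.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
    return 1.0 + plogp.sum(axis=1) / np.log2(k)


def metaprotein_scores(
    W, protein_ids=None, threshold_policy: str = "median+3*MAD"
) -> pd.DataFrame:
    """Score every protein and flag metaproteins by a robust score threshold.

    Returns a DataFrame (index = protein ID) with columns ``kim_park_score``,
    ``subtype`` (1-based argmax of the W row) and ``is_metaprotein``
    (score ≥ median + 3·MAD under the default policy).
    """
    W = np.asarray(W, dtype=float)
    if W.shape[1] < 2:
        raise ValueError("metaprotein scoring needs k >= 2")
    scores = kim_park_score(W)
    if threshold_policy in ("median+3*MAD", "median+3·MAD"):
        thr = np.median(scores) + 3.0 * median_abs_deviation(scores, scale=1.0)
    elif threshold_policy == "mean+3*SD":
        thr = scores.mean() + 3.0 * scores.std(ddof=0)
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    index = protein_ids if protein_ids is not None else pd.RangeIndex(W.shape[0])
    return pd.DataFrame(
        {
            "kim_park_score": scores,
            "subtype": np.argmax(W, axis=1) + 1,
            "is_metaprotein": scores >= thr,
        },
        index=pd.Index(index, name="protein_id"),
    )


def consensus_subtyping(
    V,
    sample_ids=None,
    protein_ids=None,
    k_range=range(2, 7),
    n_restarts: int = 50,
    final_restarts: int = 200,
    base_seed: int = 0,
) -> ConsensusNMFResult:
    """Full procedure: rank survey, final consensus fit, labels, metaproteins.

    The survey uses ``n_restarts`` random restarts per rank; the final fit at
    the selected rank uses ``final_restarts`` restarts. Subtype labels come
    from hierarchical clustering of the final consensus matrix; W for
    metaprotein extraction comes from the best (lowest-divergence) final
    restart.
    """
    V = np.asarray(V, dtype=float)
    k_star, rho_by_rank, consensus_by_rank = select_rank(
        V, k_range=k_range, n_restarts=n_restarts, base_seed=base_seed
    )
    final_C, _ = consensus_matrix(V, k_star, n_restarts=final_restarts,
                                  base_seed=base_seed + 10_000)
    labels = assign_subtypes(final_C, k_star, sample_ids=sample_ids)
    best = None
    for i in range(min(final_restarts, 10)):
        fit = nmf_factorize(V, k_star, seed=base_seed + 10_000 + i)
        if best is None or fit.divergence < best.divergence:
            best = fit
    # permute factor columns so argmax-H components line up with consensus labels
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((k_star, k_star))
    for comp, lab in zip(best.sample_labels, labels.to_numpy()):
        conf[comp, lab - 1] += 1
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(k_star, dtype=int)
    perm[cols] = rows
    best = NMFFactors(
        W=best.W[:, perm],
        H=best.H[perm, :],
        divergence=best.divergence,
        n_iter=best.n_iter,
        converged=best.converged,
        divergence_trace=best.divergence_trace,
    )
    meta = metaprotein_scores(best.W, protein_ids=protein_ids)
    return ConsensusNMFResult(
        rho_by_rank=rho_by_rank,
        consensus_by_rank=consensus_by_rank,
        selected_rank=k_star,
        final_consensus=final_C,
        subtype_labels=labels,
        metaproteins=meta,
        final_factors=best,
    )
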
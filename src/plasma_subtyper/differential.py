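"""Two-group differential screening and stage-trend clustering.

Per-protein Wilcoxon rank-sum tests (two-sided, unpaired) with
Benjamini–Hochberg FDR control; fold change is the linear-scale mean ratio of
case over control. Stage-trend profiles (control → early → advanced means)
are partitioned by seeded k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .preprocessing import ExpressionMatrix

__all__ = ["DifferentialResult", "rank_sum_test", "bh_adjust", "differential_screen", "trend_clusters"]

# exact null enumeration is affordable below this combined sample size
EXACT_N_MAX = 12


@dataclass
class DifferentialResult:
    protein_id: str
    p_value: float
    fdr: float
    fold_change: float
    direction: str          # "up" iff fold_change >= 1
    platform_used: str


def rank_sum_test(x, y):
    """Two-sided unpaired Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact null distribution when the combined sample size is at most
    12 and there are no cross-group ties, otherwise the tie-corrected normal
    approximation with continuity correction. Returns ``(U, p)`` with
    p ∈ (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), max(p, np.finfo(float).tiny)


def bh_adjust(p):
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_screen(
    m: ExpressionMatrix,
    groups: pd.Series,
    fdr_threshold: float = 0.05,
    group_order: tuple | None = None,
) -> pd.DataFrame:
    """Per-protein rank-sum screen of group1 vs group2 with BH correction.

    ``groups`` maps sample ID to one of exactly two levels; ``group_order``
    fixes (case, control) — fold change is mean(case)/mean(control) on the
    (normalized) linear scale. Returns a DataFrame indexed by protein ID with
    columns p_value, fdr, fold_change, direction, platform_used, significant.
    """
    groups = pd.Series(groups).reindex(m.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample must be assigned to a group")
    levels = list(pd.unique(groups)) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    g1 = m.sample_ids[groups == levels[0]]
    g2 = m.sample_ids[groups == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x_all = m.values.loc[:, g1].to_numpy(dtype=float)
    y_all = m.values.loc[:, g2].to_numpy(dtype=float)
    pvals = np.empty(m.values.shape[0])
    fc = np.empty(m.values.shape[0])
    for i in range(m.values.shape[0]):
        x = x_all[i][~np.isnan(x_all[i])]
        y = y_all[i][~np.isnan(y_all[i])]
        if x.size == 0 or y.size == 0:
            pvals[i] = 1.0
            fc[i] = np.nan
            continue
        _, pvals[i] = rank_sum_test(x, y)
        my = y.mean()
        fc[i] = x.mean() / my if my > 0 else np.inf
    fdr = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "p_value": pvals,
            "fdr": fdr,
            "fold_change": fc,
            "direction": np.where(fc >= 1.0, "up", "down"),
            "platform_used": m.platform.to_numpy(),
            "significant": fdr < fdr_threshold,
        },
        index=m.protein_ids,
    )
    return out


def trend_clusters(mean_profiles: pd.DataFrame, n_clusters: int = 6, seed: int = 0,
                   n_restarts: int = 25) -> pd.Series:
    """k-means partition of per-protein z-scored trend profiles.

    ``mean_profiles`` holds per-protein mean intensities over ordered groups
    (e.g. control, early stage, advanced stage). Rows are z-scored before
    clustering; constant rows are an error.
    """
    prof = pd.DataFrame(mean_profiles).astype(float)
    if n_clusters > prof.shape[0]:
        raise ValueError("n_clusters exceeds the number of proteins")
    arr = prof.to_numpy()
    sd = arr.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(prof.index[sd == 0])
        raise ValueError(f"constant profile row(s), z-score undefined: {bad}")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    return pd.Series(labels + 1, index=prof.index, name="trend_cluster")
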
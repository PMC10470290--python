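"""Matrix cleaning for dual-platform plasma proteomics.

The pipeline order is: detection filter (MS platform, pre-imputation) →
batch-minimum imputation → per-platform quantile normalization → platform
merge by smaller differential p-value → scaling (fraction-of-total for NMF
input, row z-score for heat-map style clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "impute_missing",
    "quantile_normalize",
    "filter_by_detection",
    "merge_platforms",
    "scale_matrix",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative protein × sample intensity matrix with platform/batch tags.

    Parameters
    ----------
    values
        DataFrame with protein IDs as the index and sample IDs as columns.
        Missing measurements are encoded as NaN. Observed values must be ≥ 0.
    platform
        Per-protein provenance tag, one of ``{"MS", "AB", "MERGED"}``. A single
        string is broadcast to all proteins.
    batch
        Per-sample batch label (Series indexed by sample ID).
    """

    values: pd.DataFrame
    platform: pd.Series = field(default=None)  # type: ignore[assignment]
    batch: pd.Series = field(default=None)  # type: ignore[assignment]

    def __init__(self, values: pd.DataFrame, platform="MS", batch=None):
        values = pd.DataFrame(values).astype(float)
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated protein IDs: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample IDs: {dupes}")
        with np.errstate(invalid="ignore"):
            if (values.to_numpy() < 0).any():
                raise ValueError("observed intensities must be nonnegative")
        if isinstance(platform, str):
            platform = pd.Series(platform, index=values.index)
        else:
            platform = pd.Series(platform).reindex(values.index)
            if platform.isna().any():
                raise ValueError("platform tag missing for some proteins")
        bad = set(platform.unique()) - {"MS", "AB", "MERGED"}
        if bad:
            raise ValueError(f"unknown platform tags: {sorted(bad)}")
        if batch is None:
            batch = pd.Series("batch1", index=values.columns)
        else:
            batch = pd.Series(batch).reindex(values.columns)
            if batch.isna().any():
                raise ValueError("batch label missing for some samples")
        self.values = values
        self.platform = platform
        self.batch = batch

    # -- basic introspection -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform.copy(), self.batch.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, sample_ids], self.platform, self.batch.loc[sample_ids])

    # -- I/O ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: rows = protein IDs, columns = sample IDs, NaN empty."""
        self.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")

    @classmethod
    def from_tsv(cls, path, platform="MS", batch=None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"])
        return cls(df, platform=platform, batch=batch)


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace missing cells with the protein's minimum observed value per batch.

    Fallback chain when a protein has no observation in the sample's batch:
    the protein's global minimum; if the protein is entirely unobserved, the
    matrix-wide minimum. An all-missing matrix is an error.
    """
    vals = m.values.copy()
    arr = vals.to_numpy()
    if np.isnan(arr).all():
        raise ValueError("cannot impute an all-missing matrix")
    global_min = np.nanmin(arr)
    protein_min = vals.min(axis=1, skipna=True)  # NaN for all-missing proteins
    for b in m.batch.unique():
        cols = m.batch.index[m.batch == b]
        block = vals.loc[:, cols]
        batch_min = block.min(axis=1, skipna=True)
        fill = batch_min.fillna(protein_min).fillna(global_min)
        vals.loc[:, cols] = block.apply(lambda col: col.fillna(fill))
    return ExpressionMatrix(vals, m.platform, m.batch)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one value distribution.

    Each column's order statistics are mapped to the across-sample mean of
    order statistics; ties within a column receive the mean of their quantile
    targets. Requires a complete matrix (impute first).
    """
    if m.n_missing:
        raise ValueError("matrix contains missing values; run impute_missing first")
    arr = m.values.to_numpy(dtype=float)
    # Mean of sorted columns = target distribution.
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n)
        mapped = target[ranks.astype(int)]
        # average targets over tied values
        s = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    vals = pd.DataFrame(out, index=m.protein_ids, columns=m.sample_ids)
    return ExpressionMatrix(vals, m.platform, m.batch)


def filter_by_detection(m: ExpressionMatrix, min_fraction: float = 0.8) -> ExpressionMatrix:
    """Keep proteins observed in at least ``min_fraction`` of samples.

    Applied before imputation; the 80% default mirrors common MS practice of
    dropping proteins quantified in fewer than 80% of runs.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = m.values.notna().mean(axis=1)
    keep = frac >= min_fraction - 1e-12
    vals = m.values.loc[keep]
    return ExpressionMatrix(vals, m.platform.loc[keep], m.batch)


def merge_platforms(
    ms: ExpressionMatrix,
    ab: ExpressionMatrix,
    p_ms: pd.Series,
    p_ab: pd.Series,
    tie_break: str = "MS",
) -> ExpressionMatrix:
    """Merge two platforms; shared proteins take the smaller-p-value platform.

    ``p_ms`` / ``p_ab`` are per-protein p-values (typically from the two-group
    differential screen run per platform). Ties go to ``tie_break``.
    """
    if not ms.sample_ids.equals(ab.sample_ids):
        raise ValueError("platforms must share the same sample set for merging")
    shared = ms.protein_ids.intersection(ab.protein_ids)
    for pid in shared:
        if pid not in p_ms.index or pid not in p_ab.index:
            raise ValueError(f"shared protein {pid!r} lacks a p-value on one platform")
        if pd.isna(p_ms[pid]) and pd.isna(p_ab[pid]):
            raise ValueError(f"shared protein {pid!r} lacks both p-values")
    rows = []
    tags = []
    ids = []
    for pid in ms.protein_ids:
        if pid in shared:
            pm, pa = p_ms[pid], p_ab[pid]
            use_ms = (
                pd.isna(pa)
                or (not pd.isna(pm) and (pm < pa or (pm == pa and tie_break == "MS")))
            )
            if use_ms:
                rows.append(ms.values.loc[pid])
                tags.append("MS")
            else:
                rows.append(ab.values.loc[pid])
                tags.append("AB")
        else:
            rows.append(ms.values.loc[pid])
            tags.append("MS")
        ids.append(pid)
    for pid in ab.protein_ids:
        if pid not in shared:
            rows.append(ab.values.loc[pid])
            tags.append("AB")
            ids.append(pid)
    vals = pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"))
    return ExpressionMatrix(vals, pd.Series(tags, index=vals.index), ms.batch)


def scale_matrix(m: ExpressionMatrix, mode: str = "fraction_of_total") -> ExpressionMatrix:
    """Scale a complete matrix for downstream modelling.

    ``fraction_of_total`` divides each column by its sum (NMF input: columns
    sum to 1, entries stay nonnegative). ``row_zscore`` centres and scales each
    protein to mean 0 / SD 1 (clustering and heat-map input).
    """
    if m.n_missing:
        raise ValueError("matrix contains missing values; run impute_missing first")
    arr = m.values.to_numpy(dtype=float)
    if mode == "fraction_of_total":
        colsum = arr.sum(axis=0)
        zero = np.flatnonzero(colsum == 0)
        if zero.size:
            raise ValueError(f"zero-sum column(s): {list(m.sample_ids[zero])}")
        out = arr / colsum
    elif mode == "row_zscore":
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise ValueError(f"zero-variance row(s): {list(m.protein_ids[zero])}")
        out = (arr - mu) / sd
        vals = pd.DataFrame(out, index=m.protein_ids, columns=m.sample_ids)
        # row z-scores are signed; bypass the nonnegativity check
        em = ExpressionMatrix.__new__(ExpressionMatrix)
        em.values = vals
        em.platform = m.platform.copy()
        em.batch = m.batch.copy()
        return em
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    vals = pd.DataFrame(out, index=m.protein_ids, columns=m.sample_ids)
    return ExpressionMatrix(vals, m.platform, m.batch)
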
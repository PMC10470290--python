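"""Biomarker cascade, Hans classification and the marker+IPI decision rule.

The cascade reproduces a three-stage biomarker selection: (1) candidates must
differ between responders and non-responders (rank-sum p < alpha), (2) pass a
univariate Cox screen on both PFS and OS, and (3) stay significant in a
multivariate Cox model adjusted for the IPI score. The decision rule flags a
patient high-risk when IPI is 3–5, or when IPI is 0–2 but the marker exceeds
a cutoff (default 180.636, the published circulating TIMP-1 threshold in
pg/ml). "Identification accuracy" is the fraction of event patients (relapse
within 12 months / death within 48 months) the rule flags high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import rank_sum_test
from .survival import cox_fit

__all__ = [
    "RiskRule",
    "StratificationMetrics",
    "hans_classify",
    "biomarker_cascade",
    "apply_risk_rule",
    "identification_metrics",
    "roc_auc",
    "train_subtype_classifier",
    "DEFAULT_MARKER_CUTOFF",
]

DEFAULT_MARKER_CUTOFF = 180.636  # pg/ml, published circulating TIMP-1 threshold
IPI_HIGH_SET = frozenset({3, 4, 5})

EVENT_HORIZONS = {"relapse_within_12mo": ("pfs", 12.0), "death_within_48mo": ("os", 48.0)}


@dataclass
class RiskRule:
    marker_cutoff: float = DEFAULT_MARKER_CUTOFF
    cutoff_policy: str = "fixed"   # "fixed" | "third_quartile"
    ipi_high_set: frozenset = field(default_factory=lambda: IPI_HIGH_SET)

    def __post_init__(self):
        if self.marker_cutoff <= 0:
            raise ValueError("marker cutoff must be positive")
        if self.cutoff_policy not in ("fixed", "third_quartile"):
            raise ValueError(f"unknown cutoff policy {self.cutoff_policy!r}")


@dataclass
class StratificationMetrics:
    event_definition: str
    identified_fraction: dict      # rule name -> fraction of event patients flagged
    improvement_points: float      # 100 * (combined - IPI alone)
    n_event: int


def hans_classify(cd10, bcl6, mum1) -> str:
    """Immunostain cell-of-origin call: GCB vs non-GCB (unknown propagates).

    CD10+ → GCB; CD10− & BCL6− → nonGCB; CD10− & BCL6+ → MUM1 decides
    (MUM1− → GCB, MUM1+ → nonGCB).
    """
    calls = []
    for v in (cd10, bcl6, mum1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            calls.append(None)
        else:
            calls.append(bool(int(v)))
    cd10, bcl6, mum1 = calls
    if cd10 is None:
        return "unknown"
    if cd10:
        return "GCB"
    if bcl6 is None:
        return "unknown"
    if not bcl6:
        return "nonGCB"
    if mum1 is None:
        return "unknown"
    return "GCB" if not mum1 else "nonGCB"


def biomarker_cascade(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-stage survival-anchored biomarker selection.

    ``matrix`` is proteins × samples (linear scale) restricted to case
    samples; ``clinical`` must carry response ("R"/"NR"), ipi, pfs_time/
    pfs_event and os_time/os_event indexed by sample_id. Returns the survivors
    ranked by multivariate PFS hazard ratio (descending, protein ID
    tie-break), with per-stage p-values.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    samples = [s for s in matrix.columns if s in clin.index]
    clin = clin.loc[samples]
    resp = clin["response"].astype(str)
    r_mask = (resp == "R").to_numpy()
    nr_mask = (resp == "NR").to_numpy()
    rows = []
    for pid in candidates:
        if pid not in matrix.index:
            continue
        vals = matrix.loc[pid, samples].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        x = vals[ok & nr_mask]
        y = vals[ok & r_mask]
        if x.size < 2 or y.size < 2:
            continue
        _, p_rs = rank_sum_test(x, y)
        if p_rs >= alpha:
            continue
        # standardize the marker so HRs are per SD
        z = (vals - np.nanmean(vals)) / np.nanstd(vals)
        record = {"protein_id": pid, "p_response": p_rs}
        passed = True
        hrs = {}
        for ep in ("pfs", "os"):
            t = clin[f"{ep}_time"].to_numpy(dtype=float)
            e = clin[f"{ep}_event"].to_numpy(dtype=float)
            keep = ok & ~np.isnan(t) & ~np.isnan(e)
            uni = cox_fit(pd.DataFrame({"marker": z[keep]}), t[keep], e[keep].astype(int))
            p_uni = float(uni.summary.loc["marker", "p"]) if uni.converged else 1.0
            record[f"p_uni_{ep}"] = p_uni
            if not (uni.converged and p_uni < alpha):
                passed = False
                break
            multi = cox_fit(
                pd.DataFrame({"marker": z[keep], "ipi": clin["ipi"].to_numpy(dtype=float)[keep]}),
                t[keep], e[keep].astype(int), scope="multivariate",
            )
            p_multi = float(multi.summary.loc["marker", "p"]) if multi.converged else 1.0
            record[f"p_multi_{ep}"] = p_multi
            hrs[ep] = float(multi.summary.loc["marker", "hr"]) if multi.converged else np.nan
            if not (multi.converged and p_multi < alpha):
                passed = False
                break
        if passed:
            record["hr_multi_pfs"] = hrs["pfs"]
            record["hr_multi_os"] = hrs["os"]
            rows.append(record)
    if not rows:
        return pd.DataFrame(
            columns=["protein_id", "p_response", "p_uni_pfs", "p_multi_pfs",
                     "p_uni_os", "p_multi_os", "hr_multi_pfs", "hr_multi_os"]
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(["hr_multi_pfs", "protein_id"], ascending=[False, True])
    return out.reset_index(drop=True)


def apply_risk_rule(rule: RiskRule, ipi, marker) -> str:
    """High/low risk call: high ⇔ IPI ∈ {3,4,5} or (IPI ≤ 2 and marker > cutoff)."""
    ipi = int(ipi)
    if not (0 <= ipi <= 5):
        raise ValueError(f"IPI must be in 0..5, got {ipi}")
    if ipi in rule.ipi_high_set:
        return "high"
    return "high" if marker > rule.marker_cutoff else "low"


def apply_risk_rule_vector(rule: RiskRule, ipi, marker) -> np.ndarray:
    """Vectorized risk-rule assignment (array of 'high'/'low')."""
    ipi = np.asarray(ipi)
    marker = np.asarray(marker, dtype=float)
    cutoff = rule.marker_cutoff
    if rule.cutoff_policy == "third_quartile":
        low = ~np.isin(ipi.astype(int), list(rule.ipi_high_set))
        cutoff = float(np.nanquantile(marker[low], 0.75))
    return np.asarray(
        [apply_risk_rule(RiskRule(marker_cutoff=cutoff, ipi_high_set=rule.ipi_high_set), i, m)
         for i, m in zip(ipi, marker)]
    )


def identification_metrics(
    assignments: dict,
    clinical: pd.DataFrame,
    event_definition: str = "relapse_within_12mo",
) -> StratificationMetrics:
    """Fraction of event patients each rule flags high, and the gain over IPI.

    ``assignments`` maps rule name → array of "high"/"low" aligned with
    ``clinical`` rows; it must contain "ipi_alone" and "combined". Event
    patients: endpoint event observed at or before the horizon. Patients
    censored before the horizon without an event are excluded (their status is
    unknowable).
    """
    if event_definition not in EVENT_HORIZONS:
        raise ValueError(f"unknown event definition {event_definition!r}")
    endpoint, horizon = EVENT_HORIZONS[event_definition]
    t = clinical[f"{endpoint}_time"].to_numpy(dtype=float)
    e = clinical[f"{endpoint}_event"].to_numpy(dtype=float)
    is_event = (e == 1) & (t <= horizon)
    n_event = int(is_event.sum())
    if n_event == 0:
        raise ValueError("no event patients within the horizon; metrics undefined")
    fractions = {}
    for name, flags in assignments.items():
        flags = np.asarray(flags)
        fractions[name] = float(np.sum((flags == "high") & is_event) / n_event)
    if "combined" not in fractions or "ipi_alone" not in fractions:
        raise ValueError("assignments must include 'combined' and 'ipi_alone'")
    improvement = 100.0 * (fractions["combined"] - fractions["ipi_alone"])
    return StratificationMetrics(
        event_definition=event_definition,
        identified_fraction=fractions,
        improvement_points=improvement,
        n_event=n_event,
    )


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC: [#(pos > neg) + 0.5·#ties] / (n_pos · n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def train_subtype_classifier(features: pd.DataFrame, labels, split: float = 0.7, seed: int = 0):
    """Seeded random-forest classifier for the poor-prognosis subtype.

    ``features`` is samples × markers; ``labels`` is binary (1 = target
    subtype). Returns ``(model, train_auc, test_auc)`` with AUCs from the
    rank-statistic formula on in-split and out-of-split predicted
    probabilities.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    X = pd.DataFrame(features).to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if not (0 < split < 1):
        raise ValueError("split must be in (0, 1)")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError("degenerate split: both classes required on each side")
    model = RandomForestClassifier(n_estimators=500, random_state=seed)
    model.fit(X_tr, y_tr)
    train_auc = roc_auc(model.predict_proba(X_tr)[:, 1], y_tr)
    test_auc = roc_auc(model.predict_proba(X_te)[:, 1], y_te)
    return model, train_auc, test_auc
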
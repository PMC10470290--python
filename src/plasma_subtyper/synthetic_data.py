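"""Seeded synthetic dual-platform plasma-proteomics cohorts.

The generator plants every structure the downstream pipeline is supposed to
recover: a case/control differential shift, a k-subtype block of
subtype-specific "metaproteins" (high-abundance, acute-phase-like signature
proteins), abundance-dependent (MNAR) missingness with multiplicative batch
shifts, and survival endpoints whose hazard is log-linear in a latent risk
score driven by subtype and by one named marker protein. IPI is drawn from a
proportional-odds link on the same latent risk so that the clinical score and
the proteomic subtype are correlated but not redundant.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; identical configs give bitwise-identical
cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "simulate_survival",
    "apply_missingness_and_batches",
    "simulate_cohort",
    "write_cohort",
]

LOG10_2 = np.log10(2.0)

CLINICAL_COLUMNS = [
    "sample_id", "group", "stage", "ipi", "cd10", "bcl6", "mum1",
    "response", "pfs_time", "pfs_event", "os_time", "os_event", "batch",
]


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Defaults emulate a discovery cohort of ~150 patients and ~80 controls
    measured on a ~300-protein MS-like platform and a ~150-protein
    antibody-array-like platform with 50 shared proteins, with four planted
    proteomic subtypes of which the smallest carries the worst prognosis.
    """

    seed: int = 0
    n_dlbcl: int = 150
    n_hc: int = 80
    n_proteins_ms: int = 300
    n_proteins_ab: int = 150
    n_overlap: int = 50
    k_true: int = 4
    subtype_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    metaproteins_per_subtype: int = 10
    metaprotein_log2_shift: float = 1.5
    de_fraction: float = 0.3
    de_log2_shift_range: tuple = (0.5, 2.0)
    n_batches: int = 3
    batch_log2_shift_sd: float = 0.2
    detection_logistic_midpoint: float = 3.0
    detection_logistic_slope: float = 2.0
    baseline_log10_range: tuple = (2.0, 8.0)
    within_protein_sd_log10: float = 0.25
    hazard_baseline_rate: float = 0.02
    subtype_hazard_ratios: tuple = (1.0, 1.3, 1.3, 3.0)
    marker_hazard_log_coeff: float = 0.5
    censor_window_months: tuple = (12.0, 60.0)
    ipi_risk_link: float = 1.0

    def validate(self) -> None:
        counts = {
            "n_dlbcl": self.n_dlbcl, "n_hc": self.n_hc,
            "n_proteins_ms": self.n_proteins_ms, "n_proteins_ab": self.n_proteins_ab,
            "k_true": self.k_true, "metaproteins_per_subtype": self.metaproteins_per_subtype,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"invalid config: {name} must be a positive count, got {v}")
        if self.n_overlap < 0 or self.n_overlap > min(self.n_proteins_ms, self.n_proteins_ab):
            raise ValueError("invalid config: n_overlap exceeds a platform's protein count")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != self.k_true or not np.isclose(props.sum(), 1.0) or (props <= 0).any():
            raise ValueError("invalid config: subtype_proportions must be a positive length-k_true vector summing to 1")
        hrs = np.asarray(self.subtype_hazard_ratios, dtype=float)
        if hrs.size != self.k_true or (hrs <= 0).any():
            raise ValueError("invalid config: subtype_hazard_ratios must be positive, length k_true")
        if self.hazard_baseline_rate <= 0:
            raise ValueError("invalid config: hazard_baseline_rate must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("invalid config: de_fraction must lie in [0, 1]")
        lo, hi = self.censor_window_months
        if lo <= 0 or hi < lo:
            raise ValueError("invalid config: censor_window_months must be 0 < lo <= hi")
        lo, hi = self.baseline_log10_range
        if hi <= lo:
            raise ValueError("invalid config: baseline_log10_range must be increasing")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (for recovery benchmarking)."""

    subtype_label: pd.Series            # per DLBCL sample, 1..k_true
    metaprotein_ids: dict               # subtype -> list of protein IDs (disjoint)
    de_protein_ids: dict                # protein ID -> signed log2 shift (DLBCL vs HC)
    marker_protein_id: str
    latent_risk: pd.Series              # per DLBCL sample, log relative hazard
    hazard_baseline_rate: float
    subtype_hazard_ratios: tuple

    def to_json(self, path) -> None:
        obj = {
            "subtype_label": {k: int(v) for k, v in self.subtype_label.items()},
            "metaprotein_ids": {str(k): list(v) for k, v in self.metaprotein_ids.items()},
            "de_protein_ids": {k: float(v) for k, v in self.de_protein_ids.items()},
            "marker_protein_id": self.marker_protein_id,
            "latent_risk": {k: float(v) for k, v in self.latent_risk.items()},
            "hazard_baseline_rate": self.hazard_baseline_rate,
            "subtype_hazard_ratios": list(self.subtype_hazard_ratios),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _logistic(x):
    from scipy.special import expit

    return expit(x)


def simulate_survival(latent_risk, config: SimulationConfig, rng: np.random.Generator):
    """Draw (pfs_time, pfs_event, os_time, os_event) for each latent risk.

    Progression times are exponential with rate
    ``hazard_baseline_rate * exp(latent_risk)``; overall survival adds an
    independent exponential post-progression time at the same rate, which
    enforces OS ≥ PFS. Both endpoints are administratively censored at a
    per-sample uniform time inside ``censor_window_months``.
    """
    r = np.asarray(latent_risk, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("latent_risk must be finite")
    rate = config.hazard_baseline_rate * np.exp(r)
    if (rate <= 0).any() or not np.isfinite(rate).all():
        raise ValueError("nonpositive or non-finite hazard rate")
    n = r.size
    t_prog = rng.exponential(1.0 / rate, size=n)
    t_post = rng.exponential(1.0 / rate, size=n)
    t_death = t_prog + t_post
    lo, hi = config.censor_window_months
    censor = rng.uniform(lo, hi, size=n)
    pfs_event = (t_prog <= censor).astype(int)
    pfs_time = np.minimum(t_prog, censor)
    os_event = (t_death <= censor).astype(int)
    os_time = np.minimum(t_death, censor)
    return pfs_time, pfs_event, os_time, os_event


def apply_missingness_and_batches(
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    batch_midpoint_shifts: dict | None = None,
    batch_log2_shifts: dict | None = None,
) -> ExpressionMatrix:
    """MNAR detection dropout plus multiplicative batch shifts.

    Each cell goes missing independently with probability
    ``logistic(-slope * (log10 intensity - midpoint_b))`` where ``midpoint_b``
    is the detection midpoint optionally shifted per batch; lower-abundance
    measurements are therefore lost more often. Observed values are then
    multiplied by a per-batch factor ``2**shift_b`` (additive in log scale,
    which quantile normalization is meant to remove).
    """
    if matrix.n_missing:
        raise ValueError("expected a complete (pre-missingness) matrix")
    batches = list(pd.unique(matrix.batch))
    if batch_midpoint_shifts is None:
        batch_midpoint_shifts = {b: 0.0 for b in batches}
    if batch_log2_shifts is None:
        batch_log2_shifts = {
            b: rng.normal(0.0, config.batch_log2_shift_sd) for b in batches
        }
    for d in (batch_midpoint_shifts, batch_log2_shifts):
        unknown = set(d) - set(batches)
        if unknown:
            raise ValueError(f"unknown batch label(s): {sorted(unknown)}")
    vals = matrix.values.copy()
    arr = vals.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log10 = np.log10(np.maximum(arr, np.finfo(float).tiny))
    out = arr.copy()
    for b in batches:
        cols = np.flatnonzero((matrix.batch == b).to_numpy())
        mid = config.detection_logistic_midpoint + batch_midpoint_shifts.get(b, 0.0)
        p_miss = _logistic(-config.detection_logistic_slope * (log10[:, cols] - mid))
        miss = rng.uniform(size=p_miss.shape) < p_miss
        block = arr[:, cols] * 2.0 ** batch_log2_shifts.get(b, 0.0)
        block[miss] = np.nan
        out[:, cols] = block
    vals = pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(vals, matrix.platform, matrix.batch)


# proportional-odds thresholds for IPI 0..5 at zero risk: marginal cumulative
# probabilities roughly matching a discovery-cohort-like IPI distribution
# (≈ 69% scoring 0-2).
_IPI_CUM_PROBS = (0.18, 0.44, 0.69, 0.85, 0.95)


def _draw_ipi(risk_std, link, rng):
    cuts = np.log(np.array(_IPI_CUM_PROBS) / (1 - np.array(_IPI_CUM_PROBS)))
    # P(IPI <= j) = logistic(cut_j - link * risk)
    cum = _logistic(cuts[None, :] - link * risk_std[:, None])
    u = rng.uniform(size=risk_std.size)
    return (u[:, None] > cum).sum(axis=1)  # 0..5


def generate_cohort(config: SimulationConfig):
    """Generate complete (pre-missingness) matrices, clinical table, truth.

    Returns ``(ms, ab, clinical, truth)``. Matrices are linear-scale
    intensities (log-normal in log10 space). The marker protein is named
    ``TIMP1_LIKE`` and belongs to the worst-prognosis subtype's metaprotein
    block; its standardized abundance enters the latent hazard with
    coefficient ``marker_hazard_log_coeff``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_union = config.n_proteins_ms + config.n_proteins_ab - config.n_overlap
    protein_ids = [f"P{i:04d}" for i in range(n_union)]
    # first n_proteins_ms rows are MS; last n_proteins_ab rows are AB;
    # the middle n_overlap rows appear on both platforms

    n = config.n_dlbcl + config.n_hc
    sample_ids = [f"D{i:03d}" for i in range(config.n_dlbcl)] + [
        f"H{i:03d}" for i in range(config.n_hc)
    ]
    group = np.array(["DLBCL"] * config.n_dlbcl + ["HC"] * config.n_hc)

    lo, hi = config.baseline_log10_range
    baseline = rng.uniform(lo, hi, size=n_union)

    # planted subtypes ------------------------------------------------------
    k = config.k_true
    props = np.asarray(config.subtype_proportions, dtype=float)
    subtype = rng.choice(np.arange(1, k + 1), size=config.n_dlbcl, p=props)
    # ensure every subtype occurs
    for s in range(1, k + 1):
        if not (subtype == s).any():
            subtype[rng.integers(config.n_dlbcl)] = s

    # metaproteins: disjoint blocks of high-abundance signature proteins.
    n_meta = k * config.metaproteins_per_subtype
    if n_meta > n_union:
        raise ValueError("invalid config: metaproteins_per_subtype too large for protein count")
    meta_idx = rng.choice(n_union, size=n_meta, replace=False)
    # acute-phase-like: signature proteins sit in the upper abundance decades,
    # spread evenly within each subtype block so every block carries
    # comparable weight in magnitude-weighted factorizations
    span = min(1.0, hi - lo)
    baseline[meta_idx] = np.tile(
        np.linspace(hi - span, hi, config.metaproteins_per_subtype), k
    )
    metaprotein_ids = {}
    for s in range(1, k + 1):
        block = meta_idx[(s - 1) * config.metaproteins_per_subtype: s * config.metaproteins_per_subtype]
        metaprotein_ids[s] = [protein_ids[i] for i in block]

    worst = int(np.argmax(config.subtype_hazard_ratios)) + 1
    marker_internal = metaprotein_ids[worst][0]
    marker_id = "TIMP1_LIKE"
    protein_ids[protein_ids.index(marker_internal)] = marker_id
    metaprotein_ids[worst][0] = marker_id

    # DLBCL-vs-HC differential proteins (may overlap metaproteins)
    n_de = int(round(config.de_fraction * n_union))
    de_idx = rng.choice(n_union, size=n_de, replace=False)
    de_lo, de_hi = config.de_log2_shift_range
    de_shift = rng.uniform(de_lo, de_hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    de_protein_ids = {protein_ids[i]: float(sh) for i, sh in zip(de_idx, de_shift)}

    # assemble log10 intensity matrix (union of proteins × samples)
    log10 = baseline[:, None] + rng.normal(0.0, config.within_protein_sd_log10, size=(n_union, n))
    is_dlbcl = group == "DLBCL"
    for i, sh in zip(de_idx, de_shift):
        log10[i, is_dlbcl] += sh * LOG10_2
    for s in range(1, k + 1):
        block = meta_idx[(s - 1) * config.metaproteins_per_subtype: s * config.metaproteins_per_subtype]
        cols = np.flatnonzero(is_dlbcl)[subtype == s]
        for i in block:
            log10[np.ix_([i], cols)] += config.metaprotein_log2_shift * LOG10_2

    intensities = 10.0 ** log10
    values = pd.DataFrame(intensities, index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids)

    batch = pd.Series(
        [f"batch{1 + (i % config.n_batches)}" for i in range(n)], index=values.columns
    )
    ms = ExpressionMatrix(values.iloc[: config.n_proteins_ms], "MS", batch)
    ab = ExpressionMatrix(values.iloc[config.n_proteins_ms - config.n_overlap:], "AB", batch)

    # latent risk and survival ---------------------------------------------
    marker_log10 = log10[protein_ids.index(marker_id), is_dlbcl]
    marker_z = (marker_log10 - marker_log10.mean()) / marker_log10.std(ddof=0)
    hrs = np.asarray(config.subtype_hazard_ratios, dtype=float)
    risk = np.log(hrs[subtype - 1]) + config.marker_hazard_log_coeff * marker_z
    pfs_time, pfs_event, os_time, os_event = simulate_survival(risk, config, rng)

    risk_std = (risk - risk.mean()) / (risk.std(ddof=0) if risk.std(ddof=0) > 0 else 1.0)
    ipi = _draw_ipi(risk_std, config.ipi_risk_link, rng)
    stage = np.where(
        rng.uniform(size=config.n_dlbcl) < _logistic(0.0 + 0.8 * risk_std), "III-IV", "I-II"
    )
    # response: higher risk → more likely non-responder
    p_nr = _logistic(0.2 + 1.2 * risk_std)
    response = np.where(rng.uniform(size=config.n_dlbcl) < p_nr, "NR", "R")
    cd10 = (rng.uniform(size=config.n_dlbcl) < 0.15).astype(int)
    bcl6 = (rng.uniform(size=config.n_dlbcl) < 0.50).astype(int)
    mum1 = (rng.uniform(size=config.n_dlbcl) < 0.75).astype(int)

    dlbcl_ids = [sid for sid, g in zip(sample_ids, group) if g == "DLBCL"]
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group,
        "stage": list(stage) + [""] * config.n_hc,
        "ipi": list(ipi) + [np.nan] * config.n_hc,
        "cd10": list(cd10) + [np.nan] * config.n_hc,
        "bcl6": list(bcl6) + [np.nan] * config.n_hc,
        "mum1": list(mum1) + [np.nan] * config.n_hc,
        "response": list(response) + [""] * config.n_hc,
        "pfs_time": list(pfs_time) + [np.nan] * config.n_hc,
        "pfs_event": list(pfs_event) + [np.nan] * config.n_hc,
        "os_time": list(os_time) + [np.nan] * config.n_hc,
        "os_event": list(os_event) + [np.nan] * config.n_hc,
        "batch": batch.to_numpy(),
    })

    truth = GroundTruth(
        subtype_label=pd.Series(subtype, index=dlbcl_ids),
        metaprotein_ids=metaprotein_ids,
        de_protein_ids=de_protein_ids,
        marker_protein_id=marker_id,
        latent_risk=pd.Series(risk, index=dlbcl_ids),
        hazard_baseline_rate=config.hazard_baseline_rate,
        subtype_hazard_ratios=tuple(config.subtype_hazard_ratios),
    )
    return ms, ab, clinical, truth


def simulate_cohort(config: SimulationConfig):
    """Generate a cohort and apply MNAR missingness + batch shifts to both platforms."""
    ms, ab, clinical, truth = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ms = apply_missingness_and_batches(ms, config, rng)
    ab = apply_missingness_and_batches(ab, config, rng)
    return ms, ab, clinical, truth


def write_cohort(outdir, ms, ab, clinical, truth) -> None:
    """Write matrices as TSV, the clinical table as CSV and the truth as JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ms.to_tsv(os.path.join(outdir, "ms.tsv"))
    ab.to_tsv(os.path.join(outdir, "ab.tsv"))
    clinical.to_csv(os.path.join(outdir, "clinical.csv"), index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"invalid config: unknown field(s) {sorted(unknown)}")
    d = dict(d)
    for key in ("subtype_proportions", "de_log2_shift_range", "baseline_log10_range",
                "subtype_hazard_ratios", "censor_window_months"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
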
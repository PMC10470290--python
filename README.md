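# plasma_subtyper

Proteomic subtyping and prognostic stratification for plasma-proteome
cohorts, built around the analysis pattern of a DLBCL (diffuse large B-cell
lymphoma) case/control study measured on two complementary platforms — a
DIA-MS-like intensity matrix and an antibody-array-like matrix with partial
protein overlap. The package is aimed at computational biologists who want
the full chain as tested, reusable parts:

1. **Preprocessing** — 80% detection filter, batch-minimum imputation,
   per-platform quantile normalization, smaller-p-value platform merge,
   fraction-of-total / row-z-score scaling.
2. **Differential screening** — per-protein Wilcoxon rank-sum tests with
   Benjamini–Hochberg FDR control and linear-scale fold changes; k-means
   stage-trend clustering.
3. **Consensus NMF subtyping** — multiplicative Kullback–Leibler updates
   (V ≈ WH, V proteins × samples), multi-restart consensus matrices,
   cophenetic-coefficient rank selection over k = 2..6, hierarchical
   consensus labeling, and entropy-based (Kim–Park) metaprotein extraction
   from W.
4. **Concordance** — k-means and Ward baselines with Cohen's kappa after
   Hungarian label alignment.
5. **Survival** — Kaplan–Meier with Greenwood variance, G-group log-rank,
   Cox proportional hazards (Efron ties, via lifelines), and maximally
   selected log-rank cutpoint search.
6. **Risk stratification** — Hans GCB/non-GCB calls, a three-stage
   survival-anchored biomarker cascade (response → univariate Cox →
   IPI-adjusted multivariate Cox), the marker+IPI decision rule
   (high risk ⇔ IPI 3–5, or IPI 0–2 with marker above a cutoff; default
   cutoff 180.636 pg/ml, the published circulating TIMP-1 threshold), and
   event-identification metrics.
7. **Synthetic cohorts** — a seeded generator that plants subtype blocks,
   case/control shifts, MNAR missingness with batch effects, and
   risk-linked survival/IPI/response, so every stage above is testable
   without patient-level data.

The core model is non-negative matrix factorization X ≈ WH with the
generalized KL objective D(X‖WH) = Σ X log(X/WH) − X + WH; cluster
stability over random restarts is summarized by the consensus matrix C̄ and
its cophenetic correlation ρ, and the factorization rank k\* = argmax_k ρ_k.
Representative proteins per subtype score
S(f) = 1 + (1/log₂k) Σ_a q_a log₂ q_a with q the row-normalized W weights.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import pandas as pd
from plasma_subtyper import (SimulationConfig, simulate_cohort, scale_matrix,
                             differential_screen, consensus_subtyping)
from plasma_subtyper.pipeline_cli import preprocess_cohort

cfg = SimulationConfig(seed=1)                      # 150 DLBCL + 80 HC, 400 proteins
ms, ab, clinical, truth = simulate_cohort(cfg)
merged, de_ms, de_ab = preprocess_cohort(ms, ab, clinical)
groups = pd.Series(clinical["group"].to_numpy(), index=clinical["sample_id"])
de = differential_screen(merged, groups, group_order=("DLBCL", "HC"))

dlbcl = clinical.loc[clinical["group"] == "DLBCL", "sample_id"].tolist()
V = scale_matrix(merged.subset_samples(dlbcl), "fraction_of_total")
res = consensus_subtyping(V.values.to_numpy(), sample_ids=dlbcl,
                          protein_ids=V.protein_ids, n_restarts=50,
                          final_restarts=50, base_seed=1)
print("merged matrix:", merged.values.shape)
print("significant DLBCL-vs-HC proteins (FDR<0.05):", int(de.significant.sum()))
print("cophenetic profile:", {k: round(v, 3) for k, v in res.rho_by_rank.items()})
print("selected rank:", res.selected_rank)
print("subtype sizes:", res.subtype_labels.value_counts().sort_index().to_dict())
```

prints

```
merged matrix: (334, 230)
significant DLBCL-vs-HC proteins (FDR<0.05): 118
cophenetic profile: {2: 0.955, 3: 0.977, 4: 0.996, 5: 0.973, 6: 0.978}
selected rank: 4
subtype sizes: {1: 36, 2: 41, 3: 43, 4: 30}
```

The detection filter kept 334 of the 400 simulated proteins; 118 pass the
case/control screen at FDR < 0.05 (the generator plants shifts in 30% of
proteins); and the cophenetic coefficient peaks at the planted four
subtypes. Downstream, per-subtype Kaplan–Meier curves separate the planted
poor-prognosis subtype (PFS log-rank p ≈ 5e−10 on this cohort), the planted
`TIMP1_LIKE` marker survives the three-stage biomarker cascade, and the
marker+IPI rule identifies 68% of patients relapsing within 12 months
versus 45% for IPI alone (+23 percentage points) on this simulated cohort.

A CLI wraps the same stages:

```bash
plasma-subtyper simulate --out cohort/ --seed 1
plasma-subtyper preprocess --ms cohort/ms.tsv --ab cohort/ab.tsv \
    --clinical cohort/clinical.csv --out work/
plasma-subtyper subtype --matrix work/merged.tsv --clinical cohort/clinical.csv \
    --kmin 2 --kmax 6 --restarts 50 --seed 1 --out work/
plasma-subtyper run --config pipeline.yaml --out run1/   # full pipeline
```

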
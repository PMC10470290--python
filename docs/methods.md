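# Methods

`plasma_subtyper` implements an end-to-end plasma-proteome subtyping and
prognostic-stratification workflow for a DLBCL-style case/control cohort
measured on two partially overlapping platforms (a DIA-MS-like matrix of
~300 proteins and an antibody-array-like matrix of ~150 proteins, ~50
shared). Because patient-level data of this kind are rarely public, the
package ships a synthetic cohort generator whose planted structure defines
what every downstream stage is expected to recover.

## Synthetic cohort model

Protein intensities are log-normal: each protein has a baseline log10
abundance drawn uniformly from `baseline_log10_range` (default [2, 8],
spanning the plasma dynamic range) and per-sample Gaussian noise of
`within_protein_sd_log10` (default 0.25). On top of the baseline the
generator plants:

- **Case/control shifts** — a fraction `de_fraction` (default 0.3) of
  proteins receive a signed log2 shift drawn from `de_log2_shift_range`
  (default [0.5, 2.0]) in case samples.
- **Subtypes** — `k_true` (default 4) latent subtypes with balanced default
  proportions. Each subtype owns a disjoint block of
  `metaproteins_per_subtype` (default 10) signature proteins shifted by
  `metaprotein_log2_shift` (default 1.5) log2 units in that subtype's
  samples. Signature ("metaprotein") baselines are placed in the top decade
  of the abundance range and spread evenly within each block. Two modelling
  reasons: (i) the real-world analogue of a poor-prognosis plasma signature
  is acute-phase/inflammation proteins (CRP, SAA1/2, TIMP-1), which are
  high-abundance; (ii) the downstream factorization minimizes a
  Kullback–Leibler objective on fraction-of-total intensities, which weights
  proteins by magnitude — signature blocks of equal aggregate abundance give
  every subtype comparable leverage in the fit. Balanced subtype proportions
  are the default for a related reason: with strongly unequal blocks the
  under-ranked (k < k_true) factorizations merge the same pair of subtypes
  at every restart, so consensus stability no longer discriminates the true
  rank. Both choices are generator design decisions, exposed through the
  configuration.
- **Survival** — progression times are exponential with rate
  `hazard_baseline_rate · exp(r)` (default 0.02/month) where the latent log
  relative hazard `r` sums the subtype effect (`subtype_hazard_ratios`,
  default (1, 1.3, 1.3, 3.0)) and `marker_hazard_log_coeff` (default 0.5)
  per SD of the marker protein's log abundance. The marker, named
  `TIMP1_LIKE`, is one of the worst subtype's metaproteins. Overall survival
  adds an independent exponential post-progression time, which enforces
  OS ≥ PFS — the generator does not attempt a realistic post-progression
  hazard, only the clinically forced ordering. Both endpoints are
  administratively censored uniformly inside `censor_window_months`
  (default [12, 60]).
- **Clinical covariates** — IPI (0–5) is drawn from a proportional-odds
  model on the standardized latent risk with link strength `ipi_risk_link`
  (default 1), so IPI correlates with, but does not determine, the
  proteomic subtype; thresholds put roughly 70% of patients at IPI 0–2.
  Response (R/NR) is Bernoulli with a logistic link on the same risk.
  Hans immunostain calls (CD10/BCL-6/MUM1) are independent Bernoulli draws
  calibrated to ≈25% GCB and are deliberately *uninformative* about
  survival, mirroring the weak prognostic separation of cell-of-origin
  calls in this setting.
- **Missingness and batches** — detection is missing-not-at-random: a cell
  is lost with probability `logistic(−slope · (log10 x − midpoint))`
  (defaults: slope 2, midpoint 3), optionally with per-batch midpoint
  shifts. Observed values get multiplicative per-batch shifts
  (`batch_log2_shift_sd`, default 0.2 log2 units), i.e. additive in log
  scale, the kind of artifact quantile normalization removes.

What the generator does **not** emulate: correlated protein modules beyond
the planted blocks, heavy-tailed or zero-inflated intensity distributions,
platform-specific affinity biases, informative censoring, or treatment
effects. Tests passing on this generator therefore demonstrate the
*machinery* recovers planted structure under idealized noise, not that the
biological findings generalize.

## Preprocessing

Order: detection filter (MS platform only, proteins observed in ≥ 80% of
samples, applied pre-imputation) → imputation (missing cell ← the protein's
minimum observed value within the sample's batch, falling back to the
protein's global minimum, then the matrix minimum) → quantile normalization
per platform (columns mapped to the mean order-statistic distribution; ties
receive the mean of their quantile targets) → platform merge (a protein
quantified on both platforms keeps the platform with the smaller
case/control rank-sum p-value; ties go to MS, since MS quantification is
the primary axis) → scaling (fraction-of-total per column for the
factorization; row z-scores for distance-based clustering). Normalization
is per platform because the two platforms' intensity scales are
incommensurable before merging.

## Differential screening

Per-protein two-sided unpaired Wilcoxon rank-sum tests; the exact null
distribution is used when the combined sample size is ≤ 12 with no ties
(enumeration cost grows combinatorially beyond that), otherwise the
tie-corrected normal approximation with continuity correction.
Benjamini–Hochberg adjustment across all tested proteins; significance at
FDR < 0.05. Fold change is the linear-scale mean ratio case/control (the
choice of mean over median ratio is a convention, configurable in scope).
Stage-trend profiles (control → early → advanced means, row z-scored) are
partitioned by k-means with 25 seeded restarts.

## Consensus NMF subtyping

The factorization V ≈ WH uses V = proteins × samples (fraction-of-total
scaled, case samples only), W = protein weights (f × k), H = sample
coefficients (k × s) — the orientation required by entropy-based feature
extraction on W. Updates are the multiplicative Kullback–Leibler rules
(Brunet-style):

    H_as ← H_as · [Σ_f W_fa V_fs/(WH)_fs] / Σ_f W_fa
    W_fa ← W_fa · [Σ_s V_fs/(WH)_fs H_as] / Σ_s H_as

initialized uniform-random from a seeded generator. The generalized KL
divergence D(V‖WH) = Σ V log(V/(WH)) − V + WH is non-increasing under these
updates and is asserted numerically (tolerance 1e−9 relative) on every run.
A run stops when the sample connectivity (argmax over H columns) is
unchanged for 40 consecutive checks taken every 10 iterations, capped at
2000 iterations; a run that hits the cap without a stable connectivity is
excluded from the consensus with a warning.

Cluster stability per rank k is the consensus matrix C̄ (mean over restarts
of the co-clustering indicator) and its cophenetic correlation: the Pearson
correlation between the off-diagonal distances 1 − C̄ and the cophenetic
distances of their average-linkage dendrogram. The rank survey uses 50
restarts per k over k = 2..6 and selects the argmax of the cophenetic
coefficient (ties toward the smaller rank); the final fit repeats the
consensus with 200 restarts at the selected rank. Subtype labels come from
cutting the average-linkage tree of 1 − C̄ (more stable than any single
run's argmax). Restart i uses seed base_seed + i, so the whole procedure is
reproducible from one integer.

Metaproteins are extracted with the entropy-based score on rows of W
(Kim–Park): with contributions q_a = W_fa/Σ_a W_fa, the score
S(f) = 1 + (1/log2 k) Σ_a q_a log2 q_a is 0 for uniform and 1 for
subtype-exclusive weights, and is invariant to row rescaling. The
metaprotein threshold is median(S) + 3·MAD(S) — a robust analogue of the
mean + 3·SD rule in the original feature-extraction method, chosen because
the score distribution under magnitude-weighted NMF is strongly skewed; the
policy string is configurable. Each metaprotein is assigned to the subtype
with its largest W weight, with factor columns permuted (Hungarian
assignment on the label confusion) to line up with the consensus labels.

## Concordance

Subtype robustness is re-checked with k-means (25 seeded restarts) and Ward
hierarchical clustering on Euclidean distances of row-z-scored data (Ward
chosen to target compact, k-means-comparable clusters; the linkage used by
the original heat-map analysis is not recoverable). Agreement with the NMF
labels is unweighted Cohen's kappa after optimal label alignment (Hungarian
assignment on the negated confusion matrix, equivalent to exhaustive
search over permutations for small k).

## Survival analysis

Kaplan–Meier estimation with Greenwood variance and log-log confidence
intervals; G-group log-rank tests from the observed-minus-expected vector
with multivariate hypergeometric variance (Moore–Penrose fallback on a
singular variance matrix). Cox proportional-hazards fits use Efron tie
handling (the less biased common default). Cutpoint search for a continuous
marker follows the maximally selected rank-statistic approach: every
midpoint between consecutive distinct marker values defining a split with
at least `minprop` (default 0.1) of samples on each side is scored by the
absolute standardized two-group log-rank statistic, and the maximizing
threshold is returned (ties toward the smaller threshold). No p-value
adjustment for the maximal selection is computed — the downstream use is
the cutoff itself, not its significance. PFS is the default endpoint for
cutpoint optimization.

## Risk stratification

The Hans rule maps CD10/BCL-6/MUM1 calls to GCB vs non-GCB (CD10+ → GCB;
CD10−/BCL6− → non-GCB; CD10−/BCL6+ → MUM1 decides); unknown inputs
propagate. The biomarker cascade keeps candidates that (1) differ between
responders and non-responders (rank-sum p < 0.05), (2) predict both PFS and
OS in univariate Cox fits, and (3) remain significant in multivariate Cox
fits adjusted for the IPI score, ranked by multivariate PFS hazard ratio.
The decision rule flags a patient high-risk iff IPI ∈ {3,4,5} or
(IPI ≤ 2 and marker > cutoff); the default cutoff 180.636 pg/ml is the
published circulating TIMP-1 threshold, and strict inequality at the
boundary is used ("higher than" the cutoff). Identification accuracy is
sensitivity among event patients — the fraction of patients who relapse
within 12 months (or die within 48 months) that a rule flags high; since
the combined rule's flagged set contains the IPI-only set, its improvement
in percentage points is non-negative by construction. The subtype
classifier is a seeded random forest on a small marker panel with a
stratified 70/30 split and rank-statistic AUCs.

## Numerical and testing choices

- All stochastic stages take explicit integer seeds; identical seeds give
  bitwise-identical outputs.
- NMF guards denominators at float tiny; divergence terms with V = 0
  contribute WH only (0·log 0 ≡ 0).
- The acceptance script reruns the complete chain — simulate, preprocess,
  rank survey at 50 restarts over k = 2..6 — on the default cohort
  (150 cases, 80 controls, 400 distinct proteins; ~330 retained after the
  detection filter). These sizes are the package's default study
  conditions; the survey takes a few minutes on one CPU.
- Known limitations: argmax-cophenetic rank selection is only meaningful
  when under-ranked merges are ambiguous (see the balanced-proportions
  note above); the cascade's stage thresholds are unadjusted p < 0.05 at
  each stage, as in the emulated workflow, so its family-wise error is not
  controlled; kappa values on synthetic cohorts are not comparable to any
  particular real cohort's values.
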
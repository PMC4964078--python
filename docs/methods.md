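# Methods

This note documents the models and procedures implemented in `nodesig`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Data model and standardization

Expression enters as a genes/probes × samples matrix on a log2 (RMA-like)
scale; upstream array normalization and quality control are out of scope.
Scoring operates on per-row Z values, z = (x − row mean)/row SD, computed
with the sample (n−1) standard deviation. Zero-variance rows are dropped
rather than zero-filled so no downstream correlation or scoring step can
divide by zero; every drop is reported. Z-standardization mimics the way
assay-style scores are transferred onto microarray cohorts: each gene is
expressed relative to the cohort, so scores are cohort-relative quantities,
not absolute assay read-outs.

Multiple probes per gene are collapsed by averaging their Z rows. The mean
of unit-variance rows has variance ≤ 1, so collapsed matrices keep the
`zscore` scale flag but relax the unit-SD invariant; the alternative
(picking the max-variance probe) was rejected because it makes scores
discontinuous under probe-set changes.

## Cohort curation

Cohorts are restricted to ER+/HER2− tumours with complete ER, LN and DMFS
records. Removals are attributed deterministically in the order
missing-clinical → ER− → HER2+, each sample counted once. When HER2 status
must be called from expression, each designated HER2 probe is fit with a
two-component Gaussian mixture; a sample is overexpressed when its posterior
membership in the upper-mean component exceeds 0.5, and a tumour is HER2+
if *any* HER2 probe is overexpressed. The mixture is treated as degenerate —
falling back to a mean + 2·SD threshold — when the component means are
closer than half the pooled within-component SD *or* when BIC prefers a
single component. The second clause matters: a unimodal probe is typically
split into two half-components whose means are several component-SDs apart,
which passes the distance check while being meaningless; the model
comparison catches it.

## Signature fixtures

* **Recurrence score.** The 16 prognostic genes in their seven published
  groups with the published group weights and combination coefficients
  (GRB7 0.47, ER −0.34, proliferation 1.04, invasion 0.10, CD68 0.05,
  GSTM1 −0.08, BAG1 −0.07). Housekeeping genes, group floors and the 0–100
  rescaling are omitted: on the Z scale the score is a plain linear form,
  centred near zero.
* **PAM50 / ROR.** The 50 intrinsic-subtype genes with a gene × subtype
  centroid matrix and the subtype-correlation (ROR-S) combination
  coefficients (−0.34 LumA, +0.23 LumB, +0.12 Her2-enriched, +0.05 Basal;
  Normal-like carries no coefficient). The centroid **values** bundled here
  are a synthetic stand-in (`pam50_centroids_synthetic.tsv`) constructed
  from known subtype biology — proliferation genes low in Luminal A and high
  in Luminal B/Basal, luminal/ER genes high in Luminal A, the ERBB2 amplicon
  high in HER2-enriched, basal keratins high in Basal — because the original
  training centroids are not redistributable here. Scores computed against
  them are structurally faithful (rank-correlation profile combined with the
  published coefficients) but not numerically comparable to the commercial
  assay. A six-gene exclusion list (ANLN, CDCA1/NUF2, CXXC5, FOXC1,
  TMEM45B, UBE2T) mirrors platforms on which those probesets are absent;
  restricting to the remaining genes is an option on the scorer. In-silico
  ports on U133A-era arrays describe 45 available probesets while excluding
  six genes (50 − 6 = 44); the fixture keeps the six-gene list and leaves
  that mismatch documented rather than resolved.
* **Ellen.** The 69-record pathway annotation is transcribed literally; the
  signature is derived from it. One gene (NAT10) is annotated in both
  directions — low-risk under Gene Expression, high-risk under Epigenetics —
  an inconsistency in the annotation itself. Direction conflicts resolve
  deterministically to `poor` (flagging elevated risk is the conservative
  call), giving 58 unique genes (34 good / 24 poor); the publication's
  stated totals (57 genes, 33 good / 24 poor) are carried in the fixture
  metadata alongside the transcription-derived counts. The unique high-risk
  count is 24 under either reading.
* **Aliases.** A single alias map (Ki-67→MKI67, HER2→ERBB2, STK15→AURKA,
  CTSL2→CTSV, KNTC2→NDC80, CDCA1→NUF2, ORC6L→ORC6, …) is applied to both
  signature symbols and matrix row names at load/scoring time, so published
  and current symbols interoperate.

## Scores

RS and the mean-Z index are linear in the Z matrix (hence permutation-
equivariant and homogeneous); ROR is rank-based and invariant to any
strictly increasing transform of a sample's gene vector. Genes missing from
the matrix abort scoring with a named error instead of silently
renormalizing — fixture or namespace problems should surface, not dilute. The
directional index requires at least one gene of each direction; an
`allow_one_sided` escape hatch (used by the discovery flow, where a stratum
with a single adverse program can yield an all-poor signature) treats the
absent class as contributing a zero mean.

## Survival evaluation

Scores are standardized to unit sample SD before the Cox fit so hazard
ratios are per-SD and comparable across signatures (whether published HRs
are per-unit, per-SD, or group-vs-group is generally unstated; this package
fixes and records the convention). Fits use the Efron tie correction —
better behaved than Breslow with discrete follow-up times. Scores enter in
native orientation and the fit records it; Harrell's C is computed on the
risk orientation so C > 0.5 always means "prognostic in the claimed
direction". Ties in score contribute 0.5 per comparable pair. Kaplan–Meier
curves split at the median score with median ties deterministically assigned
to the high group; the two-group log-rank statistic accompanies the curves.
Degenerate inputs raise typed errors: fewer than two events, constant
scores, all-censored groups, or a median split that empties a group.

## Signature discovery

Nearest shrunken centroids with the standard equations: standardized
centroid distances d_kg = (x̄_kg − x̄_g)/(m_k(s_g + s0)) with
m_k = √(1/n_k − 1/n), pooled within-class SD s_g, fudge constant
s0 = median(s_g); soft-thresholding d′ = sign(d)·max(|d| − Δ, 0); the
discriminant sums (x − x̄′)²/(s + s0)² over surviving genes minus 2·log π_k,
with priors π_k the observed class proportions and ties broken to the class
listed first. In the two-class case n_k·m_k is symmetric in the classes, so
both classes' distances shrink to zero together and direction labels are
well defined for every surviving gene.

Outcome classes for training: `event` = distant metastasis within 120
months; `event_free` = metastasis-free with follow-up ≥ 120 months; samples
censored before 120 months are excluded from training (their class is
ambiguous) and counted.

Δ is chosen on a 30-point grid from 0 to max|d| by stratified 10-fold
cross-validation with a recorded seed. The default selection rule is the
**1-SE rule** — the largest Δ whose mean CV error is within one standard
error of the minimum — rather than the raw minimum (available as
`rule="min"`). The CV error curve is typically flat near its minimum, and
the raw-minimum rule then retains batches of pure-noise genes whose random
directions dilute the downstream mean-Z index; the 1-SE rule is the usual
practice for this classifier and empirically restores the planted-gene
recovery and held-out concordance of the scenarios below.

Surviving genes are labelled `poor` when their event-class shrunken centroid
exceeds the overall centroid, `good` otherwise, and combined into the
directional mean-Z index. Cross-cohort validation (train on one cohort,
score a second) is the default experiment shape, mirroring
discovery-to-validation transfer between independent patient series.

## Gene-set enrichment

Genes are ranked by signal-to-noise (μ_A − μ_B)/(σ_A + σ_B) between outcome
classes, each class SD floored at max(0.2·|class mean|, 0.2) — the standard
guard against near-constant genes dominating. Ordering is deterministic
(metric descending, then symbol ascending). Walking the list, set members
increment the running sum by |metric|^p / Σ_hits|metric|^p (p = 1 by
default) and non-members decrement by 1/(N − N_H); the enrichment score is
the signed maximum-magnitude deviation. Increments and decrements each sum
to one, so the walk ends at zero — a tested invariant. Significance comes
from phenotype permutation: NES = ES / mean(|permuted ES| of matching sign),
nominal p = fraction of same-sign permuted scores at least as extreme.
Same-sign normalization makes the nominal p slightly conservative for small
n_perm. Per-stratum execution (LN− and LN+ separately) is the intended
usage. FDR across collections and leading-edge analysis are not implemented.

## Synthetic cohorts

The generator emulates an ER+/HER2− tamoxifen-era cohort followed 10 years:

* **Expression:** per sample, each latent program (default: proliferation,
  immune, epigenetic, EMT; 10 member genes each) draws an activity
  ~N(0, 1); member genes read baseline + loading·activity + N(0, noise_sd)
  with loading 1, noise SD 1, baselines uniform on log2 6–10. The default
  gene universe embeds the bundled signature genes and maps programs onto
  biologically matching symbols (proliferation → BIRC5, MKI67, …; immune →
  CXCL12, JAK1, HLA-DPA1, …; epigenetic → NAT10, H3-3A, EZH2, …), so the
  real scoring pipeline is exercised end to end, topping up with inert
  filler genes to n_genes = 200.
* **Survival:** proportional hazards with a Weibull baseline, shape 1.2
  (accelerating hazard, a realistic event-time spread over 120 months)
  and scale 240 months, giving ≈ 35% 10-year events under the null;
  log-hazard = Σ_programs effect(stratum)·activity. Stratum-specific
  effects are the central mechanism: defaults plant an immune-protective
  effect only in LN+ (−0.8), an epigenetic (+0.8/+0.2) and proliferative
  (+0.6/+0.3) hazard stronger in LN−, and an EMT hazard stronger in LN+
  (+0.2/+0.5). LN+ prevalence is 0.4.
* **Censoring:** administrative at 120 months plus random dropout
  ~Exponential(mean 600 months). Changing the dropout rate leaves the
  latent truth untouched (tested).
* **Probe layer:** each gene emits 1–3 probes (per-probe offset SD 0.3,
  measurement noise SD 0.1) plus two designated HER2 probes around log2
  intensity 7 with a planted overexpressing subpopulation (default 10% of
  samples shifted +4), exercising the HER2 caller and probe collapse.

All randomness flows from a single seeded generator; a recorded seed
reproduces a cohort bit-for-bit.

What the generator does **not** emulate: batch and platform effects,
correlated program activities, non-proportional hazards, informative
censoring, probe-level saturation, and real gene–gene covariance beyond the
planted programs. Passing tests therefore demonstrate the pipeline's
statistical machinery under a clean proportional-hazards world, not
performance on real cohorts.

## Calibration and the end-to-end experiment

Problem sizes were chosen to make the checks statistically meaningful while
keeping the default suite quick: null calibration uses 100 replicates of
n = 400 (CI coverage of HR = 1 and concordance ≈ 0.5), parameter recovery
50 replicates of n = 500 with a planted per-SD log-hazard of 0.7, and GSEA
null size 200 random sets on label-shuffled data with 200 permutations. The
end-to-end experiment plants an LN+-only protective immune program (−0.9)
and an LN−-weighted adverse program (+0.9 LN− / +0.15 LN+), trains on the
LN+ stratum of a 600-sample cohort and validates on an independent
400-sample cohort: the discovered index should recover most planted immune
genes with direction `good`, achieve held-out concordance > 0.65 in its
informative (LN+) stratum, and stay near 0.5 in the mismatched LN− stratum —
the qualitative stratum-transfer phenomenon.

## Numerical conventions

Sample (n−1) SDs throughout; Wald 95% CIs with z = 1.96; Newton–Raphson
Cox fitting with the library default tolerances (toy fits agree with a grid
maximization of the partial likelihood to < 1e-3; instances with monotone
partial likelihood have no finite MLE and are excluded from such
comparisons); soft-threshold and running-sum identities hold to 1e-12;
deterministic tie-breaks everywhere a tie is possible (median split → high
group, discriminant → first-listed class, ranking → symbol order, CV Δ ties
→ larger Δ).

## Known limitations

* The ROR score is the correlation-only (ROR-S-like) variant; the
  proliferation-weighted and tumour-size-augmented variants of the
  commercial assay are not implemented, and the synthetic centroids preclude
  numeric comparison with published ROR values.
* No multivariable Cox with clinical covariates and no time-dependent
  effects.
* The bundled Ellen gene set stands in for the original discovery output;
  rebuilding it exactly would require the original probe-level cohort and
  software vintage.
* GSEA reports ES/NES and nominal p only — no FDR q-values.
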
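# Methods

This note documents the models, the numerical choices and the synthetic
cohort the test suite runs against, in the order the pipeline executes.

## Cohort model and preprocessing

The pipeline consumes an already-normalized methylation beta matrix
(CpGs × samples, beta ∈ (0,1)), a log2 expression matrix, and a sample
sheet (group, clinical subtype, sex, age, batch, treatment flags,
optional risk-allele dosages). Raw-intensity processing and array
normalization are out of scope by design: the analysis begins where a
normalized matrix ends.

Probe filtering is ordered and reported step by step: (1) detection-p
removal — a CpG is dropped when it fails p < 0.01 in *any* sample, the
strictest reading of a detection filter, chosen because a single failed
sample already corrupts a 64-sample group contrast; (2) removal of
SNP-overlapping probes; (3) retention of the top 5% of CpGs by
|Δβ| = |mean(case β) − mean(control β)|, computed on the beta scale
(Δβ is a beta-scale quantity), with boundary ties kept so the result is
order-free. The filter order follows the order in which the steps are
described for the assay; whether the Δβ cut should precede or follow
batch adjustment is genuinely ambiguous, and this implementation filters
first and adjusts afterwards.

Batch adjustment is the parametric empirical-Bayes location/scale
scheme: per feature, standardize under a design that carries the batch
indicators plus the protected group covariate; shrink per-batch
locations toward a normal prior and per-batch scales toward an
inverse-gamma prior, hyperparameters by method of moments, the usual
fixed-point iteration for the conditional posteriors; back-transform.
Only the parametric variant is implemented. A single batch returns the
input unchanged; a batch with fewer than two samples is an error because
its scale cannot be estimated. Note the adjustment is *not* exactly
idempotent: EB shrinkage re-shrinks residual batch-mean sampling noise
on every pass (a second pass moves values at the ~0.05 RMS level on
typical sizes while leaving batch means at zero); the tests assert that
true behaviour.

Group testing happens on M values, M = log2(β/(1−β)), whose noise is far
closer to Gaussian than the bounded beta scale.

## Moderated t and calling

For each feature a least-squares fit of
`value ~ intercept + group (+ covariates)` gives the group effect, the
residual variance s²_g with d_g df, and the unscaled coefficient
variance v_g. The variance prior (d₀, s²₀) is estimated from
z = log s²_g by the method of moments: with
e = z − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over ψ′(d_g/2)
equals ψ′(d₀/2), inverted by Newton iteration on the trigamma function;
d₀ is capped at 10⁶ to represent infinity, and a non-positive excess
takes the infinite-d₀ branch directly. Posterior variances
s̃²_g = (d₀s²₀ + d_g s²_g)/(d₀ + d_g) give
t = effect/(s̃_g √v_g) on d_g + d₀ df (normal when d₀ is infinite).
`prior_df` can be imposed: 0 reproduces the ordinary t exactly, ∞ forces
one common variance — both limits are tested.

Calls require two-sided p < 0.01 *and* BH FDR < 0.05, split by effect
sign (hyper/hypo for methylation, up/down for expression). The group
test uses no covariates by default — sex and age enter only at the meQTL
stage — but a covariate design is accepted. The cohort is treated as two
independent groups: a paired contrast is impossible for 48 cases vs 16
controls, so the "paired" wording that sometimes accompanies this design
is read as a moderated two-group contrast.

BH is the step-up adjustment q_i = min_{j≥i} m·p_(j)/j in sorted order;
it is checked against an exhaustive "smallest rejection level"
oracle over all permutations of small vectors, and against an
independent library implementation.

Treatment-confounding checks: per called feature, a two-sided rank-sum
test between treatment strata within cases, BH adjusted; plus PCA of the
called-feature submatrix with point-biserial correlations of the first
three PCs against the treatment flag and each PC's variance share. A
constant covariate or a stratum below two samples is flagged, not
tested.

## DMRs

CpGs are clustered at max gap 500 bp (clusters never span chromosomes);
the per-CpG effect is the case−control mean beta difference, smoothed by
a centered running mean of width 3 inside clusters with at least 3 CpGs
(bump-hunting-style defaults; effects are kept on the beta scale because
region magnitudes are communicated as Δβ). Candidates are maximal
same-sign runs with |effect| at or above the 0.95 quantile of all
smoothed |effects|. The null pools candidate areas from B = 200 group
relabelings at the *observed* cutoff;
p = (1 + #{null areas ≥ area}) / (1 + N_pooled) — the pooled-null
quantile convention, one-sided on area, invariant to candidate order and
calibrated under the null because observed and permuted areas are then
exchangeable. Reported DMRs need p < 0.05 and ≥ 2 CpGs. Fewer than 20
pooled null candidates triggers a resolution warning in the table
attributes. Loess smoothing and bootstrap nulls are not implemented.

## DVPs

Per CpG (beta scale, the convention of the published two-stage
algorithm): Bartlett's equal-variance test between groups, BH-adjusted,
must pass q < 0.001; a pooled two-sample t-test on the means must pass
p < 0.05 — the regularization step that anchors variance hits to some
mean signal; called DVPs are ranked by the t p-value. Zero-variance rows
are skipped with a flag. Direction is gain/loss by the case/control
variance ratio. The thresholds are the published algorithm's own
defaults, since nothing else is specified for them.

## Region enrichment

All interval arithmetic is 0-based half-open; 1-based annotation
positions are converted exactly once at the boundary. Overlap counting
uses a sorted-start/prefix-max-end index (O(log n) per query), verified
against the all-pairs brute force. For each of B = 1000 permutations a
background matched in count — and in per-interval length for region
queries, centred on randomly drawn universe CpGs (without replacement
within a permutation) — is sampled from the array annotation; each
permutation yields a 2×2 overlap table, a Haldane-corrected (+0.5) odds
ratio and a two-sided Fisher exact p (the sidedness is recorded in the
result). The *averages* over permutations decide significance:
avg p < 0.01 and avg OR > 1, so depletion can never be flagged.
Single-CpG queries use the bare position by default; a `--flank` option
widens them (e.g. ±250 bp) when a window is wanted.

## cis meQTL

Candidate pairs: same chromosome, |CpG position − TSS| ≤ 5 Mb, boundary
inclusive; the TSS anchors the distance for consistency with the
promoter-window definition. Methylation (M values) and expression are
residualized on sex and age (with intercept) across all samples; r is
the Pearson correlation of residuals with t = r√((n−2−k)/(1−r²)) on
n−2−k df — the partial-correlation reading of "correlation with
covariates", equivalent to the additive linear model's slope test. With
no covariates this is plain Pearson to machine precision (tested).
Significant pairs (raw p < 0.01; no extra multiplicity correction at
this stage — FDR control already happened at DMP/DEG calling, and the
raw-p convention here is deliberate) are intersected with the DMP and
DEG call sets; both unique-feature counts and the negative/positive
split are reported. Promoter-proximal classification uses the
strand-aware window TSS−5 kb to TSS+1 kb (1-based inclusive; upstream is
5′ in transcription orientation, so it has the higher coordinates on the
minus strand).

## 3D confirmation and SNP integration

A pair (CpG, gene) is confirmed in a cell state iff some interaction of
that state lists the gene among its bait symbols (case-insensitive,
whitespace-stripped, no alias resolution) and contains the CpG in its
other-end fragment, *and* the CpG lies in no gene's promoter window —
promoter-proximal CpGs are the short-range regulation case and are
excluded from the long-range evidence. The same −5 kb/+1 kb window
serves both the exclusion and the proximal classification (one knob
controls both). Confirmation is consolidated across the three CD4
states (union, per-state counts, shared-by-all); the erythroblast set
only contributes a specificity fraction. Interaction significance is
assumed upstream: the input file defines the interactome.

SNP integration applies three sequential filters with per-step counts
(monotone nonincreasing by construction): the SNP's target genes must
include a called DEG; that DEG must own a confirmed pair; and the pair's
DMP host gene — the first annotated gene whose span TSS−5 kb through
transcript end (transcription orientation) contains the CpG, with no
nearest-gene fallback — must itself be a target of the same SNP. Hits
carry all three evidence flags. Risk-genotype stratification uses the
Jonckheere-Terpstra monotone-trend test across dosage groups (normal
approximation; pairwise Mann-Whitney counts with a 0.5 tie credit),
falling back to a rank-sum test when only two dosage groups occur and
flagging fewer than two; the trend test is this package's choice of
statistic for dosage-ordered comparisons.

## The synthetic cohort

`synthgen` emulates the study conditions: 48 cases vs 16 controls, two
chromosomes of 50 Mb (so the 5 Mb window is non-trivial), two balanced
batches, a fragment map tiling each chromosome with lognormal sizes of
median 5 kb (a HindIII-like digest), ~85% female, ages uniform 30-70.
Beta baselines are a two-component mixture (low ≈ 0.1, high ≈ 0.85, 60%
high — typical array bimodality); per-sample noise and batch shifts act
on the M scale (sd 0.4 and 0.5); group effects act on the beta scale;
betas are clipped to (0.001, 0.999). CpGs taking part in a planted
coupling are re-based to intermediate methylation (0.35-0.65) with
2× noise — the high-inter-individual-variance regime real cis-meQTL
CpGs occupy, and the reason coupling slopes near 2 are detectable at
n = 64. Expression is baseline + Gaussian noise (sd 0.3) + group log2FC
+ slope × centred beta at coupled CpGs.

Three generator choices deserve emphasis because they are what make the
recovery tests well-posed rather than cosmetic:

* **DVPs are patient-subset shifts, not pure variance scaling.** A
  planted DVP shifts a random half of the cases on the M scale by the
  amount that delivers the requested case/control variance ratio. This
  is the patient-heterogeneity mechanism the two-stage caller is built
  for — its t-test regularization would reject a symmetric equal-mean
  variance inflation by construction, so an equal-mean generator could
  never be detected by a faithful implementation.
* **Coupled effects are sign-consistent.** For a planted coupling the
  DEG's group fold change takes the sign of slope × Δβ, modelling the
  expression shift as propagating through the methylation shift (the
  causal chain the filter sequence embodies). Independent random signs
  would let the between-group component cancel the within-group
  correlation and make pooled-sample recovery a coin flip.
* **Risk alleles push in the disease direction**: per-allele beta and
  log2 shifts at the coupled CpG/gene share signs with the planted
  group effects, so dosage, methylation and expression remain
  monotonically associated for the trend test.

The default planted study (`design_cohort`) generates the annotation
first and then chooses planted features from the realised geometry:
coupling CpGs sit outside every promoter window and within 5 Mb of the
target TSS; the four "full interactome" couplings additionally sit
inside a host gene whose symbol joins the SNP's target set. Decoy SNP
links fail each filter step in roughly equal numbers (non-DEG targets /
DEG without confirmed pair / confirmed pair but host not targeted).
Planted effect sizes (Δβ ≈ 0.15-0.25, |log2FC| ≈ 0.8-1.5, |slope| ≈
1.5-2.5, variance ratio 10) are calibration choices on the realistic
end of what arrays report; no published effect-size distributions exist
for this design to copy.

What the generator does **not** emulate: probe-level artefacts (dye
bias, detection failures are synthesized only as an explicit table),
LD structure in genotypes, read-level Hi-C noise, cell-composition
shifts, or correlated noise between neighbouring CpGs beyond planted
regions. Passing recovery tests therefore demonstrates the correctness
and calibration of the inference chain under its own model, not
robustness to every artefact of real arrays.

## Problem sizes and determinism

The acceptance checks run at the cohort's own sample size (48/16)
with 1000-5000 features, B = 200 (DMR) and B = 1000 (enrichment)
permutations, and 5-100 Monte Carlo seeds per quantity — sizes chosen so
the full suite completes in a few minutes on one CPU while keeping
binomial noise on the estimated rates well below the asserted margins;
the DVP detection rate sits nearest its bound (~94% vs ≥90%), so that
check uses the largest seed count. All randomness flows from explicit
seeds (`numpy` Generator streams; per-stage child seeds derived from the
master seed), outputs are written with fixed float formatting, and a
rerun of the pipeline with the same config and seed is byte-identical —
this is itself a test.

## Known limitations

* The moderated-t engine covers two-group contrasts (with optional
  covariates) only; no F-tests across more than two groups — subtype
  analyses are re-invocations on sample subsets.
* ComBat is parametric-prior only.
* meQTL significance is raw-p by design; users wanting FDR across pairs
  must adjust downstream.
* Gene symbols are matched literally (case-insensitive); no alias
  tables.
* The DMR caller's counts on real data depend strongly on cutoff and
  smoothing settings; the defaults here are conventional, not tuned to
  reproduce any published region count.
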
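# Methods

## Scoring model

Expression is consumed on the log2 scale after upstream normalization
(RMA/quantile normalization for arrays, log-transformed normalized counts
for sequencing); `senquad` performs no probe-level processing. For gene *g*
in study *s*, z-standardization uses the non-missing samples of that study:
z = (x − mean_gs) / sd_gs with the sample standard deviation (ddof = 1).
Standardizing **per study** is what makes pooling heterogeneous studies
meaningful: any additive study offset (platform, lab, batch) cancels
exactly, as does any per-gene affine rescaling within a study. A pooled
mode (`per_study=False`) exists for single-platform cohorts.

Two degenerate cases are handled explicitly:

* a (gene, study) cell with zero variance is set missing rather than given
  z = 0 — assigning 0 would shrink set scores toward the global mean and
  dilute real signal; the drop is logged;
* a study with fewer than two samples cannot be standardized and is a hard
  error naming the study.

A gene-set score is the arithmetic mean of the available member z-values
for each sample; missing values are omitted, never imputed. Coverage
(matched members / set size) below `min_coverage` (default 0.5) warns but
does not filter — the threshold is a reporting aid, not a rule, since no
principled universal cutoff exists. A set with zero matched members is an
error. Matching is exact case-insensitive HGNC; alias/ortholog resolution
is deliberately out of scope (a documented limitation — users with probe-
or alias-level identifiers should map them upstream).

## Quadrant statistics

Quadrants are formed at the medians of the two score vectors over the
analyzed samples (per analyzed collection, not per sub-panel), with the tie
rule value ≤ split → low side. The rule makes degenerate inputs
well-defined (all-identical scores land in Q3) and mirrors the age-median
tie rule below. Samples missing either score are excluded listwise.

Enrichment of group G in quadrant Q conditions on all margins of the 2×2
table (a = G∩Q, b = G∖Q, c = Ḡ∩Q, d = Ḡ∖Q). Under the null, a follows the
central hypergeometric law; under odds ratio ψ, the Fisher noncentral
hypergeometric with weights w(x) ψˣ, w(x) = C(a+b, x)·C(c+d, a+c−x).

* **p-value** (alternative "greater"): P(X ≥ a) via `scipy.stats.hypergeom`.
  "less" is the lower tail; "two-sided" sums all outcomes with point
  probability ≤ that of a (with a 1e−7 relative tolerance, as R does).
* **Odds ratio**: the conditional MLE, i.e. the root of E_ψ[X] = a, found
  by Brent's method on log ψ with the pmf evaluated by log-sum-exp
  (xtol 1e−12). At the support boundary the MLE is 0 or +∞. The conditional
  MLE, not the sample cross-product ratio, is what R's `fisher.test`
  reports, so results are directly comparable with analyses run there.
* **Confidence bound**: the exact one-sided limit solves
  P_ψ(X ≥ a) = α in ψ (again Brent on log ψ). The residual of the returned
  root is below 1e−10 — tighter than R's `uniroot` default, so the last
  printed digits can differ from R at ~1e−4 relative while satisfying the
  defining equation more precisely. Two-sided intervals use α/2 per side.
* An empty margin makes ψ unidentifiable: p = 1, OR/CI reported absent with
  a warning.

The default contrast tests Q3 over-enrichment of the senescent (or old, or
early-stage) group, one-sided, α = 0.05, and also reports the complementary
group for paired bar-plot exports. One-sided is the default because the
hypothesis (downregulation ⇒ Q3 excess) is directional and the
published convention prints one-sided "L–Inf" intervals; a two-sided flag
is provided. No multiple-testing correction is applied across quadrants or
set pairs — the analysis is descriptive per contrast, and consumers who
scan many contrasts should correct downstream.

## Grouping rules

* Age decades: 20/30/40 → young, 50/60/70 → old, others excluded (ages come
  in 10-year bands in GTEx-style metadata; "60-69" is accepted).
* Median age: > median → old, ≤ median → young. The ≤-goes-low tie rule is
  chosen for consistency with the quadrant rule.
* Age quartiles A1–A4: boundaries at the empirical 25/50/75 percentiles
  (linear interpolation), ≤ boundary → lower bin; rank-based, so monotone
  relabelings of age do not change bins.
* Tumor stage: strings are normalized by stripping a leading "stage" token
  and trailing substage letters (IA → I, IIIB → III; arabic 1–4 accepted).
  Scheme A: I → early (the only noninvasive, localized state), II–IV →
  late. Scheme B: I–II → early, III–IV → late. Stage 0, stage X and
  unparseable strings are excluded rather than coerced, so scheme A's early
  group is always a subset of scheme B's.

## Synthetic-cohort generator

The generator draws gene g in sample i as

    x[g,i] = mu_g + b_s(i) + rho·L_g·f_cat(g),i + shift_g(group_i)
             + sigma·sqrt(1−rho²)·e[g,i]

with mu_g ~ N(8, 1) (typical log2 microarray intensity), per-study batch
b_s ~ N(0, tau), one standard-normal latent factor per functional category
(TREX, TREX-2, TREX-AFs, NPC, NTR, Ran) with loading rho for member genes
and 0 for background genes, shift −delta·sigma for target genes and
+delta_marker·sigma for marker genes in senescent samples, and N(0, 1)
residuals. With sigma = 1 a category member has unit variance and pairwise
within-category correlation rho² — the block-collinearity structure that
motivates set-level scoring. Markers are modeled as background genes with
an upward shift, reproducing the opposite (Q1) enrichment expected of
CDKN1A/CDKN2A.

Defaults: 5 studies × (6+6) samples, 200 background genes, delta = 1,
delta_marker = 1, rho = 0.5, tau = 1, sigma = 1. The cohort layout matches
a small in-vitro senescence compendium; delta = 1 residual sd is a
moderate, clearly detectable shift (the harness sweeps delta from 0 to 2
precisely because the real-world effect size is not pinned down). The model
is Gaussian on the log2 scale: it does not emulate count noise, probe
artifacts, platform mixing, or realistic clinical covariate distributions —
so passing recovery tests demonstrates correctness of the statistics under
the stated model, not robustness to every real-data pathology.

### Effect recovery and attenuation

Pipeline z-scores divide by the pooled over-groups sd, which for a balanced
two-group study contains the group shift itself: the expected z-scale score
difference is −delta/sqrt(1 + delta²/4) (for sigma = 1), i.e. attenuated at
large delta. `recovery_experiment` therefore reports both that raw score
difference and `delta_hat`, an estimate built from per-gene, per-study
standardized differences using the pooled *within-group* sd with Hedges'
small-sample factor J = 1 − 3/(4k−1), rescaled by sqrt(Vw)/sigma
(Vw = rho² + sigma²(1−rho²)). This estimator is unbiased for delta under
the generative model and is the quantity compared to the true delta in the
recovery checks.

### Monte-Carlo sizes

The operating-characteristic checks use 1,000 replicates for type-I error
at the default cohort size (5 × (6+6)) and 150 replicates per point for the
power/recovery grid at 200 pooled samples (5 × (20+20)); these sizes give
MC standard errors below 0.007 on rates while keeping the whole harness at
desk scale (≈ one minute). Replicate seeds are spawned deterministically
from the experiment seed via `numpy.random.SeedSequence`, so every number
is reproducible from a single integer.

## Known limitations

* Registry membership is a literature-based curation pinned to the
  canonical category sizes (16/5/8/31/11/4); users tracking a specific
  curation should supply their own GMT. NPC subclasses deliberately
  overlap (the long-lived-nucleoporin class is orthogonal to the
  structural classes), so subclass disjointness is not enforced.
* The exact test conditions on both margins and is conservative
  (type-I error below nominal α), as the null simulations show.
* Real-tissue contrasts (GTEx/TCGA-style) require the user to provide the
  normalized matrices; downloading and upstream normalization are out of
  scope.
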
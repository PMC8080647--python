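# senquad

Gene-set quadrant-enrichment analysis of senescence transcriptomes.

Cellular senescence is accompanied by a coordinated transcriptional
downregulation of the mRNA-export machinery (the TREX, TREX-2 and
TREX-associated-factor complexes, collectively *TREXes*) and of the classical
nucleocytoplasmic trafficking machinery (nuclear pore complexes, karyopherin
transport receptors and the Ran cycle, collectively *NCTFs*). Because the
member genes of each functional unit are highly collinear, the signal is
detected at the gene-set level rather than gene by gene. `senquad` implements
that analysis as a reusable pipeline for bulk (and pseudobulk) expression
cohorts:

1. **Signature scoring.** Each gene is z-standardized within its study
   (mean 0, sd 1, sample sd with *n*−1; missing values omitted), and a
   sample's score for gene set *S* is the mean z-value over the members of
   *S*: `score_i(S) = mean_{g∈S} z_{gi}`. Per-study standardization removes
   platform and batch offsets so samples from many studies can be pooled.
2. **Quadrant assignment.** Samples are placed in the plane of two set
   scores (default x = TREXes, y = NCTFs) and split into quadrants at the
   two score medians: Q1 upper-right, Q2 upper-left, Q3 lower-left, Q4
   lower-right (ties fall on the low side). Q3 — low on both axes — is the
   senescence-associated quadrant.
3. **Exact enrichment statistics.** For a 2×2 table of (group ×
   in/out of quadrant) with cell *a* and margins fixed, the one-sided
   p-value is the hypergeometric tail P(X ≥ a); the odds-ratio estimate is
   the **conditional MLE** ψ̂ maximizing the Fisher noncentral
   hypergeometric likelihood, and the one-sided 95% bound solves
   P_ψ(X ≥ a) = α exactly — the conventions of R's `fisher.test`, whose
   intervals print as "L–Inf". ψ̂ is 0 or ∞ at the boundary of the support.
4. **Cohort grouping rules** for tissue analyses: age-decade dichotomy
   (20s–40s young vs 50s–70s old), median-age dichotomy, age quartiles, and
   two tumor-stage dichotomies (scheme A: stage I vs II–IV; scheme B: I–II
   vs III–IV), with TCGA-style substage normalization (IIIB → III).
5. **Synthetic cohorts.** A generative model of multi-study cohorts (batch
   shifts, per-category latent factors for within-set correlation,
   senescent-group downregulation of target genes and upregulation of the
   CDKN1A/CDKN2A markers) makes every stage testable end to end and powers
   the type-I-error / power / effect-recovery harness.

The curated default registry covers TREX (16 genes), TREX-2 (5), TREX-AFs
(8), NPC (31, with Y-complex / FG / transmembrane / basket / long-lived-Nup
subclasses), NTR (11), Ran (4), and the senescence markers CDKN1A/CDKN2A.
Any registry can be substituted via standard GMT files.

## Worked example

Simulate a 5-study cohort (6 senescent + 6 nonsenescent samples per study,
one-residual-sd downregulation of the target machinery) and run the
quadrant analysis:

```sh
senquad simulate --out sim --seed 7 --delta 1.0
senquad enrich --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --target-group senescent --out enr
```

`enr/enrichment.tsv` contains one row per (quadrant × group); the senescent
rows for Q1 and Q3 read:

```text
comparison    quadrant group     a  b  c  d  odds_ratio ci_lower    ci_upper p              alpha alternative
TREXes~NCTFs  Q1       senescent 0  30 26 4  0          0           Inf      1              0.05  greater
TREXes~NCTFs  Q3       senescent 26 4  0  30 Inf        38.88008158 Inf      3.921376915e-13 0.05 greater
```

26 of 30 senescent samples fall in Q3 and none of the 30 nonsenescent
samples do, so the conditional-MLE odds ratio is infinite (the observed
cell sits at the top of the hypergeometric support), the exact one-sided
95% interval is 38.9–Inf, and the one-sided p-value is 3.9 × 10⁻¹³; Q1
shows the mirror-image depletion (OR = 0). `enr/scatter.tsv` holds the
per-sample scores and quadrant labels for plotting, and
`enr/enrichment.json` the same results with provenance.

The same analysis runs on real cohorts: a log2-scale expression TSV (genes ×
samples, already RMA/quantile-normalized upstream), a metadata TSV with
`sample_id`, `study_id` and a group column (or `age`/`age_decade`/`stage`
columns plus `--grouping age_median|age_decade|age_quartiles|stage_a|stage_b`),
and optionally `--gmt` to override the bundled gene sets.

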
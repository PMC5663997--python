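# reomet

Rank-based gene-pair risk classification and downstream metastasis analysis
for tumor expression cohorts.

A sample is classified from the *within-sample* ordering of signature gene
pairs: for each pair (gene_a, gene_b), expression(gene_a) > expression(gene_b)
is a vote for high risk. A configurable k-of-n voting rule (majority, or a
strict threshold such as 7-of-9 low votes for a low-risk call) turns the
votes into a label. Because only orderings inside one sample are consulted,
labels are invariant to any monotone per-sample transform — no cross-sample
normalization is needed.

On top of the classifier the package provides the downstream analyses such a
signature enables:

- **Calibration** of the strict voting threshold against a target high-risk
  fraction (e.g. the clinically observed 35–50% relapse interval).
- **Survival evaluation**: Kaplan–Meier curves, log-rank test, uni/multivariate
  Cox models (Efron ties, via lifelines), Harrell's C-index, and event rate at
  a horizon (default 60 months).
- **Metastasis-state reclassification**: a sample stays nonmetastatic only if
  it is clinically nonmetastatic *and* called low risk; association with
  clinical metastasis is measured with Fisher's exact test.
- **Differential expression**: CV-filtered pooled-variance t-tests with BH-FDR,
  DE-list direction concordance (exact binomial), proliferation scores,
  hypergeometric gene-set enrichment, subtype chi-square association.
- **Genomic lesions**: prevalence filtering (> 5% of samples), per-lesion
  Fisher tests (amp/del tested as separate binary lesions, BH within each
  family), per-sample burden comparison, Spearman expression–copy-number
  correlation.
- **Driver network**: significant metastasis-enriched lesions are mapped to
  candidate driver genes (mutations directly; CNA regions through network
  regulators with positive dosage coupling), then linked to DE genes through a
  directed regulator→target edge list, with per-driver target enrichment and
  two-hop reachability.
- **Synthetic cohorts** (`reomet.synth`): a seeded generator producing an
  expression matrix whose pair orderings track a latent metastasis state,
  clinical labels with occult false negatives, risk-dependent exponential
  survival, planted differential lesions, and a planted driver — so the whole
  pipeline is testable end to end without external data.

## Command line

```bash
# generate a synthetic cohort
reo-metastasis simulate --seed 17 --outdir cohort/

# classify samples under the strict 7-of-9 rule
reo-metastasis classify --expr cohort/expression.tsv \
    --signature cohort/signature.tsv --rule 7:of:9 --out calls.tsv

# calibrate the threshold to a target high-risk fraction
reo-metastasis calibrate --expr cohort/expression.tsv \
    --signature cohort/signature.tsv --ks 6-9 --interval 0.35,0.50

# survival contrast of the risk groups
reo-metastasis survival --calls calls.tsv --clinical cohort/clinical.tsv \
    --endpoint os --out surv.json

# reclassify metastasis states and report the association table
reo-metastasis reclassify --calls calls.tsv --clinical cohort/clinical.tsv \
    --out labels.tsv --association-out assoc.json

# full pipeline from one YAML config
reo-metastasis run --config cfg.yaml --outdir bundle/
```

A pipeline config lists input paths and the rule:

```yaml
inputs:
  expression: cohort/expression.tsv
  clinical: cohort/clinical.tsv
  signature: cohort/signature.tsv
  cna: cohort/cna.tsv
  region_map: cohort/region_map.tsv
  edges: cohort/edges.tsv
  gene_sets: cohort/gene_sets.gmt
rule: {k: 7, n: 9}        # or "majority", or {calibrate: {ks: [6,7,8,9]}}
```

Every stage writes plain TSV/JSON plus a `manifest.json` recording the
thresholds, seed, and a config hash, so rerunning the same config reproduces
the bundle byte-for-byte.

## File formats

Expression: TSV, genes × samples, header of sample ids. Clinical: TSV keyed by
`sample_id` with stage / survival / metastasis columns (times in months; a
`days` unit flag converts). Mutations: MAF-style TSV (nonsynonymous classes
configurable). Copy number: GISTIC-style gene/region × sample TSV, continuous
(thresholded at ±0.3, strict) or discrete. Networks: two-column TSV or SIF.
Gene sets: GMT. Signature: TSV with `gene_high` / `gene_low` columns.

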
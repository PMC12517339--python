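# bts-finemap

Joint Bayesian fine-mapping of GWAS variants and context-mapping of
functional annotation tracks, from summary statistics and LD.

The model factors each variant's causal posterior into an
**annotation-independent Bayes factor** term — computed once per region over
all causal configurations of size ≤ d, via a matrix-inversion-lemma form
that tolerates perfect-LD (singular) sub-matrices — and an
**annotation-dependent logistic prior** term. Annotation enrichment
coefficients are estimated by EM across regions; each track is scored by a
likelihood-ratio test against the annotation-free (intercept-only) null
model. Because the Bayes factors are cached and shared across all tracks
and EM iterations, scanning many tracks is cheap.

## Layout

| module | contents |
|---|---|
| `bts.core_model` | configuration enumeration, log Bayes factors, the perfect-LD pairwise closed form, the pruned Bayes-factor store, logistic priors, marginal posteriors, credible sets |
| `bts.enrichment_em` | total log-likelihood, EM fitting, LRT, per-track scan, annotated-vs-null posterior deltas |
| `bts.region_prep` | sumstats allele normalization, LD from a dosage panel, greedy LD pruning, LD expansion, block definition/merging, exclusion regions, BED overlap matrices |
| `bts.synthetic_data` | AR(1) genotype panels, Z-scores from the summary-statistic likelihood, annotated datasets with known enrichment, the LD-mismatch scenario |
| `bts.bundle` | on-disk region bundles, store serialization, manifests, dataset emission |
| `bts.reporting` / `bts.cli` | pipeline orchestration, report tables, `bts` command |

## CLI

End-to-end from full summary statistics (TSV with header
`chrom pos ref alt effect_allele beta se pvalue` or `... z pvalue`), a
genotype dosage panel (TSV, rows = samples, columns = `chrom:pos:ref:alt`
keys), and a track manifest (TSV: `track_id path label`, one BED per
track):

```sh
bts run --sumstats sumstats.tsv --panel panel.tsv \
        --tracks tracks.manifest.tsv --out results/ \
        [--d 2 --t 12 --w 1 --r2 0.7 --p-gwas 5e-8 \
         --window 1000000 --max-flank 1000 --ann-p 0.01 \
         --top-post 0.5 --delta 0.2 --exclude hla.bed --seed 1]
```

Outputs in `--out`: `annotations.tsv` (per-track enrichment scan, sorted by
LRT p-value), `region_by_context.tsv` (prioritized region × context table),
`variants.tsv` (per-variant posteriors, null posteriors, deltas,
credible-set membership), `credible_sets.tsv`, `regions.tsv`, and
`run_summary.json`.

Other commands:

```sh
bts simulate --out simdata --n-regions 20 --seed 1   # synthetic dataset
bts scan --bundles simdata/bundles --out results/    # model stages only
```

`bts simulate` writes region bundles (`<region>.z.tsv`, `<region>.ld.tsv`,
`<region>.annotations.tsv`), BED tracks with a manifest, the ground-truth
record, and pipeline-style `sumstats.tsv` / `panel.tsv`.

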
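# faime

Single-sample pathway **mechanism scoring** via exponentially rank-weighted
expression, plus the downstream analysis chain: directional
differential-mechanism signatures, cross-dataset signature overlap
statistics, and prognostic stratification with survival analysis.

## What it does

For each sample, genes are ranked by expression (highest gene receives the
maximal rank `|G|`, ties averaged) and weighted `w = r * exp(-r / |G|)`.
A mechanism (a named geneset — GO Biological Process terms from NCBI
`gene2go`, Cancer Modules from a GMT file, or anything else) is scored as
the mean weight of its member genes minus the mean weight of the
non-members; per sample, scores are rescaled by subtracting the per-sample
minimum across the collection's mechanisms. Because the transformation is
rank-based, any strictly monotone transform of a sample's expression
leaves its scores unchanged.

Downstream:

- **differential** — per-mechanism two-sample t-test (pooled by default,
  Welch optional), Benjamini–Hochberg FDR, and a directional signature:
  mechanisms with `q <= fdr`, each tagged `+1` (up in tumor) or `-1`.
- **overlap** — directional intersection across datasets (direction
  concordance required), percentages against each signature's own size,
  one-sided Fisher exact p-values on the common tested universe, and a
  fixed-size subset bootstrap (default 10,000 draws, add-one-corrected
  empirical p) for gene-level overlap.
- **prognosis** — restrict a validation cohort's scores to a signature,
  split samples with deterministic two-cluster PAM (BUILD + SWAP,
  Euclidean distance), and compare recurrence-free survival between the
  clusters with Kaplan–Meier curves and the log-rank test.
- **simulate** — seed-deterministic synthetic fixtures: geneset
  collections, multi-cohort two-group expression with planted directional
  deregulation, and exponential recurrence times for two latent prognosis
  groups, written in the exact formats the readers consume.

## CLI

```bash
# generate a synthetic 3-cohort fixture (writes pipeline.yaml alongside)
faime simulate --outdir fixtures/ --seed 1

# score one expression matrix against a GMT collection
faime score --expr expr.tsv --gmt sets.gmt --out scores.tsv \
    --rank-orientation high-is-max --min-size 5

# directional signature at FDR 5%
faime diff --scores scores.tsv --groups pheno.tsv --fdr 0.05 \
    --out records.tsv --sig-out sig.tsv

# cross-dataset overlap (directional) or gene-level bootstrap
faime overlap --sig a.tsv --sig b.tsv --mode directional --out overlap.tsv
faime overlap --sig a.tsv --sig b.tsv --mode genes --gmt sets.gmt \
    --draws 10000 --seed 1 --out gene_overlap.tsv

# PAM stratification + Kaplan-Meier / log-rank
faime prognose --scores val_scores.tsv --sig sig.tsv --surv surv.tsv --out prog/

# the whole pipeline from a YAML config
faime run --config fixtures/pipeline.yaml --outdir results/
```

Every run writes a `manifest.json` with parameters, seeds, input
checksums, and the tool version. Numeric outputs are byte-reproducible
under fixed seeds.

### File formats

- expression: TSV, first column gene ids, header row sample ids
  (`--orientation` to transpose); gzip accepted.
- genesets: GMT (`name<TAB>description<TAB>gene...`) or NCBI gene2go
  8-column format (`faime score --gene2go gene2go.tsv --taxon 9606`).
- phenotype: TSV `sample_id  group` (exactly two group labels).
- survival: TSV `sample_id  time  event` (event 1 = recurrence observed).

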
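# gapsel

Genomics-assisted prediction (GAP) and simulative selection for fruit
storage-retainability traits in bi-parental F1 crosses.

The package implements the full analysis pipeline around QTL-derived
diagnostic markers:

- **phenotype** — scores monthly cold-storage firmness/crispness series to an
  integer *retainability* (months the trait stays at or above its
  acceptability threshold: 7.0 kg/cm² firmness, 0.7 kg/cm² crispness),
  classifies softening dynamics into types I/II/III, estimates broad-sense
  heritability from multi-year records (one-way ANOVA), and computes trait
  correlations.
- **marker_effects** — estimates per-marker genotype-class effects as
  deviations of class means from the overall training mean, and classifies
  allelic action (additive / partial / complete dominant / overdominant)
  from the |d/a| ratio.
- **gap_model** — pyramids marker effects onto the training mean to get a
  genomics-predicted value (GPV) for every hybrid with a complete genotype,
  evaluates Pearson accuracy against observed values (OPV), and runs
  repeated k-fold cross-validation.
- **selection** — truncation selection at a GPV criterion with selection
  rate and efficiency.
- **candidate_filter** — candidate-gene exclusion rules over QTL intervals,
  variant annotations, expression, and DEG membership.
- **synthetic_data** — seeded generators for F1 populations (Mendelian
  segregation, (a, d) marker effects, target heritability), storage
  trajectories per softening type, and candidate-filter fixtures with
  construction-known truth; every downstream stage is testable without
  external data.
- **io_tables** — TSV/CSV genotype, phenotype and storage tables, BED
  intervals, a minimal VCF subset, and model JSON. Internal coordinates are
  0-based half-open.

## CLI

All stages are subcommands of `gapsel` (logs to stderr, results to files):

```sh
gapsel simulate --config sim.yaml --out-dir sim/
gapsel score-phenotype --storage storage.tsv --trait firmness --out retain.tsv
gapsel heritability --pheno pheno.tsv --trait firmness
gapsel effects --geno geno.tsv --pheno retain.tsv --out effects.tsv
gapsel fit --geno geno.tsv --pheno retain.tsv --out model.json
gapsel predict --model model.json --geno geno.tsv --pheno retain.tsv --out pred.tsv
gapsel cv --geno geno.tsv --pheno retain.tsv --k 5 --runs 5 --seed 17 --out cv.tsv
gapsel select --pred pred.tsv --criterion 5.0 --out selection.json
gapsel filter-candidates --qtls qtls.bed --genes genes.bed --variants variants.vcf \
    --expression expression.tsv --degs deg_ids.txt --out survivors.json
gapsel run-all --config sim.yaml --out-dir run/   # end-to-end smoke test
```

A minimal `sim.yaml`:

```yaml
seed: 123
n_hybrids: 500
population_mean: 2.0
target_h2: 0.84
marker_panel: {n_markers: 28, span_min: 0.1, span_max: 3.5}
k: 5
runs: 5
criterion: 5.0
```

## Input schemas

- Genotype table: first column `hybrid_id`, optional `population`, one
  column per marker; cells `X:Y`, `X` (homozygous), or a missing token
  (`NA`, `-`, `./.`, empty). Allele order is not meaningful (`G:A` ≡ `A:G`).
- Phenotype table: `hybrid_id`, `trait`, `opv` (months), optional `year`.
- Storage table: `hybrid_id`, `trait`, `month` (integer), `value` (kg/cm²);
  duplicate (hybrid, trait, month) rows are averaged as technical replicates.

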
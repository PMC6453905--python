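# surfdbm

Surfaceome database mining of bulk RNA-seq abundance tables.

`surfdbm` takes per-sample transcript abundance tables (the standard
pseudo-alignment TSV dialect: `target_id  length  eff_length  est_counts  tpm`),
aggregates them to a gene × sample TPM matrix, restricts the matrix to a
curated catalogue of genes encoding cell-surface and secreted proteins, and
mines the result for genotype-specific surface markers across the four DN
thymocyte developmental stages (DN1–DN4) of a two-genotype
(transgenic vs wild-type), replicated study design:

- **Expression classes** — every TPM value falls in exactly one of four bins:
  ZERO `[0, 0.1)`, LOW `[0.1, 1)`, MED `[1, 10]`, HIGH `(10, ∞)`.
- **Tile matrices** — per stage, a 4 × 4 contingency of each gene's class in
  wild type vs transgenic (16 tiles), built from replicate-mean TPMs.
- **Differential screen** — a gene is *up* at a stage iff its transgenic
  replicate-mean TPM is > 1 **and** exceeds 10 × the wild-type mean (strict,
  multiplicative, so zero comparators need no division); *down* is the
  genotype-mirrored rule.
- **Venn partition** — the per-stage up (and down) sets partitioned into the
  15 disjoint membership regions across DN1–DN4, including the all-stage
  intersection.
- **Candidate markers** — genes whose maximum transgenic stage mean is > 20
  TPM with ≥ one stage above a 5× fold gap, with per-stage means reported.
- **Expression calls** — strict `value > 4` (FPKM) cohort calls and tidy
  per-marker summary tables.
- **Sample structure** — log2(TPM + 1) transform, PCA with a deterministic
  sign convention (scores, loadings, explained variance, sorted loading
  weights, per-component silhouette for stage and genotype groupings), and
  Pearson/Spearman sample–sample correlation.
- **Synthetic data** — a seeded generator emitting the exact input dialects
  with planted marker effects (log-normal baselines, stage programs that
  dominate the leading principal components, genotype effects confined to a
  small planted surfaceome set, replicate noise), plus precision/recall
  scoring of recovery against the planted truth.

## CLI

```sh
# generate a synthetic dataset (abundance TSVs, t2g map, catalogue, sample
# sheet, truth.json) from a flat YAML config
surfdbm simulate --config sim.yaml --out dataset/

# run the full mining pipeline
surfdbm run --config run.yaml --out results/

# render a completed run directory as text (with artifact consistency checks)
surfdbm report results/
```

A minimal `run.yaml` only needs the three input paths; every threshold
defaults to the published value and can be overridden:

```yaml
sample_sheet: dataset/samples.tsv
t2g: dataset/t2g.tsv
surfaceome: dataset/surfaceome.tsv
# diff_fold: 10        # up/down fold threshold
# diff_min_mean: 1     # mean TPM gate
# candidate_min_tpm: 20
# candidate_min_fold: 5
# expression_threshold: 4
# pseudocount: 1
# n_components: 6
```

`simulate` accepts the `SyntheticConfig` fields (`n_genes`, `n_surfaceome`,
`n_replicates`, `noise_sd`, `planted: [{n_genes, stages, log2_fold,
direction}]`, `seed`, ...). Unknown keys are rejected by name. Exit codes:
0 success, 2 validation error, 1 runtime error.

`run` writes: the surfaceome-filtered matrix (TSV + metadata sidecar),
per-stage tile matrices with margins, the differential table, up/down Venn
region JSONs, the candidate table, PCA scores/loadings/explained-variance,
the sorted loading weights of the genotype-separating component, the sample
correlation matrix, and a machine-readable `report.json` echoing the
configuration. Identical inputs and config produce byte-identical outputs.

## Library

```python
from surfdbm import (
    read_abundance, aggregate_to_genes, assemble_matrix,
    load_surfaceome, filter_to_surfaceome,
    classify_expression, tile_matrix, differential_by_stage, venn_partition,
    select_candidates, log_transform, run_pca, sample_correlation,
    SyntheticConfig, generate_dataset, evaluate_recovery,
)
```

## Tests and acceptance report

```sh
python -m pytest -q tests/          # unit + property + acceptance-criteria suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` regenerates a synthetic dataset from the given seed,
runs the pipeline end to end, and reports the structural acceptance target
(the 16-cell class-transition matrix). The two real-data targets require the
study's supplementary tables / an external cohort download and are omitted
offline (a note is printed to stderr).
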
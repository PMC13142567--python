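# grexstream

Streaming individual-level imputation of **genetically regulated gene
expression (GReX)** from chromosome-split PLINK2 genotypes and sparse
transcriptomic prediction weights.

TWAS-style prediction models express a gene's cis-regulated expression as a
weighted sum of local variant dosages.  Applied cohort-wide this is one large
sparse linear problem,

    Y = G × B

where `G ∈ ℝ^{n×m}` holds ALT-allele dosages for *n* individuals and *m*
variants, `B ∈ ℝ^{m×k}` holds the (highly sparse) variant weights of *k*
gene-model pairs, and `Y ∈ ℝ^{n×k}` is the imputed expression matrix.  At
biobank scale the obstacle is computational: naive pipelines load `G` whole
and multiply densely.  grexstream instead

- streams genotypes in SNP chunks, never holding `G` in memory,
- pre-indexes `B` by variant so each streamed variant touches only the
  gene-model columns it actually feeds (updates further decomposed into row
  chunks across samples),
- harmonizes weight predictors to genotype records first — effect-allele
  orientation resolved with strand complementation permitted, and the dosage
  transform `d → 2−d` applied where the effect allele is the REF allele —
  with strand-ambiguous (A/T, C/G) sites accepted in exact orientation only,
- allocates each output column lazily at its first contributing variant and
  flushes it to disk when its last variant has been processed, so peak memory
  tracks the number of *simultaneously active* columns, and
- writes a compact, preallocated column-major binary trio
  (`prefix.grom` values + `prefix.gid` column manifest + `prefix.sid` sample
  manifest) with a selective reader that touches only the bytes of the
  columns you request.

Intended for statistical-genetics practitioners running TWAS/GReX pipelines
who need individual-level predictions across many tissue or cell-type models
without HPC-sized memory.

## Worked example

Generate a small synthetic cohort and impute it:

```python
from pathlib import Path
from grexstream import FixtureSpec, generate_cohort, run_impute, ImputeConfig, grom_read

fx = generate_cohort(FixtureSpec(n_samples=50, n_variants_per_chrom=80,
                                 n_models=2, genes_per_model=5,
                                 variants_per_gene=4, seed=7), "demo")
result = run_impute(ImputeConfig(weights_path=fx.weights_path,
                                 pgen_dir=fx.pgen_dir,
                                 grom_pfx=Path("demo") / "out"))
print(result.n_columns, result.n_samples, result.peak_active_columns)
values, gid, sid = grom_read(Path("demo") / "out")
print(values.shape)
```

prints

```
10 50 2
(50, 10)
```

— 10 gene-model columns for 50 individuals were written, and at no point did
more than 2 output columns have live accumulators.  `values` is the imputed
expression matrix; `gid`/`sid` map its columns to (ancestry, model, gene)
triples and its rows to sample IIDs.  The same run from a shell:

```sh
grexstream impute --weights demo/weights.tsv --pgen-dir demo/geno --out demo/out
grexstream read --prefix demo/out --genes M1G000 --tsv one_gene.tsv
```

A `<prefix>_meta/` directory records the chromosome→fileset mapping, the
per-entry harmonization verdicts (exact / swapped / complement /
complement_swapped / ambiguous_strand / unmatched), per-column coverage, and
a machine-readable run summary.  PrediXcan-style SQLite models can be merged
in with `--db model.db --db-model-id brain --db-ancestry EUR`.

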
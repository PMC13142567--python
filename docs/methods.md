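# Methods

## The model

Individual-level GReX imputation is a fixed sparse linear map: for sample
*i* and gene-model column *c*,

    y_ic = Σ_j  w_jc · t_jc(d_ij)

where the sum runs over the variants *j* with nonzero weight in column *c*,
`d_ij ∈ [0,2]` is the ALT-allele dosage, and `t_jc` is either the identity
or the flip `d → 2−d`, depending on whether the model's effect allele for
that entry is the genotype file's ALT or REF allele.  There is no
statistical estimation anywhere in the package: weights are taken as given,
and every design question is about computing `Y = G×B` exactly, cheaply,
and reproducibly.

## Harmonization

Weight predictors and genotype records frequently disagree on allele
encoding.  Each weight entry is resolved once, before any streaming, to a
genotype row ordinal, a signed weight, and a dosage transform:

1. effect = ALT (and other = REF when stated) → `exact`, identity;
2. effect = REF → `swapped`, flip;
3. the same two cases after strand complementation (A↔T, C↔G; multi-base
   alleles reverse-complement) → `complement` / `complement_swapped`.

At a **strand-ambiguous site** (allele pair {A,T} or {C,G}) the complement
of the pair *is* the swapped pair, so cases 2 and 3 cannot be told apart and
the flip decision is undecidable.  Such entries are accepted only in exact
orientation; otherwise they get status `ambiguous_strand`, are excluded
from the computation, and appear in the audit report.  Indels are matched
without complementation.  Positional (chromosome–position–REF–ALT) matching
is used when a full allele-pair key exists; plain weight tables carry only
rsid + effect allele, so those entries are anchored by rsid and oriented
against the manifest row's alleles — rsid never overrides allele evidence.
Multi-allelic manifest rows are never matched.

Entries lost to harmonization are not errors: a column that loses every
variant is still emitted, as an all-zero prediction, and flagged in the
coverage report, so the output column space is always exactly the catalog
of loaded (ancestry, model, gene) triples.

## Streaming engine

Variants are processed in strictly ascending ordinal; within a variant,
columns in ascending position; within a column update, samples in
contiguous row chunks.  Accumulation is always float64, whatever the output
precision (single-precision output rounds once, at flush).  Consequences:

- output is bit-identical across every SNP-chunk × row-chunk geometry, a
  property the tests assert exactly;
- the engine is single-threaded by design — the determinism contract is
  single-stream;
- the lifecycle (allocate a column's accumulator at its first contributing
  variant, flush at its last) can be *predicted* from the matched index
  alone (`column_lifecycle_plan`), and the predicted peak active-column
  count must equal the instrumented peak of a real run.

One output column must draw all its variants from one chromosome (cis
models do); a column claimed by two chromosomes is a hard error rather than
a silently half-flushed column.  Chromosomes are processed in natural sort
order (chr1, chr2, …, chr10, …) so column offsets never depend on directory
listing order.

## Genotype input

PLINK2 chromosome-split filesets are discovered by token-exact filename
matching: the `chrN` label must be delimited by non-alphanumerics, so
`chr1` can never bind `ukb_chr11`; zero or multiple candidates are hard
errors.  Two dosage backends satisfy one streaming contract: `.pgen` via
the optional Pgenlib bindings, and a plain-text dosage matrix (one
tab-separated row per variant in `.pvar` order, one column per `.psam`
sample, `NA` for missing) used by fixtures and tests — a fixture format,
not a production interchange format.

**Missing dosages** are mean-imputed per variant over the analyzed samples
at read time (all-missing → 0), the dominant convention in GReX scoring;
the per-run imputed-value count is recorded in the run summary so
concordance deviations against tools with a different policy are
diagnosable.  Sample subsetting is applied before computation, so every
buffer is sized to the analyzed individuals, and the subset also defines
the imputation means.

## Output format

`prefix.grom` is a 32-byte header (8-byte magic `GROMv001`, u64 rows, u64
columns, 1-byte value code, zero-filled reserve; all little-endian)
followed by the value matrix in contiguous column-major order.  The file is
preallocated to its exact final size at creation, columns may land in any
order, and rewriting an ordinal is an error.  Column *c* occupies bytes
`32 + c·n·s … 32 + (c+1)·n·s`, so the selective reader provably touches
only `32 + c_requested·n·s` bytes — the structural property behind low read
I/O.  `.gid`/`.sid` are header-bearing TSV, by analogy with `.pvar`/
`.psam`.  The layout here is frozen for this implementation;
property-compatible with, but not byte-compatible with, other tools'
binary outputs.  Default precision is double: storage at desk scale is
cheap and it keeps the oracle comparisons tight; single precision is
offered for very large cohorts.

## Concordance metrics

`concordance` aligns two prediction sets by column triple and sample id and
computes per-column Pearson *r* and RMSE on raw predicted values, reporting
the minimum *r* and maximum RMSE.  Constant columns (zero variance in
either source — e.g. fully-unmatched all-zero columns) have no defined
correlation; they are excluded from the Pearson summary and counted, but
retained for RMSE.  An optional seeded draw of shared samples (one draw per
report by default; per-column redraw behind a flag) mirrors subsampled
benchmarking of very large cohorts.

## Synthetic cohorts

The fixture generator emulates exactly what the pipeline consumes: Hardy–
Weinberg hard-call dosages `Binomial(2, MAF)` with MAF uniform on a stated
range, a stated missing rate, cis-local weight vectors (a contiguous run of
variants per gene) with effects `0.3·N(0,1)`, and deliberate re-encodings —
stated fractions of entries with swapped and/or complemented alleles, and a
stated fraction of strand-ambiguous sites.  It carries its own dense ground
truth (full `G`, analytic `Y`, per-entry expected match status), so each
module is tested against independent expectations rather than another
module's output.  Defaults are the desk-scale study conditions: 2,000
samples, 5,000 variants over two chromosomes, 300 gene-model pairs from 4
models, MAF ∈ [0.05, 0.5], 1% missing, 10% swapped, 10% complemented, 10%
ambiguous sites, 10 variants per gene (typical cis-model sparsity; neither
more realism nor LD structure would exercise any contract here, since the
computation is a fixed linear map).

What passing tests do **not** show about real data: no linkage
disequilibrium, no relatedness or population structure, no genotype
uncertainty beyond hard calls, rsid dialects always consistent with the
manifest, and weights that are genuinely cis-local.  The harmonization and
format guarantees are data-independent; the distributional realism of the
cohort is not the point.

## Numerical choices and edge cases

- Zero weights are dropped at load (counted), keeping per-column variant
  counts meaningful for the flush lifecycle.
- Duplicate weight entries — same (rsid, effect allele, column), or two
  entries resolving to one (variant, column) — are hard errors, never
  summed: silent summation masks malformed model exports.
- Accumulators are checked finite at flush; a violation names the column
  and its ordinal span.
- Engine tolerance against the dense reference is ≤1e-9 absolute in
  double precision; chunk-geometry invariance is asserted bit-exactly.
- PrediXcan-style `.db` imports carry no chromosome, ancestry, or model
  label: the model/ancestry labels are caller-supplied, and the chromosome
  is resolved by rsid against the manifests; entries whose rsid appears in
  no fileset are reported unmatched.

## Known limitations

- No multithreading; throughput relies on chunked vectorized updates.
- No liftover, no frequency-based disambiguation of A/T–C/G sites, no
  FUSION `.RDat` weights, no VCF/BGEN input, no `.pgen` writing.
- The `.pgen` backend requires the optional Pgenlib bindings and is
  exercised only where they are installed.
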
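"""Seeded synthetic cohorts for every test surface.

The generator emulates the inputs the imputation pipeline consumes — a weight
table, chromosome-split genotype filesets (text dosage backend; .pgen too
when the pgenlib bindings are importable) — and, crucially, carries its own
dense ground truth (the full genotype matrix and the analytic expectation of
every output column), so downstream modules are tested against independent
expectations rather than against each other.

Dosages are drawn per variant as binomial(2, MAF) — Hardy-Weinberg hard
calls — with MAF uniform in the requested range and a stated fraction masked
missing.  Weight vectors pick a contiguous run of variants per gene (cis
locality) with effects from a standard normal scaled by 0.3.  Stated
fractions of entries are re-encoded with swapped and/or strand-complemented
alleles, and a stated fraction of sites carries a complementary (A/T or C/G)
allele pair; the matching ground-truth status of every entry is recorded.
Generation is a pure function of the spec, including the seed.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 2000
    n_variants_per_chrom: int = 2500
    chromosomes: tuple[str, ...] = ("chr1", "chr2")
    n_models: int = 4
    genes_per_model: int = 75
    variants_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    frac_swapped: float = 0.10
    frac_complemented: float = 0.10
    frac_ambiguous_sites: float = 0.10
    ancestry: str = "EUR"
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_variants_per_chrom",
            "n_models",
            "genes_per_model",
            "variants_per_gene",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "missing_rate",
            "frac_swapped",
            "frac_complemented",
            "frac_ambiguous_sites",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.variants_per_gene > self.n_variants_per_chrom:
            raise ConfigError(
                "variants_per_gene exceeds the variants available per chromosome"
            )


@dataclass(frozen=True)
class WeightEntryTruth:
    """Ground truth for one written weight row."""

    chromosome: str
    rsid: str
    ancestry: str
    model_id: str
    gene: str
    effect_allele: str
    other_allele: str  # the non-effect allele as encoded
    weight: float
    variant_ordinal: int  # within the chromosome fileset
    expected_status: str
    expected_transform: str  # identity / flip / "" when excluded


@dataclass
class CohortFixture:
    """Everything the generator wrote, plus its analytic expectations."""

    spec: FixtureSpec
    root: Path
    weights_path: Path
    pgen_dir: Path
    chrom_prefixes: dict[str, Path]
    sample_ids: list[str]
    catalog_triples: tuple[tuple[str, str, str], ...]  # sorted, = column order
    expected_y: np.ndarray  # n_samples x k, sorted-catalog column order
    dosages_imputed: dict[str, np.ndarray]  # chrom -> n x m (missing mean-filled)
    dosages_raw: dict[str, np.ndarray]  # chrom -> n x m with NaN for missing
    entries: list[WeightEntryTruth]
    expected_status_counts: dict[str, int]
    expected_column_matched: dict[int, int]


def _truth_status(effect: str, ref: str, alt: str, ambiguous: bool) -> tuple[str, str]:
    """Independent case analysis of the final encoded allele strings."""
    if effect == alt:
        return "exact", "identity"
    if effect == ref:
        if ambiguous:
            return "ambiguous_strand", ""
        return "swapped", "flip"
    if _COMP[effect] == alt:
        return "complement", "identity"
    if _COMP[effect] == ref:
        return "complement_swapped", "flip"
    return "unmatched", ""


def generate_cohort(spec: FixtureSpec, out_dir: str | Path) -> CohortFixture:
    """Write a full cohort fixture under ``out_dir`` and return its truth."""
    rng = np.random.default_rng(spec.seed)
    root = Path(out_dir)
    pgen_dir = root / "geno"
    pgen_dir.mkdir(parents=True, exist_ok=True)

    n = spec.n_samples
    m = spec.n_variants_per_chrom
    sample_ids = [f"S{i:06d}" for i in range(n)]

    site_ref: dict[str, list[str]] = {}
    site_alt: dict[str, list[str]] = {}
    site_ambiguous: dict[str, np.ndarray] = {}
    rsids: dict[str, list[str]] = {}
    dosages_imputed: dict[str, np.ndarray] = {}
    dosages_raw: dict[str, np.ndarray] = {}
    chrom_prefixes: dict[str, Path] = {}

    for chrom in spec.chromosomes:
        positions = 1000 + np.cumsum(rng.integers(1, 100, size=m))
        ambiguous = rng.random(m) < spec.frac_ambiguous_sites
        refs: list[str] = []
        alts: list[str] = []
        for j in range(m):
            if ambiguous[j]:
                ref, alt = _AMBIGUOUS_PAIRS[rng.integers(0, 4)]
            else:
                ref = _BASES[rng.integers(0, 4)]
                others = [b for b in _BASES if b != ref and b != _COMP[ref]]
                alt = others[rng.integers(0, len(others))]
            refs.append(ref)
            alts.append(alt)
        ids = [f"rs{chrom[3:]}_{j:06d}" for j in range(m)]

        mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
        raw = rng.binomial(2, mafs[:, None], size=(m, n)).astype(np.float64)
        if spec.missing_rate > 0:
            raw[rng.random((m, n)) < spec.missing_rate] = np.nan
        imputed = raw.copy()
        for j in range(m):
            mask = np.isnan(imputed[j])
            if mask.any():
                rest = imputed[j][~mask]
                imputed[j][mask] = float(rest.mean()) if rest.size else 0.0

        prefix = pgen_dir / f"cohort_{chrom}"
        with open(f"{prefix}.pvar", "wt", encoding="utf-8") as fh:
            fh.write("##fileformat=PVARv1.0\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
            for j in range(m):
                fh.write(f"{chrom}\t{positions[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}\n")
        with open(f"{prefix}.psam", "wt", encoding="utf-8") as fh:
            fh.write("#IID\n")
            for s in sample_ids:
                fh.write(s + "\n")
        pd.DataFrame(raw).to_csv(
            f"{prefix}.dosage.tsv",
            sep="\t",
            header=False,
            index=False,
            na_rep="NA",
            float_format="%g",
        )

        site_ref[chrom], site_alt[chrom] = refs, alts
        site_ambiguous[chrom] = ambiguous
        rsids[chrom] = ids
        dosages_raw[chrom] = raw.T.copy()
        dosages_imputed[chrom] = imputed.T.copy()
        chrom_prefixes[chrom] = prefix

    # --- weights ---------------------------------------------------------
    entries: list[WeightEntryTruth] = []
    for t in range(spec.n_models):
        model_id = f"model{t + 1}"
        for g in range(spec.genes_per_model):
            gene = f"M{t + 1}G{g:03d}"
            chrom = spec.chromosomes[rng.integers(0, len(spec.chromosomes))]
            start = int(rng.integers(0, m - spec.variants_per_gene + 1))
            weights = rng.normal(0.0, 1.0, size=spec.variants_per_gene) * 0.3
            weights[weights == 0.0] = 0.3  # standard normal never truly zero
            for v in range(spec.variants_per_gene):
                j = start + v
                ref, alt = site_ref[chrom][j], site_alt[chrom][j]
                effect, other = alt, ref
                if rng.random() < spec.frac_swapped:
                    effect, other = other, effect
                if rng.random() < spec.frac_complemented:
                    effect, other = _COMP[effect], _COMP[other]
                status, transform = _truth_status(
                    effect, ref, alt, bool(site_ambiguous[chrom][j])
                )
                entries.append(
                    WeightEntryTruth(
                        chromosome=chrom,
                        rsid=rsids[chrom][j],
                        ancestry=spec.ancestry,
                        model_id=model_id,
                        gene=gene,
                        effect_allele=effect,
                        other_allele=other,
                        weight=float(weights[v]),
                        variant_ordinal=j,
                        expected_status=status,
                        expected_transform=transform,
                    )
                )

    weights_path = root / "weights.tsv"
    with open(weights_path, "wt", encoding="utf-8") as fh:
        fh.write("chromosome\tancestry\tmodel_ID\tgene\trsid\teffect_allele\tweight\n")
        for e in entries:
            fh.write(
                f"{e.chromosome}\t{e.ancestry}\t{e.model_id}\t{e.gene}\t"
                f"{e.rsid}\t{e.effect_allele}\t{e.weight!r}\n"
            )

    # --- analytic expectation -------------------------------------------
    triples = tuple(sorted({(e.ancestry, e.model_id, e.gene) for e in entries}))
    col_of = {t: i for i, t in enumerate(triples)}
    expected_y = np.zeros((n, len(triples)), dtype=np.float64)
    status_counts: dict[str, int] = {}
    column_matched: dict[int, int] = {c: 0 for c in range(len(triples))}
    for e in entries:
        status_counts[e.expected_status] = status_counts.get(e.expected_status, 0) + 1
        if e.expected_transform == "":
            continue
        col = col_of[(e.ancestry, e.model_id, e.gene)]
        column_matched[col] += 1
        d = dosages_imputed[e.chromosome][:, e.variant_ordinal]
        if e.expected_transform == "flip":
            expected_y[:, col] += e.weight * (2.0 - d)
        else:
            expected_y[:, col] += e.weight * d

    return CohortFixture(
        spec=spec,
        root=root,
        weights_path=weights_path,
        pgen_dir=pgen_dir,
        chrom_prefixes=chrom_prefixes,
        sample_ids=sample_ids,
        catalog_triples=triples,
        expected_y=expected_y,
        dosages_imputed=dosages_imputed,
        dosages_raw=dosages_raw,
        entries=entries,
        expected_status_counts=status_counts,
        expected_column_matched=column_matched,
    )


def generate_predixcan_db(
    fixture: CohortFixture, model_id: str, db_path: str | Path
) -> Path:
    """Mirror one model of a cohort fixture into the PrediXcan .db schema.

    Writes the conventional ``weights(rsid, gene, weight, ref_allele,
    eff_allele)`` table plus an ``extra`` table (present in real model
    databases and ignored by the loader).
    """
    rows = [e for e in fixture.entries if e.model_id == model_id]
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.execute(
            "CREATE TABLE weights (rsid TEXT, gene TEXT, weight REAL, "
            "ref_allele TEXT, eff_allele TEXT)"
        )
        con.execute("CREATE TABLE extra (gene TEXT, n_snps INTEGER)")
        con.executemany(
            "INSERT INTO weights VALUES (?, ?, ?, ?, ?)",
            [
                (e.rsid, e.gene, e.weight, e.other_allele, e.effect_allele)
                for e in rows
            ],
        )
        genes = sorted({e.gene for e in rows})
        con.executemany(
            "INSERT INTO extra VALUES (?, ?)",
            [(g, sum(1 for e in rows if e.gene == g)) for g in genes],
        )
        con.commit()
    finally:
        con.close()
    return db_path
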
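"""Allele harmonization: aligning weight predictors with genotype variants.

A weight file states which allele its coefficient multiplies (the effect
allele); the genotype file counts copies of its own ALT allele.  Before any
arithmetic, every predictor must be resolved to a genotype row plus a dosage
transform:

* effect allele == ALT  -> identity (use the dosage d as-is);
* effect allele == REF  -> flip (use 2 - d);
* the same two cases after strand complementation (A<->T, C<->G), because
  model exports and genotype files may sit on opposite strands.

Strand-ambiguous sites — allele pair {A, T} or {C, G} — are the classic trap:
there the complement of the pair equals the swapped pair, so a "swapped"
match cannot be told apart from a complement match and the flip decision is
undecidable.  Such sites match only in the exact orientation; anything else
is reported as ``ambiguous_strand`` and excluded.  Indels (multi-base
alleles) match without complementation only.

Matching is positional (chromosome-position-ref-alt) when the predictor
carries both alleles and a full key is available; plain weight tables carry
only rsid + effect allele, so those are anchored by rsid and then oriented
against the manifest row's REF/ALT.  rsid never overrides allele evidence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .engine import MatchedIndex
from .errors import DataError, FormatError
from .genotype_io import PvarManifest
from .weights_io import ColumnCatalog, SparseWeightIndex, WeightRecord

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = (frozenset(("A", "T")), frozenset(("C", "G")))


class MatchStatus(str, enum.Enum):
    EXACT = "exact"
    SWAPPED = "swapped"
    COMPLEMENT = "complement"
    COMPLEMENT_SWAPPED = "complement_swapped"
    AMBIGUOUS_STRAND = "ambiguous_strand"
    UNMATCHED = "unmatched"


#: Statuses that resolve to a usable genotype row.
MATCHED_STATUSES = frozenset(
    {
        MatchStatus.EXACT,
        MatchStatus.SWAPPED,
        MatchStatus.COMPLEMENT,
        MatchStatus.COMPLEMENT_SWAPPED,
    }
)

#: Statuses whose contribution uses 2 - d instead of d.
FLIP_STATUSES = frozenset({MatchStatus.SWAPPED, MatchStatus.COMPLEMENT_SWAPPED})


@dataclass(frozen=True)
class VariantKey:
    chromosome: str
    position: int
    allele_a: str  # effect allele
    allele_b: str  # other allele


@dataclass(frozen=True)
class MatchResult:
    status: MatchStatus
    genotype_ordinal: int | None
    dosage_transform: str  # "identity" or "flip"

    def __post_init__(self) -> None:
        has_ordinal = self.genotype_ordinal is not None
        if has_ordinal != (self.status in MATCHED_STATUSES):
            raise ValueError(
                "genotype ordinal must be present exactly for matched statuses"
            )


def complement_allele(allele: str) -> str:
    """Base-wise complement; reverse-complement for multi-base alleles."""
    allele = allele.upper()
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError as exc:
        raise FormatError(f"cannot complement allele {allele!r}: non-ACGT base") from exc


def is_strand_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True for the complementary pairs A/T and C/G (single-base only)."""
    return frozenset((allele_a.upper(), allele_b.upper())) in _AMBIGUOUS_PAIRS


def _is_acgt(*alleles: str) -> bool:
    return all(a and set(a) <= set("ACGT") for a in alleles)


def orient_alleles(
    effect: str, other: str | None, ref: str, alt: str
) -> tuple[MatchStatus, str]:
    """Resolve a predictor's allele orientation against one manifest row.

    ``other`` may be None (plain-table predictors); then only the effect
    allele constrains the match.  Returns (status, transform).
    """
    effect = effect.upper()
    other = other.upper() if other is not None else None
    snv = (
        len(effect) == 1
        and len(ref) == 1
        and len(alt) == 1
        and (other is None or len(other) == 1)
    )
    ambiguous_site = snv and is_strand_ambiguous(ref, alt)

    if effect == alt and (other is None or other == ref):
        return MatchStatus.EXACT, "identity"
    if effect == ref and (other is None or other == alt):
        if ambiguous_site:
            # Swap and strand-complement are indistinguishable here: the flip
            # decision cannot be made safely.
            return MatchStatus.AMBIGUOUS_STRAND, "identity"
        return MatchStatus.SWAPPED, "flip"
    if snv and not ambiguous_site and _is_acgt(effect, ref, alt) and (
        other is None or _is_acgt(other)
    ):
        ce = complement_allele(effect)
        co = complement_allele(other) if other is not None else None
        if ce == alt and (co is None or co == ref):
            return MatchStatus.COMPLEMENT, "identity"
        if ce == ref and (co is None or co == alt):
            return MatchStatus.COMPLEMENT_SWAPPED, "flip"
    return MatchStatus.UNMATCHED, "identity"


def match_variant(key: VariantKey, manifest: PvarManifest) -> MatchResult:
    """Positional (CPRA) matching of a full allele-pair key against a manifest.

    Candidate orientations are tried in a fixed order: exact, swapped, then
    both complemented forms; strand-ambiguous keys are allowed the exact
    orientation only and report ``ambiguous_strand`` when only a
    swap/complement would succeed.  All failures are statuses, never
    exceptions — they feed the audit report.
    """
    if key.chromosome != manifest.chromosome:
        raise DataError(
            f"key chromosome {key.chromosome} does not match manifest "
            f"chromosome {manifest.chromosome}"
        )
    effect = key.allele_a.upper()
    other = key.allele_b.upper()
    pos = key.position
    chrom = key.chromosome
    lookup = manifest.cpra_index.get

    def result(status: MatchStatus, ordinal: int | None) -> MatchResult:
        transform = "flip" if status in FLIP_STATUSES else "identity"
        return MatchResult(status, ordinal, transform)

    ordinal = lookup((chrom, pos, other, effect))
    if ordinal is not None:
        return result(MatchStatus.EXACT, ordinal)
    snv = len(effect) == 1 and len(other) == 1
    ambiguous_key = snv and is_strand_ambiguous(effect, other)
    ordinal = lookup((chrom, pos, effect, other))
    if ordinal is not None:
        if ambiguous_key:
            return result(MatchStatus.AMBIGUOUS_STRAND, None)
        return result(MatchStatus.SWAPPED, ordinal)
    if snv and not ambiguous_key and _is_acgt(effect, other):
        ce, co = complement_allele(effect), complement_allele(other)
        ordinal = lookup((chrom, pos, co, ce))
        if ordinal is not None:
            return result(MatchStatus.COMPLEMENT, ordinal)
        ordinal = lookup((chrom, pos, ce, co))
        if ordinal is not None:
            return result(MatchStatus.COMPLEMENT_SWAPPED, ordinal)
    return result(MatchStatus.UNMATCHED, None)


@dataclass
class MatchReport:
    """Per-entry harmonization audit for one chromosome."""

    rows: list[dict]
    n_matched: int
    n_unmatched: int
    n_ambiguous: int
    per_column_matched: dict[int, int]
    per_column_total: dict[int, int]

    @property
    def n_total(self) -> int:
        return self.n_matched + self.n_unmatched + self.n_ambiguous

    def to_frame(self) -> pd.DataFrame:
        columns = [
            "rsid",
            "ancestry",
            "model_ID",
            "gene",
            "effect_allele",
            "status",
            "genotype_ordinal",
            "dosage_transform",
            "reason",
        ]
        return pd.DataFrame(self.rows, columns=columns)

    def coverage_frame(self, catalog: ColumnCatalog) -> pd.DataFrame:
        rows = []
        for col in sorted(self.per_column_total):
            total = self.per_column_total[col]
            matched = self.per_column_matched.get(col, 0)
            ancestry, model_id, gene = catalog.columns[col]
            rows.append(
                {
                    "column_ordinal": col,
                    "ancestry": ancestry,
                    "model_ID": model_id,
                    "gene": gene,
                    "matched_variants": matched,
                    "total_variants": total,
                    "coverage": matched / total if total else 0.0,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "column_ordinal",
                "ancestry",
                "model_ID",
                "gene",
                "matched_variants",
                "total_variants",
                "coverage",
            ],
        )


def build_matched_index(
    records: Sequence[WeightRecord],
    catalog: ColumnCatalog,
    manifest: PvarManifest,
    index: SparseWeightIndex | None = None,
) -> tuple[MatchedIndex, MatchReport]:
    """Resolve every weight entry once, before streaming.

    Each record is anchored to a manifest row (by rsid for plain-table
    predictors; allele evidence then settles orientation), its dosage
    transform fixed, and the result recorded.  Unmatched and ambiguous
    entries are excluded from the computation but kept in the report;
    per-column matched counts are recomputed on the matched subset because
    they drive the engine's allocate/flush lifecycle.  A column that loses
    all its variants is still emitted (all-zero prediction) and flagged.
    """
    entries: list[tuple[int, int, float, bool]] = []
    seen: set[tuple[int, int]] = set()
    rows: list[dict] = []
    n_matched = n_unmatched = n_ambiguous = 0
    per_column_matched: dict[int, int] = {}
    per_column_total: dict[int, int] = {}
    owned: set[int] = set()

    ordered = sorted(
        records, key=lambda r: (r.rsid, r.effect_allele, r.column_triple)
    )
    for rec in ordered:
        if rec.chromosome is not None and rec.chromosome != manifest.chromosome:
            raise DataError(
                f"record {rec.rsid} is on {rec.chromosome}, manifest is "
                f"{manifest.chromosome}: build_matched_index expects one chromosome"
            )
        col = catalog.index[rec.column_triple]
        owned.add(col)
        per_column_total[col] = per_column_total.get(col, 0) + 1
        ordinal = manifest.id_index.get(rec.rsid)
        reason = ""
        if ordinal is None:
            status, transform = MatchStatus.UNMATCHED, "identity"
            reason = "rsid_not_in_pvar"
        elif ordinal in manifest.multiallelic:
            status, transform, ordinal = MatchStatus.UNMATCHED, "identity", None
            reason = "multiallelic_site"
        else:
            row = manifest.records[ordinal]
            status, transform = orient_alleles(
                rec.effect_allele, rec.other_allele, row.ref_allele, row.alt_allele
            )
            if status == MatchStatus.UNMATCHED:
                ordinal = None
                reason = "allele_mismatch"
            elif status == MatchStatus.AMBIGUOUS_STRAND:
                ordinal = None
                reason = "strand_ambiguous_site"

        if status in MATCHED_STATUSES:
            assert ordinal is not None
            dup = (ordinal, col)
            if dup in seen:
                raise DataError(
                    f"two weight entries resolve to genotype ordinal {ordinal} "
                    f"for column {rec.column_triple}: ambiguous model"
                )
            seen.add(dup)
            entries.append((ordinal, col, rec.weight, transform == "flip"))
            n_matched += 1
            per_column_matched[col] = per_column_matched.get(col, 0) + 1
        elif status == MatchStatus.AMBIGUOUS_STRAND:
            n_ambiguous += 1
        else:
            n_unmatched += 1

        ancestry, model_id, gene = rec.column_triple
        rows.append(
            {
                "rsid": rec.rsid,
                "ancestry": ancestry,
                "model_ID": model_id,
                "gene": gene,
                "effect_allele": rec.effect_allele,
                "status": status.value,
                "genotype_ordinal": ordinal if ordinal is not None else -1,
                "dosage_transform": transform if status in MATCHED_STATUSES else "",
                "reason": reason,
            }
        )

    if index is not None:
        # Cross-check the entry accounting against the prebuilt weight index.
        expected = sum(
            index.per_column_variant_count.get(c, 0) for c in per_column_total
        )
        if expected and expected != sum(per_column_total.values()):
            raise DataError(
                "weight-index entry count disagrees with the records handed to "
                "build_matched_index"
            )

    matched = MatchedIndex.from_entries(
        entries, n_columns=catalog.k, owned_columns=frozenset(owned)
    )
    report = MatchReport(
        rows=rows,
        n_matched=n_matched,
        n_unmatched=n_unmatched,
        n_ambiguous=n_ambiguous,
        per_column_matched=per_column_matched,
        per_column_total=per_column_total,
    )
    return matched, report
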
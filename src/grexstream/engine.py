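"""The streaming sparse computation Y = G x B.

Genotypes are streamed in SNP chunks; for each variant only the output
columns with a nonzero weight are visited, and each update is further broken
into row chunks across samples so accumulation walks contiguous slices of the
dosage and accumulator vectors.  An output column's dense accumulator is
allocated the first time one of its variants is touched and flushed to the
sink as soon as its last contributing variant has been processed, so peak
memory scales with the number of *simultaneously active* columns plus one
genotype chunk — never with the full sample-by-gene matrix.

Determinism contract: variants are processed in strictly ascending genotype
ordinal and, within a variant, columns in ascending position; accumulation is
double precision regardless of the output precision (single rounds at
flush).  Outputs are therefore bit-identical across any chunk-size choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError, DataError
from .weights_io import ColumnCatalog

#: entry tuple: (genotype ordinal, column position, weight, flip?)
Entry = tuple[int, int, float, bool]


@dataclass(frozen=True)
class EngineConfig:
    snp_chunk_size: int = 1024
    row_chunk_size: int = 8192
    value_precision: str = "double"  # or "single"
    flush_batch_size: int = 64

    def __post_init__(self) -> None:
        for name in ("snp_chunk_size", "row_chunk_size", "flush_batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.value_precision not in ("double", "single"):
            raise ValueError("value_precision must be 'double' or 'single'")


@dataclass
class MatchedIndex:
    """Harmonized weights laid out for streaming.

    ``entries_by_ordinal`` maps each genotype ordinal to its (column, weight,
    flip) updates; the per-column first/last contributing ordinals drive the
    allocate/flush lifecycle; ``owned_columns`` is the set of catalog columns
    this index is responsible for emitting (including ones that lost every
    variant during harmonization and are written as all-zero).
    """

    entries_by_ordinal: dict[int, tuple[tuple[int, float, bool], ...]]
    first_ordinal: dict[int, int]
    last_ordinal: dict[int, int]
    matched_count: dict[int, int]
    n_columns: int
    owned_columns: frozenset[int]

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[Entry],
        n_columns: int,
        owned_columns: frozenset[int] | None = None,
    ) -> "MatchedIndex":
        by_ordinal: dict[int, list[tuple[int, float, bool]]] = {}
        first: dict[int, int] = {}
        last: dict[int, int] = {}
        count: dict[int, int] = {}
        for ordinal, col, weight, flip in entries:
            if not 0 <= col < n_columns:
                raise ContractError(f"column {col} outside 0..{n_columns - 1}")
            by_ordinal.setdefault(ordinal, []).append((col, weight, flip))
            first[col] = min(first.get(col, ordinal), ordinal)
            last[col] = max(last.get(col, ordinal), ordinal)
            count[col] = count.get(col, 0) + 1
        frozen = {
            o: tuple(sorted(pairs, key=lambda p: p[0]))
            for o, pairs in by_ordinal.items()
        }
        if owned_columns is None:
            owned_columns = frozenset(count)
        return cls(
            entries_by_ordinal=frozen,
            first_ordinal=first,
            last_ordinal=last,
            matched_count=count,
            n_columns=n_columns,
            owned_columns=owned_columns,
        )

    @property
    def total_entries(self) -> int:
        return sum(len(v) for v in self.entries_by_ordinal.values())

    @property
    def max_ordinal(self) -> int:
        return max(self.last_ordinal.values(), default=-1)


@dataclass
class RunSummary:
    columns_written: int
    variants_processed: int
    peak_active_columns: int
    values_imputed: int = 0


@dataclass
class LifecyclePlan:
    """Predicted allocate/flush schedule for a given SNP chunk size."""

    allocate: dict[int, list[int]]  # chunk index -> columns to allocate
    flush: dict[int, list[int]]  # chunk index -> columns to flush after
    peak_active: int
    n_chunks: int


def column_lifecycle_plan(matched: MatchedIndex, snp_chunk_size: int) -> LifecyclePlan:
    """Simulate the allocate/flush lifecycle without touching genotypes.

    A column is allocated in the chunk holding its first contributing ordinal
    and flushed after the chunk holding its last; the predicted peak is the
    running allocated-minus-flushed maximum, measured before each chunk's
    flushes (matching the engine's instrumentation point).
    """
    if snp_chunk_size < 1:
        raise ValueError("snp_chunk_size must be >= 1")
    allocate: dict[int, list[int]] = {}
    flush: dict[int, list[int]] = {}
    for col, first in matched.first_ordinal.items():
        allocate.setdefault(first // snp_chunk_size, []).append(col)
    for col, last in matched.last_ordinal.items():
        flush.setdefault(last // snp_chunk_size, []).append(col)
    for lst in allocate.values():
        lst.sort()
    for lst in flush.values():
        lst.sort()
    n_chunks = (matched.max_ordinal // snp_chunk_size + 1) if matched.first_ordinal else 0
    peak = 0
    active = 0
    for chunk in range(n_chunks):
        active += len(allocate.get(chunk, ()))
        peak = max(peak, active)
        active -= len(flush.get(chunk, ()))
    return LifecyclePlan(allocate=allocate, flush=flush, peak_active=peak, n_chunks=n_chunks)


def stream_impute(
    source,
    matched: MatchedIndex,
    catalog: ColumnCatalog,
    sample_set,
    config: EngineConfig,
    sink,
) -> RunSummary:
    """Run the streaming computation and write columns through ``sink``.

    ``source`` implements the dosage-source contract (``n_variants``,
    ``read_dosage_chunk``); ``sink`` implements the writer contract
    (``write_column(ordinal, values)``).  Every owned column is written
    exactly once; zero-variant columns are emitted as all-zero at
    finalization.
    """
    n = source.n_samples
    m = source.n_variants
    if matched.max_ordinal >= m:
        raise DataError(
            f"matched index references ordinal {matched.max_ordinal} but the "
            f"genotype source holds only {m} variants"
        )
    active: dict[int, np.ndarray] = {}
    remaining = dict(matched.matched_count)
    peak_active = 0
    columns_written = 0

    for start in range(0, m, config.snp_chunk_size):
        length = min(config.snp_chunk_size, m - start)
        chunk = source.read_dosage_chunk(start, length)
        if chunk.values.shape != (n, length):
            raise ContractError(
                f"dosage chunk shape {chunk.values.shape} != ({n}, {length})"
            )
        for j in range(length):
            ordinal = start + j
            entries = matched.entries_by_ordinal.get(ordinal)
            if not entries:
                continue
            dosage = np.ascontiguousarray(chunk.values[:, j], dtype=np.float64)
            flipped: np.ndarray | None = None
            for col, weight, flip in entries:
                acc = active.get(col)
                if acc is None:
                    acc = np.zeros(n, dtype=np.float64)
                    active[col] = acc
                    if len(active) > peak_active:
                        peak_active = len(active)
                if flip:
                    if flipped is None:
                        flipped = 2.0 - dosage
                    vec = flipped
                else:
                    vec = dosage
                for r0 in range(0, n, config.row_chunk_size):
                    r1 = min(r0 + config.row_chunk_size, n)
                    acc[r0:r1] += weight * vec[r0:r1]
                remaining[col] -= 1

        done = sorted(
            col for col, acc in active.items() if remaining.get(col, 0) == 0
        )
        for b0 in range(0, len(done), config.flush_batch_size):
            for col in done[b0 : b0 + config.flush_batch_size]:
                acc = active.pop(col)
                if not np.all(np.isfinite(acc)):
                    raise DataError(
                        f"non-finite accumulator in column {col} "
                        f"(ordinals {matched.first_ordinal[col]}.."
                        f"{matched.last_ordinal[col]})"
                    )
                sink.write_column(col, acc)
                columns_written += 1

    if active:
        raise DataError(
            "genotype source exhausted with unflushed column(s): "
            + ", ".join(str(c) for c in sorted(active))
        )
    zeros = np.zeros(n, dtype=np.float64)
    for col in sorted(matched.owned_columns):
        if matched.matched_count.get(col, 0) == 0:
            sink.write_column(col, zeros)
            columns_written += 1
    imputed = sum(getattr(source, "imputed_per_variant", {}).values())
    return RunSummary(
        columns_written=columns_written,
        variants_processed=m,
        peak_active_columns=peak_active,
        values_imputed=int(imputed),
    )


def dense_oracle_impute(
    dosages: np.ndarray, matched: MatchedIndex, catalog: ColumnCatalog
) -> np.ndarray:
    """Brute-force dense reference: materialize B and multiply once.

    Splits B by dosage transform — Y = G @ B_identity + (2 - G) @ B_flip —
    because the transform is a property of each weight entry, not of the
    variant.  Test/oracle scale only: the full dosage matrix must fit in
    memory.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    if matched.max_ordinal >= m:
        raise DataError("matched index references ordinals beyond the dosage matrix")
    k = matched.n_columns
    b_identity = np.zeros((m, k), dtype=np.float64)
    b_flip = np.zeros((m, k), dtype=np.float64)
    for ordinal, entries in matched.entries_by_ordinal.items():
        for col, weight, flip in entries:
            (b_flip if flip else b_identity)[ordinal, col] += weight
    return dosages @ b_identity + (2.0 - dosages) @ b_flip
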
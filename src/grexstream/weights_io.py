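"""Loading and indexing of GReX prediction weights.

Prediction models arrive either as tab-delimited tables (one row per
variant-gene weight, header-driven column order) or as PrediXcan-style SQLite
``.db`` files.  Both are normalised into :class:`WeightRecord` sequences and
then compiled into two structures the rest of the pipeline runs on:

* :class:`ColumnCatalog` — the deterministic enumeration of output columns,
  one per distinct ``(ancestry, model_id, gene)`` triple.  Its size is *k*,
  the number of gene-model pairs.
* :class:`SparseWeightIndex` — the weight matrix *B* stored variant-first, so
  each genotype variant can visit only the columns it actually contributes to.
"""

from __future__ import annotations

import logging
import math
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

#: Columns a tab-delimited weight table must carry (order irrelevant).
MANDATORY_COLUMNS = (
    "chromosome",
    "ancestry",
    "model_ID",
    "gene",
    "rsid",
    "effect_allele",
    "weight",
)

_VALID_CHROMOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)

#: A column is identified by the (ancestry, model_id, gene) triple.
ColumnTriple = tuple[str, str, str]


@dataclass(frozen=True)
class WeightRecord:
    """One variant's weight for one gene under one prediction model.

    ``chromosome`` is None for ``.db`` imports (resolved later against the
    genotype manifest); ``other_allele`` is None for plain tables, which carry
    only the effect allele.
    """

    chromosome: str | None
    ancestry: str
    model_id: str
    gene: str
    rsid: str
    effect_allele: str
    other_allele: str | None
    weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight) or self.weight == 0.0:
            raise DataError(
                f"weight for {self.rsid}/{self.gene} must be finite and "
                f"nonzero, got {self.weight!r}"
            )
        if self.chromosome is not None and self.chromosome not in _VALID_CHROMOSOMES:
            raise FormatError(
                f"chromosome label {self.chromosome!r} for {self.rsid} does not "
                "match chr{1..22,X,Y}"
            )

    @property
    def column_triple(self) -> ColumnTriple:
        return (self.ancestry, self.model_id, self.gene)


@dataclass(frozen=True)
class ColumnCatalog:
    """Ordered, deterministic enumeration of output columns.

    Columns are sorted by (ancestry, model_id, gene) so the catalog — and
    every downstream column offset — is a pure function of the set of loaded
    weights, independent of file row order.
    """

    columns: tuple[ColumnTriple, ...]
    index: Mapping[ColumnTriple, int]

    @classmethod
    def from_records(cls, records: Iterable[WeightRecord]) -> "ColumnCatalog":
        triples = sorted({r.column_triple for r in records})
        return cls(columns=tuple(triples), index={t: i for i, t in enumerate(triples)})

    @property
    def k(self) -> int:
        return len(self.columns)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.columns)


@dataclass
class SparseWeightIndex:
    """The weight matrix *B*, keyed by variant.

    ``by_variant`` maps ``(rsid, effect_allele)`` to the (column position,
    weight) pairs that variant feeds.  Keying excludes ``other_allele`` so a
    table import and a ``.db`` import of identical weights build identical
    structures.
    """

    by_variant: dict[tuple[str, str], list[tuple[int, float]]]
    n_variants_with_weights: int
    per_column_variant_count: dict[int, int]

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.by_variant.values())

    def iter_entries(self) -> Iterator[tuple[str, str, int, float]]:
        """Yield (rsid, effect_allele, column, weight) for every stored entry."""
        for (rsid, eff), pairs in self.by_variant.items():
            for col, w in pairs:
                yield rsid, eff, col, w


def _parse_weight(raw: object, line_no: int) -> float:
    text = "" if raw is None else str(raw).strip()
    if text in ("", ".", "nan", "NaN", "NA"):
        raise FormatError(f"unparseable weight {raw!r} on line {line_no}")
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable weight {raw!r} on line {line_no}") from exc
    if not math.isfinite(value):
        raise FormatError(f"non-finite weight {raw!r} on line {line_no}")
    return value


def load_weight_table(path: str | Path, delimiter: str = "\t") -> list[WeightRecord]:
    """Load a header-driven delimited weight table.

    Rows with weight exactly zero are dropped (and counted in the log);
    malformed weights raise with the 1-based file line number.  An optional
    ``other_allele`` column is honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"weight table not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(
            f"weight table {path} is missing mandatory column(s): "
            + ", ".join(missing)
        )
    has_other = "other_allele" in frame.columns

    records: list[WeightRecord] = []
    n_zero = 0
    for pos, row in enumerate(frame.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header line
        value = _parse_weight(getattr(row, "weight"), line_no)
        if value == 0.0:
            n_zero += 1
            continue
        other = getattr(row, "other_allele", None) if has_other else None
        if other is not None:
            other = str(other).strip() or None
        try:
            records.append(
                WeightRecord(
                    chromosome=str(getattr(row, "chromosome")).strip(),
                    ancestry=str(getattr(row, "ancestry")).strip(),
                    model_id=str(getattr(row, "model_ID")).strip(),
                    gene=str(getattr(row, "gene")).strip(),
                    rsid=str(getattr(row, "rsid")).strip(),
                    effect_allele=str(getattr(row, "effect_allele")).strip().upper(),
                    other_allele=other.upper() if other else None,
                    weight=value,
                )
            )
        except (FormatError, DataError) as exc:
            raise type(exc)(f"{exc} (line {line_no} of {path})") from exc
    if n_zero:
        logger.info("%s: dropped %d zero-weight row(s)", path.name, n_zero)
    if not records:
        logger.warning("%s: no usable weight rows after filtering", path.name)
    return records


_DB_REQUIRED_FIELDS = ("rsid", "gene", "weight", "ref_allele", "eff_allele")


def load_predixcan_db(
    path: str | Path, model_id: str, ancestry: str
) -> list[WeightRecord]:
    """Import a PrediXcan-convention SQLite model.

    The ``weights`` table supplies rsid, gene, weight and the allele pair;
    ancestry and model identity are caller-supplied because the ``.db``
    carries neither, and the chromosome is resolved later against the
    genotype manifest.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"weight database not found: {path}")
    con = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
    try:
        tables = {
            row[0]
            for row in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        if "weights" not in tables:
            raise FormatError(f"{path}: no 'weights' table (not a model database?)")
        cols = {row[1] for row in con.execute("PRAGMA table_info(weights)")}
        missing = [c for c in _DB_REQUIRED_FIELDS if c not in cols]
        if missing:
            raise FormatError(
                f"{path}: weights table lacks field(s): " + ", ".join(missing)
            )
        rows = con.execute(
            "SELECT rsid, gene, weight, ref_allele, eff_allele FROM weights"
        ).fetchall()
    finally:
        con.close()

    records: list[WeightRecord] = []
    n_zero = 0
    for rsid, gene, weight, ref_allele, eff_allele in rows:
        value = _parse_weight(weight, -1) if weight is not None else math.nan
        if not math.isfinite(value):
            raise FormatError(f"{path}: non-finite weight for {rsid}/{gene}")
        if value == 0.0:
            n_zero += 1
            continue
        records.append(
            WeightRecord(
                chromosome=None,
                ancestry=ancestry,
                model_id=model_id,
                gene=str(gene),
                rsid=str(rsid),
                effect_allele=str(eff_allele).strip().upper(),
                other_allele=str(ref_allele).strip().upper(),
                weight=value,
            )
        )
    if n_zero:
        logger.info("%s: dropped %d zero-weight row(s)", path.name, n_zero)
    if not records:
        logger.warning("%s: empty weights table after filtering", path.name)
    return records


def build_weight_index(
    records: Sequence[WeightRecord],
) -> tuple[ColumnCatalog, SparseWeightIndex]:
    """Compile records into the column catalog and the variant-keyed index.

    A repeated ``(rsid, effect_allele, column)`` entry is rejected outright:
    silent summation would mask a malformed model export.
    """
    catalog = ColumnCatalog.from_records(records)
    seen: set[tuple[str, str, int]] = set()
    by_variant: dict[tuple[str, str], list[tuple[int, float]]] = {}
    per_column: dict[int, int] = {i: 0 for i in range(catalog.k)}
    for rec in sorted(
        records, key=lambda r: (r.rsid, r.effect_allele, r.column_triple)
    ):
        col = catalog.index[rec.column_triple]
        dedup_key = (rec.rsid, rec.effect_allele, col)
        if dedup_key in seen:
            raise DataError(
                "duplicate weight entry for variant "
                f"{rec.rsid} (effect allele {rec.effect_allele}) in column "
                f"{rec.column_triple}: ambiguous model specification"
            )
        seen.add(dedup_key)
        by_variant.setdefault((rec.rsid, rec.effect_allele), []).append(
            (col, rec.weight)
        )
        per_column[col] += 1
    index = SparseWeightIndex(
        by_variant=by_variant,
        n_variants_with_weights=len(by_variant),
        per_column_variant_count=per_column,
    )
    return catalog, index
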
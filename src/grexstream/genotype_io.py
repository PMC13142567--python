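"""Chromosome-split genotype input: manifests, file discovery, dosage streaming.

The production container is the PLINK2 fileset trio (.pgen/.pvar/.psam), one
per chromosome, with the literal ``chrN`` token in each filename.  Manifests
(.pvar/.psam) are plain text and parsed here; dosage values are streamed in
SNP chunks through a backend implementing :class:`DosageSource`:

* ``PgenDosageSource`` — .pgen via the pgenlib bindings (used when installed);
* ``TextDosageSource`` — a plain-text dosage matrix (variant rows in .pvar
  order, one column per sample, ``NA`` for missing).  A fixture/test format,
  not advertised for production data.

Missing dosages are mean-imputed per variant over the analyzed samples at
read time (all-missing variants impute to 0); the per-variant imputation
count is tracked so downstream audit output can report it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError, FormatError

#: Suffix of the text fallback dosage matrix.
TEXT_DOSAGE_SUFFIX = ".dosage.tsv"


@dataclass(frozen=True)
class PvarVariant:
    variant_id: str
    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str


@dataclass
class PvarManifest:
    """Parsed .pvar: ordered variant records plus the two lookup indices.

    Row ordinals are 0-based and match genotype-record order in the companion
    .pgen.  ``cpra_index`` holds biallelic records only; multi-allelic rows
    (comma-separated ALT) stay in ``id_index`` but are flagged non-matchable.
    """

    chromosome: str
    records: list[PvarVariant]
    id_index: dict[str, int]
    cpra_index: dict[tuple[str, int, str, str], int]
    multiallelic: set[int] = field(default_factory=set)

    @property
    def n_variants(self) -> int:
        return len(self.records)


def parse_pvar(path: str | Path) -> PvarManifest:
    """Parse a PLINK2 .pvar (## meta lines, then ``#CHROM POS ID REF ALT``).

    All rows must share one chromosome label — the chromosome-split contract.
    """
    path = Path(path)
    header_cols: list[str] | None = None
    records: list[PvarVariant] = []
    id_index: dict[str, int] = {}
    cpra_index: dict[tuple[str, int, str, str], int] = {}
    multiallelic: set[int] = set()
    chromosome: str | None = None

    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if header_cols is None:
                if not line.startswith("#CHROM"):
                    raise FormatError(f"{path}: expected #CHROM header, got {line[:40]!r}")
                header_cols = line.lstrip("#").split("\t")
                for needed in ("CHROM", "POS", "ID", "REF", "ALT"):
                    if needed not in header_cols:
                        raise FormatError(f"{path}: .pvar header lacks {needed}")
                continue
            fields = line.split("\t")
            row = dict(zip(header_cols, fields))
            chrom = row["CHROM"]
            if chromosome is None:
                chromosome = chrom
            elif chrom != chromosome:
                raise DataError(
                    f"{path}: mixed chromosomes ({chromosome} and {chrom}) in one "
                    ".pvar violate the chromosome-split contract"
                )
            ordinal = len(records)
            vid = row["ID"]
            if vid in id_index:
                raise DataError(f"{path}: duplicate variant ID {vid}")
            alt = row["ALT"]
            rec = PvarVariant(
                variant_id=vid,
                chromosome=chrom,
                position=int(row["POS"]),
                ref_allele=row["REF"].upper(),
                alt_allele=alt.upper(),
            )
            records.append(rec)
            id_index[vid] = ordinal
            if "," in alt:
                multiallelic.add(ordinal)
            else:
                cpra_index[(chrom, rec.position, rec.ref_allele, rec.alt_allele)] = ordinal
    if header_cols is None:
        raise FormatError(f"{path}: missing #CHROM header line")
    if chromosome is None:
        raise FormatError(f"{path}: no variant records")
    return PvarManifest(
        chromosome=chromosome,
        records=records,
        id_index=id_index,
        cpra_index=cpra_index,
        multiallelic=multiallelic,
    )


@dataclass
class SampleSet:
    """Samples from .psam, with the analyzed subset in original file order."""

    all_ids: list[str]
    analyzed_ids: list[str]
    analyzed_ordinals: np.ndarray  # positions of analyzed ids within all_ids

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed_ids)

    def subset(self, ids: Sequence[str]) -> "SampleSet":
        """Restrict to ``ids`` while preserving .psam order."""
        wanted = set(ids)
        unknown = sorted(wanted - set(self.all_ids))
        if unknown:
            raise DataError(
                "sample subset contains id(s) absent from .psam: "
                + ", ".join(unknown)
            )
        analyzed = [(i, s) for i, s in enumerate(self.all_ids) if s in wanted]
        return SampleSet(
            all_ids=self.all_ids,
            analyzed_ids=[s for _, s in analyzed],
            analyzed_ordinals=np.array([i for i, _ in analyzed], dtype=np.int64),
        )


def parse_psam(path: str | Path) -> SampleSet:
    """Parse a PLINK2 .psam (``#IID`` or ``#FID IID`` header)."""
    path = Path(path)
    ids: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: .psam must start with a # header line")
        cols = header.lstrip("#").split("\t")
        if "IID" in cols:
            iid_pos = cols.index("IID")
        elif cols and cols[0] in ("IID", "FID"):  # pragma: no cover - defensive
            iid_pos = 0
        else:
            raise FormatError(f"{path}: .psam header lacks an IID column")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            iid = line.split("\t")[iid_pos]
            if iid in ids:
                raise DataError(f"{path}: duplicate IID {iid}")
            ids.append(iid)
    return SampleSet(
        all_ids=ids,
        analyzed_ids=list(ids),
        analyzed_ordinals=np.arange(len(ids), dtype=np.int64),
    )


def read_sample_file(path: str | Path) -> list[str]:
    """One IID per line; blank lines ignored."""
    with open(path, "rt", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def discover_chromosome_files(
    pgen_dir: str | Path, chromosomes: Sequence[str]
) -> dict[str, Path]:
    """Map each requested chromosome to exactly one fileset prefix.

    Matching is token-exact: the chromosome label must be delimited by
    non-alphanumeric characters or string boundaries within the filename, so
    ``chr1`` never matches ``ukb_chr11.pvar``.  Zero or multiple candidates
    for a requested chromosome is always a hard error — ambiguity is never
    resolved silently.
    """
    pgen_dir = Path(pgen_dir)
    if not pgen_dir.is_dir():
        raise ConfigError(f"genotype directory not found: {pgen_dir}")
    prefixes: list[Path] = []
    for pvar in sorted(pgen_dir.glob("*.pvar")):
        prefixes.append(pvar.with_suffix(""))
    mapping: dict[str, Path] = {}
    for chrom in chromosomes:
        token = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(chrom) + r"(?![A-Za-z0-9])"
        )
        hits = [p for p in prefixes if token.search(p.name)]
        if not hits:
            raise ConfigError(
                f"no genotype fileset for {chrom} in {pgen_dir} "
                "(filenames must contain the literal chromosome token)"
            )
        if len(hits) > 1:
            raise ConfigError(
                f"ambiguous genotype filesets for {chrom} in {pgen_dir}: "
                + ", ".join(p.name for p in hits)
            )
        mapping[chrom] = hits[0]
    return mapping


@dataclass
class DosageChunk:
    """A streamed slice of the genotype matrix G.

    ``values`` is analyzed-samples x chunk-variants, ALT-allele dosage in
    [0, 2], missing already mean-imputed.
    """

    variant_ordinals: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.variant_ordinals):
            raise ContractError("dosage chunk width disagrees with ordinals")


class DosageSource:
    """Streaming dosage contract shared by the pgen and text backends."""

    n_variants: int
    n_samples: int
    imputed_per_variant: dict[int, int]

    def read_dosage_chunk(self, start: int, length: int) -> DosageChunk:
        raise NotImplementedError

    def read_all(self) -> np.ndarray:
        """Full analyzed-samples x variants matrix (test/oracle scale only)."""
        return self.read_dosage_chunk(0, self.n_variants).values

    def close(self) -> None:  # pragma: no cover - default no-op
        pass

    def _check_range(self, start: int, length: int) -> None:
        if length < 1 or start < 0 or start + length > self.n_variants:
            raise ContractError(
                f"chunk [{start}, {start + length}) outside the "
                f"{self.n_variants}-variant source"
            )


class TextDosageSource(DosageSource):
    """Plain-text dosage backend (fixture format).

    The file holds one row per variant in .pvar order and one tab-separated
    column per .psam sample; ``NA`` marks missing calls.
    """

    def __init__(self, path: str | Path, sample_set: SampleSet):
        frame = pd.read_csv(path, sep="\t", header=None, na_values=["NA"], dtype=float)
        matrix = frame.to_numpy(dtype=np.float64)
        if matrix.shape[1] != len(sample_set.all_ids):
            raise DataError(
                f"{path}: {matrix.shape[1]} dosage columns but "
                f"{len(sample_set.all_ids)} .psam samples"
            )
        # Subset before anything else so buffers are sized to analyzed samples.
        self._matrix = matrix[:, sample_set.analyzed_ordinals]
        finite = self._matrix[~np.isnan(self._matrix)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise FormatError(f"{path}: dosage values outside [0, 2]")
        self.n_variants = matrix.shape[0]
        self.n_samples = sample_set.n_analyzed
        self.imputed_per_variant: dict[int, int] = {}

    def read_dosage_chunk(self, start: int, length: int) -> DosageChunk:
        self._check_range(start, length)
        block = self._matrix[start : start + length].copy()
        for j in range(length):
            row = block[j]
            mask = np.isnan(row)
            n_missing = int(mask.sum())
            if n_missing:
                mean = float(row[~mask].mean()) if n_missing < row.size else 0.0
                row[mask] = mean
                self.imputed_per_variant[start + j] = n_missing
        return DosageChunk(
            variant_ordinals=np.arange(start, start + length, dtype=np.int64),
            values=block.T.copy(),
        )


class PgenDosageSource(DosageSource):
    """PLINK2 .pgen backend via the pgenlib bindings (optional dependency)."""

    def __init__(self, path: str | Path, sample_set: SampleSet):
        try:
            import pgenlib  # type: ignore
        except ImportError as exc:  # pragma: no cover - depends on install
            raise ConfigError(
                "reading .pgen requires the Pgenlib bindings; install the "
                "'pgen' extra or supply the text dosage format"
            ) from exc
        subset = np.asarray(sample_set.analyzed_ordinals, dtype=np.uint32)
        self._reader = pgenlib.PgenReader(
            str(path).encode(), sample_subset=subset
        )
        self.n_variants = self._reader.get_variant_ct()
        self.n_samples = sample_set.n_analyzed
        self.imputed_per_variant: dict[int, int] = {}

    def read_dosage_chunk(self, start: int, length: int) -> DosageChunk:  # pragma: no cover
        self._check_range(start, length)
        buf = np.empty((length, self.n_samples), dtype=np.float32)
        self._reader.read_dosages_range(start, start + length, buf)
        block = buf.astype(np.float64)
        for j in range(length):
            row = block[j]
            mask = (row < 0) | ~np.isfinite(row)  # pgenlib encodes missing as -9
            n_missing = int(mask.sum())
            if n_missing:
                mean = float(row[~mask].mean()) if n_missing < row.size else 0.0
                row[mask] = mean
                self.imputed_per_variant[start + j] = n_missing
        return DosageChunk(
            variant_ordinals=np.arange(start, start + length, dtype=np.int64),
            values=block.T.copy(),
        )

    def close(self) -> None:  # pragma: no cover
        self._reader.close()


def open_genotype_source(
    prefix: str | Path,
    sample_set: SampleSet,
    expected_variants: int | None = None,
) -> DosageSource:
    """Open the dosage backend for a fileset prefix.

    Prefers .pgen when present and readable; otherwise falls back to the text
    dosage matrix.  ``expected_variants`` (normally the .pvar record count)
    guards against manifest/genotype drift.
    """
    prefix = Path(prefix)
    pgen = prefix.with_suffix(".pgen")
    text = Path(str(prefix) + TEXT_DOSAGE_SUFFIX)
    if pgen.exists():
        source: DosageSource = PgenDosageSource(pgen, sample_set)
    elif text.exists():
        source = TextDosageSource(text, sample_set)
    else:
        raise ConfigError(f"no genotype data ({pgen.name} or {text.name}) for {prefix}")
    if expected_variants is not None and source.n_variants != expected_variants:
        raise DataError(
            f"{prefix}: genotype source holds {source.n_variants} variants but "
            f"the .pvar manifest lists {expected_variants}"
        )
    return source
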
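"""The .grom/.gid/.sid output trio.

``prefix.grom`` is a preallocated, contiguous column-major binary matrix:

* bytes 0-7    magic ``GROMv001``
* bytes 8-15   n_rows  (samples), unsigned 64-bit little-endian
* bytes 16-23  n_cols  (gene-model pairs), unsigned 64-bit little-endian
* byte  24     value code (1 = float64, 2 = float32)
* bytes 25-31  reserved, written as zero and ignored on read
* then         n_rows x n_cols values, column-major, little-endian

The file size is exactly ``32 + n_rows * n_cols * value_size``; column ``c``
starts at byte ``32 + c * n_rows * value_size``, so reading a column touches
only that column's bytes.  The sidecar manifests are header-bearing TSV:
``.gid`` maps column ordinals to (ancestry, model_ID, gene, matched variant
count) — the analogue of .pvar — and ``.sid`` maps row ordinals to sample
IIDs, the analogue of .psam.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError, FormatError

MAGIC = b"GROMv001"
HEADER_LENGTH = 32
VALUE_DTYPES = {1: np.dtype("<f8"), 2: np.dtype("<f4")}
VALUE_CODES = {"double": 1, "single": 2}


@dataclass(frozen=True)
class GromHeader:
    n_rows: int
    n_cols: int
    value_code: int  # 1 = double, 2 = single

    def __post_init__(self) -> None:
        if self.value_code not in VALUE_DTYPES:
            raise FormatError(f"unknown value code {self.value_code}")
        if self.n_rows < 0 or self.n_cols < 0:
            raise FormatError("negative matrix dimensions")

    @property
    def dtype(self) -> np.dtype:
        return VALUE_DTYPES[self.value_code]

    @property
    def value_size(self) -> int:
        return self.dtype.itemsize

    @property
    def data_bytes(self) -> int:
        return self.n_rows * self.n_cols * self.value_size

    def column_offset(self, ordinal: int) -> int:
        return HEADER_LENGTH + ordinal * self.n_rows * self.value_size

    def pack(self) -> bytes:
        packed = MAGIC + struct.pack("<QQB", self.n_rows, self.n_cols, self.value_code)
        return packed + b"\0" * (HEADER_LENGTH - len(packed))

    @classmethod
    def unpack(cls, raw: bytes) -> "GromHeader":
        if len(raw) < HEADER_LENGTH or raw[:8] != MAGIC:
            raise FormatError("not a .grom file (bad magic)")
        n_rows, n_cols, code = struct.unpack("<QQB", raw[8:25])
        return cls(n_rows=n_rows, n_cols=n_cols, value_code=code)


@dataclass(frozen=True)
class GidRecord:
    column_ordinal: int
    ancestry: str
    model_id: str
    gene: str
    matched_variant_count: int


@dataclass(frozen=True)
class SidRecord:
    row_ordinal: int
    iid: str


def _trio_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    base = str(prefix)
    return Path(base + ".grom"), Path(base + ".gid"), Path(base + ".sid")


class GromWriter:
    """Writes the trio; the value file is preallocated to its exact final size.

    Columns may arrive in any order; each ordinal may be written exactly once
    (a second write is an upstream lifecycle bug).  Values are accepted as
    float64 and rounded to the file precision at write time.
    """

    def __init__(
        self,
        prefix: str | Path,
        header: GromHeader,
        gid: Sequence[GidRecord],
        sid: Sequence[SidRecord],
        overwrite: bool = False,
    ):
        if len(gid) != header.n_cols:
            raise DataError(
                f".gid holds {len(gid)} records but header says {header.n_cols} columns"
            )
        if len(sid) != header.n_rows:
            raise DataError(
                f".sid holds {len(sid)} records but header says {header.n_rows} rows"
            )
        grom, gid_path, sid_path = _trio_paths(prefix)
        if grom.exists() and not overwrite:
            raise ConfigError(
                f"{grom} exists; pass overwrite to replace it"
            )
        self.header = header
        self._written: set[int] = set()
        pd.DataFrame(
            {
                "column_ordinal": [r.column_ordinal for r in gid],
                "ancestry": [r.ancestry for r in gid],
                "model_ID": [r.model_id for r in gid],
                "gene": [r.gene for r in gid],
                "matched_variants": [r.matched_variant_count for r in gid],
            }
        ).to_csv(gid_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "row_ordinal": [r.row_ordinal for r in sid],
                "IID": [r.iid for r in sid],
            }
        ).to_csv(sid_path, sep="\t", index=False)
        # Preallocate: header + zero-filled value region, final size up front
        # so disk-space failures surface here rather than mid-run.
        self._fh = open(grom, "wb+")
        self._fh.write(header.pack())
        self._fh.truncate(HEADER_LENGTH + header.data_bytes)
        self.path = grom

    @property
    def columns_written(self) -> int:
        return len(self._written)

    def write_column(self, ordinal: int, values: np.ndarray) -> None:
        if not 0 <= ordinal < self.header.n_cols:
            raise ContractError(f"column ordinal {ordinal} out of range")
        if ordinal in self._written:
            raise ContractError(
                f"column {ordinal} written twice (lifecycle bug upstream)"
            )
        values = np.asarray(values)
        if values.shape != (self.header.n_rows,):
            raise DataError(
                f"column {ordinal}: expected length {self.header.n_rows}, "
                f"got shape {values.shape}"
            )
        self._fh.seek(self.header.column_offset(ordinal))
        self._fh.write(np.ascontiguousarray(values, dtype=self.header.dtype).tobytes())
        self._written.add(ordinal)

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.flush()
            self._fh.close()

    def __enter__(self) -> "GromWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def grom_create(
    prefix: str | Path,
    header: GromHeader,
    gid: Sequence[GidRecord],
    sid: Sequence[SidRecord],
    overwrite: bool = False,
) -> GromWriter:
    """Create the trio at ``prefix`` and return the open writer."""
    return GromWriter(prefix, header, gid, sid, overwrite=overwrite)


class GromReader:
    """Selective reader; tracks bytes read so seek economy is assertable."""

    def __init__(self, prefix: str | Path):
        grom, gid_path, sid_path = _trio_paths(prefix)
        for p in (grom, gid_path, sid_path):
            if not p.exists():
                raise ConfigError(f"missing output file: {p}")
        self._fh = open(grom, "rb")
        raw = self._fh.read(HEADER_LENGTH)
        self.bytes_read = len(raw)
        self.header = GromHeader.unpack(raw)
        actual = grom.stat().st_size
        expected = HEADER_LENGTH + self.header.data_bytes
        if actual != expected:
            raise FormatError(
                f"{grom}: corrupt file — size {actual}, header implies {expected}"
            )
        self.gid = pd.read_csv(gid_path, sep="\t", dtype={"ancestry": str, "model_ID": str, "gene": str})
        self.sid = pd.read_csv(sid_path, sep="\t", dtype={"IID": str})
        if len(self.gid) != self.header.n_cols or len(self.sid) != self.header.n_rows:
            raise DataError(f"{prefix}: manifest lengths disagree with the header")

    def select(
        self,
        models: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Resolve selectors to (column ordinals, row ordinals) in file order."""
        gid = self.gid
        mask = np.ones(len(gid), dtype=bool)
        if models is not None:
            known = set(gid["model_ID"].astype(str))
            unknown = sorted(set(models) - known)
            if unknown:
                raise DataError("unknown model id(s): " + ", ".join(unknown))
            mask &= gid["model_ID"].astype(str).isin(set(models)).to_numpy()
        if genes is not None:
            known = set(gid["gene"].astype(str))
            unknown = sorted(set(genes) - known)
            if unknown:
                raise DataError("unknown gene id(s): " + ", ".join(unknown))
            mask &= gid["gene"].astype(str).isin(set(genes)).to_numpy()
        cols = np.flatnonzero(mask)
        if samples is not None:
            known = set(self.sid["IID"].astype(str))
            unknown = sorted(set(samples) - known)
            if unknown:
                raise DataError("unknown sample id(s): " + ", ".join(unknown))
            rows = np.flatnonzero(self.sid["IID"].astype(str).isin(set(samples)).to_numpy())
        else:
            rows = np.arange(self.header.n_rows)
        return cols, rows

    def read_columns(self, ordinals: Sequence[int]) -> np.ndarray:
        """Read whole columns, touching only their byte ranges."""
        n = self.header.n_rows
        out = np.empty((n, len(ordinals)), dtype=self.header.dtype)
        col_bytes = n * self.header.value_size
        for i, c in enumerate(ordinals):
            if not 0 <= c < self.header.n_cols:
                raise ContractError(f"column ordinal {c} out of range")
            self._fh.seek(self.header.column_offset(int(c)))
            raw = self._fh.read(col_bytes)
            if len(raw) != col_bytes:
                raise FormatError("truncated .grom while reading a column")
            self.bytes_read += len(raw)
            out[:, i] = np.frombuffer(raw, dtype=self.header.dtype)
        return out

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "GromReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def grom_read(
    prefix: str | Path,
    models: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Selective load: (value slice, gid slice, sid slice), in file order.

    ``models`` and ``genes`` filter .gid rows (their intersection when both
    are given); ``samples`` filters .sid rows.  With no selectors the full
    matrix is returned.  Only the requested columns' byte ranges are read.
    """
    with GromReader(prefix) as reader:
        cols, rows = reader.select(models=models, genes=genes, samples=samples)
        values = reader.read_columns(cols)
        if len(rows) != reader.header.n_rows:
            values = values[rows, :]
        gid = reader.gid.iloc[cols].reset_index(drop=True)
        sid = reader.sid.iloc[rows].reset_index(drop=True)
    return values, gid, sid


def grom_export_tsv(
    prefix: str | Path,
    out_path: str | Path,
    models: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
) -> Path:
    """Export (a slice of) the matrix as TSV: IID + one column per pair.

    Column names are ``ancestry.model_ID.gene``; doubles are printed with 17
    significant digits so a re-parse round-trips losslessly.  An empty
    selection is an error, never an empty file.
    """
    values, gid, sid = grom_read(prefix, models=models, genes=genes, samples=samples)
    if values.shape[1] == 0 or values.shape[0] == 0:
        raise DataError("selection matches no data; refusing to write an empty export")
    names = [
        f"{a}.{m}.{g}"
        for a, m, g in zip(gid["ancestry"], gid["model_ID"], gid["gene"])
    ]
    out_path = Path(out_path)
    with open(out_path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["IID"] + names) + "\n")
        for i, iid in enumerate(sid["IID"]):
            row = "\t".join(f"{v:.17g}" for v in values[i])
            fh.write(f"{iid}\t{row}\n")
    return out_path
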
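"""Concordance between two prediction sets.

Used to verify that the streaming engine reproduces a reference computation
(or another tool's output): per-column Pearson correlation and RMSE on raw
predicted values, aligned by column identity and sample id, summarised by
the minimum correlation and maximum RMSE over columns.  Constant columns
(zero variance in either source) have no defined correlation; they are
skipped for Pearson — and reported — but still included in RMSE, so an
all-zero column can never poison the headline minimum with NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .grom_format import grom_read

PredictionSource = "str | Path | pd.DataFrame"


@dataclass
class ConcordanceReport:
    per_column: pd.DataFrame  # column, pearson_r, rmse, n_used
    min_pearson: float
    max_rmse: float
    n_compared: int
    n_skipped_constant: int

    @property
    def summary(self) -> dict:
        return {
            "min_pearson": self.min_pearson,
            "max_rmse": self.max_rmse,
            "columns_compared": self.n_compared,
            "columns_skipped_constant": self.n_skipped_constant,
        }


def load_predictions(source) -> pd.DataFrame:
    """Normalise a prediction source to a DataFrame (index IID).

    Accepts a .grom prefix (the trio must exist), a TSV prediction table
    (IID column + one column per gene/pair), or an existing DataFrame.
    Column labels from .grom sources are ``ancestry.model_ID.gene``.
    """
    if isinstance(source, pd.DataFrame):
        return source
    path = Path(source)
    if Path(str(path) + ".grom").exists():
        values, gid, sid = grom_read(path)
        names = [
            f"{a}.{m}.{g}"
            for a, m, g in zip(gid["ancestry"], gid["model_ID"], gid["gene"])
        ]
        return pd.DataFrame(
            np.asarray(values, dtype=np.float64),
            index=pd.Index(sid["IID"].astype(str), name="IID"),
            columns=names,
        )
    if path.exists():
        frame = pd.read_csv(path, sep="\t", dtype={"IID": str})
        if "IID" not in frame.columns:
            raise DataError(f"{path}: prediction TSV lacks an IID column")
        return frame.set_index("IID").astype(np.float64)
    raise DataError(f"prediction source not found: {source}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / denom)


def concordance(
    a,
    b,
    sample_draw: tuple[int, int] | None = None,
    per_column_redraw: bool = False,
) -> ConcordanceReport:
    """Compare two prediction sets column by column.

    Columns are aligned by label and rows by sample id.  When
    ``sample_draw=(count, seed)`` is given, that many shared samples are
    drawn without replacement under the seed; with ``per_column_redraw`` a
    fresh draw is made per column (both readings of per-pair subsampling are
    supported).
    """
    fa = load_predictions(a)
    fb = load_predictions(b)
    shared_cols = sorted(set(fa.columns) & set(fb.columns))
    if not shared_cols:
        raise DataError("no shared columns between the two prediction sets")
    shared_samples = [s for s in fa.index if s in set(fb.index)]
    if not shared_samples:
        raise DataError("no shared samples between the two prediction sets")
    fa = fa.loc[shared_samples, shared_cols]
    fb = fb.loc[shared_samples, shared_cols]

    rng = None
    base_rows = np.arange(len(shared_samples))
    if sample_draw is not None:
        count, seed = sample_draw
        if count > len(shared_samples):
            raise DataError(
                f"sample_draw of {count} exceeds the {len(shared_samples)} shared samples"
            )
        rng = np.random.default_rng(seed)
        if not per_column_redraw:
            base_rows = rng.choice(len(shared_samples), size=count, replace=False)

    rows = []
    n_skipped = 0
    va = fa.to_numpy(dtype=np.float64)
    vb = fb.to_numpy(dtype=np.float64)
    for j, name in enumerate(shared_cols):
        if sample_draw is not None and per_column_redraw:
            idx = rng.choice(len(shared_samples), size=sample_draw[0], replace=False)
        else:
            idx = base_rows
        x, y = va[idx, j], vb[idx, j]
        rmse = float(np.sqrt(np.mean((x - y) ** 2)))
        if x.std() == 0.0 or y.std() == 0.0:
            n_skipped += 1
            pearson = np.nan
        else:
            pearson = _pearson(x, y)
        rows.append({"column": name, "pearson_r": pearson, "rmse": rmse, "n_used": len(idx)})

    table = pd.DataFrame(rows, columns=["column", "pearson_r", "rmse", "n_used"])
    finite = table["pearson_r"].dropna()
    return ConcordanceReport(
        per_column=table,
        min_pearson=float(finite.min()) if len(finite) else np.nan,
        max_rmse=float(table["rmse"].max()),
        n_compared=len(shared_cols) - n_skipped,
        n_skipped_constant=n_skipped,
    )
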
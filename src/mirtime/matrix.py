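"""Count-matrix assembly and normalization for the 5-point time course.

Raw counts feed the chi-square differential-expression test directly;
everything downstream of it (heatmap clustering, temporal profiles,
co-expression, miRNA-mRNA correlation) consumes quantile-normalized
log2 counts-per-million, optionally row Z-scored for display.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError


def build_count_matrix(
    count_maps: Iterable[tuple[str, Mapping[str, int]]],
) -> pd.DataFrame:
    """Assemble per-sample miRNA count maps into a features x samples matrix.

    Rows are the union of miRNA ids (sorted); missing entries are 0.
    """
    samples: list[str] = []
    maps: list[Mapping[str, int]] = []
    for sample, cmap in count_maps:
        if sample in samples:
            raise InputError(f"duplicate sample id {sample!r}")
        samples.append(sample)
        maps.append(cmap)
    rows = sorted(set().union(*[set(m) for m in maps])) if maps else []
    data = np.zeros((len(rows), len(samples)), dtype=np.int64)
    row_idx = {r: i for i, r in enumerate(rows)}
    for j, cmap in enumerate(maps):
        for mid, c in cmap.items():
            data[row_idx[mid], j] = c
    return pd.DataFrame(data, index=rows, columns=samples)


def log_transform(
    counts: pd.DataFrame, pseudocount: float = 1.0, scale: float = 1e6
) -> pd.DataFrame:
    """log2 counts-per-million: ``log2(count / column_total * scale + pseudocount)``."""
    if pseudocount <= 0:
        raise ConfigurationError(f"pseudocount must be > 0, got {pseudocount}")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise InputError(
            f"zero column total for sample(s) {list(zero.index)}; cannot scale"
        )
    cpm = counts / totals * scale
    return np.log2(cpm + pseudocount)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    After normalization each column's sorted values equal the across-column
    mean of order statistics. Ties within a column receive the mean of the
    reference values at their tied ranks (dialects differ here; this is the
    documented convention of this package).
    """
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return m.copy()
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("quantile_normalize: non-finite values in input")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        col_sorted = col[order]
        assigned = ref.copy()
        # tie groups share the mean reference value of their occupied ranks
        start = 0
        for i in range(1, len(col_sorted) + 1):
            if i == len(col_sorted) or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = ref[start:i].mean()
                start = i
        out[order, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sample sd 1 (divisor n-1).

    Constant rows cannot be standardized; they are excluded from the result
    and reported through a warning naming them.
    """
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(m.index[constant])
        warnings.warn(f"zscore_rows: excluded {len(dropped)} constant row(s): {dropped[:10]}")
    keep = values[~constant]
    z = (keep - keep.mean(axis=1, keepdims=True)) / sd[~constant][:, None]
    return pd.DataFrame(z, index=m.index[~constant], columns=m.columns)


# ---------------------------------------------------------------------------
# TSV round-trip (row-label first column, header row; 12 significant digits)


def write_matrix_tsv(m: pd.DataFrame, path: str | Path, label: str = "id") -> None:
    m.to_csv(path, sep="\t", float_format="%.12g", index_label=label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
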
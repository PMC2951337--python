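"""Expression-matrix I/O, two-channel lowess normalization, and gene filters.

Expression matrices are plain :class:`pandas.DataFrame` objects, genes in
rows (index = gene identifiers) and samples in columns, on the log2 scale.
Missing values are ``NaN``; the presence mask is simply ``df.notna()``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_spot_table",
    "write_spot_table",
    "collapse_duplicate_genes",
    "lowess_normalize",
    "filter_genes",
    "median_center",
]


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a tab-delimited genes x samples matrix.

    First column holds gene identifiers, header row holds sample
    identifiers; blank cells become ``NaN`` (missing).

    Raises
    ------
    ValueError
        On duplicate sample identifiers or ragged rows.
    """
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    names = header.rstrip("\n").split("\t")[1:]
    dupes = pd.Index(names)[pd.Index(names).duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    try:
        df = df.astype(float)
    except ValueError as exc:  # ragged rows shift text into value cells
        raise ValueError(f"non-numeric cells in expression matrix: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix so that ``read_expression_matrix`` round-trips bit-exactly.

    Full ``repr`` float precision is used; missing values are written as
    empty cells.
    """
    matrix.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


def read_spot_table(path) -> pd.DataFrame:
    """Read a per-spot two-channel table: columns probe_id, cy3, cy5."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "cy3", "cy5"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot table must have columns {sorted(required)}")
    if (df[["cy3", "cy5"]] < 0).any().any():
        raise ValueError("channel intensities must be non-negative")
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene identifiers to their per-sample median.

    Deterministic and standard practice for multi-probe 4x44K designs.
    Row order follows first occurrence of each identifier.
    """
    if not matrix.index.duplicated().any():
        return matrix
    order = matrix.index[~matrix.index.duplicated()]
    collapsed = matrix.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def lowess_normalize(
    spots: pd.DataFrame,
    span: float = 0.4,
    iterations: int = 3,
) -> pd.DataFrame:
    """Intensity-dependent (M-A) lowess normalization of a two-channel array.

    Computes per spot M = log2(cy5/cy3) and A = 0.5*log2(cy5*cy3), fits a
    locally weighted linear regression of M on A (tricube weights,
    ``iterations`` robustness iterations), and returns the residual
    M' = M - fit(A) as the normalized log-ratio.

    Parameters
    ----------
    spots : DataFrame with columns probe_id, cy3, cy5 (positive intensities).
    span : lowess span (fraction of spots per local neighborhood), in (0, 1].
    iterations : robustness re-weighting iterations.

    Returns
    -------
    DataFrame with columns probe_id, m_raw, a, m_norm, in input spot order.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    cy3 = np.asarray(spots["cy3"], dtype=float)
    cy5 = np.asarray(spots["cy5"], dtype=float)
    if (cy3 <= 0).all() or (cy5 <= 0).all():
        raise ValueError("a channel is entirely non-positive; cannot form log-ratios")
    if (cy3 <= 0).any() or (cy5 <= 0).any():
        raise ValueError("all spots must have positive intensities in both channels")
    if len(cy3) < 20:
        raise ValueError("need at least 20 spots for a stable lowess fit")
    if span * len(cy3) < 2:
        raise ValueError("span too small for the neighborhood size")
    m = np.log2(cy5 / cy3)
    a = 0.5 * np.log2(cy5 * cy3)
    fit = _sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return pd.DataFrame(
        {
            "probe_id": spots["probe_id"].to_numpy(),
            "m_raw": m,
            "a": a,
            "m_norm": m - fit,
        }
    )


def filter_genes(
    matrix: pd.DataFrame,
    cy3: pd.DataFrame | None = None,
    cy5: pd.DataFrame | None = None,
    min_intensity: float = 10.0,
    min_present: float = 0.70,
    conjunctive: bool = True,
) -> pd.DataFrame:
    """Keep genes with adequate signal and presence across samples.

    A gene is retained when at least ``min_present`` of its samples are
    "good". With ``conjunctive=True`` (default) a sample is good when the
    value is present (non-missing) AND both raw channels reach
    ``min_intensity``; with ``conjunctive=False`` the intensity and
    presence clauses are evaluated independently and both fractions must
    reach ``min_present``.

    ``cy3``/``cy5`` are raw channel intensity matrices aligned to
    ``matrix`` (same index/columns). When omitted, only the presence
    criterion applies. Row order is preserved; the filter is idempotent.
    """
    if not 0 < min_present <= 1:
        raise ValueError(f"min_present must be in (0, 1], got {min_present}")
    present = matrix.notna()
    if cy3 is not None or cy5 is not None:
        if cy3 is None or cy5 is None:
            raise ValueError("provide both cy3 and cy5 raw channel matrices")
        cy3 = cy3.reindex(index=matrix.index, columns=matrix.columns)
        cy5 = cy5.reindex(index=matrix.index, columns=matrix.columns)
        bright = (cy3 >= min_intensity) & (cy5 >= min_intensity)
        if conjunctive:
            keep = (present & bright).mean(axis=1) >= min_present
        else:
            keep = (present.mean(axis=1) >= min_present) & (
                bright.mean(axis=1) >= min_present
            )
    else:
        keep = present.mean(axis=1) >= min_present
    return matrix.loc[keep]


def median_center(matrix: pd.DataFrame, axis: str = "genes") -> pd.DataFrame:
    """Subtract the per-gene (or per-sample) median over present values."""
    if axis == "genes":
        med = matrix.median(axis=1, skipna=True)
        return matrix.sub(med, axis=0)
    if axis == "samples":
        med = matrix.median(axis=0, skipna=True)
        return matrix.sub(med, axis=1)
    raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
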
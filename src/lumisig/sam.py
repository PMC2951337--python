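"""Two-class unpaired Significance Analysis of Microarrays (SAM).

Implements the relative-difference statistic d = r / (s + s0) with
pooled-SD gene scatter s, the percentile search for the fudge factor s0,
a permutation null of expected order statistics (exhaustive enumeration
of label assignments when feasible, seeded sampling otherwise), the
asymmetric delta-band significance call around the observed-vs-expected
quantile line, and the median-false-positive FDR table from which gene
signatures are extracted.

The estimator :class:`SAM` ties the steps together in a scikit-learn
fit interface; the module-level functions expose each step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SamResult",
    "Signature",
    "SAM",
    "sam_statistic",
    "estimate_s0",
    "permutation_null",
    "call_significant",
    "fdr_table",
    "derive_signature",
]


# ---------------------------------------------------------------------------
# data containers

@dataclass
class Signature:
    """Gene identifiers weighted by their SAM statistic.

    ``positive_set``/``negative_set`` partition the genes by the sign of
    the weight; ``fdr_threshold`` records the FDR level used to call them.
    """

    weights: pd.Series           # index = gene ids, values = SAM d
    fdr_threshold: float
    delta: float = np.nan
    note: str = ""

    def __post_init__(self):
        if (self.weights == 0).any():
            raise ValueError("signature weights must be non-zero")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def positive_set(self) -> set[str]:
        return set(self.weights.index[self.weights > 0])

    @property
    def negative_set(self) -> set[str]:
        return set(self.weights.index[self.weights < 0])

    def __len__(self) -> int:
        return len(self.weights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"weight": self.weights}).rename_axis("gene_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fdr_threshold=np.nan) -> "Signature":
        return cls(weights=df["weight"].astype(float), fdr_threshold=fdr_threshold)


@dataclass
class SamResult:
    """Everything a two-class SAM run produces."""

    gene_ids: pd.Index
    d: np.ndarray                # observed statistic, gene order
    s: np.ndarray                # per-gene scatter (pooled-SD based)
    r: np.ndarray                # raw class-mean difference (mean2 - mean1)
    s0: float
    dbar: np.ndarray             # expected order statistics, ascending
    perm_d_sorted: np.ndarray    # n_perm x n_genes, rows sorted ascending
    exhaustive: bool
    n_permutations: int
    seed: int | None
    delta_table: pd.DataFrame = field(default=None)  # delta, n_called, median_fp, fdr
    excluded_genes: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def d_sorted(self) -> np.ndarray:
        return self.d[self.order]

    @property
    def order(self) -> np.ndarray:
        # stable sort: ties broken by gene index
        return np.argsort(self.d, kind="stable")


# ---------------------------------------------------------------------------
# statistic

def _class_stats(x: np.ndarray, member2: np.ndarray):
    """Vectorized per-gene class means and pooled scatter.

    ``x`` is genes x samples (NaN = missing); ``member2`` is a boolean
    samples x P matrix whose columns are class-2 memberships (one column
    per permutation). Returns (r, s) arrays of shape genes x P.
    """
    present = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    x2 = x0 * x0
    w = member2.astype(float)

    n_tot = present.sum(axis=1)[:, None]
    sum_tot = x0.sum(axis=1)[:, None]
    ss_tot = x2.sum(axis=1)[:, None]

    n2 = present @ w
    n1 = n_tot - n2
    sum2 = x0 @ w
    sum1 = sum_tot - sum2
    ss2 = x2 @ w
    ss1 = ss_tot - ss2

    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = sum1 / n1
        m2 = sum2 / n2
        r = m2 - m1
        pooled = (ss1 - n1 * m1 * m1) + (ss2 - n2 * m2 * m2)
        dof = n1 + n2 - 2
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled / dof)
    bad = (n1 < 2) | (n2 < 2) | (dof <= 0)
    r[bad] = np.nan
    s[bad] = np.nan
    return r, s


def _validate_labels(labels, columns) -> tuple[np.ndarray, list]:
    labels = pd.Series(labels).astype(str)
    if len(labels) != len(columns):
        raise ValueError("labels length must match number of samples")
    classes = sorted(pd.unique(labels))  # lexicographic: swap names -> negate d
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return (labels.to_numpy() == classes[1]), classes


def sam_statistic(
    matrix: pd.DataFrame, labels, s0: float = 0.0
) -> pd.Series:
    """Relative difference d = (mean2 - mean1) / (s + s0) per gene.

    ``s`` is the pooled standard deviation scaled by sqrt(1/n1 + 1/n2);
    with ``s0 = 0`` this is exactly the classical pooled two-sample
    t statistic. Class 1 / class 2 are the two label values in
    lexicographic order, so exchanging the label names negates every d.

    Genes with fewer than 2 present values in either class get ``NaN``
    (a warning is issued); callers typically exclude them first.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    is2, _ = _validate_labels(labels, matrix.columns)
    x = matrix.to_numpy(dtype=float)
    r, s = _class_stats(x, is2[:, None])
    r, s = r[:, 0], s[:, 0]
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} genes have <2 present values in a class; d set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    # zero scatter with zero s0 and zero difference -> define d = 0
    d[np.isnan(d) & ~np.isnan(r) & (r == 0)] = 0.0
    return pd.Series(d, index=matrix.index, name="d")


def estimate_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Choose the fudge factor s0 as the percentile of s minimizing the
    coefficient of variation of d's scale across s-quantile windows.

    Candidate s0 values are the percentiles {0, 5, ..., 100} of s. For
    each candidate, d = r/(s + s0) is computed and the genes are split
    into 100 quantile windows of s; the window-wise scale is the median
    absolute deviation (normal-consistent). The candidate minimizing the
    CV of these scales wins; ties break to the lowest percentile.
    """
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    ok = np.isfinite(r) & np.isfinite(s)
    r, s = r[ok], s[ok]
    if len(s) == 0:
        raise ValueError("no finite genes to estimate s0 from")
    if np.allclose(s, s[0]):
        return float(s[0])
    if len(s) < 100:
        warnings.warn("fewer than 100 genes; s0 estimate may be unstable")

    alphas = np.arange(0, 101, 5)
    candidates = np.percentile(s, alphas)
    n_windows = min(100, max(2, len(s) // 10))
    # quantile windows of s, stable against ties
    order = np.argsort(s, kind="stable")
    window = np.minimum((np.arange(len(s)) * n_windows) // len(s), n_windows - 1)
    win_of_gene = np.empty(len(s), dtype=int)
    win_of_gene[order] = window

    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = r / (s + cand)
        mads = np.array(
            [_mad(d[win_of_gene == jw]) for jw in range(n_windows)]
        )
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _mad(v: np.ndarray) -> float:
    if len(v) == 0:
        return 0.0
    return float(np.median(np.abs(v - np.median(v))) * 1.4826)


# ---------------------------------------------------------------------------
# permutation null

def permutation_null(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    seed: int | None = 0,
    s0: float = 0.0,
    enumeration_limit: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Null distribution of d under label permutation.

    When the number of distinct class assignments C(n, n1) is at most
    ``enumeration_limit``, every assignment is enumerated exactly once
    (the result is then seed-independent); otherwise ``n_perm`` seeded
    draws are taken. Returns ``(dbar, perm_d_sorted, exhaustive)`` where
    ``dbar[i]`` is the mean of the i-th ascending order statistic across
    permutations and ``perm_d_sorted`` is the P x n_genes matrix of
    sorted permuted statistics.
    """
    is2, _ = _validate_labels(labels, matrix.columns)
    n = len(is2)
    n2 = int(is2.sum())
    n_distinct = math.comb(n, n2)

    if n_distinct <= enumeration_limit:
        member2 = np.zeros((n, n_distinct), dtype=bool)
        for j, idx in enumerate(combinations(range(n), n2)):
            member2[list(idx), j] = True
        exhaustive = True
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        member2 = np.zeros((n, n_perm), dtype=bool)
        for j in range(n_perm):
            member2[rng.choice(n, size=n2, replace=False), j] = True
        exhaustive = False

    x = matrix.to_numpy(dtype=float)
    r, s = _class_stats(x, member2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    d[~np.isfinite(d)] = 0.0
    perm_d_sorted = np.sort(d, axis=0).T  # P x genes, each row ascending
    dbar = perm_d_sorted.mean(axis=0)
    return dbar, perm_d_sorted, exhaustive


# ---------------------------------------------------------------------------
# delta calibration

def call_significant(
    d: np.ndarray, dbar: np.ndarray, delta: float
) -> tuple[np.ndarray, float, float]:
    """Asymmetric significance call at band half-width ``delta``.

    The observed statistics (sorted ascending) are paired with the
    expected order statistics ``dbar``. The upper cutpoint is the
    smallest observed d whose displacement d - dbar >= delta; every gene
    with d >= cut-up is called up. Symmetrically, cut-low is the largest
    observed d with dbar - d >= delta and genes with d <= cut-low are
    called down.

    Returns ``(called, cut_up, cut_low)`` where ``called`` is a boolean
    mask over the *sorted* gene order and the cutpoints are ±inf when no
    gene qualifies on that side.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    d_sorted = np.sort(np.asarray(d, float), kind="stable")
    disp = d_sorted - dbar
    up = np.nonzero(disp >= delta)[0]
    low = np.nonzero(-disp >= delta)[0]
    cut_up = d_sorted[up].min() if len(up) else np.inf
    cut_low = d_sorted[low].max() if len(low) else -np.inf
    called = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    return called, float(cut_up), float(cut_low)


def _delta_grid(d_sorted: np.ndarray, dbar: np.ndarray, n_max: int = 200):
    disp = np.abs(d_sorted - dbar)
    deltas = np.unique(np.concatenate([[0.0], disp, [disp.max() + 1e-12]]))
    if len(deltas) > n_max:
        deltas = np.quantile(deltas, np.linspace(0, 1, n_max))
        deltas = np.unique(np.concatenate([[0.0], deltas]))
    return deltas


def fdr_table(
    d: np.ndarray,
    dbar: np.ndarray,
    perm_d_sorted: np.ndarray,
    delta_grid=None,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Median-false-positive FDR per delta.

    For each delta the observed cutpoints are found, ``n_called`` counted
    on the observed data, and for every permutation the number of
    permuted statistics beyond the same cutpoints is counted; the median
    of these counts (scaled by ``pi0``) over ``max(n_called, 1)`` is the
    FDR, reported clipped to [0, 1].
    """
    d = np.asarray(d, float)
    d_sorted = np.sort(d, kind="stable")
    if delta_grid is None:
        delta_grid = _delta_grid(d_sorted, dbar)
    delta_grid = np.asarray(delta_grid, float)
    if delta_grid.size == 0:
        raise ValueError("delta grid is empty")

    rows = []
    for delta in delta_grid:
        called, cut_up, cut_low = call_significant(d, dbar, delta)
        n_called = int(called.sum())
        counts = (perm_d_sorted >= cut_up).sum(axis=1) + (
            perm_d_sorted <= cut_low
        ).sum(axis=1)
        median_fp = float(np.median(counts)) * pi0
        fdr = median_fp / max(n_called, 1)
        rows.append((float(delta), n_called, median_fp, min(fdr, 1.0)))
    table = pd.DataFrame(rows, columns=["delta", "n_called", "median_fp", "fdr"])
    return table


def derive_signature(
    result: SamResult, fdr_threshold: float = 0.01
) -> Signature:
    """Signature = genes called at the smallest delta with FDR below threshold.

    Weights are the observed SAM statistics; the positive/negative
    partition follows the sign of d. If no delta achieves the threshold
    an empty signature is returned with a diagnostic note.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    if result.delta_table is None:
        raise ValueError("SamResult has no delta table; run fdr_table first")
    ok = result.delta_table[result.delta_table["fdr"] < fdr_threshold]
    if ok.empty:
        return Signature(
            weights=pd.Series(dtype=float),
            fdr_threshold=fdr_threshold,
            note="no delta achieves the requested FDR; empty signature",
        )
    delta = float(ok["delta"].iloc[0])
    called_sorted, cut_up, cut_low = call_significant(result.d, result.dbar, delta)
    order = result.order
    called = np.zeros(len(result.d), dtype=bool)
    called[order] = called_sorted
    weights = pd.Series(result.d[called], index=result.gene_ids[called])
    weights = weights[weights != 0]
    return Signature(weights=weights, fdr_threshold=fdr_threshold, delta=delta)


# ---------------------------------------------------------------------------
# estimator

class SAM(BaseEstimator):
    """Two-class unpaired SAM as a scikit-learn style estimator.

    Parameters
    ----------
    fdr : float, default 0.01
        FDR level at which ``signature_`` is derived after fitting.
    s0 : float or None, default None
        Fudge factor; estimated by the percentile/CV search when None.
    n_perm : int, default 1000
        Sampled permutations when exhaustive enumeration is infeasible.
    enumeration_limit : int, default 10000
        Enumerate all C(n, n1) label assignments when at most this many.
    pi0 : float, default 1.0
        Optional proportion-of-nulls correction applied to the median
        false-positive count (1.0 = the plain median-FP FDR).
    random_state : int or None
        Seed for sampled permutations.

    Attributes (after ``fit``)
    --------------------------
    d_, s_, r_ : per-gene statistic, scatter, raw difference (gene order)
    s0_ : fitted fudge factor
    dbar_ : expected order statistics (ascending)
    delta_table_ : DataFrame (delta, n_called, median_fp, fdr)
    signature_ : :class:`Signature` at the requested FDR
    result_ : the full :class:`SamResult`
    """

    def __init__(
        self,
        fdr: float = 0.01,
        s0: float | None = None,
        n_perm: int = 1000,
        enumeration_limit: int = 10_000,
        pi0: float = 1.0,
        random_state: int | None = 0,
    ):
        self.fdr = fdr
        self.s0 = s0
        self.n_perm = n_perm
        self.enumeration_limit = enumeration_limit
        self.pi0 = pi0
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        """Run the full SAM analysis.

        X : genes x samples log2 expression DataFrame (NaN = missing).
        y : per-sample two-class labels aligned with X's columns.
        """
        X = pd.DataFrame(X)
        is2, self.classes_ = _validate_labels(y, X.columns)

        # exclude genes lacking >=2 present values in either class
        present = X.notna().to_numpy()
        n2p = present[:, is2].sum(axis=1)
        n1p = present[:, ~is2].sum(axis=1)
        usable = (n1p >= 2) & (n2p >= 2)
        excluded = X.index[~usable]
        if len(excluded):
            warnings.warn(
                f"excluding {len(excluded)} genes with <2 present values per class"
            )
        X = X.loc[usable]

        x = X.to_numpy(dtype=float)
        r, s = _class_stats(x, is2[:, None])
        r, s = r[:, 0], s[:, 0]
        s0 = estimate_s0(r, s) if self.s0 is None else float(self.s0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r / (s + s0)
        d[~np.isfinite(d)] = 0.0

        dbar, perm_sorted, exhaustive = permutation_null(
            X,
            y,
            n_perm=self.n_perm,
            seed=self.random_state,
            s0=s0,
            enumeration_limit=self.enumeration_limit,
        )
        table = fdr_table(d, dbar, perm_sorted, pi0=self.pi0)

        self.result_ = SamResult(
            gene_ids=X.index,
            d=d,
            s=s,
            r=r,
            s0=s0,
            dbar=dbar,
            perm_d_sorted=perm_sorted,
            exhaustive=exhaustive,
            n_permutations=perm_sorted.shape[0],
            seed=self.random_state,
            delta_table=table,
            excluded_genes=excluded,
        )
        self.d_ = pd.Series(d, index=X.index, name="d")
        self.r_ = pd.Series(r, index=X.index, name="r")
        self.s_ = pd.Series(s, index=X.index, name="s")
        self.s0_ = s0
        self.dbar_ = dbar
        self.delta_table_ = table
        self.signature_ = derive_signature(self.result_, self.fdr)
        return self
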
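"""Signature-activity projection and group comparison.

A signature's activity in a sample is the inner product of the signature
gene weights (SAM statistics) with the sample's expression profile — a
relative, within-dataset measure. Profiles are gene-median-centered by
default so that the score is a contrast and two-channel log-ratio
datasets stay comparable; the raw (uncentered) inner product is
available via ``center=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .prep import median_center
from .sam import Signature

__all__ = ["ActivityScores", "SignatureProjector", "project_signature", "compare_activity"]


@dataclass
class ActivityScores:
    scores: pd.Series            # index = sample ids
    n_genes_matched: int
    signature_name: str = ""
    unmatched_genes: tuple = ()

    def __len__(self):
        return len(self.scores)


class SignatureProjector(BaseEstimator, TransformerMixin):
    """Project a weighted gene signature onto expression profiles.

    Parameters
    ----------
    signature : :class:`~lumisig.sam.Signature` or weight Series
    center : bool, default True
        Gene-median-center each projected dataset before the inner product.
    mean_mode : bool, default False
        Divide scores by the matched-gene count (for comparisons across
        signatures with unequal coverage).

    Gene matching is by exact identifier after upper-casing; unmatched
    signature genes are dropped and reported in ``unmatched_genes_``.
    """

    def __init__(self, signature=None, center: bool = True, mean_mode: bool = False):
        self.signature = signature
        self.center = center
        self.mean_mode = mean_mode

    def _weights(self) -> pd.Series:
        w = (
            self.signature.weights
            if isinstance(self.signature, Signature)
            else pd.Series(self.signature)
        )
        if w is None or len(w) == 0:
            raise ValueError("signature is empty")
        w = w.astype(float)
        w.index = w.index.astype(str).str.upper()
        # duplicate ids after upper-casing: keep first, deterministic
        return w[~w.index.duplicated()]

    def fit(self, X=None, y=None):
        self.weights_ = self._weights()
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        """Return one activity score per sample (column) of X."""
        if not hasattr(self, "weights_"):
            self.fit()
        w = self.weights_
        X = pd.DataFrame(X)
        genes = X.index.astype(str).str.upper()
        X = X.set_axis(genes, axis=0)
        X = X[~X.index.duplicated()]
        matched = w.index.intersection(X.index)
        self.unmatched_genes_ = tuple(w.index.difference(X.index))
        if len(matched) == 0:
            raise ValueError("no signature genes found in the expression matrix")
        self.n_genes_matched_ = len(matched)
        sub = X.loc[matched]
        if self.center:
            sub = median_center(sub)
        vals = sub.to_numpy(dtype=float)
        vals = np.nan_to_num(vals)  # missing treated as 0 after centering
        scores = w.loc[matched].to_numpy() @ vals
        if self.mean_mode:
            scores = scores / len(matched)
        return pd.Series(scores, index=X.columns, name="activity")


def project_signature(
    signature, matrix: pd.DataFrame, center: bool = True, name: str = ""
) -> ActivityScores:
    """Functional wrapper over :class:`SignatureProjector`."""
    proj = SignatureProjector(signature=signature, center=center).fit()
    scores = proj.transform(matrix)
    if proj.unmatched_genes_:
        warnings.warn(
            f"{len(proj.unmatched_genes_)} signature genes not in matrix",
            stacklevel=2,
        )
    return ActivityScores(
        scores=scores,
        n_genes_matched=proj.n_genes_matched_,
        signature_name=name,
        unmatched_genes=proj.unmatched_genes_,
    )


def compare_activity(scores: pd.Series, groups) -> dict:
    """One-way ANOVA of activity scores across groups.

    Returns a dict with the F statistic, p-value, and a boxplot-ready
    per-group quartile summary (n, min, q1, median, q3, max).
    """
    scores = pd.Series(scores)
    groups = pd.Series(groups)
    groups = groups.reindex(scores.index) if groups.index.equals(scores.index) or set(
        scores.index
    ) <= set(groups.index) else groups.set_axis(scores.index)
    by = scores.groupby(groups.to_numpy())
    sizes = by.size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with <2 samples: {small}")
    arrays = [g.to_numpy() for _, g in by]
    f_stat, p = stats.f_oneway(*arrays)
    summary = by.agg(
        n="size", min="min", q1=lambda v: v.quantile(0.25),
        median="median", q3=lambda v: v.quantile(0.75), max="max",
    )
    return {"F": float(f_stat), "p": float(p), "summary": summary}
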
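"""Temporal clustering of accessible chromatin.

Builds the consensus peak x stage matrix, applies the filter/normalization
chain (RPKM presence filter -> quantile normalization -> CV filter ->
quantile normalization -> z-score), clusters the standardized temporal
profiles with fuzzy c-means, maps clusters onto the three accessibility
categories (I: high at stages 1+2, II: 2+3, III: 3+4), and attaches
nearest-gene expression summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .intervals import GenomicInterval

__all__ = [
    "CATEGORIES",
    "FuzzyCMeans",
    "merge_within",
    "consensus_union",
    "rpkm",
    "filter_peaks",
    "presence_mask",
    "cv_mask",
    "quantile_normalize",
    "zscore_rows",
    "fuzzy_cmeans",
    "assign_categories",
    "nearest_gene_expression",
]

CATEGORIES = ("I", "II", "III")


# ---------------------------------------------------------------------------
# consensus peaks
# ---------------------------------------------------------------------------

def merge_within(peaks: Sequence[GenomicInterval], gap: int = 100) -> List[GenomicInterval]:
    """Merge overlapping peaks and peaks separated by <= ``gap`` bp.

    Merging is transitive; output intervals are sorted and pairwise
    separated by more than ``gap``.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    merged: List[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for p in ordered[1:]:
        if p.chrom == cur_chrom and p.start <= cur_end + gap:
            cur_end = max(cur_end, p.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = p.chrom, p.start, p.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def consensus_union(
    per_stage_peaks: Sequence[Sequence[GenomicInterval]], gap: int = 100
) -> List[GenomicInterval]:
    """Union of all stages' peaks followed by within-``gap`` merging."""
    if not per_stage_peaks:
        raise ValueError("need at least one stage")
    pooled = [p for stage in per_stage_peaks for p in stage]
    return merge_within(pooled, gap=gap)


# ---------------------------------------------------------------------------
# normalization chain
# ---------------------------------------------------------------------------

def rpkm(
    counts: pd.DataFrame,
    peak_lengths: Sequence[int],
    library_sizes: Mapping[str, float] | Sequence[float],
) -> pd.DataFrame:
    """count / (library/1e6) / (length/1e3), per stage column."""
    lengths = np.asarray(peak_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length peak")
    if isinstance(library_sizes, Mapping):
        libs = np.array([library_sizes[c] for c in counts.columns], dtype=float)
    else:
        libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / (libs / 1e6) / (lengths[:, None] / 1e3)


def presence_mask(
    matrix: pd.DataFrame, min_rpkm: float = 5.0, min_stages: int = 2
) -> np.ndarray:
    """Rows with value strictly > ``min_rpkm`` in at least ``min_stages`` stages."""
    return ((matrix > min_rpkm).sum(axis=1) >= min_stages).to_numpy()


def cv_mask(matrix: pd.DataFrame, min_cv: float = 0.10) -> np.ndarray:
    """Rows whose coefficient of variation (population sd / mean) is at
    least ``min_cv``; rows with mean 0 are dropped."""
    mean = matrix.mean(axis=1).to_numpy()
    sd = matrix.std(axis=1, ddof=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return (mean > 0) & (cv >= min_cv)


def filter_peaks(
    matrix: pd.DataFrame,
    min_rpkm: float = 5.0,
    min_stages: int = 2,
    min_cv: float = 0.10,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Presence + CV filters applied jointly; returns (filtered, kept mask)."""
    keep = presence_mask(matrix, min_rpkm, min_stages) & cv_mask(matrix, min_cv)
    return matrix.loc[keep], keep


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; within-column ties receive the mean of their target
    quantile values, and rank order within each column is preserved.
    Idempotent: applying it twice equals applying it once.
    """
    X = matrix.to_numpy(dtype=float)
    n, _ = X.shape
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = target
        # average target values over tie groups
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                mapped[order[s:e]] = target[s:e].mean()
        out[:, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean) / population sd; zero-sd rows are an error."""
    mean = matrix.mean(axis=1).to_numpy()[:, None]
    sd = matrix.std(axis=1, ddof=0).to_numpy()[:, None]
    if (sd == 0).any():
        raise ValueError("zero-variance row; apply the CV filter first")
    return (matrix - mean) / sd


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

class FuzzyCMeans(BaseEstimator):
    """Fuzzy c-means clustering of temporal profiles.

    Standard alternating updates: memberships proportional to
    d^(-2/(m-1)), centroids are membership^m-weighted means.  The
    objective sum(u^m d^2) is non-increasing across full update cycles.
    ``n_restarts`` random initializations are run and the lowest final
    objective is kept.

    Parameters
    ----------
    n_clusters : number of clusters c (6 for the staged accessibility
        analysis).
    m : fuzzifier > 1; 1.25 suits z-scored profiles (m = 2 over-fuzzifies
        standardized rows).

    Fitted attributes: ``cluster_centers_`` (c x stages), ``membership_``
    (rows sum to 1), ``labels_`` (argmax membership, ties -> lowest
    cluster index), ``objective_``, ``objective_history_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_clusters: int = 6,
        m: float = 1.25,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 10,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _memberships(self, X, C):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        u = np.zeros_like(d2)
        has_zero = zero.any(axis=1)
        if has_zero.any():
            first = zero[has_zero].argmax(axis=1)
            u[np.flatnonzero(has_zero), first] = 1.0
        rest = ~has_zero
        if rest.any():
            d2r = d2[rest]
            w = (d2r / d2r.min(axis=1, keepdims=True)) ** (-1.0 / (self.m - 1.0))
            u[rest] = w / w.sum(axis=1, keepdims=True)
        return u, d2

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, _ = X.shape
        c = self.n_clusters
        if n < c:
            raise ValueError("need at least n_clusters rows")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            C = X[rng.choice(n, size=c, replace=False)].copy()
            u_prev = None
            history: List[float] = []
            for it in range(self.max_iter):
                u, d2 = self._memberships(X, C)
                um = u ** self.m
                history.append(float((um * d2).sum()))
                denom = um.sum(axis=0)
                collapsed = denom < 1e-12
                if collapsed.any():
                    warnings.warn("re-seeding collapsed centroid(s)")
                    for k in np.flatnonzero(collapsed):
                        C[k] = X[rng.integers(n)]
                    continue
                C = (um.T @ X) / denom[:, None]
                # merge-collapse guard: identical centroids get re-seeded
                for k in range(c):
                    for l in range(k + 1, c):
                        if ((C[k] - C[l]) ** 2).sum() < 1e-20:
                            warnings.warn("re-seeding duplicate centroid")
                            C[l] = X[rng.integers(n)]
                if u_prev is not None and np.abs(u - u_prev).max() < self.tol:
                    u_prev = u
                    break
                u_prev = u
            u, d2 = self._memberships(X, C)
            obj = float((u ** self.m * d2).sum())
            history.append(obj)
            if best is None or obj < best[0]:
                best = (obj, C, u, history, it + 1)
        self.objective_, self.cluster_centers_, self.membership_, self.objective_history_, self.n_iter_ = best
        self.labels_ = self.membership_.argmax(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        u, _ = self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)
        return u.argmax(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fuzzy_cmeans(
    matrix,
    c: int = 6,
    m: float = 1.25,
    seed=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> FuzzyCMeans:
    """Fit a :class:`FuzzyCMeans` on a (peaks x stages) matrix."""
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    return FuzzyCMeans(
        n_clusters=c,
        m=m,
        tol=tol,
        max_iter=max_iter,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(X)


# ---------------------------------------------------------------------------
# categories and nearest-gene expression
# ---------------------------------------------------------------------------

def assign_categories(centers: np.ndarray) -> Dict[int, str]:
    """Map each cluster to category I/II/III by its centroid.

    Per cluster the mean centroid value over each consecutive stage pair
    (1+2, 2+3, 3+4) is computed and the argmax pair names the category;
    ties go to the earlier category.  Defined only for 4-stage series.
    """
    centers = np.asarray(centers)
    if centers.shape[1] != 4:
        raise ValueError("categories are defined for a 4-stage series only")
    pair_means = np.stack(
        [
            (centers[:, 0] + centers[:, 1]) / 2,
            (centers[:, 1] + centers[:, 2]) / 2,
            (centers[:, 2] + centers[:, 3]) / 2,
        ],
        axis=1,
    )
    return {k: CATEGORIES[int(pair_means[k].argmax())] for k in range(len(centers))}


def nearest_gene_expression(
    peaks: Sequence[GenomicInterval],
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    labels: Sequence[int],
    n_clusters: int | None = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Mean log2(count + 1) of each peak's nearest gene, per cluster x stage.

    Each peak is assigned the gene whose TSS is nearest its midpoint (ties
    -> smaller TSS coordinate).  Empty clusters yield an all-NaN row.
    Returns (cluster x stage matrix, per-peak nearest gene ids).
    """
    labels = np.asarray(labels)
    if n_clusters is None:
        n_clusters = int(labels.max()) + 1 if len(labels) else 0
    nearest: List[str] = []
    ann_by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="mergesort")
        for chrom, sub in annotation.groupby("chrom")
    }
    for p in peaks:
        sub = ann_by_chrom.get(p.chrom)
        if sub is None or not len(sub):
            raise ValueError(f"no annotated genes on {p.chrom}")
        tss = sub["tss"].to_numpy()
        dist = np.abs(tss - p.midpoint)
        best = np.flatnonzero(dist == dist.min())
        # ties: smaller TSS coordinate (sub already sorted by tss)
        nearest.append(sub["gene_id"].iloc[best[0]])
    logexpr = np.log2(expression + 1.0)
    rows = []
    for k in range(n_clusters):
        genes = [g for g, lab in zip(nearest, labels) if lab == k]
        if genes:
            rows.append(logexpr.loc[genes].mean(axis=0))
        else:
            rows.append(pd.Series(np.nan, index=expression.columns))
    result = pd.DataFrame(rows, index=[f"cluster{k + 1}" for k in range(n_clusters)])
    return result, nearest
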
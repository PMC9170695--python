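"""Chromatin-state segmentation from two histone marks.

Binned H3K4me3/H3K27me3 count tracks are binarized against a global Poisson
background and segmented with a K-state hidden Markov model whose emissions
are independent Bernoulli variables, one per mark.  With K = 4 the states
are given the standard semantic reading: both marks on -> bivalent, only
H3K4me3 -> H3K4me3_only, only H3K27me3 -> H3K27me3_only, neither ->
unmarked.

The Baum-Welch and Viterbi recursions are written here (scaled, so long
chromosomes cannot underflow) and jitted with numba when available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .intervals import GenomicInterval, SignalTrack

__all__ = [
    "BinarizedTrack",
    "BernoulliHMM",
    "ChromatinSegmentation",
    "STATE_LABELS",
    "binarize_poisson",
    "poisson_threshold",
    "fit_hmm",
    "decode_states",
    "label_states",
    "segment_genome",
]

MARK_K4 = "H3K4me3"
MARK_K27 = "H3K27me3"
STATE_LABELS = ("H3K4me3_only", "bivalent", "H3K27me3_only", "unmarked")

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=False)(fn)

except Exception:  # pragma: no cover

    def _jit(fn):
        return fn


@_jit
def _forward_scaled(pi, A, B):
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    if s <= 0.0:
        s = 1e-300
    alpha[0] = a / s
    c[0] = s
    for t in range(1, T):
        a = np.dot(alpha[t - 1], A) * B[t]
        s = a.sum()
        if s <= 0.0:
            s = 1e-300
        alpha[t] = a / s
        c[t] = s
    return alpha, c


@_jit
def _backward_scaled(A, B, c):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = np.dot(A, B[t + 1] * beta[t + 1]) / c[t + 1]
    return beta


@_jit
def _xi_sum(alpha, beta, A, B, c):
    T, K = B.shape
    out = np.zeros((K, K))
    for t in range(T - 1):
        right = B[t + 1] * beta[t + 1] / c[t + 1]
        for i in range(K):
            for j in range(K):
                out[i, j] += alpha[t, i] * A[i, j] * right[j]
    return out


@_jit
def _viterbi_path(log_pi, log_A, log_B):
    T, K = log_B.shape
    delta = log_pi + log_B[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nxt = np.empty(K)
        for j in range(K):
            best_i = 0
            best = delta[0] + log_A[0, j]
            for i in range(1, K):
                v = delta[i] + log_A[i, j]
                if v > best:
                    best = v
                    best_i = i
            nxt[j] = best + log_B[t, j]
            psi[t, j] = best_i
        delta = nxt
    path = np.zeros(T, dtype=np.int64)
    best_k = 0
    best = delta[0]
    for k in range(1, K):
        if delta[k] > best:
            best = delta[k]
            best_k = k
    path[T - 1] = best_k
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

@dataclass
class BinarizedTrack:
    """Per-chromosome binary (bins x marks) matrices with a fixed mark order."""

    data: Dict[str, np.ndarray]
    marks: List[str]
    bin_size: int

    def concatenated(self) -> tuple:
        """(stacked T x M matrix, per-chromosome lengths in chromosome order)."""
        mats = [self.data[c] for c in self.data]
        return np.vstack(mats), [m.shape[0] for m in mats]


def poisson_threshold(lam: float, alpha: float) -> float:
    """Smallest integer count c with P(X >= c | lam) < alpha (inf if lam == 0
    never reaches it)."""
    if lam <= 0:
        return 1.0  # any positive count is already impossible under lam=0
    c = max(1, int(lam))
    while stats.poisson.sf(c - 1, lam) >= alpha:
        c += 1
    return float(c)


def binarize_poisson(
    tracks: Mapping[str, SignalTrack], alpha: float = 1e-4
) -> BinarizedTrack:
    """Binarize binned count tracks against a global Poisson background.

    Per mark the background rate lambda is the genome-wide mean bin count;
    a bin is set to 1 iff the upper-tail probability P(X >= count | lambda)
    is below ``alpha``.  An all-zero track binarizes to all zeros.
    """
    marks = list(tracks)
    if not marks:
        raise ValueError("no tracks given")
    bin_size = tracks[marks[0]].bin_size
    chroms = list(tracks[marks[0]].data)
    for m in marks:
        if list(tracks[m].data) != chroms or tracks[m].bin_size != bin_size:
            raise ValueError("tracks disagree on chromosomes or bin size")
    thresholds = {}
    for m in marks:
        counts = np.rint(tracks[m].concatenated(chroms))
        if (counts < 0).any():
            raise ValueError(f"track {m!r} has negative counts")
        lam = counts.mean() if counts.size else 0.0
        thresholds[m] = poisson_threshold(lam, alpha) if lam > 0 else np.inf
    data = {}
    for chrom in chroms:
        cols = [
            (np.rint(tracks[m].data[chrom]) >= thresholds[m]).astype(np.uint8)
            for m in marks
        ]
        data[chrom] = np.column_stack(cols)
    return BinarizedTrack(data=data, marks=marks, bin_size=bin_size)


# ---------------------------------------------------------------------------
# the HMM estimator
# ---------------------------------------------------------------------------

class BernoulliHMM(BaseEstimator):
    """Hidden Markov model with independent Bernoulli emissions per mark.

    Parameters
    ----------
    n_states : number of hidden states (4 for the two-mark chromatin model).
    n_restarts : EM restarts; the solution with the highest log-likelihood
        is kept.  Restarts randomize the emission matrix in [0.2, 0.8].
    tol : absolute log-likelihood gain below which EM stops.
    max_iter : EM iteration cap per restart.
    random_state : seed for the restart stream.

    Fitted attributes (trailing underscore): ``startprob_``, ``transmat_``,
    ``emissionprob_`` (n_states x n_marks), ``log_likelihood_``,
    ``history_`` (per-iteration log-likelihoods of the winning restart),
    ``n_iter_``.
    """

    def __init__(
        self,
        n_states: int = 4,
        n_restarts: int = 5,
        tol: float = 1e-4,
        max_iter: int = 200,
        random_state=None,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("X must be a (T, n_marks) matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("observations must be binary (0/1)")
        return X.astype(np.float64)

    @staticmethod
    def _split(X, lengths):
        if lengths is None:
            return [X]
        if sum(lengths) != X.shape[0]:
            raise ValueError("lengths do not sum to the number of rows")
        out, i = [], 0
        for L in lengths:
            out.append(X[i : i + L])
            i += L
        return out

    def _frameprob(self, X, E):
        logp = np.log(E.T)
        logq = np.log1p(-E.T)
        return np.exp(X @ logp + (1.0 - X) @ logq)

    # -- EM ---------------------------------------------------------------
    def fit(self, X, lengths: Sequence[int] | None = None):
        X = self._validate(X)
        seqs = self._split(X, lengths)
        K, M = self.n_states, X.shape[1]
        n_unique = len({tuple(r) for r in np.unique(X, axis=0)})
        if n_unique < min(K, 2 ** M):
            # not an error per se, but warn: EM may be under-determined
            warnings.warn("fewer distinct observation rows than states")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            pi = rng.dirichlet(np.ones(K))
            A = 0.85 * np.eye(K) + 0.15 * rng.dirichlet(np.ones(K), size=K)
            A /= A.sum(axis=1, keepdims=True)
            E = rng.uniform(0.2, 0.8, size=(K, M))
            history: List[float] = []
            prev_ll = -np.inf
            for _it in range(self.max_iter):
                ll = 0.0
                pi_num = np.zeros(K)
                trans_num = np.zeros((K, K))
                e_num = np.zeros((K, M))
                e_den = np.zeros(K)
                for seq in seqs:
                    B = self._frameprob(seq, E)
                    alpha, c = _forward_scaled(pi, A, B)
                    beta = _backward_scaled(A, B, c)
                    ll += float(np.log(c).sum())
                    gamma = alpha * beta
                    gamma /= gamma.sum(axis=1, keepdims=True)
                    pi_num += gamma[0]
                    trans_num += _xi_sum(alpha, beta, A, B, c)
                    e_num += gamma.T @ seq
                    e_den += gamma.sum(axis=0)
                history.append(ll)
                if ll + 1e-6 * (1.0 + abs(ll)) < prev_ll:
                    raise RuntimeError("EM log-likelihood decreased")
                if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                    break
                prev_ll = ll
                pi = pi_num / pi_num.sum()
                row = trans_num.sum(axis=1, keepdims=True)
                A = np.where(row > 0, trans_num / np.maximum(row, 1e-300), 1.0 / K)
                E = np.clip(e_num / np.maximum(e_den[:, None], 1e-300), 1e-6, 1 - 1e-6)
                # stochasticity must survive every update
                if not (
                    np.allclose(pi.sum(), 1.0, atol=1e-9)
                    and np.allclose(A.sum(axis=1), 1.0, atol=1e-9)
                ):
                    raise RuntimeError("EM produced a non-stochastic parameter")
            if best is None or history[-1] > best[0]:
                best = (history[-1], pi, A, E, history)
        self.log_likelihood_, self.startprob_, self.transmat_, self.emissionprob_, self.history_ = best
        self.n_iter_ = len(self.history_)
        self.n_features_in_ = M
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "emissionprob_"):
            raise RuntimeError("model is not fitted")

    def score(self, X, lengths=None) -> float:
        self._check_fitted()
        X = self._validate(X)
        ll = 0.0
        for seq in self._split(X, lengths):
            B = self._frameprob(seq, self.emissionprob_)
            _, c = _forward_scaled(self.startprob_, self.transmat_, B)
            ll += float(np.log(c).sum())
        return ll

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi maximum-probability state path."""
        self._check_fitted()
        X = self._validate(X)
        paths = []
        for seq in self._split(X, lengths):
            B = self._frameprob(seq, self.emissionprob_)
            log_B = np.log(np.maximum(B, 1e-300))
            path, _ = _viterbi_path(
                np.log(np.maximum(self.startprob_, 1e-300)),
                np.log(np.maximum(self.transmat_, 1e-300)),
                log_B,
            )
            paths.append(path)
        return np.concatenate(paths)

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Forward-backward posterior state probabilities (rows sum to 1)."""
        self._check_fitted()
        X = self._validate(X)
        out = []
        for seq in self._split(X, lengths):
            B = self._frameprob(seq, self.emissionprob_)
            alpha, c = _forward_scaled(self.startprob_, self.transmat_, B)
            beta = _backward_scaled(self.transmat_, B, c)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            out.append(gamma)
        return np.vstack(out)

    def path_log_probability(self, X, path, lengths=None) -> float:
        """Joint log-probability of an explicit state path and observations."""
        self._check_fitted()
        X = self._validate(X)
        path = np.asarray(path)
        lp = 0.0
        offset = 0
        for seq in self._split(X, lengths):
            p = path[offset : offset + len(seq)]
            offset += len(seq)
            B = self._frameprob(seq, self.emissionprob_)
            lp += float(np.log(max(self.startprob_[p[0]], 1e-300)))
            lp += float(np.log(np.maximum(B[np.arange(len(seq)), p], 1e-300)).sum())
            lp += float(
                np.log(np.maximum(self.transmat_[p[:-1], p[1:]], 1e-300)).sum()
            )
        return lp

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_states": self.n_states,
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "emissionprob": self.emissionprob_.tolist(),
            "log_likelihood": self.log_likelihood_,
        }


# ---------------------------------------------------------------------------
# module-level wrappers and semantic labeling
# ---------------------------------------------------------------------------

def fit_hmm(
    binarized: BinarizedTrack,
    n_states: int = 4,
    seed=None,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> BernoulliHMM:
    """Fit a :class:`BernoulliHMM` on all chromosomes of a binarized track."""
    X, lengths = binarized.concatenated()
    model = BernoulliHMM(
        n_states=n_states,
        n_restarts=n_restarts,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    return model.fit(X, lengths=lengths)


def decode_states(model: BernoulliHMM, binarized: BinarizedTrack) -> Dict[str, np.ndarray]:
    """Viterbi state indices per chromosome."""
    if model.n_features_in_ != len(binarized.marks):
        raise ValueError("model and data disagree on the number of marks")
    return {chrom: model.predict(mat) for chrom, mat in binarized.data.items()}


def label_states(
    model: BernoulliHMM, marks: Sequence[str], threshold: float = 0.5
) -> Dict[int, str]:
    """Semantic 4-way labels from the fitted emission matrix.

    A mark counts as "on" in a state when its emission probability is at
    least ``threshold``.  Both on -> bivalent, only H3K4me3 ->
    H3K4me3_only, only H3K27me3 -> H3K27me3_only, neither -> unmarked.
    """
    if set(marks) != {MARK_K4, MARK_K27}:
        raise ValueError(f"semantic labeling needs marks {{{MARK_K4}, {MARK_K27}}}")
    i4 = list(marks).index(MARK_K4)
    i27 = list(marks).index(MARK_K27)
    labels: Dict[int, str] = {}
    for k in range(model.emissionprob_.shape[0]):
        on4 = model.emissionprob_[k, i4] >= threshold
        on27 = model.emissionprob_[k, i27] >= threshold
        if on4 and on27:
            labels[k] = "bivalent"
        elif on4:
            labels[k] = "H3K4me3_only"
        elif on27:
            labels[k] = "H3K27me3_only"
        else:
            labels[k] = "unmarked"
    if len(set(labels.values())) < len(labels):
        warnings.warn("multiple states map to the same semantic label")
    return labels


@dataclass
class ChromatinSegmentation:
    """Per-bin state indices with their semantic labels."""

    states: Dict[str, np.ndarray]
    state_labels: Dict[int, str]
    bin_size: int

    def label_array(self, chrom: str) -> np.ndarray:
        lut = np.array(
            [self.state_labels[k] for k in sorted(self.state_labels)], dtype=object
        )
        return lut[self.states[chrom]]

    def segments(self, label: str) -> List[GenomicInterval]:
        """Merged, sorted intervals of consecutive bins carrying ``label``."""
        out: List[GenomicInterval] = []
        wanted = {k for k, v in self.state_labels.items() if v == label}
        for chrom, st in self.states.items():
            mask = np.isin(st, list(wanted))
            if not mask.any():
                continue
            padded = np.concatenate([[False], mask, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                out.append(
                    GenomicInterval(chrom, int(s) * self.bin_size, int(e) * self.bin_size)
                )
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, st in self.states.items():
                boundaries = np.flatnonzero(np.diff(st)) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [len(st)]])
                for s, e in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{s * self.bin_size}\t{e * self.bin_size}\t"
                        f"{self.state_labels[int(st[s])]}\n"
                    )


def segment_genome(
    binarized: BinarizedTrack,
    model: BernoulliHMM,
    threshold: float = 0.5,
) -> ChromatinSegmentation:
    """Decode + label a binarized genome with a fitted model."""
    labels = label_states(model, binarized.marks, threshold=threshold)
    return ChromatinSegmentation(
        states=decode_states(model, binarized),
        state_labels=labels,
        bin_size=binarized.bin_size,
    )


def save_model(model: BernoulliHMM, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
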
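"""PWM scanning, motif enrichment, candidate-regulator intersection, and
aggregate ATAC footprint profiling.

Position count matrices become probability matrices with a pseudocount and
log2-odds scores against a background base composition.  Peaks are scanned
on both strands; a window is reported when its score reaches a fraction of
the maximum achievable score.  Enrichment of a motif in a foreground peak
set against a background peak set is the one-sided Fisher exact test on
peaks-containing-the-motif counts (binary per peak), BH-corrected across
TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, SignalTrack

__all__ = [
    "PWM",
    "FootprintProfile",
    "pwm_from_counts",
    "read_jaspar",
    "write_jaspar",
    "scan_pwm",
    "fisher_one_sided",
    "motif_enrichment",
    "candidate_regulators",
    "lift_occurrences",
    "footprint_profile",
    "footprint_depth",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix with derived log2-odds scores.

    ``probs`` is 4 x width in ACGT order; each column sums to 1.
    ``log_odds`` is log2(prob / background).  N bases score 0 (background).
    """

    name: str
    probs: np.ndarray
    background: np.ndarray
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("probability matrix must be 4 x width")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        self.log_odds = np.log2(self.probs / self.background[:, None])

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PWM:
    """Position count matrix -> PWM: (count + pc) / (column total + 4 pc)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("count matrix must have 4 rows (ACGT)")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("empty count column")
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name=name, probs=probs, background=bg)


# ---------------------------------------------------------------------------
# JASPAR-style PFM text
# ---------------------------------------------------------------------------

def read_jaspar(path, pseudocount: float = 1.0) -> List[PWM]:
    """Read JASPAR-style position frequency matrices.

    Format: ``>NAME`` header then four lines ``A [ 1 2 3 ]`` (brackets
    optional) in ACGT order.
    """
    pwms: List[PWM] = []
    name, rows = None, {}

    def flush():
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"motif {name!r}: missing base rows")
        counts = np.array([rows[b] for b in BASES], dtype=float)
        pwms.append(pwm_from_counts(name, counts, pseudocount=pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], {}
            else:
                base, rest = line[0].upper(), line[1:]
                rest = rest.replace("[", " ").replace("]", " ")
                rows[base] = [float(x) for x in rest.split()]
    flush()
    return pwms


def write_jaspar(counts_by_name: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for name, counts in counts_by_name.items():
            fh.write(f">{name}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(str(int(v)) for v in np.asarray(counts)[i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)  # 4 = N / unknown
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lo_ext: np.ndarray, width: int) -> np.ndarray:
    n_win = codes.size - width + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for j in range(width):
        scores += lo_ext[codes[j : j + n_win], j]
    return scores


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Scan both strands of every sequence for PWM matches.

    A window is reported iff its log-odds score is at least
    ``threshold_fraction`` x the maximum achievable score.  Minus-strand
    windows are scored on the reverse complement; their offset is the
    forward coordinate of the window start.  N scores as background
    (log-odds contribution 0).  Sequences shorter than the motif are
    skipped with a warning.
    """
    import warnings

    W = pwm.width
    threshold = threshold_fraction * pwm.max_score
    lo_ext = np.vstack([pwm.log_odds, np.zeros((1, W))])  # row 4: N
    rows = []
    for peak_id, seq in sequences.items():
        if len(seq) < W:
            warnings.warn(f"sequence {peak_id!r} shorter than motif; skipped")
            continue
        codes = _encode(seq)
        fwd = _window_scores(codes, lo_ext, W)
        for off in np.flatnonzero(fwd >= threshold):
            rows.append((peak_id, int(off), "+", float(fwd[off])))
        rc_codes = _encode(reverse_complement(seq))
        rev = _window_scores(rc_codes, lo_ext, W)
        L = len(seq)
        for off in np.flatnonzero(rev >= threshold):
            rows.append((peak_id, int(L - off - W), "-", float(rev[off])))
    df = pd.DataFrame(rows, columns=["peak_id", "offset", "strand", "score"])
    df.insert(0, "tf", pwm.name)
    return df.sort_values(["peak_id", "offset", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def scan_all(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Concatenated scan results for several PWMs."""
    frames = [scan_pwm(sequences, p, threshold_fraction) for p in pwms]
    if not frames:
        return pd.DataFrame(columns=["tf", "peak_id", "offset", "strand", "score"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_one_sided(fg_hits, fg_total, bg_hits, bg_total):
    """One-sided Fisher exact p (enrichment direction), vectorized.

    Equals the hypergeometric upper-tail probability of drawing at least
    ``fg_hits`` motif-containing peaks when ``fg_total`` peaks are drawn
    from the pooled set.
    """
    a = np.asarray(fg_hits)
    n_fg = np.asarray(fg_total)
    b = np.asarray(bg_hits)
    n_bg = np.asarray(bg_total)
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(a - 1, n_fg + n_bg, a + b, n_fg)
    # empty population: observing nothing has probability 1
    return np.where(n_fg + n_bg > 0, p, 1.0)


def motif_enrichment(
    occurrences: pd.DataFrame,
    foreground_ids: Iterable[str],
    background_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-TF foreground-vs-background enrichment.

    Counting is binary per peak (a peak "contains" the motif if it has at
    least one occurrence).  The p-value is the one-sided Fisher exact test
    in the enrichment direction (hypergeometric upper tail); q is BH across
    the TFs of this call.  Odds ratio is the sample odds ratio with
    +inf for degenerate denominators.
    """
    fg = set(foreground_ids)
    bg = set(background_ids)
    if not fg:
        raise ValueError("empty foreground")
    if fg & bg:
        raise ValueError("foreground and background overlap")
    rows = []
    for tf, sub in occurrences.groupby("tf"):
        hit_peaks = set(sub["peak_id"])
        a = len(fg & hit_peaks)
        b = len(bg & hit_peaks)
        n_fg, n_bg = len(fg), len(bg)
        p = float(fisher_one_sided(a, n_fg, b, n_bg))
        with np.errstate(divide="ignore", invalid="ignore"):
            num = a / (n_fg - a) if n_fg > a else np.inf
            den = b / (n_bg - b) if n_bg > b else np.inf
            if den == 0:
                odds = np.inf if num > 0 else np.nan
            elif np.isinf(den):
                odds = 0.0 if not np.isinf(num) else np.nan
            else:
                odds = num / den
        rows.append((tf, a, n_fg, b, n_bg, a / n_fg, b / n_bg if n_bg else np.nan, odds, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "tf",
            "fg_hits",
            "fg_total",
            "bg_hits",
            "bg_total",
            "fg_prop",
            "bg_prop",
            "odds_ratio",
            "p",
        ],
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values(["p", "tf"], kind="mergesort").reset_index(drop=True)


def candidate_regulators(
    enrichment_by_category: Mapping[str, pd.DataFrame],
    activated_genes: Set[str],
    categories: Sequence[str] = ("II", "III"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """TFs enriched in the chosen categories that are also activated
    bivalent genes, ordered by best q then name."""
    best_q: Dict[str, float] = {}
    for cat in categories:
        enr = enrichment_by_category.get(cat)
        if enr is None or not len(enr):
            continue
        passing = enr[enr["q"] <= alpha]
        for tf, q in zip(passing["tf"], passing["q"]):
            best_q[tf] = min(q, best_q.get(tf, np.inf))
    hits = sorted(
        (tf for tf in best_q if tf in activated_genes),
        key=lambda tf: (best_q[tf], tf),
    )
    return pd.DataFrame({"tf": hits, "best_q": [best_q[tf] for tf in hits]})


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def lift_occurrences(occurrences: pd.DataFrame, width: int) -> pd.DataFrame:
    """Peak-relative occurrences -> genome coordinates.

    Peak ids must be of the form ``chrom:start-end`` (the convention used
    for consensus peaks and peak FASTA records throughout the package).
    """
    chroms, starts, ends = [], [], []
    for peak_id, off in zip(occurrences["peak_id"], occurrences["offset"]):
        chrom, span = peak_id.rsplit(":", 1)
        p_start, _ = span.split("-")
        g = int(p_start) + int(off)
        chroms.append(chrom)
        starts.append(g)
        ends.append(g + width)
    out = occurrences.copy()
    out["chrom"] = chroms
    out["start"] = starts
    out["end"] = ends
    return out


@dataclass
class FootprintProfile:
    """Position-wise mean cut signal around aligned motif sites."""

    tf_name: str
    stage: str
    radius: int
    width: int
    values: np.ndarray
    n_sites: int
    n_skipped: int = 0

    def __post_init__(self):
        expected = 2 * self.radius + self.width
        if self.values.shape != (expected,):
            raise ValueError("profile length must be 2*radius + width")


def footprint_profile(
    track: SignalTrack,
    occurrences: pd.DataFrame,
    width: int,
    radius: int = 100,
    tf_name: str = "",
    stage: str = "",
) -> FootprintProfile:
    """Mean per-base cut signal across motif sites, aligned on the motif.

    ``track`` must be at base-pair resolution.  Each site's window
    ``[start - radius, end + radius)`` is extracted (reversed for minus
    strand sites); sites whose window leaves the chromosome are skipped
    and counted.
    """
    if track.bin_size != 1:
        raise ValueError("footprints need a base-pair resolution track")
    if radius <= 0:
        raise ValueError("radius must be positive")
    L = 2 * radius + width
    acc = np.zeros(L)
    n_sites = n_skipped = 0
    for chrom, start, strand in zip(
        occurrences["chrom"], occurrences["start"], occurrences["strand"]
    ):
        vec = track.data[chrom]
        w0 = int(start) - radius
        w1 = int(start) + width + radius
        if w0 < 0 or w1 > len(vec):
            n_skipped += 1
            continue
        window = vec[w0:w1]
        acc += window[::-1] if strand == "-" else window
        n_sites += 1
    values = acc / n_sites if n_sites else np.full(L, np.nan)
    return FootprintProfile(
        tf_name=tf_name,
        stage=stage,
        radius=radius,
        width=width,
        values=values,
        n_sites=n_sites,
        n_skipped=n_skipped,
    )


def footprint_depth(profile: FootprintProfile) -> float:
    """1 - mean(core) / mean(flank); flank = outermost radius/2 per side.

    A flat profile gives exactly 0; a core at half the flank level gives
    0.5.  A zero flank mean yields NaN.
    """
    r, w = profile.radius, profile.width
    v = profile.values
    core = v[r : r + w]
    k = r // 2
    flank = np.concatenate([v[:k], v[-k:]])
    fm = flank.mean()
    if fm == 0:
        return float("nan")
    return float(1.0 - core.mean() / fm)
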
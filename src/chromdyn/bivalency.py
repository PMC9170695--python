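"""Promoter chromatin-state calls and bivalent-domain transition dynamics.

A gene promoter (TSS +/- 2.5 kb by default) is called bivalent when its
total base overlap with bivalent segments exceeds 200 bp (strict), the rule
used for bivalent-gene identification; otherwise the non-bivalent label with
the largest promoter overlap wins.  Between successive stages a bivalent
promoter has exactly four possible fates in the 4-label alphabet, giving the
four transition modes: stable_bivalent, activated (-> H3K4me3_only),
repressed (-> H3K27me3_only) and resolved_unmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .hmm import ChromatinSegmentation
from .intervals import GenomicInterval, SignalTrack, promoter_window

__all__ = [
    "TRANSITION_MODES",
    "TransitionSummary",
    "call_promoter_state",
    "classify_bivalent_transitions",
    "activated_gene_sets",
    "promoter_signal_correlation",
]

TRANSITION_MODES = ("stable_bivalent", "activated", "repressed", "resolved_unmarked")

#: fate of a bivalent promoter, by its state at the later stage
_MODE_OF_STATE = {
    "bivalent": "stable_bivalent",
    "H3K4me3_only": "activated",
    "H3K27me3_only": "repressed",
    "unmarked": "resolved_unmarked",
}

#: tie-break priority for the non-bivalent plurality label
_PRIORITY = ("H3K4me3_only", "H3K27me3_only", "unmarked")


def call_promoter_state(
    segmentation: ChromatinSegmentation,
    annotation: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int = 2500,
    min_bivalent_overlap: int = 200,
) -> pd.DataFrame:
    """Per-gene promoter state calls.

    Returns a DataFrame with columns gene_id, state, bivalent_overlap
    (base pairs of the promoter window covered by bivalent segments,
    aggregated across segments before the strict > ``min_bivalent_overlap``
    test).
    """
    B = segmentation.bin_size
    missing = set(annotation["chrom"]) - set(segmentation.states)
    if missing:
        genes = annotation.loc[annotation["chrom"].isin(missing), "gene_id"].tolist()
        raise ValueError(
            f"genes on chromosome(s) absent from segmentation: {genes[:5]}..."
            if len(genes) > 5
            else f"genes on chromosome(s) absent from segmentation: {genes}"
        )
    rows = []
    for gene_id, chrom, tss in zip(
        annotation["gene_id"], annotation["chrom"], annotation["tss"]
    ):
        win = promoter_window(chrom, int(tss), chrom_sizes, flank=flank)
        st = segmentation.states[chrom]
        b0 = win.start // B
        b1 = -(-win.end // B)  # ceil
        b1 = min(b1, len(st))
        overlap: Dict[str, float] = {lab: 0.0 for lab in set(segmentation.state_labels.values())}
        idx = np.arange(b0, b1)
        if idx.size:
            bin_starts = idx * B
            ov = np.minimum(win.end, bin_starts + B) - np.maximum(win.start, bin_starts)
            labels = segmentation.label_array(chrom)[b0:b1]
            for lab in overlap:
                overlap[lab] = float(ov[labels == lab].sum())
        biv = overlap.get("bivalent", 0.0)
        if biv > min_bivalent_overlap:
            state = "bivalent"
        else:
            state = max(
                _PRIORITY,
                key=lambda lab: (overlap.get(lab, 0.0), -_PRIORITY.index(lab)),
            )
        rows.append((gene_id, state, int(biv)))
    return pd.DataFrame(rows, columns=["gene_id", "state", "bivalent_overlap"])


@dataclass
class TransitionSummary:
    """Counts and ratios of the four bivalent-transition modes for one
    stage pair.  Ratios are counts / n_bivalent_start; with no bivalent
    promoters at the earlier stage they are reported as 0 with
    ``degenerate`` set."""

    stage_pair: Tuple[str, str]
    counts: Dict[str, int]
    ratios: Dict[str, float]
    n_bivalent_start: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "stage_pair": list(self.stage_pair),
            "counts": self.counts,
            "ratios": self.ratios,
            "n_bivalent_start": self.n_bivalent_start,
            "degenerate": self.degenerate,
        }


def classify_bivalent_transitions(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    stage_pair: Tuple[str, str] = ("A", "B"),
) -> Tuple[pd.DataFrame, TransitionSummary]:
    """Classify the fate of every promoter bivalent at the earlier stage."""
    if set(calls_a["gene_id"]) != set(calls_b["gene_id"]):
        raise ValueError("stage call sets cover different genes")
    b_state = calls_b.set_index("gene_id")["state"]
    biv = calls_a.loc[calls_a["state"] == "bivalent", "gene_id"]
    records = pd.DataFrame(
        {
            "gene_id": biv.to_numpy(),
            "stage_pair": [f"{stage_pair[0]}->{stage_pair[1]}"] * len(biv),
            "mode": [_MODE_OF_STATE[b_state[g]] for g in biv],
        }
    )
    n = len(records)
    counts = {m: int((records["mode"] == m).sum()) for m in TRANSITION_MODES}
    if n:
        ratios = {m: counts[m] / n for m in TRANSITION_MODES}
        degenerate = False
    else:
        ratios = {m: 0.0 for m in TRANSITION_MODES}
        degenerate = True
    return records, TransitionSummary(
        stage_pair=tuple(stage_pair),
        counts=counts,
        ratios=ratios,
        n_bivalent_start=n,
        degenerate=degenerate,
    )


def activated_gene_sets(
    calls_by_stage: Mapping[str, pd.DataFrame],
    stages: Sequence[str],
) -> Dict[Tuple[str, str], Set[str]]:
    """Genes activated (bivalent -> H3K4me3_only) per successive stage pair.

    Sets may share members across pairs: a gene can re-enter bivalency.
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    out: Dict[Tuple[str, str], Set[str]] = {}
    for a, b in zip(stages[:-1], stages[1:]):
        records, _ = classify_bivalent_transitions(
            calls_by_stage[a], calls_by_stage[b], stage_pair=(a, b)
        )
        out[(a, b)] = set(records.loc[records["mode"] == "activated", "gene_id"])
    return out


def _promoter_sums(
    track: SignalTrack,
    annotation: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int,
) -> np.ndarray:
    """Per-gene summed signal over the promoter window (partial bins counted
    proportionally)."""
    B = track.bin_size
    out = np.zeros(len(annotation))
    for i, (chrom, tss) in enumerate(zip(annotation["chrom"], annotation["tss"])):
        win = promoter_window(chrom, int(tss), chrom_sizes, flank=flank)
        vec = track.data[chrom]
        b0 = win.start // B
        b1 = min(-(-win.end // B), len(vec))
        idx = np.arange(b0, b1)
        bin_starts = idx * B
        frac = (
            np.minimum(win.end, bin_starts + B) - np.maximum(win.start, bin_starts)
        ) / B
        out[i] = float((vec[b0:b1] * frac).sum())
    return out


def promoter_signal_correlation(
    expression: pd.DataFrame,
    tracks_by_stage: Mapping[str, Mapping[str, SignalTrack]],
    annotation: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int = 2500,
) -> Dict[str, pd.DataFrame]:
    """Pearson correlation of promoter-level features, per stage.

    Features per gene: log2(expression + 1) and log2(promoter-window summed
    signal + 1) for each assay track (e.g. H3K4me3, H3K27me3, ATAC).
    Zero-variance features yield NaN correlations rather than an error.
    """
    genes = annotation["gene_id"]
    if not set(genes).issubset(expression.index):
        raise ValueError("expression matrix does not cover all annotated genes")
    out: Dict[str, pd.DataFrame] = {}
    for stage, assays in tracks_by_stage.items():
        feats = {"expression": np.log2(expression.loc[genes, stage].to_numpy() + 1.0)}
        for assay, track in assays.items():
            feats[assay] = np.log2(
                _promoter_sums(track, annotation, chrom_sizes, flank) + 1.0
            )
        names = list(feats)
        mat = np.vstack([feats[n] for n in names])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat)
        sd = mat.std(axis=1)
        corr[sd == 0, :] = np.nan
        corr[:, sd == 0] = np.nan
        np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
        out[stage] = pd.DataFrame(corr, index=names, columns=names)
    return out
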
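"""Knockout-dependent open-region classification.

Consensus peaks are split by the WT/KO accessibility fold change with a
pseudocount: peaks attenuated at least ``fold``-fold in the knockout are
*dependent* open regions, peaks gained at least ``fold``-fold are
*independent* (the same symmetric rule), everything else is *unchanged*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .motif import motif_enrichment

__all__ = [
    "KO_LABELS",
    "KOClassification",
    "classify_ko_peaks",
    "fraction_summary",
    "percent_string",
    "dependent_vs_independent_enrichment",
]

KO_LABELS = ("dependent", "independent", "unchanged")


@dataclass
class KOClassification:
    """Per-peak KO labels with the fold-change vector and the rule used."""

    labels: np.ndarray  # dtype object, values in KO_LABELS
    fold_changes: np.ndarray  # (wt + pc) / (ko + pc)
    fold: float
    pseudocount: float
    peak_ids: Sequence[str] | None = None

    @property
    def counts(self) -> Dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in KO_LABELS}

    @property
    def total(self) -> int:
        return int(len(self.labels))


def classify_ko_peaks(
    wt: Sequence[float],
    ko: Sequence[float],
    fold: float = 2.0,
    pseudocount: float = 0.5,
    peak_ids: Sequence[str] | None = None,
) -> KOClassification:
    """Classify peaks by the pseudocounted WT/KO ratio.

    r = (wt + pc) / (ko + pc); dependent iff r >= fold, independent iff
    1/r >= fold, else unchanged.
    """
    wt = np.asarray(wt, dtype=float)
    ko = np.asarray(ko, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError("WT and KO vectors differ in length")
    if (wt < 0).any() or (ko < 0).any():
        raise ValueError("negative accessibility values")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    r = (wt + pseudocount) / (ko + pseudocount)
    labels = np.full(wt.shape, "unchanged", dtype=object)
    labels[r >= fold] = "dependent"
    labels[1.0 / r >= fold] = "independent"
    return KOClassification(
        labels=labels,
        fold_changes=r,
        fold=fold,
        pseudocount=pseudocount,
        peak_ids=peak_ids,
    )


def percent_string(count: int, total: int) -> str:
    """100 x count/total, rounded half-up to one decimal (e.g. '34.1')."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * Decimal(100) / Decimal(total)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def fraction_summary(classification: KOClassification) -> dict:
    """Counts, exact fractions and one-decimal percentage strings per label."""
    total = classification.total
    if total <= 0:
        raise ValueError("no peaks to summarize")
    counts = classification.counts
    return {
        "total": total,
        "counts": counts,
        "fractions": {lab: counts[lab] / total for lab in KO_LABELS},
        "percent": {lab: percent_string(counts[lab], total) for lab in KO_LABELS},
    }


def dependent_vs_independent_enrichment(
    classification: KOClassification,
    occurrences: pd.DataFrame,
) -> pd.DataFrame:
    """Motif enrichment of dependent against independent open regions.

    Delegates to :func:`chromdyn.motif.motif_enrichment` with foreground =
    dependent peaks and background = independent peaks.
    """
    if classification.peak_ids is None:
        raise ValueError("classification carries no peak ids")
    ids = np.asarray(classification.peak_ids, dtype=object)
    fg = ids[classification.labels == "dependent"]
    bg = ids[classification.labels == "independent"]
    if not len(fg) or not len(bg):
        raise ValueError("both dependent and independent classes must be non-empty")
    return motif_enrichment(occurrences, fg, bg)
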
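"""Synthetic multi-stage genome with planted ground truth.

The generator emulates the staged differentiation design the analysis
expects: a small random genome with non-overlapping promoter windows,
per-stage H3K4me3/H3K27me3 count tracks driven by planted promoter
chromatin states and their transition modes, intergenic accessibility
peaks following six temporal archetypes grouped into categories I/II/III,
TF motifs embedded into category-specific peak sequences (with
footprint-shaped cut-site dips), expression coupled to promoter state,
and a WT/KO accessibility pair with a planted fraction of attenuated
peaks.  Every planted quantity is recorded in truth tables so downstream
stages can be tested for recovery.

All randomness flows from one root seed; each submodule draws from its own
fixed-offset child stream, so regenerating one layer never reshuffles the
others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, SignalTrack
from .motif import BASES, pwm_from_counts, reverse_complement, write_jaspar

__all__ = [
    "SyntheticConfig",
    "TruthTables",
    "SimulatedGenome",
    "SimulationResult",
    "simulate_genome",
    "simulate_chip_tracks",
    "simulate_atac",
    "simulate_expression",
    "simulate_ko",
    "simulate_ko_counts",
    "simulate_all",
    "tf_count_matrix",
]

# fixed child-stream offsets (root seed, offset)
_STREAM_SEQUENCE = 1
_STREAM_STATES = 2
_STREAM_CHIP = 3
_STREAM_ATAC = 4
_STREAM_EXPR = 5
_STREAM_KO = 6
_STREAM_MOTIF = 7

_K4_STATES = {"H3K4me3_only", "bivalent"}
_K27_STATES = {"H3K27me3_only", "bivalent"}
_OPEN_STATES = _K4_STATES  # accessible promoter states

# Six temporal archetypes, two per category.  Shapes are designed in rank
# space (per-stage value ranks), because quantile normalization makes the
# downstream category rule depend on within-stage ranks, not raw levels.
_DEFAULT_ARCHETYPES = (
    (1.00, 0.70, 0.10, 0.05),  # cluster 1, category I: open in hPSC+VME
    (0.70, 1.00, 0.40, 0.10),  # cluster 2, category I
    (0.10, 1.00, 0.70, 0.10),  # cluster 3, category II: open in VME+EPC
    (0.05, 0.75, 1.00, 0.05),  # cluster 4, category II
    (0.10, 0.30, 1.00, 0.80),  # cluster 5, category III: open in EPC+HPC
    (0.05, 0.10, 0.40, 1.00),  # cluster 6, category III
)


def _default_forced_gene_states() -> Dict[str, Tuple[str, ...]]:
    """Hand-planted regulator genes: promoter-state programs for the TFs
    whose motifs are planted, mirroring staged activation of hematopoietic
    regulators.  POU5F1 is constitutively active, CTCF stays poised."""
    biv, k4 = "bivalent", "H3K4me3_only"
    return {
        "POU5F1": (k4, k4, k4, k4),
        "CTCF": (biv, biv, biv, biv),
        "SOX17": (biv, biv, k4, k4),
        "JUNB": (biv, biv, k4, k4),
        "GATA2": (biv, biv, biv, k4),
        "RUNX1": (biv, biv, biv, k4),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults are the conditions the recovery analyses assume: a 4-stage
    series, 2000 genes, a 10x marked/background Poisson rate ratio, a 20%
    activated bivalent-transition share, six accessibility archetypes in
    three categories, an 80% motif planting rate, a 0.5 footprint dip, and
    a 34.1% KO-dependent peak fraction attenuated 4-fold.
    """

    seed: int = 0
    stages: Tuple[str, ...] = ("hPSC", "VME", "EPC", "HPC")
    n_chroms: int = 4
    chrom_length: int = 13_500_000
    n_genes: int = 2000
    n_intergenic_peaks: int = 900
    bin_size: int = 200
    gene_spacing: int = 25_000
    peak_spacing: int = 1_000
    peak_width: int = 500
    flank: int = 2_500
    # promoter chromatin states
    initial_state_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "bivalent": 0.30,
            "H3K4me3_only": 0.15,
            "H3K27me3_only": 0.10,
            "unmarked": 0.45,
        }
    )
    mode_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "activated": 0.20,
            "stable_bivalent": 0.70,
            "repressed": 0.05,
            "resolved_unmarked": 0.05,
        }
    )
    forced_gene_states: Dict[str, Tuple[str, ...]] = field(
        default_factory=_default_forced_gene_states
    )
    # ChIP signal model (per-bin Poisson rates)
    lambda_lo: float = 2.0
    lambda_hi: float = 20.0
    # promoter accessibility (per-bin Poisson rates for the binned ATAC layer)
    atac_promoter_lo: float = 1.0
    atac_promoter_hi: float = 10.0
    # accessibility archetypes
    archetype_profiles: Tuple[Tuple[float, ...], ...] = _DEFAULT_ARCHETYPES
    archetype_categories: Tuple[str, ...] = ("I", "I", "II", "II", "III", "III")
    peak_height: float = 300.0  # expected cut count of a fully open peak
    presence_threshold: float = 100.0  # expected count needed to call a stage peak
    # motifs
    motif_assignments: Dict[str, str] = field(
        default_factory=lambda: {
            "POU5F1": "I",
            "SOX17": "II",
            "JUNB": "II",
            "CTCF": "II",
            "GATA2": "III",
            "RUNX1": "III",
        }
    )
    motif_width: int = 10
    motif_planting_rate: float = 0.8
    motif_margin: int = 100  # keep planted sites this far from peak edges
    footprint_dip: float = 0.5
    # expression model
    nb_mean_by_state: Dict[str, float] = field(
        default_factory=lambda: {
            "H3K4me3_only": 200.0,
            "bivalent": 20.0,
            "H3K27me3_only": 10.0,
            "unmarked": 10.0,
        }
    )
    nb_dispersion: float = 10.0
    # knockout contrast
    ko_dependent_fraction: float = 0.341
    ko_independent_fraction: float = 0.132
    ko_fold: float = 4.0
    ko_wt_mean: float = 100.0
    ko_motif_tf: str = "ERG"
    ko_dep_motif_rate: float = 0.40
    ko_indep_motif_rate: float = 0.05

    def __post_init__(self):
        if len(self.stages) < 2 or len(set(self.stages)) != len(self.stages):
            raise ValueError("stages must be >= 2 unique labels")
        if abs(sum(self.mode_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("mode_proportions must sum to 1")
        if abs(sum(self.initial_state_probs.values()) - 1.0) > 1e-9:
            raise ValueError("initial_state_probs must sum to 1")
        if not (self.lambda_hi > self.lambda_lo >= 0):
            raise ValueError("need lambda_hi > lambda_lo >= 0")
        if not (0 <= self.ko_dependent_fraction <= 1):
            raise ValueError("ko_dependent_fraction must be in [0, 1]")
        if self.ko_dependent_fraction + self.ko_independent_fraction > 1:
            raise ValueError("KO fractions sum to more than 1")
        for profile in self.archetype_profiles:
            if len(profile) != len(self.stages):
                raise ValueError("archetype profiles must span the stage series")
        for tf, states in self.forced_gene_states.items():
            if len(states) != len(self.stages):
                raise ValueError(f"forced states for {tf!r} must cover all stages")
        if self.motif_width + 2 * self.motif_margin > self.peak_width:
            raise ValueError("motif plus margins wider than peak")

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


@dataclass
class TruthTables:
    """Ground truth emitted by the generator."""

    gene_states: pd.DataFrame  # index gene_id, columns stages
    transition_modes: pd.DataFrame  # gene_id, stage_pair, mode
    peak_table: pd.DataFrame  # peak_id, chrom, start, end, archetype, category
    motif_placements: pd.DataFrame  # peak_id, tf, offset, strand, sequence
    ko_labels: pd.DataFrame  # peak_id, label

    def to_json(self, path) -> None:
        payload = {
            "gene_states": self.gene_states.reset_index().to_dict(orient="list"),
            "transition_modes": self.transition_modes.to_dict(orient="list"),
            "peak_table": self.peak_table.to_dict(orient="list"),
            "motif_placements": self.motif_placements.to_dict(orient="list"),
            "ko_labels": self.ko_labels.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTables":
        with open(path) as fh:
            payload = json.load(fh)
        gene_states = pd.DataFrame(payload["gene_states"]).set_index("gene_id")
        return cls(
            gene_states=gene_states,
            transition_modes=pd.DataFrame(payload["transition_modes"]),
            peak_table=pd.DataFrame(payload["peak_table"]),
            motif_placements=pd.DataFrame(payload["motif_placements"]),
            ko_labels=pd.DataFrame(payload["ko_labels"]),
        )

    def planted_candidates(self, categories=("II", "III")) -> set:
        """TFs with motifs planted in the chosen categories whose genes are
        planted activated-bivalent at some stage pair."""
        activated = set(
            self.transition_modes.loc[
                self.transition_modes["mode"] == "activated", "gene_id"
            ]
        )
        by_cat = (
            self.motif_placements.merge(
                self.peak_table[["peak_id", "category"]], on="peak_id"
            )
            if len(self.motif_placements)
            else pd.DataFrame(columns=["tf", "category"])
        )
        planted = set(
            by_cat.loc[by_cat["category"].isin(categories), "tf"]
        )
        return planted & activated


@dataclass
class SimulatedGenome:
    sequences: Dict[str, np.ndarray]  # uint8 base codes, 0..3 = ACGT
    chrom_sizes: Dict[str, int]
    annotation: pd.DataFrame  # gene_id, chrom, tss, strand
    peaks: List[GenomicInterval]

    def sequence_str(self, chrom: str) -> str:
        lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        return lut[self.sequences[chrom]].tobytes().decode()

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequence_str(c)), id=c, description="")
            for c in self.sequences
        ]
        seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genome geometry and states
# ---------------------------------------------------------------------------

def simulate_genome(config: SyntheticConfig) -> Tuple[SimulatedGenome, TruthTables]:
    """Random uniform background sequence plus gene/peak geometry and the
    planted promoter-state truth.

    TSSs sit at gene-slot centers so promoter windows never overlap each
    other or the intergenic peaks; infeasible packing raises.
    """
    rng_seq = config.rng(_STREAM_SEQUENCE)
    rng_states = config.rng(_STREAM_STATES)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    # geometry: gene slots first, then peak slots, greedily per chromosome
    gene_rows = []
    peaks: List[GenomicInterval] = []
    genes_left, peaks_left = config.n_genes, config.n_intergenic_peaks
    forced = list(config.forced_gene_states)
    gi = 0
    for chrom in chroms:
        pos = 0
        while genes_left and pos + config.gene_spacing <= config.chrom_length:
            tss = pos + config.gene_spacing // 2
            gene_id = forced[gi] if gi < len(forced) else f"G{gi:05d}"
            strand = "+" if rng_states.random() < 0.5 else "-"
            gene_rows.append((gene_id, chrom, tss, strand))
            pos += config.gene_spacing
            genes_left -= 1
            gi += 1
        while peaks_left and pos + config.peak_spacing <= config.chrom_length:
            start = pos + (config.peak_spacing - config.peak_width) // 2
            peaks.append(GenomicInterval(chrom, start, start + config.peak_width))
            pos += config.peak_spacing
            peaks_left -= 1
    if genes_left or peaks_left:
        raise ValueError(
            "geometry infeasible: "
            f"{genes_left} genes and {peaks_left} peaks do not fit into "
            f"{config.n_chroms} x {config.chrom_length} bp"
        )
    annotation = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])

    sequences = {
        c: rng_seq.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        for c in chroms
    }

    gene_states = _assign_gene_states(config, annotation, rng_states)
    transition_modes = _derive_transition_modes(gene_states, config.stages)
    peak_ids = [p.id for p in peaks]
    peak_table = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "archetype": -1,
            "category": "",
        }
    )
    truth = TruthTables(
        gene_states=gene_states,
        transition_modes=transition_modes,
        peak_table=peak_table,
        motif_placements=pd.DataFrame(
            columns=["peak_id", "tf", "offset", "strand", "sequence"]
        ),
        ko_labels=pd.DataFrame(columns=["peak_id", "label"]),
    )
    genome = SimulatedGenome(
        sequences=sequences,
        chrom_sizes=chrom_sizes,
        annotation=annotation,
        peaks=peaks,
    )
    return genome, truth


def _assign_gene_states(
    config: SyntheticConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    stages = list(config.stages)
    states_list = list(config.initial_state_probs)
    init_p = np.array([config.initial_state_probs[s] for s in states_list])
    modes = list(config.mode_proportions)
    mode_p = np.array([config.mode_proportions[m] for m in modes])
    mode_to_state = {
        "stable_bivalent": "bivalent",
        "activated": "H3K4me3_only",
        "repressed": "H3K27me3_only",
        "resolved_unmarked": "unmarked",
    }
    rows = {}
    for gene_id in annotation["gene_id"]:
        if gene_id in config.forced_gene_states:
            rows[gene_id] = list(config.forced_gene_states[gene_id])
            continue
        state = states_list[rng.choice(len(states_list), p=init_p)]
        seq = [state]
        for _ in stages[1:]:
            if seq[-1] == "bivalent":
                mode = modes[rng.choice(len(modes), p=mode_p)]
                seq.append(mode_to_state[mode])
            else:
                seq.append(seq[-1])
        rows[gene_id] = seq
    df = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    df.index.name = "gene_id"
    return df


def _derive_transition_modes(
    gene_states: pd.DataFrame, stages: Sequence[str]
) -> pd.DataFrame:
    state_to_mode = {
        "bivalent": "stable_bivalent",
        "H3K4me3_only": "activated",
        "H3K27me3_only": "repressed",
        "unmarked": "resolved_unmarked",
    }
    rows = []
    for a, b in zip(stages[:-1], stages[1:]):
        biv = gene_states.index[gene_states[a] == "bivalent"]
        for gene_id in biv:
            rows.append((gene_id, f"{a}->{b}", state_to_mode[gene_states.loc[gene_id, b]]))
    return pd.DataFrame(rows, columns=["gene_id", "stage_pair", "mode"])


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------

def simulate_chip_tracks(
    genome: SimulatedGenome,
    truth: TruthTables,
    config: SyntheticConfig,
) -> Dict[str, Dict[str, SignalTrack]]:
    """Per-stage, per-mark binned Poisson count tracks.

    Bins inside the promoter window of a gene whose state carries the mark
    draw from Poisson(lambda_hi); all other bins draw Poisson(lambda_lo).
    Bivalent promoters are high in both mark tracks at the same bins.
    """
    rng = config.rng(_STREAM_CHIP)
    B = config.bin_size
    out: Dict[str, Dict[str, SignalTrack]] = {}
    ann = genome.annotation
    for stage in config.stages:
        out[stage] = {}
        state_of = truth.gene_states[stage]
        for mark, active_states in (("H3K4me3", _K4_STATES), ("H3K27me3", _K27_STATES)):
            data = {}
            for chrom, size in genome.chrom_sizes.items():
                n_bins = -(-size // B)
                rate = np.full(n_bins, config.lambda_lo)
                sub = ann[ann["chrom"] == chrom]
                for gene_id, tss in zip(sub["gene_id"], sub["tss"]):
                    if state_of[gene_id] in active_states:
                        b0 = max(0, (tss - config.flank) // B)
                        b1 = min(n_bins, -(-(tss + config.flank) // B))
                        rate[b0:b1] = config.lambda_hi
                data[chrom] = rng.poisson(rate).astype(float)
            out[stage][mark] = SignalTrack(data=data, bin_size=B)
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: TruthTables, config: SyntheticConfig
) -> pd.DataFrame:
    """Gene x stage negative-binomial counts with state-dependent means.

    ``nb_dispersion = inf`` gives the Poisson limit (variance = mean).
    """
    rng = config.rng(_STREAM_EXPR)
    means = truth.gene_states.apply(
        lambda col: col.map(config.nb_mean_by_state)
    ).to_numpy(dtype=float)
    r = config.nb_dispersion
    if np.isinf(r):
        counts = rng.poisson(means)
    else:
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    return pd.DataFrame(
        counts, index=truth.gene_states.index, columns=list(config.stages)
    )


# ---------------------------------------------------------------------------
# knockout contrast
# ---------------------------------------------------------------------------

def simulate_ko_counts(
    peak_ids: Sequence[str], config: SyntheticConfig
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """WT/KO Poisson count vectors plus planted labels for arbitrary peak ids.

    A random subset (ko_dependent_fraction) is attenuated ko_fold-fold in
    the KO; a disjoint subset (ko_independent_fraction) gains ko_fold-fold;
    the rest is unchanged.  ``ko_fold = 1`` labels everything unchanged.
    """
    rng = config.rng(_STREAM_KO)
    n = len(peak_ids)
    labels = np.full(n, "unchanged", dtype=object)
    if config.ko_fold != 1.0:
        n_dep = int(round(config.ko_dependent_fraction * n))
        n_ind = int(round(config.ko_independent_fraction * n))
        perm = rng.permutation(n)
        labels[perm[:n_dep]] = "dependent"
        labels[perm[n_dep : n_dep + n_ind]] = "independent"
    wt_mean = np.full(n, config.ko_wt_mean)
    ko_mean = wt_mean.copy()
    ko_mean[labels == "dependent"] /= config.ko_fold
    ko_mean[labels == "independent"] *= config.ko_fold
    wt = rng.poisson(wt_mean).astype(float)
    ko = rng.poisson(ko_mean).astype(float)
    label_df = pd.DataFrame({"peak_id": list(peak_ids), "label": labels})
    return wt, ko, label_df


def simulate_ko(
    truth: TruthTables, config: SyntheticConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Planted KO contrast over the truth table's peaks; labels are recorded
    in ``truth.ko_labels``."""
    wt, ko, labels = simulate_ko_counts(truth.peak_table["peak_id"], config)
    truth.ko_labels = labels
    return wt, ko


# ---------------------------------------------------------------------------
# motifs + accessibility
# ---------------------------------------------------------------------------

def tf_count_matrix(tf: str, width: int = 10) -> np.ndarray:
    """Deterministic synthetic position count matrix for a TF name.

    One dominant base per column (85 vs 5 counts), drawn from a stream
    seeded by crc32 of the name, so every TF gets a distinct, strongly
    informative motif that is stable across runs.
    """
    rng = np.random.default_rng([zlib.crc32(tf.encode()), width])
    counts = np.full((4, width), 5.0)
    dominant = rng.integers(0, 4, size=width)
    counts[dominant, np.arange(width)] = 85.0
    return counts


def _plant_motif(
    genome: SimulatedGenome,
    peak: GenomicInterval,
    tf: str,
    consensus: str,
    occupied: List[Tuple[int, int]],
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> Tuple[int, str, str] | None:
    W = len(consensus)
    lo = config.motif_margin
    hi = config.peak_width - W - config.motif_margin
    if hi < lo:
        raise ValueError(f"motif {tf!r} too wide for peak {peak.id}")
    for _ in range(50):
        off = int(rng.integers(lo, hi + 1))
        if all(off + W <= s or off >= e for s, e in occupied):
            break
    else:
        return None
    strand = "+" if rng.random() < 0.5 else "-"
    planted = consensus if strand == "+" else reverse_complement(consensus)
    codes = np.array([BASES.index(b) for b in planted], dtype=np.uint8)
    genome.sequences[peak.chrom][peak.start + off : peak.start + off + W] = codes
    occupied.append((off, off + W))
    return off, strand, planted


def simulate_atac(
    genome: SimulatedGenome,
    truth: TruthTables,
    config: SyntheticConfig,
) -> Dict[str, object]:
    """Accessibility layer: archetypes, motif planting, per-stage peak calls
    and cut-count records, peak sequences.

    Returns a dict with per-stage peak BED interval lists, per-stage
    bedGraph record DataFrames (binned promoter/background layer at
    ``bin_size`` resolution plus per-base cut counts inside peaks), peak
    sequences, and the PWM count matrices used.
    """
    rng_atac = config.rng(_STREAM_ATAC)
    rng_motif = config.rng(_STREAM_MOTIF)
    stages = list(config.stages)
    n_arch = len(config.archetype_profiles)
    peaks = genome.peaks

    # archetype assignment
    arch = rng_atac.integers(0, n_arch, size=len(peaks))
    truth.peak_table["archetype"] = arch
    truth.peak_table["category"] = [config.archetype_categories[a] for a in arch]

    # motif planting (category motifs; KO-conditional motif on top)
    pwm_counts = {
        tf: tf_count_matrix(tf, config.motif_width)
        for tf in list(config.motif_assignments) + [config.ko_motif_tf]
    }
    consensus = {
        tf: pwm_from_counts(tf, counts).consensus for tf, counts in pwm_counts.items()
    }
    ko_label_of = (
        truth.ko_labels.set_index("peak_id")["label"]
        if len(truth.ko_labels)
        else pd.Series(dtype=object)
    )
    placements = []
    for i, peak in enumerate(peaks):
        occupied: List[Tuple[int, int]] = []
        category = config.archetype_categories[arch[i]]
        for tf, cat in config.motif_assignments.items():
            if cat != category or rng_motif.random() >= config.motif_planting_rate:
                continue
            res = _plant_motif(genome, peak, tf, consensus[tf], occupied, rng_motif, config)
            if res is not None:
                placements.append((peak.id, tf, *res[:2], res[2]))
        ko_lab = ko_label_of.get(peak.id, "unchanged")
        rate = {
            "dependent": config.ko_dep_motif_rate,
            "independent": config.ko_indep_motif_rate,
        }.get(ko_lab, 0.0)
        if rate and rng_motif.random() < rate:
            res = _plant_motif(
                genome, peak, config.ko_motif_tf, consensus[config.ko_motif_tf],
                occupied, rng_motif, config,
            )
            if res is not None:
                placements.append((peak.id, config.ko_motif_tf, *res[:2], res[2]))
    truth.motif_placements = pd.DataFrame(
        placements, columns=["peak_id", "tf", "offset", "strand", "sequence"]
    )

    # per-stage peak presence + cut counts + promoter/background layer
    peak_beds: Dict[str, List[GenomicInterval]] = {}
    records: Dict[str, pd.DataFrame] = {}
    plc_by_peak = {
        pid: list(zip(sub["offset"], sub["tf"]))
        for pid, sub in truth.motif_placements.groupby("peak_id")
    }
    B = config.bin_size
    ann = genome.annotation
    for s_idx, stage in enumerate(stages):
        state_of = truth.gene_states[stage]
        # binned background + promoter accessibility
        frames = []
        for chrom, size in genome.chrom_sizes.items():
            n_bins = -(-size // B)
            rate = np.full(n_bins, config.atac_promoter_lo)
            sub = ann[ann["chrom"] == chrom]
            for gene_id, tss in zip(sub["gene_id"], sub["tss"]):
                if state_of[gene_id] in _OPEN_STATES:
                    b0 = max(0, (tss - config.flank) // B)
                    b1 = min(n_bins, -(-(tss + config.flank) // B))
                    rate[b0:b1] = config.atac_promoter_hi
            counts = rng_atac.poisson(rate)
            nz = np.flatnonzero(counts)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": nz * B,
                        "end": np.minimum((nz + 1) * B, size),
                        "value": counts[nz] / B,
                    }
                )
            )
        # per-base cut counts inside present peaks
        bed: List[GenomicInterval] = []
        for i, peak in enumerate(peaks):
            expected = config.peak_height * config.archetype_profiles[arch[i]][s_idx]
            if expected <= config.presence_threshold:
                continue
            bed.append(peak)
            rate = np.full(config.peak_width, expected / config.peak_width)
            for off, _tf in plc_by_peak.get(peak.id, []):
                rate[off : off + config.motif_width] *= config.footprint_dip
            cuts = rng_atac.poisson(rate)
            nz = np.flatnonzero(cuts)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": peak.chrom,
                        "start": peak.start + nz,
                        "end": peak.start + nz + 1,
                        "value": cuts[nz].astype(float),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        records[stage] = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )
        peak_beds[stage] = bed

    peak_sequences = {
        p.id: genome.sequence_str(p.chrom)[p.start : p.end] for p in peaks
    }
    return {
        "peak_beds": peak_beds,
        "atac_records": records,
        "peak_sequences": peak_sequences,
        "pwm_counts": pwm_counts,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SyntheticConfig
    genome: SimulatedGenome
    truth: TruthTables
    chip_tracks: Dict[str, Dict[str, SignalTrack]]
    expression: pd.DataFrame
    atac: Dict[str, object]
    wt_counts: np.ndarray
    ko_counts: np.ndarray
    paths: Dict[str, object] = field(default_factory=dict)


def _write_track_bedgraph(track: SignalTrack, path) -> None:
    """Binned counts -> bedGraph with value = count / bin_size, so that the
    per-base-sum binning rule recovers counts exactly."""
    B = track.bin_size
    frames = []
    for chrom, vec in track.data.items():
        nz = np.flatnonzero(vec)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": nz * B,
                    "end": (nz + 1) * B,
                    "value": vec[nz] / B,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )


def simulate_all(
    config: SyntheticConfig, outdir, write_genome_fasta: bool = True
) -> SimulationResult:
    """Run the full generator and write every artifact as plain text.

    Outputs: genome FASTA (optional), chrom.sizes TSV, annotation TSV,
    expression TSV, per-stage/mark ChIP bedGraphs, per-stage ATAC
    bedGraphs and peak BEDs, peak FASTA, PWM file, WT/KO count TSV, and a
    JSON truth file.  Byte-identical for a fixed config.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    from .intervals import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    wt, ko = simulate_ko(truth, config)
    atac = simulate_atac(genome, truth, config)
    chip = simulate_chip_tracks(genome, truth, config)
    expression = simulate_expression(truth, config)

    paths: Dict[str, object] = {}
    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = sizes_path

    ann_path = outdir / "annotation.tsv"
    genome.annotation.to_csv(ann_path, sep="\t", index=False)
    paths["annotation"] = ann_path

    expr_path = outdir / "expression.tsv"
    expression.to_csv(expr_path, sep="\t", index_label="gene_id")
    paths["expression"] = expr_path

    if write_genome_fasta:
        fasta_path = outdir / "genome.fa"
        genome.write_fasta(fasta_path)
        paths["genome_fasta"] = fasta_path

    paths["chip"] = {}
    for stage, marks in chip.items():
        for mark, track in marks.items():
            p = outdir / f"chip_{mark}_{stage}.bedGraph"
            _write_track_bedgraph(track, p)
            paths["chip"][(stage, mark)] = p

    paths["atac_bedgraph"] = {}
    paths["peak_bed"] = {}
    for stage in config.stages:
        p = outdir / f"atac_{stage}.bedGraph"
        atac["atac_records"][stage].to_csv(
            p, sep="\t", header=False, index=False, float_format="%.10g"
        )
        paths["atac_bedgraph"][stage] = p
        b = outdir / f"peaks_{stage}.bed"
        write_bed(atac["peak_beds"][stage], b)
        paths["peak_bed"][stage] = b

    peak_fa = outdir / "peaks.fa"
    seqio_write(
        [
            SeqRecord(Seq(seq), id=pid, description="")
            for pid, seq in atac["peak_sequences"].items()
        ],
        str(peak_fa),
        "fasta",
    )
    paths["peak_fasta"] = peak_fa

    pwm_path = outdir / "motifs.jaspar"
    write_jaspar(atac["pwm_counts"], pwm_path)
    paths["pwms"] = pwm_path

    ko_path = outdir / "ko_counts.tsv"
    pd.DataFrame(
        {
            "peak_id": truth.peak_table["peak_id"],
            "wt": wt,
            "ko": ko,
        }
    ).to_csv(ko_path, sep="\t", index=False)
    paths["ko_counts"] = ko_path

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path

    return SimulationResult(
        config=config,
        genome=genome,
        truth=truth,
        chip_tracks=chip,
        expression=expression,
        atac=atac,
        wt_counts=wt,
        ko_counts=ko,
        paths=paths,
    )
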
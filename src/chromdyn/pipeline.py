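"""End-to-end orchestration: simulate -> segment -> bivalency ->
accessibility clustering -> motif enrichment -> candidates -> footprints ->
KO classification, as one seeded run with a machine-readable report.

Every intermediate is written as a plain standard format (BED/TSV/JSON) so
each stage can be re-run independently from disk; re-running with an
identical config and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import bivalency as biv_mod
from . import hmm as hmm_mod
from . import ko as ko_mod
from . import motif as motif_mod
from .intervals import (
    GenomicInterval,
    bedgraph_coverage,
    bin_bedgraph,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_gene_annotation,
    write_bed,
)
from .simulate import SimulationResult, SyntheticConfig, simulate_all

__all__ = ["RunConfig", "validate_config", "run_all"]

MARKS = ("H3K4me3", "H3K27me3")


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig`) or ``inputs``
    (a mapping of input file paths) must be set.  All module parameters
    default to the values used throughout the package.
    """

    outdir: str
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    inputs: Optional[Dict[str, object]] = None
    stages: Tuple[str, ...] = ("hPSC", "VME", "EPC", "HPC")
    # chromstate
    bin_size: int = 200
    binarize_alpha: float = 1e-4
    n_states: int = 4
    hmm_restarts: int = 5
    hmm_tol: float = 1e-4
    hmm_max_iter: int = 200
    refit_per_stage: bool = False
    # bivalency
    flank: int = 2500
    min_bivalent_overlap: int = 200
    # atac dynamics
    merge_gap: int = 100
    min_rpkm: float = 5.0
    min_stages: int = 2
    min_cv: float = 0.10
    single_qnorm: bool = False
    n_clusters: int = 6
    fuzzifier: float = 1.25
    cluster_restarts: int = 10
    assign_categories: bool = True
    # motifs / footprints
    threshold_fraction: float = 0.8
    enrich_alpha: float = 0.05
    footprint_radius: int = 100
    # knockout
    ko_fold: float = 2.0
    ko_pseudocount: float = 0.5


_INPUT_KEYS = (
    "chrom_sizes",
    "annotation",
    "expression",
    "chip",
    "atac_bedgraph",
    "peak_bed",
    "peak_fasta",
    "pwms",
    "ko_counts",
)


def validate_config(raw) -> RunConfig:
    """Normalize a raw mapping (or RunConfig) into a validated RunConfig."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if isinstance(syn, Mapping):
            syn = SyntheticConfig(**syn)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = RunConfig(synthetic=syn, **raw)
    if (cfg.synthetic is None) == (cfg.inputs is None):
        raise ValueError("exactly one of synthetic config or input paths must be set")
    if cfg.synthetic is not None:
        cfg.stages = tuple(cfg.synthetic.stages)
        cfg.bin_size = cfg.synthetic.bin_size
    if cfg.inputs is not None:
        missing = [k for k in _INPUT_KEYS if k not in cfg.inputs]
        if missing:
            raise ValueError(f"missing input path key(s): {missing}")
        for key in ("chrom_sizes", "annotation", "expression", "peak_fasta", "pwms", "ko_counts"):
            if not Path(str(cfg.inputs[key])).exists():
                raise FileNotFoundError(f"input {key!r}: {cfg.inputs[key]} not found")
        for key in ("atac_bedgraph", "peak_bed"):
            for stage in cfg.stages:
                if stage not in cfg.inputs[key]:
                    raise ValueError(f"input {key!r} missing stage {stage!r}")
    if cfg.assign_categories and len(cfg.stages) != 4:
        raise ValueError(
            "category assignment (I/II/III) requires a 4-stage series; "
            "disable assign_categories for other designs"
        )
    return cfg


def _read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: RunConfig) -> dict:
    """Execute every module in dependency order; returns the run report.

    The report aggregates per-module summaries (transition ratios, cluster
    sizes, category map, enrichment tables, candidate list, KO fractions)
    and is also written to ``<outdir>/report.json``.
    """
    config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: List[str] = []
    report: dict = {
        "package": "chromdyn",
        "seed": config.seed,
        "stages": list(config.stages),
    }

    # ------------------------------------------------------------------ inputs
    if config.synthetic is not None:
        sim = simulate_all(config.synthetic, outdir / "sim")
        paths = sim.paths
        truth_available = True
    else:
        paths = dict(config.inputs)
        truth_available = False

    chrom_sizes = read_chrom_sizes(paths["chrom_sizes"])
    annotation = read_gene_annotation(paths["annotation"])
    expression = pd.read_csv(paths["expression"], sep="\t", index_col="gene_id")
    stages = list(config.stages)

    # --------------------------------------------------------------- chromstate
    binarized = {}
    for stage in stages:
        tracks = {
            mark: bin_bedgraph(paths["chip"][(stage, mark)], config.bin_size, chrom_sizes)
            for mark in MARKS
        }
        binarized[stage] = hmm_mod.binarize_poisson(tracks, alpha=config.binarize_alpha)
    model = hmm_mod.fit_hmm(
        binarized[stages[0]],
        n_states=config.n_states,
        seed=config.seed,
        n_restarts=config.hmm_restarts,
        tol=config.hmm_tol,
        max_iter=config.hmm_max_iter,
    )
    hmm_mod.save_model(model, outdir / "hmm_model.json")
    segmentations = {}
    for stage in stages:
        m = model
        if config.refit_per_stage and stage != stages[0]:
            m = hmm_mod.fit_hmm(
                binarized[stage],
                n_states=config.n_states,
                seed=config.seed,
                n_restarts=config.hmm_restarts,
                tol=config.hmm_tol,
                max_iter=config.hmm_max_iter,
            )
        seg = hmm_mod.segment_genome(binarized[stage], m)
        seg.to_bed(outdir / f"segments_{stage}.bed")
        segmentations[stage] = seg
    report["hmm"] = {
        "log_likelihood": model.log_likelihood_,
        "emissionprob": model.emissionprob_.tolist(),
        "state_labels": {
            str(k): v
            for k, v in hmm_mod.label_states(model, binarized[stages[0]].marks).items()
        },
    }

    # ---------------------------------------------------------------- bivalency
    calls = {}
    for stage in stages:
        c = biv_mod.call_promoter_state(
            segmentations[stage],
            annotation,
            chrom_sizes,
            flank=config.flank,
            min_bivalent_overlap=config.min_bivalent_overlap,
        )
        c.to_csv(outdir / f"promoter_calls_{stage}.tsv", sep="\t", index=False)
        calls[stage] = c
    transitions = []
    summaries = []
    for a, b in zip(stages[:-1], stages[1:]):
        rec, summ = biv_mod.classify_bivalent_transitions(calls[a], calls[b], (a, b))
        transitions.append(rec)
        summaries.append(summ)
    pd.concat(transitions, ignore_index=True).to_csv(
        outdir / "bivalent_transitions.tsv", sep="\t", index=False
    )
    activated = biv_mod.activated_gene_sets(calls, stages)
    report["bivalency"] = {
        "transition_summaries": [s.to_dict() for s in summaries],
        "n_activated_per_pair": {
            f"{a}->{b}": len(v) for (a, b), v in activated.items()
        },
    }

    # Fig-1e style promoter correlation (expression, marks, accessibility)
    tracks_by_stage = {}
    for stage in stages:
        tracks_by_stage[stage] = {
            mark: bin_bedgraph(paths["chip"][(stage, mark)], config.bin_size, chrom_sizes)
            for mark in MARKS
        }
        tracks_by_stage[stage]["ATAC"] = bin_bedgraph(
            paths["atac_bedgraph"][stage], config.bin_size, chrom_sizes
        )
    corr = biv_mod.promoter_signal_correlation(
        expression, tracks_by_stage, annotation, chrom_sizes, flank=config.flank
    )
    report["promoter_correlation"] = {
        stage: df.round(6).to_dict() for stage, df in corr.items()
    }

    # ------------------------------------------------------------ atac dynamics
    per_stage_peaks = [read_bed(paths["peak_bed"][stage]) for stage in stages]
    consensus = atac_mod.consensus_union(per_stage_peaks, gap=config.merge_gap)
    write_bed(consensus, outdir / "consensus_peaks.bed")
    peak_ids = [p.id for p in consensus]
    atac_records = {stage: read_bedgraph(paths["atac_bedgraph"][stage]) for stage in stages}
    counts = pd.DataFrame(
        {
            stage: bedgraph_coverage(atac_records[stage], consensus)
            for stage in stages
        },
        index=peak_ids,
    )
    counts.to_csv(outdir / "peak_counts.tsv", sep="\t", index_label="peak_id")
    library_sizes = {
        stage: float(
            (
                atac_records[stage]["value"]
                * (atac_records[stage]["end"] - atac_records[stage]["start"])
            ).sum()
        )
        for stage in stages
    }
    rpkm_mat = atac_mod.rpkm(counts, [len(p) for p in consensus], library_sizes)
    rpkm_mat.to_csv(outdir / "peak_rpkm.tsv", sep="\t", index_label="peak_id")

    # filter/normalization chain:
    # presence -> qnorm -> CV -> (qnorm again unless --single-qnorm) -> z-score
    present = rpkm_mat.loc[atac_mod.presence_mask(rpkm_mat, config.min_rpkm, config.min_stages)]
    qn = atac_mod.quantile_normalize(present)
    dynamic = qn.loc[atac_mod.cv_mask(qn, config.min_cv)]
    if not config.single_qnorm:
        dynamic = atac_mod.quantile_normalize(dynamic)
    zmat = atac_mod.zscore_rows(dynamic)
    zmat.to_csv(outdir / "peak_zscore.tsv", sep="\t", index_label="peak_id")

    fcm = atac_mod.fuzzy_cmeans(
        zmat,
        c=config.n_clusters,
        m=config.fuzzifier,
        seed=config.seed,
        n_restarts=config.cluster_restarts,
    )
    membership = pd.DataFrame(
        fcm.membership_,
        index=zmat.index,
        columns=[f"cluster{k + 1}" for k in range(config.n_clusters)],
    )
    membership["hard"] = fcm.labels_
    membership.to_csv(outdir / "cluster_membership.tsv", sep="\t", index_label="peak_id")
    cluster_sizes = {
        f"cluster{k + 1}": int((fcm.labels_ == k).sum()) for k in range(config.n_clusters)
    }
    report["clustering"] = {
        "objective": fcm.objective_,
        "cluster_sizes": cluster_sizes,
        "centroids": {
            f"cluster{k + 1}": [round(v, 6) for v in fcm.cluster_centers_[k]]
            for k in range(config.n_clusters)
        },
    }

    category_of_cluster: Dict[int, str] = {}
    if config.assign_categories:
        category_of_cluster = atac_mod.assign_categories(fcm.cluster_centers_)
        report["clustering"]["categories"] = {
            f"cluster{k + 1}": v for k, v in category_of_cluster.items()
        }
    zindex = list(zmat.index)
    category_of_peak = {
        pid: category_of_cluster.get(lab, "")
        for pid, lab in zip(zindex, fcm.labels_)
    }

    cluster_expr, _nearest = atac_mod.nearest_gene_expression(
        [consensus[peak_ids.index(pid)] for pid in zindex],
        annotation,
        expression,
        fcm.labels_,
        n_clusters=config.n_clusters,
    )
    cluster_expr.to_csv(outdir / "cluster_expression.tsv", sep="\t", index_label="cluster")

    # ----------------------------------------------------------------- motifs
    pwms = motif_mod.read_jaspar(paths["pwms"])
    peak_seqs = _read_fasta(paths["peak_fasta"])
    occurrences = motif_mod.scan_all(peak_seqs, pwms, config.threshold_fraction)
    occurrences.to_csv(outdir / "motif_occurrences.tsv", sep="\t", index=False)

    enrichment_by_category: Dict[str, pd.DataFrame] = {}
    if config.assign_categories:
        for cat in atac_mod.CATEGORIES:
            fg = [pid for pid in zindex if category_of_peak[pid] == cat]
            bg = [pid for pid in peak_ids if pid not in set(fg)]
            if not fg:
                warnings_log.append(f"category {cat} has no peaks; enrichment skipped")
                continue
            enr = motif_mod.motif_enrichment(occurrences, fg, bg)
            enr.to_csv(outdir / f"enrichment_category_{cat}.tsv", sep="\t", index=False)
            enrichment_by_category[cat] = enr
        report["enrichment"] = {
            cat: enr.round(10).to_dict(orient="records")
            for cat, enr in enrichment_by_category.items()
        }

        activated_union = sorted(set().union(*activated.values())) if activated else []
        candidates = motif_mod.candidate_regulators(
            enrichment_by_category,
            set(activated_union),
            categories=("II", "III"),
            alpha=config.enrich_alpha,
        )
        candidates.to_csv(outdir / "candidate_regulators.tsv", sep="\t", index=False)
        report["candidates"] = candidates["tf"].tolist()

    # -------------------------------------------------------------- footprints
    width_of = {p.name: p.width for p in pwms}
    footprint_rows = []
    for stage in stages:
        track = bin_bedgraph(atac_records[stage], 1, chrom_sizes)
        for p in pwms:
            occ = occurrences[occurrences["tf"] == p.name]
            if not len(occ):
                continue
            lifted = motif_mod.lift_occurrences(occ, p.width)
            prof = motif_mod.footprint_profile(
                track,
                lifted,
                width=p.width,
                radius=config.footprint_radius,
                tf_name=p.name,
                stage=stage,
            )
            depth = motif_mod.footprint_depth(prof) if prof.n_sites else float("nan")
            footprint_rows.append(
                (p.name, stage, prof.n_sites, prof.n_skipped, depth)
            )
        del track
    footprints = pd.DataFrame(
        footprint_rows, columns=["tf", "stage", "n_sites", "n_skipped", "depth"]
    )
    footprints.to_csv(outdir / "footprint_depths.tsv", sep="\t", index=False)
    report["footprints"] = footprints.round(6).to_dict(orient="records")

    # ---------------------------------------------------------------- knockout
    ko_df = pd.read_csv(paths["ko_counts"], sep="\t")
    classification = ko_mod.classify_ko_peaks(
        ko_df["wt"],
        ko_df["ko"],
        fold=config.ko_fold,
        pseudocount=config.ko_pseudocount,
        peak_ids=ko_df["peak_id"].tolist(),
    )
    pd.DataFrame(
        {
            "peak_id": ko_df["peak_id"],
            "label": classification.labels,
            "fold_change": classification.fold_changes,
        }
    ).to_csv(outdir / "ko_labels.tsv", sep="\t", index=False)
    summary = ko_mod.fraction_summary(classification)
    report["ko"] = summary
    try:
        dep_enr = ko_mod.dependent_vs_independent_enrichment(classification, occurrences)
        dep_enr.to_csv(outdir / "ko_dependent_enrichment.tsv", sep="\t", index=False)
        report["ko"]["dependent_vs_independent"] = dep_enr.round(10).to_dict(
            orient="records"
        )
    except ValueError as exc:
        warnings_log.append(f"KO enrichment skipped: {exc}")

    report["warnings"] = warnings_log
    if truth_available:
        try:
            report["truth_file"] = str(Path(paths["truth"]).relative_to(outdir))
        except ValueError:
            report["truth_file"] = str(paths["truth"])
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
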
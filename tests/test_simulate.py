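import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from chromdyn.simulate import (
    SyntheticConfig,
    simulate_all,
    simulate_chip_tracks,
    simulate_expression,
    simulate_genome,
    simulate_ko,
    simulate_ko_counts,
)


def small_config(**overrides):
    base = dict(
        seed=3,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=40,
        n_intergenic_peaks=120,
        gene_spacing=12_000,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestGenome:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        r1 = simulate_all(cfg, tmp_path / "a", write_genome_fasta=True)
        r2 = simulate_all(cfg, tmp_path / "b", write_genome_fasta=True)
        for key in ("truth", "annotation", "expression", "peak_fasta", "genome_fasta"):
            assert filecmp.cmp(r1.paths[key], r2.paths[key], shallow=False), key
        assert filecmp.cmp(
            r1.paths["chip"][("hPSC", "H3K4me3")],
            r2.paths["chip"][("hPSC", "H3K4me3")],
            shallow=False,
        )

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(small_config(n_genes=200))

    def test_base_composition_near_uniform(self):
        cfg = SyntheticConfig(
            seed=0, n_chroms=1, chrom_length=1_000_000, n_genes=4,
            n_intergenic_peaks=4, gene_spacing=12_000,
        )
        genome, _ = simulate_genome(cfg)
        freqs = np.bincount(genome.sequences["chr1"], minlength=4) / 1e6
        # binomial concentration: each base 0.25 +/- 0.01 at 1 Mb
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_promoter_windows_disjoint(self):
        genome, _ = simulate_genome(small_config())
        ann = genome.annotation
        for chrom, sub in ann.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            assert (np.diff(tss) >= 2 * 2500).all()


class TestChipTracks:
    def test_background_zero_when_lambda_lo_zero(self):
        cfg = small_config(lambda_lo=0.0, lambda_hi=10.0)
        genome, truth = simulate_genome(cfg)
        tracks = simulate_chip_tracks(genome, truth, cfg)
        track = tracks["hPSC"]["H3K4me3"]
        B = cfg.bin_size
        promoter_bins = set()
        for _, row in genome.annotation.iterrows():
            state = truth.gene_states.loc[row.gene_id, "hPSC"]
            if state in {"H3K4me3_only", "bivalent"}:
                for b in range((row.tss - 2500) // B, -(-(row.tss + 2500) // B)):
                    promoter_bins.add((row.chrom, b))
        for chrom, vec in track.data.items():
            outside = [
                v for b, v in enumerate(vec) if (chrom, b) not in promoter_bins
            ]
            assert sum(outside) == 0

    def test_marked_bin_mean_matches_rate(self):
        cfg = small_config(seed=5)
        genome, truth = simulate_genome(cfg)
        tracks = simulate_chip_tracks(genome, truth, cfg)
        vals = []
        B = cfg.bin_size
        for _, row in genome.annotation.iterrows():
            if truth.gene_states.loc[row.gene_id, "hPSC"] in {"H3K4me3_only", "bivalent"}:
                vec = tracks["hPSC"]["H3K4me3"].data[row.chrom]
                vals.extend(vec[(row.tss - 2500) // B : (row.tss + 2500) // B])
        vals = np.asarray(vals)
        se = np.sqrt(cfg.lambda_hi / len(vals))
        assert abs(vals.mean() - cfg.lambda_hi) <= 3 * se

    def test_bivalent_promoter_high_in_both_marks(self):
        cfg = small_config(seed=6)
        genome, truth = simulate_genome(cfg)
        tracks = simulate_chip_tracks(genome, truth, cfg)
        biv = truth.gene_states.index[truth.gene_states["hPSC"] == "bivalent"][0]
        row = genome.annotation.set_index("gene_id").loc[biv]
        B = cfg.bin_size
        sl = slice((row.tss - 2500) // B, (row.tss + 2500) // B)
        for mark in ("H3K4me3", "H3K27me3"):
            mean = tracks["hPSC"][mark].data[row.chrom][sl].mean()
            assert mean > (cfg.lambda_lo + cfg.lambda_hi) / 2


class TestAtacLayer:
    def test_planted_motifs_verbatim_in_peak_fasta(self, tmp_path):
        from Bio import SeqIO

        res = simulate_all(small_config(), tmp_path / "sim", write_genome_fasta=False)
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(res.paths["peak_fasta"]), "fasta")}
        placements = res.truth.motif_placements
        assert len(placements) > 10
        for _, row in placements.iterrows():
            found = seqs[row.peak_id][row.offset : row.offset + len(row.sequence)]
            assert found == row.sequence

    def test_archetype_thresholds_presence(self, tmp_path):
        res = simulate_all(small_config(), tmp_path / "sim", write_genome_fasta=False)
        cfg = res.config
        present_ids = {
            stage: {p.id for p in res.atac["peak_beds"][stage]} for stage in cfg.stages
        }
        for _, row in res.truth.peak_table.iterrows():
            profile = cfg.archetype_profiles[row.archetype]
            for stage, value in zip(cfg.stages, profile):
                expected = cfg.peak_height * value
                assert (row.peak_id in present_ids[stage]) == (
                    expected > cfg.presence_threshold
                )

    def test_category_planting_rate_binomial(self, tmp_path):
        cfg = small_config(n_intergenic_peaks=300, n_genes=10, seed=9)
        res = simulate_all(cfg, tmp_path / "sim", write_genome_fasta=False)
        # JUNB is assigned to category II: planted in category-II peaks at
        # the configured rate, up to binomial noise
        cat2 = res.truth.peak_table[res.truth.peak_table["category"] == "II"]
        junb_peaks = set(
            res.truth.motif_placements.loc[
                res.truth.motif_placements["tf"] == "JUNB", "peak_id"
            ]
        )
        n = len(cat2)
        rate = len(junb_peaks & set(cat2["peak_id"])) / n
        p = cfg.motif_planting_rate
        assert abs(rate - p) <= 3 * np.sqrt(p * (1 - p) / n)
        # and never planted outside its category
        assert junb_peaks <= set(cat2["peak_id"])


class TestExpression:
    def test_same_seed_identical(self):
        cfg = small_config()
        _, truth = simulate_genome(cfg)
        a = simulate_expression(truth, cfg)
        b = simulate_expression(truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_poisson_limit_variance(self):
        cfg = small_config(nb_dispersion=np.inf, n_genes=40)
        _, truth = simulate_genome(cfg)
        expr = simulate_expression(truth, cfg)
        active = truth.gene_states["hPSC"] == "H3K4me3_only"
        vals = expr.loc[active.to_numpy(), "hPSC"].to_numpy(dtype=float)
        ratio = vals.var() / vals.mean()
        assert 0.5 < ratio < 2.0  # variance ~ mean in the Poisson limit

    def test_activated_gene_expression_rises(self):
        cfg = small_config()
        _, truth = simulate_genome(cfg)
        expr = simulate_expression(truth, cfg)
        act = truth.transition_modes.query("mode == 'activated'")
        assert len(act) > 0
        gene = act.iloc[0]["gene_id"]
        later = act.iloc[0]["stage_pair"].split("->")[1]
        means = cfg.nb_mean_by_state
        st = truth.gene_states.loc[gene]
        assert means[st[later]] > means[st[act.iloc[0]["stage_pair"].split("->")[0]]]


class TestKO:
    def test_identity_fold_all_unchanged(self):
        cfg = small_config(ko_fold=1.0)
        _, truth = simulate_genome(cfg)
        simulate_ko(truth, cfg)
        assert (truth.ko_labels["label"] == "unchanged").all()

    def test_planted_fraction_exact_in_truth(self):
        cfg = SyntheticConfig(seed=0, ko_dependent_fraction=0.341)
        ids = [f"p{i}" for i in range(10_000)]
        _, _, labels = simulate_ko_counts(ids, cfg)
        assert (labels["label"] == "dependent").sum() == round(0.341 * 10_000)

    def test_dependent_independent_disjoint(self):
        cfg = small_config()
        ids = [f"p{i}" for i in range(500)]
        _, _, labels = simulate_ko_counts(ids, cfg)
        dep = set(labels.loc[labels["label"] == "dependent", "peak_id"])
        ind = set(labels.loc[labels["label"] == "independent", "peak_id"])
        assert not (dep & ind)

    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError):
            small_config(ko_dependent_fraction=0.7, ko_independent_fraction=0.4)
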
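"""Simulator: construction, WGD bookkeeping, determinism, conservation,
deletion bias and the emitted dating signal."""

import filecmp
import math

import numpy as np
import pytest

from paleograss.simulate import (
    ConfigurationError,
    SimulationConfig,
    build_ancestor,
    emit_dataset,
    simulate,
    tree_divergences,
)

SMALL = dict(n_proto=3, genes_per_chrom=40)


class TestAncestor:
    def test_counts_forced_by_construction(self):
        g = build_ancestor(SimulationConfig(n_proto=7, genes_per_chrom=100))
        assert len(g.chromosomes) == 7
        assert g.n_genes() == 700

    def test_degenerate_single_gene(self):
        g = build_ancestor(SimulationConfig(n_proto=1, genes_per_chrom=1))
        assert g.n_genes() == 1
        assert g.chromosomes[0].centromeres[0].functional

    def test_paper_scale_protogene_count(self):
        g = build_ancestor(SimulationConfig(n_proto=7, genes_per_chrom=2352))
        assert g.n_genes() == 16_464

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            build_ancestor(SimulationConfig(n_proto=0))
        with pytest.raises(ConfigurationError):
            SimulationConfig(p_del_D=0.5, p_del_S=0.1).validate()

    def test_uniform_grid_layout(self):
        cfg = SimulationConfig(n_proto=1, genes_per_chrom=5)
        g = build_ancestor(cfg)
        starts = [gene.start for gene in g.genes()]
        assert starts == [i * cfg.gene_spacing for i in range(5)]


class TestWgdAndTruth:
    def test_wgd_doubles_chromosomes_and_registers_pairs(self, small_sim):
        truth = small_sim.truth
        wgd = [e for e in truth.events if e.kind == "WGD" and e.operands.get("shared")]
        assert len(wgd) == 1
        # every surviving non-maize genome pair appears exactly once per genome
        per_genome = {}
        for rec in truth.true_pairs:
            if rec["wgd"] != "shared":
                continue
            key = (rec["genome"], rec["orig_d"], rec["orig_s"])
            assert key not in per_genome
            per_genome[key] = rec

    def test_ds_split_is_half_and_half(self, small_sim):
        labels = list(small_sim.truth.ds_assignment.values())
        assert labels.count("D") == labels.count("S") == 3

    def test_two_wgds_give_four_copies(self):
        cfg = SimulationConfig(
            **SMALL,
            seed=3,
            p_del_D=0.0,
            p_del_S=0.0,
            p_shuffle=0.0,
            inversion_rate=0.0,
            tandem_rate=0.0,
            pav_rate=0.0,
            fusion_plan={},
        )
        sim = simulate(cfg)
        meta = sim.truth.gene_meta
        maize = sim.genomes["maize"]
        per_proto = {}
        for gene in maize.genes():
            per_proto.setdefault(meta[gene.id]["protogene"], []).append(gene.id)
        assert all(len(v) == 4 for v in per_proto.values())

    def test_zero_rates_identity(self):
        cfg = SimulationConfig(
            **SMALL,
            seed=5,
            p_del_D=0.0,
            p_del_S=0.0,
            p_shuffle=0.0,
            inversion_rate=0.0,
            tandem_rate=0.0,
            pav_rate=0.0,
            fusion_plan={},
            wgd_times=(("root", 60.0),),
        )
        sim = simulate(cfg)
        for name, genome in sim.genomes.items():
            assert genome.n_genes() == 2 * 3 * 40  # post-WGD ancestor untouched
            assert all(rec["status"] == "retained" for rec in sim.truth.true_pairs)

    def test_conservation_survivors_plus_deletions(self):
        cfg = SimulationConfig(**SMALL, seed=11, tandem_rate=0.0, fusion_plan={}, wgd_times=(("root", 60.0),))
        sim = simulate(cfg)
        deleted_by_lineage = {}
        for e in sim.truth.events:
            if e.kind in ("deletion", "segmental_deletion"):
                deleted_by_lineage.setdefault(e.lineage, []).extend(e.operands["genes"])
        paths = {
            "rice": ["root", "bep", "rice"],
            "brachypodium": ["root", "bep", "brachypodium"],
            "sorghum": ["root", "paccad", "sorghum"],
            "maize": ["root", "paccad", "maize"],
        }
        for leaf, genome in sim.genomes.items():
            survivors = sum(1 for g in genome.genes())
            deleted = sum(len(deleted_by_lineage.get(l, [])) for l in paths[leaf])
            assert survivors + deleted == 2 * 3 * 40

    def test_repeated_wgd_rejected(self):
        cfg = SimulationConfig(**SMALL, seed=1, wgd_times=(("root", 60.0), ("root", 60.0)))
        with pytest.raises(ConfigurationError):
            simulate(cfg)


class TestDeterminismAndBias:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(**SMALL, seed=23)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = emit_dataset(simulate(cfg), d1)
        m2 = emit_dataset(simulate(cfg), d2)
        for key in m1:
            f1, f2 = m1[key], m2[key]
            assert filecmp.cmp(f1, f2, shallow=False), f"{key} differs between runs"

    def test_different_seed_changes_output(self, tmp_path):
        a = simulate(SimulationConfig(**SMALL, seed=1))
        b = simulate(SimulationConfig(**SMALL, seed=2))
        assert a.genomes["rice"].n_genes() != b.genomes["rice"].n_genes() or [
            g.id for g in a.genomes["rice"].genes()
        ] != [g.id for g in b.genomes["rice"].genes()]

    def test_bias_monotone_in_sensitive_rate(self):
        # raising p_del_S lowers mean S retention (Monte-Carlo over 20 reps)
        def s_retention(p_del_s, seeds):
            vals = []
            for seed in seeds:
                cfg = SimulationConfig(
                    n_proto=2, genes_per_chrom=30, seed=seed, p_del_S=p_del_s,
                    tandem_rate=0.0, pav_rate=0.0, fusion_plan={},
                )
                sim = simulate(cfg)
                alive = dead = 0
                for rec in sim.truth.true_pairs:
                    if rec["wgd"] != "shared" or rec["genome"] == "maize":
                        continue
                    alive += rec["gene_s"] is not None
                    dead += rec["gene_s"] is None
                vals.append(alive / (alive + dead))
            return float(np.mean(vals))

        seeds = range(20)
        assert s_retention(0.004, seeds) < s_retention(0.0016, seeds)


class TestEmittedSignal:
    def test_ks_table_mean_matches_clock(self, small_sim, tmp_path):
        manifest = emit_dataset(small_sim, tmp_path)
        import pandas as pd

        tbl = pd.read_csv(manifest["ks_table"], sep="\t")
        shared = tbl[(tbl["true_age_mya"] == 60.0)]
        assert len(shared) >= 100
        expect = 2 * small_sim.config.ks_rate * 60e6
        se = shared["ks"].std() / math.sqrt(len(shared))
        assert abs(shared["ks"].mean() - expect) < 3 * se + expect * 0.005

    def test_age_zero_pair_identity(self, small_sim, tmp_path):
        # emitted identity decreases with age; recent pairs are near-identical
        manifest = emit_dataset(small_sim, tmp_path)
        import pandas as pd

        from paleograss.io import BLAST6_COLUMNS

        blast = pd.read_csv(manifest["blast"], sep="\t", names=BLAST6_COLUMNS)
        joined = blast.merge(
            pd.read_csv(manifest["ks_table"], sep="\t"),
            left_on=["qseqid", "sseqid"],
            right_on=["gene1", "gene2"],
        )
        old = joined[joined.true_age_mya == 60.0]["pident"].mean()
        young = joined[joined.true_age_mya < 10.0]["pident"].mean()
        assert young > old

    def test_sequences_mode_realized_ks(self, tmp_path):
        from Bio import SeqIO

        from paleograss.dating import estimate_ks

        cfg = SimulationConfig(n_proto=3, genes_per_chrom=60, seed=31, track_sequences=True)
        sim = simulate(cfg)
        manifest = emit_dataset(sim, tmp_path, mode="sequences")
        seqs = {}
        for leaf in sim.genomes:
            for rec in SeqIO.parse(manifest[f"fasta:{leaf}"], "fasta"):
                seqs[rec.id] = str(rec.seq)
        meta = sim.truth.gene_meta
        ks_vals = []
        for rec in sim.truth.true_pairs:
            if rec["wgd"] != "shared" or rec["status"] == "deleted" or rec["genome"] == "maize":
                continue
            s1, s2 = seqs.get(rec["gene_d"]), seqs.get(rec["gene_s"])
            if s1 and s2:
                ks = estimate_ks(s1, s2)
                if math.isfinite(ks):
                    ks_vals.append(ks)
        assert len(ks_vals) >= 400
        expect = 2 * cfg.ks_rate * 60e6  # Ks = 2 r T
        se = float(np.std(ks_vals) / math.sqrt(len(ks_vals)))
        assert abs(float(np.mean(ks_vals)) - expect) < 3 * se + 0.006

    def test_round_trip_counts(self, small_sim, tmp_path):
        from paleograss.io import load_genome

        manifest = emit_dataset(small_sim, tmp_path)
        for leaf, genome in small_sim.genomes.items():
            tbl = load_genome(manifest[f"gff3:{leaf}"])
            assert len(tbl) == genome.n_genes()

    def test_cluster_transposition_sizes(self):
        cfg = SimulationConfig(
            n_proto=2,
            genes_per_chrom=60,
            seed=41,
            p_shuffle=0.01,
            cluster_size_dist={1: 0.0, 2: 0.0, 3: 1.0, 4: 0.0},
        )
        sim = simulate(cfg)
        sizes = [e.operands["size"] for e in sim.truth.events if e.kind == "transposition"]
        assert sizes and all(1 <= s <= 3 for s in sizes)
        assert max(sizes) == 3

    def test_divergence_table(self):
        div = tree_divergences("((rice:40,brachypodium:40)bep:10,(sorghum:40,maize:40)paccad:10)root;")
        assert div[("brachypodium", "rice")] == pytest.approx(40.0)
        assert div[("maize", "rice")] == pytest.approx(50.0)
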
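"""Retained/shuffled partition arithmetic, shuffled-gene clustering,
deletion chronology on the four-leaf species tree, and feature contrast."""

import pytest

from paleograss.duplicates import (
    ShuffledCluster,
    classify_chronology,
    classify_duplicates,
    cluster_shuffled,
    chronology_summary,
    feature_contrast,
    small_cluster_permil,
    summarize_partition,
)
from paleograss.synteny import Anchor, SyntenyBlock, assign_block_ancestry

CLADES = {"BEP": ["rice", "brachypodium"], "PACCAD": ["sorghum", "maize"]}
SPECIES = ["rice", "brachypodium", "sorghum", "maize"]


class TestPartitionSummary:
    @pytest.mark.parametrize(
        "genome,total,retained,shuffled,pct",
        [
            ("rice", 604, 427, 177, 29),
            ("brachypodium", 475, 355, 120, 25),
            ("sorghum", 410, 245, 165, 40),
            ("maize", 647, 247, 400, 62),
        ],
    )
    def test_printed_percentages(self, genome, total, retained, shuffled, pct):
        s = summarize_partition(genome, total, retained)
        assert s.shuffled == shuffled
        assert s.shuffled_pct == pct
        assert s.retained + s.shuffled == s.total  # row-sum identity

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            summarize_partition("x", 10, 11)


def _paralogon_map():
    """One recognised paralogon on genome G: a1[0..100k] ~ a2[0..100k]."""
    anchors = [
        Anchor(f"p{i}", f"q{i}", "a1", i * 20_000, "a2", i * 20_000, "G", "G", "paralog")
        for i in range(6)
    ]
    return assign_block_ancestry([SyntenyBlock(anchors, "same", "paralog")])


class TestClassify:
    def test_retained_vs_shuffled_by_position(self):
        amap = _paralogon_map()
        positions = {
            "x1": ("G", "a1", 50_000),
            "x2": ("G", "a2", 60_000),
            "y1": ("G", "a1", 50_000),
            "y2": ("G", "a9", 1_000_000),  # moved to a nonsyntenic chromosome
        }
        calls, summaries = classify_duplicates(
            [("x1", "x2", "G"), ("y1", "y2", "G")], amap, positions
        )
        status = {(c.gene_a, c.gene_b): c.status for c in calls}
        assert status[("x1", "x2")] == "retained"
        assert status[("y1", "y2")] == "shuffled"
        assert summaries[0].total == 2 and summaries[0].retained == 1

    def test_unannotated_gene_skipped(self):
        amap = _paralogon_map()
        calls, _ = classify_duplicates([("nope", "x", "G")], amap, {})
        assert calls == []

    def test_zero_shuffling_means_all_retained(self):
        amap = _paralogon_map()
        positions = {f"g{i}": ("G", "a1" if i % 2 else "a2", 40_000) for i in range(8)}
        pairs = [(f"g{i}", f"g{i+1}", "G") for i in range(0, 8, 2)]
        calls, summaries = classify_duplicates(pairs, amap, positions)
        assert summaries[0].retained_pct == 100


class TestClusters:
    def test_small_cluster_rate(self):
        assert small_cluster_permil(10, 824) == pytest.approx(12.135922, abs=1e-4)

    def test_far_apart_genes_stay_singletons(self):
        positions = {"s1": ("G", "c1", 0.0), "s2": ("G", "c1", 500_000.0)}
        order = {("G", "c1"): ["s1", "s2"]}
        clusters = cluster_shuffled(["s1", "s2"], positions, order)
        assert sorted(c.kind for c in clusters) == ["singleton", "singleton"]

    def test_nearby_genes_form_small_cluster(self):
        positions = {f"s{i}": ("G", "c1", i * 30_000.0) for i in range(3)}
        order = {("G", "c1"): [f"s{i}" for i in range(3)]}
        clusters = cluster_shuffled([f"s{i}" for i in range(3)], positions, order)
        assert len(clusters) == 1 and clusters[0].kind == "small"

    def test_intervening_gene_limit(self):
        # 5 non-shuffled genes between the two shuffled ones: not merged
        order = {("G", "c1"): [f"g{i}" for i in range(7)]}
        positions = {"g0": ("G", "c1", 0.0), "g6": ("G", "c1", 60_000.0)}
        clusters = cluster_shuffled(["g0", "g6"], positions, order, max_intervening=3)
        assert len(clusters) == 2

    def test_large_shared_flag_across_genomes(self):
        genes, positions, ogs = [], {}, {}
        order = {}
        for g in ("A", "B"):
            ids = [f"{g}_s{i}" for i in range(6)]
            genes += ids
            order[(g, "c1")] = ids
            for i, gid in enumerate(ids):
                positions[gid] = (g, "c1", i * 10_000.0)
                ogs[gid] = f"OG{i}"
        clusters = cluster_shuffled(genes, positions, order, orthogroup_of=ogs)
        assert all(c.kind == "large_shared" for c in clusters)


class TestChronology:
    def mk(self, absent):
        return {(1, "S"): {sp: sp not in absent for sp in SPECIES}}

    def test_absent_everywhere_is_ancestral(self):
        calls = classify_chronology(self.mk(set(SPECIES)), CLADES)
        assert calls[0].call == "ancestral"

    def test_paccad_lineage_loss(self):
        calls = classify_chronology(self.mk({"sorghum", "maize"}), CLADES)
        assert calls[0].call == "lineage_PACCAD"

    def test_single_species_loss(self):
        calls = classify_chronology(self.mk({"maize"}), CLADES)
        assert calls[0].call == "species_specific(maize)"

    def test_cross_clade_pair_is_two_species_events(self):
        # Fitch parsimony on ((rice,brachy),(sorghum,maize)): losses in rice
        # and sorghum cannot be one clade event; minimum is two independent
        calls = classify_chronology(self.mk({"rice", "sorghum"}), CLADES)
        assert calls[0].events == ("species_rice", "species_sorghum")

    def test_clade_plus_one(self):
        calls = classify_chronology(self.mk({"rice", "brachypodium", "maize"}), CLADES)
        assert set(calls[0].events) == {"lineage_BEP", "species_maize"}

    def test_leaf_order_invariance(self):
        pres = {(1, "S"): {"maize": False, "rice": True, "sorghum": False, "brachypodium": True}}
        pres_rev = {(1, "S"): dict(reversed(list(pres[(1, "S")].items())))}
        a = classify_chronology(pres, CLADES)
        b = classify_chronology(pres_rev, CLADES)
        assert a == b

    def test_fully_retained_copy_produces_no_call(self):
        calls = classify_chronology(self.mk(set()), CLADES)
        assert calls == []

    def test_summary_percentages(self):
        pres = {}
        for i in range(10):
            pres[(i, "S")] = {sp: False for sp in SPECIES}  # ancestral
        for i in range(10, 15):
            pres[(i, "S")] = {sp: sp not in {"rice", "brachypodium"} for sp in SPECIES}
        summary = chronology_summary(classify_chronology(pres, CLADES))
        assert summary["ancestral"] == 67
        assert summary["lineage_BEP"] == 33

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classify_chronology({(1, "S"): {}}, CLADES)


class TestFeatureContrast:
    def test_identical_sets(self):
        rows = [(3000.0, 5.0)] * 10
        out = feature_contrast(rows, rows)
        assert out["p_length"] == 1.0
        assert out["retained"]["mean_length_bp"] == out["shuffled"]["mean_length_bp"]

    def test_report_shows_means_side_by_side(self):
        out = feature_contrast([(4728.0, 8.6)] * 5, [(2940.0, 4.6)] * 5)
        assert out["retained"]["mean_length_bp"] == pytest.approx(4728.0)
        assert out["shuffled"]["mean_exons"] == pytest.approx(4.6)

    def test_short_gene_bias_detected_in_simulation(self):
        from paleograss.simulate import SimulationConfig, simulate

        cfg = SimulationConfig(
            n_proto=2, genes_per_chrom=80, seed=17, p_shuffle=0.004, shuffle_prefers_short=True
        )
        sim = simulate(cfg)
        meta = sim.truth.gene_meta
        lengths = {"moved": [], "kept": []}
        for name, genome in sim.genomes.items():
            for gene in genome.genes():
                if meta[gene.id]["origin"] != "ancestral":
                    continue
                lengths["moved" if meta[gene.id]["moved"] else "kept"].append((gene.length, gene.exon_count))
        out = feature_contrast(lengths["kept"], lengths["moved"])
        assert out["shuffled"]["mean_length_bp"] < out["retained"]["mean_length_bp"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            feature_contrast([], [(1.0, 1.0)])
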
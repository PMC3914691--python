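"""End-to-end orchestration: homology -> dating -> synteny -> duplicates ->
dominance -> ancestor -> scenario, plus truth-based evaluation on
simulated datasets.

The pipeline consumes a dataset directory (per-genome GFF3, BLAST tabular
homology, a Ks table or codon FASTA) and a dated species tree, and writes
a report bundle: the duplicate partition summary, the dominance table,
compartment rates, CAR files, the scenario evaluation, and a run log of
every parameter actually used.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from . import io as pgio
from .ancestor import conserved_adjacencies, linearize_cars, preduplication_order
from .dating import DatingParams, InsufficientDataError, fit_ks_mixture, label_wgd_pairs
from .dominance import chi_square_dominance
from .duplicates import classify_duplicates, feature_contrast
from .homology import (
    CLOSE_POLICY,
    DISTANT_POLICY,
    FilterPolicy,
    compute_homology_metrics,
    filter_pairs,
    reciprocal_best_pairs,
)
from .scenario import build_event_ledger, load_fixture_scenarios, score_scenarios
from .simulate import DEFAULT_TREE, SimulationResult, tree_divergences, _parse_tree
from .synteny import AncestryMap, Anchor, ChainParams, assign_block_ancestry, chain_all


@dataclass
class PipelineConfig:
    dataset_dir: str
    out_dir: Optional[str] = None
    tree: str = DEFAULT_TREE
    close_policy: FilterPolicy = CLOSE_POLICY
    distant_policy: FilterPolicy = DISTANT_POLICY
    close_max_mya: float = 50.0
    chain: ChainParams = field(default_factory=ChainParams)
    dating: DatingParams = field(default_factory=DatingParams)
    alpha: float = 0.05
    mixture_k_range: tuple = (1, 2, 3)
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    genes: dict  # genome -> gene table (DataFrame)
    positions: dict  # gene id -> (genome, chrom, midpoint)
    ortholog_pairs: set
    paralog_pairs: list  # (gene_a, gene_b, genome, ks, label)
    blocks: list
    ancestry: AncestryMap
    calls: list
    summaries: list
    dominance: list
    mixtures: dict
    orthogroups: dict  # gene id -> orthogroup id
    orders: dict  # genome -> chrom -> restricted orthogroup order
    postdup_cars: list
    pre_cars: list
    car_pairing: list
    scenario_ranking: list
    ledger: Optional[object]
    log: dict


def _clades(tree_str: str) -> dict[str, list[str]]:
    tree = _parse_tree(tree_str)
    out = {}
    for child in tree.root.clades:
        leaves = [lf.name for lf in child.get_terminals()]
        out[child.name or "+".join(leaves)] = leaves
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    ddir = Path(config.dataset_dir)
    log: dict = {"config": {
        "tree": config.tree,
        "close_policy": asdict(config.close_policy),
        "distant_policy": asdict(config.distant_policy),
        "chain": asdict(config.chain),
        "dating": asdict(config.dating),
        "alpha": config.alpha,
        "seed": config.seed,
    }}

    # ---- load gene models -------------------------------------------------
    genes: dict[str, pd.DataFrame] = {}
    for gff in sorted(ddir.glob("*.gff3")):
        genes[gff.stem] = pgio.load_genome(gff)
    if not genes:
        raise FileNotFoundError(f"no *.gff3 gene models under {ddir}")
    genomes = sorted(genes)
    genome_of: dict[str, str] = {}
    positions: dict[str, tuple[str, str, float]] = {}
    cds_len: dict[str, int] = {}
    features: dict[str, tuple[float, float]] = {}
    order_by_chrom: dict[tuple[str, str], list[str]] = {}
    strand: dict[str, int] = {}
    for gname, tbl in genes.items():
        for row in tbl.itertuples(index=False):
            genome_of[row.gene] = gname
            positions[row.gene] = (gname, row.chrom, 0.5 * (row.start + row.end))
            cds_len[row.gene] = int(row.cds_length)
            features[row.gene] = (float(row.length), float(row.exons))
            strand[row.gene] = int(row.strand)
            order_by_chrom.setdefault((gname, row.chrom), []).append(row.gene)

    # ---- homology ---------------------------------------------------------
    hsps = pgio.load_hsps(ddir / "homology.blast.tsv")
    metrics = []
    for (q, s), group in sorted(hsps.items()):
        if q not in cds_len:
            continue
        metrics.append(compute_homology_metrics(group, cds_len[q]))
    div = tree_divergences(config.tree)

    def policy_for(ga: str, gb: str) -> FilterPolicy:
        if ga == gb:
            return config.distant_policy
        d = div.get(tuple(sorted((ga, gb))), config.close_max_mya + 1)
        return config.close_policy if d < config.close_max_mya else config.distant_policy

    inter = [m for m in metrics if genome_of.get(m.subject_id) not in (None, genome_of[m.query_id])]
    intra = [m for m in metrics if genome_of.get(m.subject_id) == genome_of[m.query_id]]
    # divergence-dependent acceptance policy, applied pair by pair
    inter_ok = [
        m
        for m in inter
        if filter_pairs([m], policy_for(genome_of[m.query_id], genome_of[m.subject_id]))
    ]
    intra_ok = [m for m in intra if filter_pairs([m], config.distant_policy)]
    ortho = reciprocal_best_pairs(inter_ok, "inter_genome", genome_of)
    log["homology"] = {
        "pairs_scored": len(metrics),
        "inter_accepted": len(inter_ok),
        "intra_accepted": len(intra_ok),
        "rbh_orthologs": len(ortho),
    }

    # ---- dating -----------------------------------------------------------
    ks_map: dict[frozenset, float] = {}
    ks_path = ddir / "pairs.ks.tsv"
    if ks_path.exists():
        ks_tbl = pgio.read_ks_table(ks_path)
        for row in ks_tbl.itertuples(index=False):
            ks_map[frozenset((row.gene1, row.gene2))] = float(row.ks)
    else:
        from Bio import SeqIO

        from .dating import estimate_ks

        seqs: dict[str, str] = {}
        for fa in sorted(ddir.glob("*.cds.fasta")):
            for rec in SeqIO.parse(str(fa), "fasta"):
                seqs[rec.id] = str(rec.seq)
        for m in intra_ok:
            key = frozenset((m.query_id, m.subject_id))
            if key in ks_map:
                continue
            s1, s2 = seqs.get(m.query_id), seqs.get(m.subject_id)
            if s1 and s2 and len(s1) == len(s2):
                ks_map[key] = estimate_ks(s1, s2)

    seen_pairs: set[frozenset] = set()
    paralog_pairs: list[tuple[str, str, str, float, str]] = []
    for m in intra_ok:
        key = frozenset((m.query_id, m.subject_id))
        if key in seen_pairs or len(key) != 2:
            continue
        seen_pairs.add(key)
        ks = ks_map.get(key, math.nan)
        label = label_wgd_pairs([ks], config.dating)[0]
        a, b = sorted(key)
        paralog_pairs.append((a, b, genome_of[a], ks, label))
    paralog_pairs.sort()

    mixtures = {}
    for gname in genomes:
        vals = [ks for a, b, g, ks, _ in paralog_pairs if g == gname and math.isfinite(ks)]
        try:
            mixtures[gname] = fit_ks_mixture(vals, config.mixture_k_range, config.dating, seed=config.seed)
        except InsufficientDataError:
            mixtures[gname] = None
    log["dating"] = {
        "paralog_pairs": len(paralog_pairs),
        "ancient": sum(1 for p in paralog_pairs if p[4] == "ancient_wgd"),
        "recent": sum(1 for p in paralog_pairs if p[4] == "recent_wgd"),
        "mixture_k": {g: (m.k if m else None) for g, m in mixtures.items()},
    }

    # ---- synteny ----------------------------------------------------------
    anchors: list[Anchor] = []
    for pair in sorted(ortho, key=sorted):
        a, b = sorted(pair)
        (ga, ca, pa), (gb, cb, pb) = positions[a], positions[b]
        if ga > gb:
            (a, ga, ca, pa), (b, gb, cb, pb) = (b, gb, cb, pb), (a, ga, ca, pa)
        anchors.append(Anchor(a, b, ca, pa, cb, pb, ga, gb, "ortholog", strand[a], strand[b]))
    wgd_labels = {"ancient_wgd", "recent_wgd"}
    for a, b, g, ks, label in paralog_pairs:
        if label not in wgd_labels:
            continue
        (_, ca, pa), (_, cb, pb) = positions[a], positions[b]
        if ca == cb and abs(pa - pb) <= config.chain.max_gap_bp:
            continue  # tandem-proximal pair: CNV candidate, not a WGD relic
        anchors.append(Anchor(a, b, ca, pa, cb, pb, g, g, "paralog", strand[a], strand[b]))
    blocks = chain_all(anchors, config.chain)
    amap = assign_block_ancestry(blocks)
    log["synteny"] = {
        "anchors": len(anchors),
        "blocks": len(blocks),
        "components": len(set(amap.block_labels)),
    }

    # ---- duplicates -------------------------------------------------------
    ancient = [(a, b, g) for a, b, g, ks, label in paralog_pairs if label == "ancient_wgd"]
    recent = [(a, b, g) for a, b, g, ks, label in paralog_pairs if label == "recent_wgd"]
    calls, summaries = classify_duplicates(ancient + recent, amap, positions)
    log["duplicates"] = {s.genome: {"total": s.total, "retained": s.retained, "shuffled": s.shuffled} for s in summaries}
    ret_feats = [features[g] for c in calls if c.status == "retained" for g in (c.gene_a, c.gene_b)]
    shuf_feats = [features[g] for c in calls if c.status == "shuffled" for g in (c.gene_a, c.gene_b)]
    if ret_feats and shuf_feats:
        log["feature_contrast"] = feature_contrast(ret_feats, shuf_feats)

    # ---- orthogroups (needed for dominance retention and CARs) ------------
    og_graph = nx.Graph()
    for pair in ortho:
        a, b = sorted(pair)
        og_graph.add_edge(a, b)
    orthogroups: dict[str, str] = {}
    comps = sorted(nx.connected_components(og_graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        og = f"OG{i + 1:05d}"
        for gid in sorted(comp):
            orthogroups[gid] = og

    # ---- dominance --------------------------------------------------------
    hulls = amap.paralogon_hulls()
    dominance = []
    for key in sorted(hulls):
        gname, c1, c2, label = key
        side1, side2 = hulls[key]
        n = [0, 0]
        for gid, (g, chrom, mid) in positions.items():
            if g != gname or gid not in orthogroups:
                continue
            for si, (schrom, lo, hi) in enumerate((side1, side2)):
                if chrom == schrom and lo <= mid <= hi:
                    n[si] += 1
        if n[0] + n[1] == 0:
            continue
        dominance.append(
            chi_square_dominance(n[0], n[1], config.alpha, f"{gname}:{side1[0]}", f"{gname}:{side2[0]}")
        )
    log["dominance"] = {"pairs_tested": len(dominance)}

    # ---- ancestral reconstruction ----------------------------------------
    # per-genome orthogroup counts (skip duplicated and displaced members)
    og_count_per_genome: Counter = Counter()
    for gid, og in orthogroups.items():
        og_count_per_genome[(genome_of[gid], og)] += 1
    og_major: dict[str, Optional[str]] = {}
    votes: dict[str, Counter] = defaultdict(Counter)
    for gid, og in orthogroups.items():
        g, chrom, mid = positions[gid]
        lab = amap.locate(g, chrom, mid)
        if lab is not None:
            votes[og][lab] += 1
    for og, cnt in votes.items():
        og_major[og] = max(sorted(cnt), key=lambda lab: cnt[lab])

    og_genomes: dict[str, set] = defaultdict(set)
    for gid, og in orthogroups.items():
        og_genomes[og].add(genome_of[gid])

    orders: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for (gname, chrom), gids in sorted(order_by_chrom.items()):
        seq = []
        for gid in gids:
            og = orthogroups.get(gid)
            if og is None or len(og_genomes[og]) < 2:
                continue  # a single-genome group carries no ancestral evidence
            g, c, mid = positions[gid]
            lab = amap.locate(g, c, mid)
            if lab is not None and og_major.get(og) is not None and lab != og_major[og]:
                continue  # displaced copy: at a position inconsistent with its group
            seq.append((og, strand[gid]))
        orders.setdefault(gname, {})[chrom] = seq

    clades = _clades(config.tree)
    adj = conserved_adjacencies(orders, skip_duplicated=False)
    candidates = adj.candidates(clades)
    postdup_cars = linearize_cars(candidates)

    # the pre-WGD order is built from *retained* duplicates only: shuffled
    # pairs sit at nonsyntenic positions and would bridge unrelated CARs
    retained_pairs = {
        frozenset((c.gene_a, c.gene_b)) for c in calls if c.status == "retained"
    }
    og_pairs = []
    for a, b, g, ks, label in paralog_pairs:
        if label != "ancient_wgd" or frozenset((a, b)) not in retained_pairs:
            continue
        oa, ob = orthogroups.get(a), orthogroups.get(b)
        if oa and ob and oa != ob:
            og_pairs.append((oa, ob))
    pre_cars, pairing = preduplication_order(postdup_cars, og_pairs, orders=orders)
    log["ancestor"] = {
        "adjacencies": len(adj.adjacencies),
        "candidates": len(candidates.adjacencies),
        "postdup_cars": len(postdup_cars),
        "pre_cars": len(pre_cars),
    }

    # ---- scenario ---------------------------------------------------------
    fixtures, observed = load_fixture_scenarios()
    ranking = score_scenarios(fixtures, observed)
    ledger = None
    truth_path = ddir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            tdata = json.load(fh)
        per_lineage: dict[str, list] = defaultdict(list)
        for ev in tdata.get("events", []):
            per_lineage[ev["lineage"]].append(
                {"kind": ev["kind"], "count": ev.get("operands", {}).get("size", 1)}
            )
        per_lineage = {
            lin: [e for e in evs if e["kind"] in ("CCF", "TCF", "fission", "inversion", "transposition", "translocation")]
            for lin, evs in per_lineage.items()
        }
        ledger = build_event_ledger(per_lineage)

    result = PipelineResult(
        config=config,
        genes=genes,
        positions=positions,
        ortholog_pairs=ortho,
        paralog_pairs=paralog_pairs,
        blocks=blocks,
        ancestry=amap,
        calls=calls,
        summaries=summaries,
        dominance=dominance,
        mixtures=mixtures,
        orthogroups=orthogroups,
        orders=orders,
        postdup_cars=postdup_cars,
        pre_cars=pre_cars,
        car_pairing=pairing,
        scenario_ranking=ranking,
        ledger=ledger,
        log=log,
    )
    if config.out_dir:
        write_bundle(result, config.out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    summary = pd.DataFrame(
        [
            {
                "genome": s.genome,
                "total_pairs": s.total,
                "retained": s.retained,
                "shuffled": s.shuffled,
                "retained_pct": s.retained_pct,
                "shuffled_pct": s.shuffled_pct,
            }
            for s in result.summaries
        ]
    )
    pgio.write_tsv(summary, out / "partition_summary.tsv")
    written["partition_summary"] = str(out / "partition_summary.tsv")

    calls = pd.DataFrame(
        [
            {"gene_a": c.gene_a, "gene_b": c.gene_b, "genome": c.genome, "status": c.status}
            for c in result.calls
        ]
    )
    pgio.write_tsv(calls, out / "duplicate_calls.tsv")
    written["duplicate_calls"] = str(out / "duplicate_calls.tsv")

    dom = pd.DataFrame(
        [
            {
                "compartment_a": d.compartment_a,
                "compartment_b": d.compartment_b,
                "n_a": d.n_a,
                "n_b": d.n_b,
                "chi2": round(d.chi2, 4),
                "p": d.p,
                "label_a": d.labels[0],
                "label_b": d.labels[1],
            }
            for d in result.dominance
        ]
    )
    pgio.write_tsv(dom, out / "dominance.tsv")
    written["dominance"] = str(out / "dominance.tsv")

    blocks = pd.DataFrame(
        [
            {
                "genome_a": b.side_a[0],
                "chrom_a": b.side_a[1],
                "start_a": b.side_a[2],
                "end_a": b.side_a[3],
                "genome_b": b.side_b[0],
                "chrom_b": b.side_b[1],
                "start_b": b.side_b[2],
                "end_b": b.side_b[3],
                "anchors": b.anchor_count,
                "orientation": b.orientation,
                "source": b.source,
                "ancestry_label": b.ancestry_label,
            }
            for b in result.blocks
        ]
    )
    pgio.write_tsv(blocks, out / "synteny_blocks.tsv")
    written["synteny_blocks"] = str(out / "synteny_blocks.tsv")

    rows = []
    for car in result.postdup_cars + result.pre_cars:
        for rank, (g, o) in enumerate(zip(car.genes, car.orientations)):
            rows.append({"car": car.id, "rank": rank, "orthogroup": g, "orientation": o})
    pgio.write_tsv(pd.DataFrame(rows), out / "cars.tsv")
    written["cars"] = str(out / "cars.tsv")

    scen = [
        {
            "scenario": ev.scenario_id,
            "ancestor_n": ev.ancestor_n,
            "violations": ev.violations,
            "structural_errors": ev.structural_errors,
            "parsimony": ev.parsimony_score,
            "ledger": ev.ledger.as_dict(),
            "accepted": ev.accepted,
        }
        for ev in result.scenario_ranking
    ]
    pgio.write_json(scen, out / "scenario_evaluation.json")
    written["scenario_evaluation"] = str(out / "scenario_evaluation.json")
    if result.ledger is not None:
        pgio.write_json(result.ledger.as_dict(), out / "event_ledger.json")
        written["event_ledger"] = str(out / "event_ledger.json")

    pgio.write_json(result.log, out / "run_log.json")
    written["run_log"] = str(out / "run_log.json")
    return written


# ---------------------------------------------------------------------------
# truth-based evaluation (simulated datasets)
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult, sim: SimulationResult) -> dict:
    """Score the pipeline's calls against the simulator's ground truth.

    Returns retained/shuffled status recovery, ancestral-adjacency recovery
    (among reconstructible adjacencies: both genes surviving, unmoved, in at
    least one genome of each clade) and the pre-WGD CAR count.
    """
    truth = sim.truth
    call_by_pair = {frozenset((c.gene_a, c.gene_b)): c.status for c in result.calls}
    recent_leaves = {ev.lineage for ev in truth.events if ev.kind == "WGD" and not ev.operands.get("shared")}

    n_match = n_tot = 0
    for rec in truth.true_pairs:
        if rec["status"] not in ("retained", "shuffled"):
            continue
        if rec["wgd"] == "shared" and rec["genome"] in recent_leaves:
            continue  # ancient pairs are 4-way ambiguous after a second WGD
        key = frozenset((rec["gene_d"], rec["gene_s"]))
        call = call_by_pair.get(key)
        if call is None:
            continue
        n_tot += 1
        n_match += call == rec["status"]
    status_recovery = n_match / n_tot if n_tot else math.nan

    # adjacency recovery
    clades = _clades(result.config.tree)
    meta = truth.gene_meta
    present_unmoved: dict[tuple, set] = defaultdict(set)  # (protogene, subg) -> genomes
    for leaf, genome in sim.genomes.items():
        for gene in genome.genes():
            m = meta[gene.id]
            if m["origin"] == "ancestral" and not m["moved"]:
                present_unmoved[(m["protogene"], m["subgenome"])].add(leaf)

    def reconstructible(key: tuple) -> bool:
        gs = present_unmoved.get(key, set())
        return all(gs & set(members) for members in clades.values())

    truth_adj: set[frozenset] = set()
    for chrom, order in truth.ancestor_order.items():
        kept = [tuple(k) for k in order if reconstructible(tuple(k))]
        for u, v in zip(kept, kept[1:]):
            truth_adj.add(frozenset((u, v)))

    # map orthogroups to true ancestral copies by majority vote
    og_truth: dict[str, tuple] = {}
    og_votes: dict[str, Counter] = defaultdict(Counter)
    for gid, og in result.orthogroups.items():
        m = meta.get(gid)
        if m:
            og_votes[og][(m["protogene"], m["subgenome"])] += 1
    for og, cnt in og_votes.items():
        og_truth[og] = max(sorted(cnt), key=lambda k: cnt[k])

    candidate_adj: set[frozenset] = set()
    adj = conserved_adjacencies(result.orders, skip_duplicated=False).candidates(clades)
    for (u, v) in adj.adjacencies:
        tu, tv = og_truth.get(u), og_truth.get(v)
        if tu and tv:
            candidate_adj.add(frozenset((tu, tv)))
    recovered = sum(1 for a in truth_adj if a in candidate_adj)
    adj_recovery = recovered / len(truth_adj) if truth_adj else math.nan

    return {
        "status_recovery": status_recovery,
        "status_pairs_scored": n_tot,
        "adjacency_recovery": adj_recovery,
        "true_adjacencies": len(truth_adj),
        "pre_wgd_car_count": len(result.pre_cars),
    }


def run_default_analysis(seed: int = 0, out_dir: Optional[str] = None, scratch: Optional[str] = None) -> tuple:
    """Simulate the default four-genome dataset, run the full pipeline on
    the emitted files and score it against the truth."""
    import tempfile

    from .simulate import SimulationConfig, emit_dataset, simulate

    cfg = SimulationConfig(seed=seed)
    sim = simulate(cfg)
    with tempfile.TemporaryDirectory() as tmp:
        ddir = scratch or tmp
        emit_dataset(sim, ddir, mode="ks_table")
        pcfg = PipelineConfig(dataset_dir=str(ddir), out_dir=out_dir, tree=cfg.tree, seed=seed)
        result = run_pipeline(pcfg)
    metrics = evaluate_against_truth(result, sim)
    return result, sim, metrics
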
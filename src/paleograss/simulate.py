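"""Forward simulator of paleopolyploid grass-like genome evolution.

An ancestral karyotype of ``n_proto`` protochromosomes with uniformly
spaced protogenes goes through a shared whole-genome duplication (WGD);
each chromosome pair is split into a dominant (D) and a sensitive (S)
copy.  Lineages then descend a dated species tree accumulating, in time
order: compartment-biased gene deletion (S copies deleted at a higher
per-gene rate than D copies), single-gene and small-cluster transposition,
chromosomal inversions, tandem duplication (CNV), segmental deletion (PAV),
planned chromosome fusions/fissions, and optional lineage-specific WGDs
(the maize-like neopolyploidy).  Every event is logged, every modern gene
keeps its protogene identity, and WGD duplicate pairs carry a ground-truth
status (retained / shuffled / deleted), so downstream inference can be
scored against the truth without any external data.

Dating inputs are emitted either as a Ks table computed from true pair
ages (Ks = 2 r T with multiplicative log-normal noise) or, in sequences
mode, as codon FASTA whose third positions evolve along the genealogy
under a Jukes-Cantor clock at rate r, so that realized Ks matches 2 r T in
expectation.
"""

from __future__ import annotations

import copy
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import Phylo

from ._util import lineage_rng
from .core import Centromere, Chromosome, EvolutionEvent, Gene, Genome

DEFAULT_TREE = "((rice:40,brachypodium:40)bep:10,(sorghum:40,maize:40)paccad:10)root;"

#: Codon prefixes of fourfold-degenerate families without first-position
#: synonymy (Leu CTx and Arg CGx are excluded), so every simulated codon has
#: exactly one synonymous site and realized Ks equals 2 r T in expectation.
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
_BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions of the default simulation.

    Deletion/transposition probabilities are per gene per Myr; inversion,
    tandem and segmental-deletion rates are per genome per Myr.  The S/D
    deletion bias ratio of 2 encodes subgenome dominance; absolute erosion
    is kept moderate so that ancestral-order reconstruction remains
    well-posed at this scale (see docs/methods.md).
    """

    n_proto: int = 7
    genes_per_chrom: int = 200
    gene_spacing: int = 10_000
    gene_length: int = 3_000
    tree: str = DEFAULT_TREE
    wgd_times: tuple = (("root", 60.0), ("maize", 5.0))
    p_del_D: float = 0.0008
    p_del_S: float = 0.0016
    p_shuffle: float = 0.0008
    cluster_size_dist: dict = field(
        default_factory=lambda: {1: 0.99598, 2: 0.00134, 3: 0.00134, 4: 0.00134}
    )
    inversion_rate: float = 0.08
    tandem_rate: float = 0.05
    pav_rate: float = 0.03
    pav_size: tuple = (2, 6)
    fusion_plan: dict = field(
        default_factory=lambda: {
            "brachypodium": [
                {"kind": "CCF", "time": 20.0},
                {"kind": "CCF", "time": 15.0},
            ],
            "maize": [
                {"kind": "CCF", "time": 4.0},
                {"kind": "CCF", "time": 3.0},
                {"kind": "TCF", "time": 2.0},
            ],
        }
    )
    ks_rate: float = 6.5e-9
    ks_lognoise_sd: float = 0.08
    n_codons: int = 150
    ssd_mode: bool = False  # transposition as duplicate-then-delete instead of a move
    shuffle_prefers_short: bool = False
    track_sequences: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_proto < 1 or self.genes_per_chrom < 1:
            raise ConfigurationError("n_proto and genes_per_chrom must be >= 1")
        for p in (self.p_del_D, self.p_del_S, self.p_shuffle):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.p_del_S < self.p_del_D:
            raise ConfigurationError("p_del_S must be >= p_del_D (dominance bias)")
        if abs(sum(self.cluster_size_dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_size_dist must sum to 1")


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    ancestral_registry: dict = field(default_factory=dict)  # (protogene, subg) -> genome -> [gene ids]
    ds_assignment: dict = field(default_factory=dict)  # chromosome name at WGD -> D/S
    events: list = field(default_factory=list)
    true_pairs: list = field(default_factory=list)  # dicts per genome/pair
    ancestor_order: dict = field(default_factory=dict)  # post-WGD chrom -> [(protogene, subg)]
    pair_ages: dict = field(default_factory=dict)  # frozenset({id,id}) -> Myr
    divergence: dict = field(default_factory=dict)  # (leafA, leafB) sorted -> Myr
    gene_meta: dict = field(default_factory=dict)  # modern id -> dict

    def pairs_for(self, genome: str, wgd: Optional[str] = None) -> list[dict]:
        return [
            p
            for p in self.true_pairs
            if p["genome"] == genome and (wgd is None or p["wgd"] == wgd)
        ]


@dataclass
class SimulationResult:
    genomes: dict  # leaf name -> Genome
    truth: SimulationTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# ancestor + WGD
# ---------------------------------------------------------------------------

def build_ancestor(config: SimulationConfig, counter: Optional[list] = None) -> Genome:
    """Ancestral genome: ``n_proto`` chromosomes, ``genes_per_chrom`` genes
    each on a uniform grid, one functional centromere at the midpoint."""
    config.validate()
    rng = lineage_rng(config.seed, "ancestor")
    counter = counter if counter is not None else [0]
    genome = Genome(name="ancestor")
    proto = 0
    for c in range(1, config.n_proto + 1):
        chrom = Chromosome(
            name=f"C{c}",
            centromeres=[Centromere(pos=config.genes_per_chrom / 2.0, functional=True)],
            anc_chrom=c,
        )
        for _ in range(config.genes_per_chrom):
            gid = f"g{counter[0]:06d}"
            counter[0] += 1
            length = int(np.clip(rng.gamma(4.0, config.gene_length / 4.0), 300, config.gene_spacing - 500))
            gene = Gene(
                id=gid,
                protogene=proto,
                anc_chrom=c,
                strand=int(rng.choice([-1, 1])),
                exon_count=int(1 + rng.poisson(7.6)),
                length=length,
                cds_length=config.n_codons * 3,
            )
            if config.track_sequences:
                gene_seq = rng.integers(0, 4, size=config.n_codons)
                prefix = rng.integers(0, len(_FOURFOLD_PREFIXES), size=config.n_codons)
                gene.__dict__["seq3"] = gene_seq
                gene.__dict__["prefix"] = prefix
            chrom.genes.append(gene)
            proto += 1
        genome.chromosomes.append(chrom)
    genome.layout(config.gene_spacing, config.gene_length)
    return genome


def apply_wgd(
    genome: Genome,
    time: float,
    rng: np.random.Generator,
    truth: SimulationTruth,
    lineage: str,
    counter: list,
    shared: bool,
) -> None:
    """Duplicate every chromosome, assign one D and one S copy per pair,
    register every duplicate pair in the truth with its birth time."""
    for ev in truth.events:
        if ev.kind == "WGD" and ev.lineage == lineage and ev.time == time:
            raise ConfigurationError(f"repeated WGD on lineage {lineage!r} at {time} Myr")
    new_chroms: list[Chromosome] = []
    for chrom in genome.chromosomes:
        sister = Chromosome(
            name="",
            centromeres=[Centromere(c.pos, c.functional) for c in chrom.centromeres],
            anc_chrom=chrom.anc_chrom,
        )
        pairs = []
        for gene in chrom.genes:
            gid = f"g{counter[0]:06d}"
            counter[0] += 1
            twin = copy.copy(gene)
            twin.id = gid
            twin.moved = gene.moved
            if getattr(gene, "seq3", None) is not None:
                twin.__dict__["seq3"] = gene.__dict__["seq3"].copy()
                twin.__dict__["prefix"] = gene.__dict__["prefix"]
            sister.genes.append(twin)
            pairs.append((gene, twin))
        first_is_d = bool(rng.random() < 0.5)
        if shared:
            d_chrom, s_chrom = (chrom, sister) if first_is_d else (sister, chrom)
            d_chrom.subgenome, s_chrom.subgenome = "D", "S"
            base = chrom.name
            d_chrom.name, s_chrom.name = f"{base}D", f"{base}S"
            truth.ds_assignment[d_chrom.name] = "D"
            truth.ds_assignment[s_chrom.name] = "S"
            for g_orig, g_twin in pairs:
                gd, gs = (g_orig, g_twin) if first_is_d else (g_twin, g_orig)
                gd.subgenome, gs.subgenome = "D", "S"
                truth.true_pairs.append(
                    {
                        "genome": None,  # filled per leaf at finalization
                        "wgd": "shared",
                        "gene_d": gd.id,
                        "gene_s": gs.id,
                        "time": time,
                        "lineage": lineage,
                    }
                )
        else:
            base = chrom.name
            lbl1, lbl2 = ("D", "S") if first_is_d else ("S", "D")
            chrom.name, sister.name = f"{base}.r1", f"{base}.r2"
            for g_orig, g_twin in pairs:
                g_orig.recent_copy, g_twin.recent_copy = lbl1, lbl2
                gd, gs = (g_orig, g_twin) if first_is_d else (g_twin, g_orig)
                truth.true_pairs.append(
                    {
                        "genome": None,
                        "wgd": "recent",
                        "gene_d": gd.id,
                        "gene_s": gs.id,
                        "time": time,
                        "lineage": lineage,
                    }
                )
        new_chroms.append(sister)
    genome.chromosomes.extend(new_chroms)
    truth.events.append(
        EvolutionEvent("WGD", lineage, time, {"shared": shared, "n_chrom_after": len(genome.chromosomes)})
    )
    if shared:
        truth.ancestor_order = {
            chrom.name: [(g.protogene, g.subgenome) for g in chrom.genes]
            for chrom in genome.chromosomes
        }


# ---------------------------------------------------------------------------
# branch evolution
# ---------------------------------------------------------------------------

def _p_event(rate: float, dt: float) -> float:
    return 1.0 - math.exp(-rate * dt)


def _erode_branch(
    genome: Genome,
    lineage: str,
    t_hi: float,
    t_lo: float,
    cfg: SimulationConfig,
    truth: SimulationTruth,
    rng: np.random.Generator,
    counter: list,
    tandem_times: dict,
) -> None:
    """Apply Poisson-scheduled events on one branch, in time order."""
    dt = t_hi - t_lo
    if dt <= 0:
        return
    sched: list[tuple[float, int, str, dict]] = []
    tie = 0

    sizes = np.array(sorted(cfg.cluster_size_dist))
    size_p = np.array([cfg.cluster_size_dist[int(s)] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()

    mean_len = float(np.mean([g.length for g in genome.genes()])) or 1.0
    for chrom in sorted(genome.chromosomes, key=lambda c: c.name):
        for gene in chrom.genes:
            if gene.subgenome == "S":
                pdel = _p_event(cfg.p_del_S, dt)
            else:
                pdel = _p_event(cfg.p_del_D, dt)
            if rng.random() < pdel:
                sched.append((float(rng.uniform(t_lo, t_hi)), tie, "deletion", {"gene": gene.id}))
                tie += 1
            p_sh = _p_event(cfg.p_shuffle, dt)
            if cfg.shuffle_prefers_short:
                p_sh = min(1.0, p_sh * mean_len / max(gene.length, 1))
            if rng.random() < p_sh:
                size = int(rng.choice(sizes, p=size_p))
                sched.append(
                    (float(rng.uniform(t_lo, t_hi)), tie, "transposition", {"gene": gene.id, "size": size})
                )
                tie += 1
    for kind, rate in (("inversion", cfg.inversion_rate), ("tandem_duplication", cfg.tandem_rate), ("segmental_deletion", cfg.pav_rate)):
        for _ in range(int(rng.poisson(rate * dt))):
            sched.append((float(rng.uniform(t_lo, t_hi)), tie, kind, {}))
            tie += 1
    for entry in cfg.fusion_plan.get(lineage, []):
        t = float(entry.get("time", t_lo))
        if t_lo <= t <= t_hi:
            sched.append((t, tie, entry["kind"], dict(entry)))
            tie += 1

    # Myr-before-present decreases as time advances: apply from t_hi downward
    sched.sort(key=lambda e: (-e[0], e[1]))

    index: dict[str, Chromosome] = {}

    def reindex() -> None:
        index.clear()
        for chrom in genome.chromosomes:
            for g in chrom.genes:
                index[g.id] = chrom

    reindex()
    for t, _, kind, op in sched:
        if kind == "deletion":
            chrom = index.get(op["gene"])
            if chrom is None:
                continue
            gene = next(g for g in chrom.genes if g.id == op["gene"])
            chrom.genes.remove(gene)
            del index[gene.id]
            truth.events.append(EvolutionEvent("deletion", lineage, t, {"genes": [gene.id], "chrom": chrom.name}))
            _drop_if_empty(genome, chrom, lineage, index)
        elif kind == "transposition":
            _apply_transposition(genome, lineage, t, op, cfg, truth, rng, counter, index, tandem_times)
        elif kind == "inversion":
            _apply_inversion(genome, lineage, t, truth, rng)
            reindex()
        elif kind == "tandem_duplication":
            _apply_tandem(genome, lineage, t, cfg, truth, rng, counter, index, tandem_times)
        elif kind == "segmental_deletion":
            _apply_pav(genome, lineage, t, cfg, truth, rng, index)
        elif kind in ("CCF", "TCF", "fission"):
            _apply_karyotype_event(genome, lineage, t, kind, op, truth, rng)
            reindex()
        if cfg.track_sequences:
            pass  # sequence mutation is applied branch-wise below

    if cfg.track_sequences:
        _mutate_sequences(genome, lineage, dt, cfg)


def _drop_if_empty(genome: Genome, chrom: Chromosome, lineage: str, index: dict) -> None:
    if not chrom.genes:
        import warnings

        warnings.warn(f"{lineage}: chromosome {chrom.name} emptied by deletion; dropped")
        genome.chromosomes.remove(chrom)


def _apply_transposition(genome, lineage, t, op, cfg, truth, rng, counter, index, tandem_times) -> None:
    chrom = index.get(op["gene"])
    if chrom is None:
        return
    i = next(k for k, g in enumerate(chrom.genes) if g.id == op["gene"])
    cluster = chrom.genes[i : i + op["size"]]
    dest_choices = sorted(genome.chromosomes, key=lambda c: c.name)
    weights = np.array([len(c.genes) for c in dest_choices], dtype=float)
    dest = dest_choices[int(rng.choice(len(dest_choices), p=weights / weights.sum()))]
    if cfg.ssd_mode:
        moved = []
        for g in cluster:
            gid = f"g{counter[0]:06d}"
            counter[0] += 1
            dup = copy.copy(g)
            dup.id = gid
            dup.moved = True
            if getattr(g, "seq3", None) is not None:
                dup.__dict__["seq3"] = g.__dict__["seq3"].copy()
                dup.__dict__["prefix"] = g.__dict__["prefix"]
            moved.append(dup)
        # duplicate-then-delete: the source copies are lost
        for g in cluster:
            chrom.genes.remove(g)
            del index[g.id]
    else:
        for g in cluster:
            chrom.genes.remove(g)
        moved = cluster
        for g in moved:
            g.moved = True
    j = int(rng.integers(0, len(dest.genes) + 1))
    if dest is chrom and j > i:
        j = min(j, len(dest.genes))
    dest.genes[j:j] = moved
    for g in moved:
        index[g.id] = dest
    truth.events.append(
        EvolutionEvent(
            "transposition",
            lineage,
            t,
            {"genes": [g.id for g in moved], "src": chrom.name, "dst": dest.name, "dst_index": j, "size": len(moved)},
        )
    )
    _drop_if_empty(genome, chrom, lineage, index)


def _apply_inversion(genome, lineage, t, truth, rng) -> None:
    chroms = sorted((c for c in genome.chromosomes if len(c.genes) >= 2), key=lambda c: c.name)
    if not chroms:
        return
    weights = np.array([len(c.genes) for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
    n = len(chrom.genes)
    i = int(rng.integers(0, n - 1))
    j = int(rng.integers(i + 2, min(n, i + max(3, n // 3)) + 1))
    chrom.genes[i:j] = [g for g in reversed(chrom.genes[i:j])]
    for g in chrom.genes[i:j]:
        g.strand = -g.strand
    for c in chrom.centromeres:
        if i <= c.pos < j:
            c.pos = i + (j - 1) - c.pos
    truth.events.append(EvolutionEvent("inversion", lineage, t, {"chrom": chrom.name, "start": i, "end": j}))


def _apply_tandem(genome, lineage, t, cfg, truth, rng, counter, index, tandem_times) -> None:
    genes = [g for chrom in sorted(genome.chromosomes, key=lambda c: c.name) for g in chrom.genes]
    if not genes:
        return
    template = genes[int(rng.integers(0, len(genes)))]
    chrom = index[template.id]
    gid = f"g{counter[0]:06d}"
    counter[0] += 1
    dup = copy.copy(template)
    dup.id = gid
    dup.origin = "tandem"
    dup.moved = False
    if getattr(template, "seq3", None) is not None:
        dup.__dict__["seq3"] = template.__dict__["seq3"].copy()
        dup.__dict__["prefix"] = template.__dict__["prefix"]
    i = chrom.genes.index(template)
    chrom.genes.insert(i + 1, dup)
    index[dup.id] = chrom
    tandem_times[dup.id] = (template.id, t)
    truth.events.append(
        EvolutionEvent("tandem_duplication", lineage, t, {"template": template.id, "copy": gid, "chrom": chrom.name})
    )


def _apply_pav(genome, lineage, t, cfg, truth, rng, index) -> None:
    chroms = sorted((c for c in genome.chromosomes if len(c.genes) >= cfg.pav_size[0]), key=lambda c: c.name)
    if not chroms:
        return
    weights = np.array([len(c.genes) for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
    size = int(rng.integers(cfg.pav_size[0], cfg.pav_size[1] + 1))
    size = min(size, len(chrom.genes))
    i = int(rng.integers(0, len(chrom.genes) - size + 1))
    removed = chrom.genes[i : i + size]
    del chrom.genes[i : i + size]
    for g in removed:
        index.pop(g.id, None)
    truth.events.append(
        EvolutionEvent("segmental_deletion", lineage, t, {"genes": [g.id for g in removed], "chrom": chrom.name, "start": i})
    )
    _drop_if_empty(genome, chrom, lineage, index)


def _apply_karyotype_event(genome, lineage, t, kind, op, truth, rng) -> None:
    names = sorted(c.name for c in genome.chromosomes)
    if kind in ("CCF", "TCF"):
        chosen = op.get("chroms")
        if chosen is None:
            if len(names) < 2:
                return
            idx = rng.choice(len(names), size=2, replace=False)
            chosen = [names[int(idx[0])], names[int(idx[1])]]
        for nm in chosen:
            if nm not in names:
                raise ConfigurationError(f"fusion_plan references absent chromosome {nm!r}")
        if chosen[0] == chosen[1]:
            raise ConfigurationError("cannot fuse a chromosome with itself")
        a = genome.get_chromosome(chosen[0])
        b = genome.get_chromosome(chosen[1])
        merged = Chromosome(name=f"{a.name}+{b.name}", anc_chrom=None)
        if kind == "CCF":
            b_genes = [g for g in reversed(b.genes)]
            for g in b_genes:
                g.strand = -g.strand
            merged.genes = a.genes + b_genes
            b_cent = [Centromere(len(b.genes) - 1 - c.pos + len(a.genes), False) for c in b.centromeres]
        else:
            merged.genes = a.genes + b.genes
            b_cent = [Centromere(c.pos + len(a.genes), False) for c in b.centromeres]
        merged.centromeres = [Centromere(c.pos, c.functional) for c in a.centromeres] + b_cent
        funcs = [c for c in merged.centromeres if c.functional]
        for extra in funcs[1:]:
            extra.functional = False
        genome.chromosomes.remove(a)
        genome.chromosomes.remove(b)
        genome.chromosomes.append(merged)
        truth.events.append(EvolutionEvent(kind, lineage, t, {"chroms": chosen, "result": merged.name}))
    else:  # fission
        nm = op.get("chrom")
        if nm is None:
            nm = names[int(rng.integers(0, len(names)))]
        if nm not in names:
            raise ConfigurationError(f"fusion_plan references absent chromosome {nm!r}")
        chrom = genome.get_chromosome(nm)
        if len(chrom.genes) < 2:
            return
        mode = op.get("mode", "centromeric")
        if mode == "centromeric" and chrom.functional_centromeres:
            cut = int(round(chrom.functional_centromeres[0].pos))
        else:
            cut = int(rng.integers(1, max(2, len(chrom.genes))))
        cut = min(max(cut, 1), len(chrom.genes) - 1)
        left = Chromosome(name=f"{nm}a", genes=chrom.genes[:cut])
        right = Chromosome(name=f"{nm}b", genes=chrom.genes[cut:])
        for c in chrom.centromeres:
            target, pos = (left, c.pos) if c.pos < cut else (right, c.pos - cut)
            functional = c.functional and mode != "centromeric"
            target.centromeres.append(Centromere(pos, functional))
        if mode == "centromeric":
            left.centromeres.append(Centromere(float(cut), False))
            right.centromeres.append(Centromere(0.0, False))
        genome.chromosomes.remove(chrom)
        genome.chromosomes.extend([left, right])
        truth.events.append(EvolutionEvent("fission", lineage, t, {"chrom": nm, "cut": cut, "mode": mode}))


def _mutate_sequences(genome: Genome, lineage: str, dt_myr: float, cfg: SimulationConfig) -> None:
    rng = lineage_rng(cfg.seed, lineage, "seq")
    p = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * cfg.ks_rate * dt_myr * 1e6))
    for chrom in sorted(genome.chromosomes, key=lambda c: c.name):
        for gene in chrom.genes:
            seq = getattr(gene, "seq3", None)
            if seq is None:
                continue
            mask = rng.random(len(seq)) < p
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                seq[mask] = (seq[mask] + shift) % 4


# ---------------------------------------------------------------------------
# tree descent
# ---------------------------------------------------------------------------

def _parse_tree(newick: str):
    tree = Phylo.read(StringIO(newick), "newick")
    i = 0
    for cl in tree.find_clades():
        if not cl.name:
            cl.name = f"node{i}"
            i += 1
    return tree


def tree_divergences(newick: str) -> dict[tuple[str, str], float]:
    """Pairwise divergence times (Myr) between leaves of an ultrametric tree."""
    tree = _parse_tree(newick)
    leaves = tree.get_terminals()
    root_age = max(tree.distance(tree.root, lf) for lf in leaves)
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            mrca = tree.common_ancestor([a.name, b.name])
            age = root_age - tree.distance(tree.root, mrca)
            out[tuple(sorted((a.name, b.name)))] = age
    return out


def evolve_lineages(genome: Genome, config: SimulationConfig, counter: Optional[list] = None) -> tuple[dict, SimulationTruth]:
    """Run the full descent from the (pre-WGD) ancestor to the tree leaves."""
    config.validate()
    counter = counter if counter is not None else [int(1e6)]
    truth = SimulationTruth()
    truth.divergence = tree_divergences(config.tree)
    tandem_times: dict[str, tuple[str, float]] = {}
    tree = _parse_tree(config.tree)
    leaves = [lf.name for lf in tree.get_terminals()]
    if len(leaves) < 2:
        raise ConfigurationError("tree must have >= 2 leaves")
    root_age = max(tree.distance(tree.root, lf) for lf in tree.get_terminals())
    root_name = tree.root.name

    wgd_by_lineage: dict[str, list[float]] = defaultdict(list)
    for lin, t in config.wgd_times:
        wgd_by_lineage[lin].append(float(t))

    t_start = max([root_age] + wgd_by_lineage.get(root_name, [root_age]))
    work = copy.deepcopy(genome)

    # stem: WGDs scheduled on the root lineage, then erosion down to the root split
    t_cursor = t_start
    rng_stem = lineage_rng(config.seed, root_name)
    for wt in sorted(wgd_by_lineage.get(root_name, []), reverse=True):
        _erode_branch(work, root_name, t_cursor, wt, config, truth, rng_stem, counter, tandem_times)
        apply_wgd(work, wt, lineage_rng(config.seed, root_name, f"wgd{wt}"), truth, root_name, counter, shared=True)
        t_cursor = wt
    _erode_branch(work, root_name, t_cursor, root_age, config, truth, rng_stem, counter, tandem_times)

    genomes: dict[str, Genome] = {}

    def descend(g: Genome, node, t_top: float) -> None:
        for child in node.clades:
            sub = copy.deepcopy(g)
            t_bot = t_top - child.branch_length
            name = child.name
            rng_c = lineage_rng(config.seed, name)
            t_cur = t_top
            for wt in sorted(wgd_by_lineage.get(name, []), reverse=True):
                if t_bot <= wt <= t_cur:
                    _erode_branch(sub, name, t_cur, wt, config, truth, rng_c, counter, tandem_times)
                    apply_wgd(sub, wt, lineage_rng(config.seed, name, f"wgd{wt}"), truth, name, counter, shared=False)
                    t_cur = wt
            _erode_branch(sub, name, t_cur, t_bot, config, truth, rng_c, counter, tandem_times)
            if child.is_terminal():
                genomes[name] = sub
            else:
                descend(sub, child, t_bot)

    descend(work, tree.root, root_age)

    _finalize(genomes, truth, config, tandem_times)
    return genomes, truth


def _finalize(genomes: dict, truth: SimulationTruth, cfg: SimulationConfig, tandem_times: dict) -> None:
    presence: dict[str, dict[str, str]] = {}
    recent_leaves = set()
    for ev in truth.events:
        if ev.kind == "WGD" and not ev.operands.get("shared"):
            recent_leaves.add(ev.lineage)
    for leaf in sorted(genomes):
        genome = genomes[leaf]
        genome.name = leaf
        pres: dict[str, str] = {}
        genome.chromosomes.sort(key=lambda c: (-len(c.genes), c.name))
        for ci, chrom in enumerate(genome.chromosomes, start=1):
            old = chrom.name
            chrom.name = f"{leaf}_chr{ci}"
            truth.gene_meta[f"{leaf}:{chrom.name}"] = {"was": old, "subgenome": chrom.subgenome}
            for gene in chrom.genes:
                new_id = f"{leaf}_{gene.id}"
                if gene.id in tandem_times:
                    truth.gene_meta.setdefault("_tandem", {})[new_id] = tandem_times[gene.id][1]
                pres[gene.id] = new_id
                gene.id = new_id
        genome.layout(cfg.gene_spacing, cfg.gene_length)
        presence[leaf] = pres
        for gene in genome.genes():
            truth.gene_meta[gene.id] = {
                "protogene": gene.protogene,
                "subgenome": gene.subgenome,
                "recent_copy": gene.recent_copy,
                "origin": gene.origin,
                "moved": gene.moved,
                "anc_chrom": gene.anc_chrom,
            }
            key = f"{gene.protogene}|{gene.subgenome}"
            truth.ancestral_registry.setdefault(key, {}).setdefault(leaf, []).append(gene.id)

    moved_flags = {g.id: g.moved for genome in genomes.values() for g in genome.genes()}
    expanded: list[dict] = []
    for rec in truth.true_pairs:
        if rec["wgd"] == "shared":
            targets = [lf for lf in sorted(genomes) if lf not in recent_leaves]
        else:
            targets = [rec["lineage"]]
        for leaf in targets:
            pres = presence.get(leaf, {})
            gd, gs = pres.get(rec["gene_d"]), pres.get(rec["gene_s"])
            if gd is None or gs is None:
                status = "deleted"
            elif moved_flags.get(gd) or moved_flags.get(gs):
                status = "shuffled"
            else:
                status = "retained"
            expanded.append(
                {
                    "genome": leaf,
                    "wgd": rec["wgd"],
                    "gene_d": gd,
                    "gene_s": gs,
                    "orig_d": rec["gene_d"],
                    "orig_s": rec["gene_s"],
                    "time": rec["time"],
                    "status": status,
                }
            )
    truth.true_pairs = expanded


def simulate(config: Optional[SimulationConfig] = None) -> SimulationResult:
    """Build the ancestor, run the descent, return genomes plus truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    counter = [0]
    ancestor = build_ancestor(cfg, counter)
    genomes, truth = evolve_lineages(ancestor, cfg, counter)
    return SimulationResult(genomes, truth, cfg)


# ---------------------------------------------------------------------------
# pair ages and dataset emission
# ---------------------------------------------------------------------------

def pair_age(truth: SimulationTruth, meta_a: dict, meta_b: dict, genome_a: str, genome_b: str, wgd_times: dict) -> float:
    """True divergence time (Myr) between two homologous genes."""
    if genome_a != genome_b:
        if meta_a["subgenome"] != meta_b["subgenome"]:
            return wgd_times["shared"]
        return truth.divergence[tuple(sorted((genome_a, genome_b)))]
    if meta_a["subgenome"] != meta_b["subgenome"]:
        return wgd_times["shared"]
    if meta_a.get("recent_copy") != meta_b.get("recent_copy"):
        return wgd_times["recent"]
    return wgd_times.get("tandem_default", 1.0)


def emit_dataset(result: SimulationResult, outdir: str | Path, mode: str = "ks_table") -> dict:
    """Write the dataset: per-genome GFF3 + BED, BLAST-tabular homology,
    a Ks table (or codon FASTA in sequences mode) and the truth JSON.

    Returns a manifest of written paths.
    """
    if mode not in ("ks_table", "sequences"):
        raise ValueError(f"unknown emission mode {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, truth = result.config, result.truth
    rng = lineage_rng(cfg.seed, "emit")
    manifest: dict[str, str] = {}

    from . import io as pgio

    for leaf in sorted(result.genomes):
        genome = result.genomes[leaf]
        gff = outdir / f"{leaf}.gff3"
        bed = outdir / f"{leaf}.bed"
        pgio.write_gff3(genome, gff)
        pgio.write_bed(genome, bed)
        manifest[f"gff3:{leaf}"] = str(gff)
        manifest[f"bed:{leaf}"] = str(bed)

    root_name = _parse_tree(cfg.tree).root.name
    wgd_shared = max((t for lin, t in cfg.wgd_times if lin == root_name), default=0.0)
    wgd_recent = next((t for lin, t in cfg.wgd_times if lin != root_name), 5.0)
    wtimes = {"shared": wgd_shared, "recent": wgd_recent, "tandem_default": 1.0}
    tandem_ages = truth.gene_meta.get("_tandem", {})

    by_proto: dict[int, list[tuple[str, str, dict]]] = defaultdict(list)
    for leaf in sorted(result.genomes):
        for gene in result.genomes[leaf].genes():
            meta = truth.gene_meta[gene.id]
            by_proto[meta["protogene"]].append((gene.id, leaf, meta))

    cds_len = cfg.n_codons * 3
    blast_rows: list[tuple] = []
    ks_rows: list[tuple] = []
    all_ids: list[str] = []
    for proto in sorted(by_proto):
        members = by_proto[proto]
        all_ids.extend(m[0] for m in members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ga, la, ma = members[i]
                gb, lb, mb = members[j]
                age = pair_age(truth, ma, mb, la, lb, wtimes)
                if la == lb and ma["subgenome"] == mb["subgenome"] and ma.get("recent_copy") == mb.get("recent_copy"):
                    ts = [tandem_ages[g] for g in (ga, gb) if g in tandem_ages]
                    if ts:
                        age = min(ts)
                truth.pair_ages[f"{ga}|{gb}"] = age
                noise = rng.normal(0.0, 1.0)
                pid = 100.0 if age == 0 else float(np.clip(100.0 - 0.55 * age + noise, 35.0, 100.0))
                ident = int(round(pid * cds_len / 100.0))
                bits = round(2.0 * cds_len * pid / 100.0, 1)
                for q, s in ((ga, gb), (gb, ga)):
                    blast_rows.append(
                        (q, s, f"{pid:.2f}", cds_len, cds_len - ident, 0, 1, cds_len, 1, cds_len, "1e-180", f"{bits:.1f}")
                    )
                if la == lb:
                    noise = float(np.exp(rng.normal(0.0, cfg.ks_lognoise_sd))) if cfg.ks_lognoise_sd > 0 else 1.0
                    ks = 2.0 * cfg.ks_rate * age * 1e6 * noise
                    ks_rows.append((ga, gb, la, f"{ks:.6f}", f"{age:.3f}"))

    n_noise = max(1, len(blast_rows) // 200)
    ids_arr = sorted(all_ids)
    for _ in range(n_noise):
        q, s = (ids_arr[int(rng.integers(0, len(ids_arr)))] for _ in range(2))
        if q == s:
            continue
        pid = float(rng.uniform(30, 45))
        ident = int(round(pid * cds_len / 100.0))
        blast_rows.append(
            (q, s, f"{pid:.2f}", cds_len, cds_len - ident, 0, 1, cds_len, 1, cds_len, "1e-5", f"{2.0 * cds_len * pid / 100.0:.1f}")
        )

    blast_path = outdir / "homology.blast.tsv"
    with open(blast_path, "w") as fh:
        for row in sorted(blast_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    manifest["blast"] = str(blast_path)

    if mode == "ks_table":
        ks_path = outdir / "pairs.ks.tsv"
        with open(ks_path, "w") as fh:
            fh.write("gene1\tgene2\tgenome\tks\ttrue_age_mya\n")
            for row in sorted(ks_rows):
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest["ks_table"] = str(ks_path)
    else:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        for leaf in sorted(result.genomes):
            recs = []
            for gene in result.genomes[leaf].genes():
                seq3 = getattr(gene, "seq3", None)
                if seq3 is None:
                    continue
                prefix = gene.__dict__["prefix"]
                codons = [
                    _FOURFOLD_PREFIXES[int(p)] + _BASES[int(b)] for p, b in zip(prefix, seq3)
                ]
                recs.append(SeqRecord(Seq("".join(codons)), id=gene.id, description=""))
            path = outdir / f"{leaf}.cds.fasta"
            SeqIO.write(recs, str(path), "fasta")
            manifest[f"fasta:{leaf}"] = str(path)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "config": {k: v for k, v in asdict(cfg).items() if k != "fusion_plan"} | {"fusion_plan": cfg.fusion_plan},
                "ds_assignment": truth.ds_assignment,
                "true_pairs": truth.true_pairs,
                "ancestor_order": {k: [[p, s] for p, s in v] for k, v in truth.ancestor_order.items()},
                "gene_meta": {k: v for k, v in truth.gene_meta.items() if isinstance(v, dict)},
                "divergence": {"|".join(k): v for k, v in truth.divergence.items()},
                "events": [
                    {"kind": e.kind, "lineage": e.lineage, "time": e.time, "operands": _jsonable(e.operands)}
                    for e in truth.events
                ],
            },
            fh,
            indent=0,
            sort_keys=True,
        )
    manifest["truth"] = str(truth_path)
    return manifest


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x
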
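"""Synteny block chaining and ancestral-compartment labelling.

Homology anchors (accepted ortholog or paralog pairs with chromosome
positions on both sides) are chained into collinear blocks per chromosome
pair with the classical cleaning parameters: a minimum number of anchors
per block (> 5, i.e. at least 6), a maximum gap between consecutive
anchors (100 kb, measured independently on each side; a break on either
side splits the chain) and a minimum block span (100 kb).  Chains are found
by dynamic programming (longest collinear subsequence per orientation) and
extracted greedily by anchor count, ties broken by span then leftmost
start, so that no anchor belongs to two blocks.

Blocks from all genome pairs are then stitched into ancestral compartments:
chromosome segments covered by blocks are graph nodes, orthology/paralogy
block links are edges, and connected components define ancestral-group
labels - duplicated segments found at orthologous positions in two or more
genomes descend from a single ancestral region.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: float  # midpoint bp
    chrom_b: str
    pos_b: float
    genome_a: str = ""
    genome_b: str = ""
    source: str = "ortholog"  # ortholog | paralog
    strand_a: int = 1
    strand_b: int = 1


@dataclass(frozen=True)
class ChainParams:
    min_anchors: int = 6  # "> 5" read strictly
    max_gap_bp: float = 100_000.0
    min_span_bp: float = 100_000.0

    def __post_init__(self) -> None:
        if self.min_anchors < 1 or self.max_gap_bp <= 0 or self.min_span_bp < 0:
            raise ValueError("chain parameters must be positive")


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    source: str
    ancestry_label: Optional[str] = None

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    @property
    def side_a(self) -> tuple[str, str, float, float]:
        ps = [a.pos_a for a in self.anchors]
        a0 = self.anchors[0]
        return (a0.genome_a, a0.chrom_a, min(ps), max(ps))

    @property
    def side_b(self) -> tuple[str, str, float, float]:
        ps = [a.pos_b for a in self.anchors]
        a0 = self.anchors[0]
        return (a0.genome_b, a0.chrom_b, min(ps), max(ps))

    @property
    def span_a(self) -> float:
        _, _, lo, hi = self.side_a
        return hi - lo

    @property
    def span_b(self) -> float:
        _, _, lo, hi = self.side_b
        return hi - lo


def _chain_valid(anchors: Sequence[Anchor], orientation: str, max_gap: float) -> bool:
    """A chain is valid when strictly monotone on side a, monotone per
    orientation on side b, with consecutive gaps <= max_gap on both sides."""
    sign = 1 if orientation == "same" else -1
    for p, q in itertools.pairwise(anchors):
        if not (q.pos_a > p.pos_a):
            return False
        if not (sign * (q.pos_b - p.pos_b) > 0):
            return False
        if q.pos_a - p.pos_a > max_gap or abs(q.pos_b - p.pos_b) > max_gap:
            return False
    return True


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: float) -> list[Anchor]:
    """Longest collinear chain by DP; ties by larger side-a span, then
    leftmost side-a start.  Returns [] when no anchor is available."""
    if not anchors:
        return []
    sign = 1.0 if orientation == "same" else -1.0
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].pos_a, sign * anchors[i].pos_b))
    pa = [anchors[i].pos_a for i in order]
    pb = [anchors[i].pos_b for i in order]
    n = len(order)
    count = [1] * n
    start = list(pa)  # side-a start of the best chain ending here
    parent = [-1] * n
    for i in range(n):
        for j in range(i):
            if not (pa[i] > pa[j] and sign * (pb[i] - pb[j]) > 0):
                continue
            if pa[i] - pa[j] > max_gap or abs(pb[i] - pb[j]) > max_gap:
                continue
            cand = (count[j] + 1, pa[i] - start[j], -start[j])
            cur = (count[i], pa[i] - start[i], -start[i])
            if cand > cur:
                count[i] = count[j] + 1
                start[i] = start[j]
                parent[i] = j
    best_i = max(range(n), key=lambda i: (count[i], pa[i] - start[i], -start[i]))
    chain = []
    i = best_i
    while i != -1:
        chain.append(anchors[order[i]])
        i = parent[i]
    chain.reverse()
    return chain


def chain_anchors(anchors: Iterable[Anchor], params: ChainParams = ChainParams()) -> list[SyntenyBlock]:
    """Chain the anchors of one chromosome pair into synteny blocks.

    Chains are extracted greedily per orientation until no chain reaches
    ``min_anchors``; each anchor is used at most once.  Chains whose span is
    below ``min_span_bp`` on both sides are discarded.
    """
    pool = list(anchors)
    if not pool:
        return []
    blocks: list[SyntenyBlock] = []
    remaining = pool
    while True:
        same = _best_chain(remaining, "same", params.max_gap_bp)
        inv = _best_chain(remaining, "inverted", params.max_gap_bp)
        chain, orient = max(
            ((same, "same"), (inv, "inverted")),
            key=lambda c: (len(c[0]), _span(c[0]), c[1] == "same"),
        )
        if len(chain) < params.min_anchors:
            break
        taken = set(map(id, chain))
        remaining = [a for a in remaining if id(a) not in taken]
        blk = SyntenyBlock(anchors=chain, orientation=orient, source=chain[0].source)
        if blk.span_a >= params.min_span_bp or blk.span_b >= params.min_span_bp:
            blocks.append(blk)
    blocks.sort(key=lambda b: (-b.anchor_count, b.side_a))
    return blocks


def _span(chain: Sequence[Anchor]) -> float:
    if not chain:
        return 0.0
    ps = [a.pos_a for a in chain]
    return max(ps) - min(ps)


def chain_all(
    anchors: Iterable[Anchor], params: ChainParams = ChainParams()
) -> list[SyntenyBlock]:
    """Group anchors by (genome, chromosome) pair and chain each group."""
    groups: dict[tuple, list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.genome_a, a.chrom_a, a.genome_b, a.chrom_b)].append(a)
    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        blocks.extend(chain_anchors(groups[key], params))
    return blocks


# ---------------------------------------------------------------------------
# ancestry assignment
# ---------------------------------------------------------------------------

@dataclass
class AncestryMap:
    """Result of stitching blocks into ancestral compartments.

    ``block_labels[i]`` is the component label of ``blocks[i]``;
    ``segments[(genome, chrom)]`` is a sorted list of labelled intervals
    (start, end, label); component flags mark ancestral duplications
    (paralogy supported by >= 2 genomes) vs lineage-specific ones.
    """

    blocks: list[SyntenyBlock]
    block_labels: list[str]
    segments: dict[tuple[str, str], list[tuple[float, float, str]]]
    component_flags: dict[str, str] = field(default_factory=dict)

    def locate(self, genome: str, chrom: str, pos: float) -> Optional[str]:
        for lo, hi, label in self.segments.get((genome, chrom), ()):
            if lo <= pos <= hi:
                return label
        return None

    def paralogon_hulls(self) -> dict[tuple, list[tuple]]:
        """Per (genome, chromA, chromB, label): hull intervals of the two
        sides of all kept paralogous blocks linking that chromosome pair."""
        hulls: dict[tuple, list] = {}
        for blk, label in zip(self.blocks, self.block_labels):
            if blk.source != "paralog":
                continue
            ga, ca, alo, ahi = blk.side_a
            gb, cb, blo, bhi = blk.side_b
            key = (ga, *sorted([ca, cb]), label)
            if (ca, alo) > (cb, blo):
                (ca, alo, ahi), (cb, blo, bhi) = (cb, blo, bhi), (ca, alo, ahi)
            cur = hulls.get(key)
            if cur is None:
                hulls[key] = [ca, alo, ahi, cb, blo, bhi]
            else:
                cur[1], cur[2] = min(cur[1], alo), max(cur[2], ahi)
                cur[4], cur[5] = min(cur[4], blo), max(cur[5], bhi)
        return {k: [tuple(v[:3]), tuple(v[3:])] for k, v in hulls.items()}


def assign_block_ancestry(blocks: Sequence[SyntenyBlock]) -> AncestryMap:
    """Label blocks by connected component of the segment graph.

    Block sides overlapping on the same chromosome are merged into one
    node; each block contributes an edge between its two sides.  Components
    whose paralogy edges span >= 2 genomes are flagged ``ancestral_duplication``;
    paralogy confined to one genome is ``lineage_specific``; components
    without paralogy edges are ``single_copy``.
    """
    g = nx.Graph()
    side_nodes: list[tuple] = []
    for i, blk in enumerate(blocks):
        for side in (blk.side_a, blk.side_b):
            node = ("side", i, side)
            g.add_node(node, interval=side)
            side_nodes.append(node)
        g.add_edge(("side", i, blk.side_a), ("side", i, blk.side_b), kind=blk.source)

    # merge overlapping sides on the same chromosome
    by_chrom: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for node in side_nodes:
        genome, chrom, lo, hi = node[2]
        by_chrom[(genome, chrom)].append(node)
    for nodes in by_chrom.values():
        nodes.sort(key=lambda n: n[2][2])
        for p, q in itertools.pairwise(nodes):
            if q[2][2] <= p[2][3]:  # intervals overlap
                g.add_edge(p, q, kind="overlap")

    block_labels = [""] * len(blocks)
    segments: dict[tuple[str, str], list[tuple[float, float, str]]] = defaultdict(list)
    flags: dict[str, str] = {}
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for ci, comp in enumerate(comps):
        label = f"ANC{ci + 1:02d}"
        para_genomes = set()
        for u, v, data in g.edges(comp, data=True):
            if data.get("kind") == "paralog":
                para_genomes.add(u[2][0])
        for node in comp:
            _, bi, (genome, chrom, lo, hi) = node
            block_labels[bi] = label
            segments[(genome, chrom)].append((lo, hi, label))
        if len(para_genomes) >= 2:
            flags[label] = "ancestral_duplication"
        elif len(para_genomes) == 1:
            flags[label] = "lineage_specific"
        else:
            flags[label] = "single_copy"

    merged: dict[tuple[str, str], list[tuple[float, float, str]]] = {}
    for key, ivs in segments.items():
        ivs.sort()
        out: list[list] = []
        for lo, hi, lab in ivs:
            if out and lab == out[-1][2] and lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi, lab])
        merged[key] = [tuple(t) for t in out]

    amap = AncestryMap(list(blocks), block_labels, merged, flags)
    for blk, lab in zip(blocks, block_labels):
        blk.ancestry_label = lab
    return amap
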
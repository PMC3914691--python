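"""Retained vs shuffled duplicate classification and deletion chronology.

Ancient duplicate pairs (same dating value, i.e. labelled as coming from
one WGD) are *retained* when both copies still sit inside a recognized
paralogon - a pair of chromosomal segments descending from the same
pre-WGD region - and *shuffled* when at least one copy is found at a
nonsyntenic location.  Shuffled copies mostly move alone; occasionally
they move in small clusters of two to four genes, and a few much larger
blocks shared by all genomes betray ancestral translocations rather than
gene movement.

Deletion chronology places each lost duplicate copy on the species tree by
small parsimony: a copy absent from every species was lost before
speciation (ancestral), absence confined to one clade is lineage specific,
absence in a single species is species specific, and other patterns are
resolved to the minimum-loss combination of lineage/species events.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import round_half_away
from .synteny import AncestryMap


@dataclass(frozen=True)
class DuplicateCall:
    gene_a: str
    gene_b: str
    genome: str
    status: str  # retained | shuffled
    paralogon: Optional[tuple] = None  # hull key when retained
    cluster_id: Optional[int] = None


@dataclass(frozen=True)
class PartitionSummary:
    genome: str
    total: int
    retained: int
    shuffled: int
    retained_pct: int
    shuffled_pct: int


@dataclass(frozen=True)
class ChronologyCall:
    protogene: int
    copy: str  # subgenome of the lost copy
    absent_in: frozenset
    call: str
    events: tuple  # minimal loss events, e.g. ("lineage_BEP",) or two species losses


def summarize_partition(genome: str, total: int, retained: int) -> PartitionSummary:
    """Partition arithmetic for one genome: shuffled = total - retained,
    percentages rounded half away from zero (as printed in summary tables)."""
    if retained > total or retained < 0:
        raise ValueError("retained count out of range")
    shuffled = total - retained
    return PartitionSummary(
        genome,
        total,
        retained,
        shuffled,
        round_half_away(100.0 * retained / total) if total else 0,
        round_half_away(100.0 * shuffled / total) if total else 0,
    )


def classify_duplicates(
    wgd_pairs: Iterable[tuple[str, str, str]],
    amap: AncestryMap,
    positions: Mapping[str, tuple[str, str, float]],
) -> tuple[list[DuplicateCall], list[PartitionSummary]]:
    """Classify WGD-dated pairs as retained or shuffled.

    ``wgd_pairs`` yields (gene_a, gene_b, genome); ``positions`` maps gene id
    to (genome, chrom, midpoint bp).  A pair is retained when its two genes
    fall inside the two sides of one paralogon hull (the merged span of the
    kept paralogous blocks of one ancestral component on one chromosome
    pair); otherwise it is shuffled.  Pairs with unannotated genes are
    skipped.
    """
    hulls = amap.paralogon_hulls()
    by_genome: dict[str, list] = defaultdict(list)
    for key, (side1, side2) in hulls.items():
        by_genome[key[0]].append((side1, side2))

    calls: list[DuplicateCall] = []
    for gene_a, gene_b, genome in wgd_pairs:
        pa = positions.get(gene_a)
        pb = positions.get(gene_b)
        if pa is None or pb is None:
            continue  # unannotated gene: skip with no call
        status = "shuffled"
        paralogon = None
        for side1, side2 in by_genome.get(genome, ()):
            if _inside(pa, side1) and _inside(pb, side2) or _inside(pa, side2) and _inside(pb, side1):
                status = "retained"
                paralogon = (side1[0], side2[0])
                break
        calls.append(DuplicateCall(gene_a, gene_b, genome, status, paralogon))

    summaries = []
    for genome in sorted({c.genome for c in calls}):
        sub = [c for c in calls if c.genome == genome]
        retained = sum(c.status == "retained" for c in sub)
        summaries.append(summarize_partition(genome, len(sub), retained))
    return calls, summaries


def _inside(pos: tuple[str, str, float], side: tuple[str, float, float]) -> bool:
    _, chrom, mid = pos
    s_chrom, lo, hi = side
    return chrom == s_chrom and lo <= mid <= hi


# ---------------------------------------------------------------------------
# shuffled-gene clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShuffledCluster:
    genes: tuple[str, ...]
    genome: str
    chrom: str
    kind: str  # singleton | small | large_shared


def cluster_shuffled(
    shuffled_genes: Iterable[str],
    positions: Mapping[str, tuple[str, str, float]],
    gene_order: Mapping[tuple[str, str], Sequence[str]],
    max_gap_bp: float = 100_000.0,
    max_intervening: int = 3,
    orthogroup_of: Optional[Mapping[str, object]] = None,
) -> list[ShuffledCluster]:
    """Merge co-moved shuffled genes into clusters.

    Shuffled genes on the same destination chromosome merge when their
    midpoints are within ``max_gap_bp`` and at most ``max_intervening``
    genes lie between them.  Cluster sizes 2-4 are flagged ``small``;
    clusters whose member orthogroups recur in >= 2 genomes (orthologous
    destination) are flagged ``large_shared``.
    """
    shuffled = set(shuffled_genes)
    per_chrom: dict[tuple[str, str], list[tuple[float, int, str]]] = defaultdict(list)
    for g in shuffled:
        if g not in positions:
            continue
        genome, chrom, mid = positions[g]
        order = gene_order.get((genome, chrom), ())
        idx = order.index(g) if g in order else -1
        per_chrom[(genome, chrom)].append((mid, idx, g))

    clusters: list[ShuffledCluster] = []
    for (genome, chrom), items in sorted(per_chrom.items()):
        items.sort()
        cur = [items[0]]
        for prev, nxt in zip(items, items[1:]):
            close = nxt[0] - prev[0] <= max_gap_bp and (
                prev[1] < 0 or nxt[1] < 0 or nxt[1] - prev[1] - 1 <= max_intervening
            )
            if close:
                cur.append(nxt)
            else:
                clusters.append(_mk_cluster(cur, genome, chrom))
                cur = [nxt]
        clusters.append(_mk_cluster(cur, genome, chrom))

    if orthogroup_of:
        groups: dict[frozenset, list[int]] = defaultdict(list)
        for i, cl in enumerate(clusters):
            ogs = frozenset(orthogroup_of[g] for g in cl.genes if g in orthogroup_of)
            if ogs:
                groups[ogs].append(i)
        seen: dict[object, set[str]] = defaultdict(set)
        for i, cl in enumerate(clusters):
            for g in cl.genes:
                if g in (orthogroup_of or {}):
                    seen[orthogroup_of[g]].add(cl.genome)
        for i, cl in enumerate(clusters):
            if len(cl.genes) >= 5:
                genomes = set()
                for g in cl.genes:
                    og = (orthogroup_of or {}).get(g)
                    if og is not None:
                        genomes |= seen[og]
                if len(genomes) >= 2:
                    clusters[i] = ShuffledCluster(cl.genes, cl.genome, cl.chrom, "large_shared")
    return clusters


def _mk_cluster(items: list, genome: str, chrom: str) -> ShuffledCluster:
    genes = tuple(g for _, _, g in items)
    kind = "singleton" if len(genes) == 1 else ("small" if len(genes) <= 4 else "large_shared")
    return ShuffledCluster(genes, genome, chrom, kind)


def small_cluster_permil(n_cluster_genes: int, n_shuffled_total: int) -> float:
    """Per-mil rate of shuffled genes that moved in clusters of 2-4."""
    if n_shuffled_total <= 0:
        raise ValueError("no shuffled genes")
    return 1000.0 * n_cluster_genes / n_shuffled_total


# ---------------------------------------------------------------------------
# deletion chronology
# ---------------------------------------------------------------------------

def classify_chronology(
    presence: Mapping[tuple[int, str], Mapping[str, bool]],
    clades: Mapping[str, Sequence[str]],
) -> list[ChronologyCall]:
    """Place each lost duplicate copy on the species tree by small parsimony.

    ``presence[(protogene, copy)][species]`` is True when that post-WGD copy
    survives in that species; ``clades`` maps clade name to its species
    (two clades on a four-leaf tree).  For each copy absent somewhere:

    * absent in all species          -> ``ancestral`` (prespeciation loss)
    * absent in exactly one clade    -> ``lineage_<clade>``
    * absent in exactly one species  -> ``species_specific``
    * other patterns                 -> minimum-loss combination of
      lineage/species events (cross-clade absences are independent losses)

    The protogene must have >= 1 surviving copy in >= 1 species.
    Calls depend only on the absence *set*, so leaf order is irrelevant.
    """
    species = sorted({s for cl in clades.values() for s in cl})
    clade_sets = {name: frozenset(cl) for name, cl in clades.items()}
    calls: list[ChronologyCall] = []
    for (protogene, copy), pres in sorted(presence.items()):
        if not pres:
            raise ValueError("empty presence matrix")
        absent = frozenset(s for s in species if not pres.get(s, False))
        if not absent:
            continue  # copy fully retained: no loss to date
        if absent == frozenset(species):
            call, events = "ancestral", ("ancestral",)
        elif absent in clade_sets.values():
            name = next(n for n, cs in clade_sets.items() if cs == absent)
            call, events = f"lineage_{name}", (f"lineage_{name}",)
        elif len(absent) == 1:
            sp = next(iter(absent))
            call, events = f"species_specific({sp})", (f"species_{sp}",)
        else:
            events_l: list[str] = []
            rest = set(absent)
            for name, cs in sorted(clade_sets.items()):
                if cs <= rest:
                    events_l.append(f"lineage_{name}")
                    rest -= cs
            events_l.extend(f"species_{sp}" for sp in sorted(rest))
            call, events = "composite", tuple(events_l)
        calls.append(ChronologyCall(protogene, copy, absent, call, events))
    return calls


def chronology_summary(calls: Sequence[ChronologyCall]) -> dict[str, int]:
    """Percentages of loss events by chronology class (half-away rounding)."""
    events = [e for c in calls for e in c.events]
    total = len(events)
    out: dict[str, int] = {}
    for e in sorted(set(events)):
        out[e] = round_half_away(100.0 * events.count(e) / total) if total else 0
    return out


# ---------------------------------------------------------------------------
# structural contrast of retained vs shuffled genes
# ---------------------------------------------------------------------------

def feature_contrast(
    retained: Sequence[tuple[float, float]],
    shuffled: Sequence[tuple[float, float]],
    retained_expressed: Optional[Sequence[bool]] = None,
    shuffled_expressed: Optional[Sequence[bool]] = None,
) -> dict:
    """Contrast gene structure between retained and shuffled gene sets.

    Each input row is (gene length bp, exon count).  Returns per-set means
    side by side, an optional expressed fraction, and two-sided rank-sum
    p-values for the length and exon-count comparisons.
    """
    if not retained or not shuffled:
        raise ValueError("empty gene set")
    r = np.asarray(retained, dtype=float)
    s = np.asarray(shuffled, dtype=float)

    def _p(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) == len(y) and np.array_equal(np.sort(x), np.sort(y)):
            return 1.0
        if np.ptp(np.concatenate([x, y])) == 0:
            return 1.0
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    out = {
        "retained": {"mean_length_bp": float(r[:, 0].mean()), "mean_exons": float(r[:, 1].mean())},
        "shuffled": {"mean_length_bp": float(s[:, 0].mean()), "mean_exons": float(s[:, 1].mean())},
        "p_length": _p(r[:, 0], s[:, 0]),
        "p_exons": _p(r[:, 1], s[:, 1]),
    }
    if retained_expressed is not None:
        out["retained"]["expressed_fraction"] = float(np.mean(retained_expressed))
    if shuffled_expressed is not None:
        out["shuffled"]["expressed_fraction"] = float(np.mean(shuffled_expressed))
    return out
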
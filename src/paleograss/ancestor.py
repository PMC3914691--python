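"""Ancestral gene-order reconstruction (contiguous ancestral regions, CARs).

The post-WGD ancestor's gene order is inferred from adjacencies conserved
across descendant genomes: for every genome, each chromosome's gene order
is restricted to genes with an ancestral assignment (orthogroup members;
intervening non-ancestral genes are skipped) and every consecutive
orthogroup pair is recorded as one adjacency observation.  An adjacency is
an *ancestral candidate* only when it is supported in at least one genome
of each clade (root-spanning support) - adjacencies confined to one clade
are lineage specific.  Candidates are then linearized into CARs:
maximum-weight selection of adjacencies subject to each orthogroup having
at most two selected neighbours and no cycles, exact within small conflict
components and greedy beyond.

The pre-duplication order is derived from the post-duplication CARs by
restricting them to orthogroups whose WGD duplicate survives in a sister
CAR, folding duplicate pairs onto one canonical ancestral gene, and merging
the two sister orders by adjacency voting.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

OrderMap = Mapping[str, Mapping[str, Sequence[tuple[str, int]]]]
"""genome -> chromosome -> ordered list of (orthogroup id, orientation)."""


@dataclass
class AdjacencySet:
    """Weighted conserved adjacencies.

    ``adjacencies`` maps a canonical unordered pair (u, v), u < v, to a
    record with the accumulated weight (one per supporting genome;
    orientation-mismatched support counts 0.5), the supporting genomes and
    the first-seen relative orientation.
    """

    adjacencies: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(self, u: str, ou: int, v: str, ov: int, genome: str) -> None:
        if u > v:
            u, v, ou, ov = v, u, -ov, -ou
        key = (u, v)
        rec = self.adjacencies.get(key)
        if rec is None:
            self.adjacencies[key] = {
                "weight": 1.0,
                "genomes": {genome},
                "orientation": (ou, ov),
            }
        elif genome not in rec["genomes"]:
            rec["weight"] += 1.0 if (ou, ov) == rec["orientation"] else 0.5
            rec["genomes"].add(genome)

    def candidates(self, clades: Mapping[str, Sequence[str]]) -> "AdjacencySet":
        """Adjacencies with root-spanning support (>= 1 genome per clade)."""
        out = AdjacencySet()
        for key, rec in self.adjacencies.items():
            if all(rec["genomes"] & set(members) for members in clades.values()):
                out.adjacencies[key] = dict(rec)
        return out

    def weights(self) -> dict[tuple[str, str], float]:
        return {k: rec["weight"] for k, rec in self.adjacencies.items()}


@dataclass
class CAR:
    id: str
    genes: list[str]
    orientations: list[int]
    min_edge_weight: float = 0.0

    def __len__(self) -> int:
        return len(self.genes)


def conserved_adjacencies(orders: OrderMap, skip_duplicated: bool = True) -> AdjacencySet:
    """Record per-genome orthogroup adjacencies.

    Each genome supports a given adjacency at most once, whatever the
    number of occurrences.  With ``skip_duplicated`` a genome in which an
    orthogroup occurs more than once (e.g. after a lineage-specific WGD)
    contributes no observations for that orthogroup; without it, every
    occurrence's neighbourhood is read, which lets a recently reduplicated
    genome still attest ancestral adjacencies.
    """
    adj = AdjacencySet()
    for genome in sorted(orders):
        chrom_orders = orders[genome]
        if skip_duplicated:
            counts: dict[str, int] = defaultdict(int)
            for seq in chrom_orders.values():
                for og, _ in seq:
                    counts[og] += 1
            keep = {og for og, c in counts.items() if c == 1}
        else:
            keep = None
        for chrom in sorted(chrom_orders):
            seq = [(og, o) for og, o in chrom_orders[chrom] if keep is None or og in keep]
            for (u, ou), (v, ov) in itertools.pairwise(seq):
                if u != v:
                    adj.add(u, ou, v, ov, genome)
    return adj


# ---------------------------------------------------------------------------
# linearization: maximum-weight path cover
# ---------------------------------------------------------------------------

def _select_edges(
    edges: list[tuple[float, str, str]], exact_limit: int = 15
) -> tuple[list[tuple[float, str, str]], float]:
    """Select a maximum-weight subset of edges forming vertex-disjoint paths.

    Exact branch-and-bound when the component has few edges, greedy by
    descending weight (ties lexicographic) otherwise.
    """
    edges = sorted(edges, key=lambda e: (-e[0], e[1], e[2]))
    if len(edges) <= exact_limit:
        return _select_exact(edges)
    return _select_greedy(edges)


class _PathState:
    """Union-find with degree tracking for incremental path building."""

    def __init__(self, nodes: Iterable[str]):
        self.parent = {n: n for n in nodes}
        self.degree = {n: 0 for n in nodes}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def can_add(self, u: str, v: str) -> bool:
        if self.degree[u] >= 2 or self.degree[v] >= 2:
            return False
        return self.find(u) != self.find(v)  # reject cycle-closing edges

    def add(self, u: str, v: str) -> None:
        self.parent[self.find(u)] = self.find(v)
        self.degree[u] += 1
        self.degree[v] += 1


def _select_greedy(edges: list[tuple[float, str, str]]):
    nodes = {n for _, u, v in edges for n in (u, v)}
    st = _PathState(nodes)
    chosen: list[tuple[float, str, str]] = []
    for w, u, v in edges:
        if st.can_add(u, v):
            st.add(u, v)
            chosen.append((w, u, v))
    return chosen, sum(w for w, _, _ in chosen)


def _select_exact(edges: list[tuple[float, str, str]]):
    n = len(edges)
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + edges[i][0]
    best: dict = {"w": -1.0, "sel": []}

    def rec(i: int, chosen: list[int], weight: float, st_edges: list[tuple[str, str]]):
        if weight + suffix[i] <= best["w"]:
            return
        if i == n:
            if weight > best["w"]:
                best["w"] = weight
                best["sel"] = list(chosen)
            return
        w, u, v = edges[i]
        nodes = {x for a, b in st_edges for x in (a, b)} | {u, v}
        st = _PathState(nodes)
        ok = True
        for a, b in st_edges:
            st.add(a, b)
        if st.can_add(u, v):
            chosen.append(i)
            st_edges.append((u, v))
            rec(i + 1, chosen, weight + w, st_edges)
            st_edges.pop()
            chosen.pop()
        rec(i + 1, chosen, weight, st_edges)

    rec(0, [], 0.0, [])
    sel = [edges[i] for i in best["sel"]]
    return sel, best["w"]


def linearize_cars(adj: AdjacencySet, exact_limit: int = 15, repair_depth: int = 1) -> list[CAR]:
    """Turn a weighted adjacency set into CARs (vertex-disjoint paths).

    Every orthogroup appearing in any adjacency ends up in exactly one CAR
    (isolated ones as singletons).  Ties are broken lexicographically so the
    output is deterministic.
    """
    # split into connected components of the candidate graph
    graph: dict[str, set[str]] = defaultdict(set)
    for (u, v), rec in adj.adjacencies.items():
        graph[u].add(v)
        graph[v].add(u)
    seen: set[str] = set()
    cars: list[CAR] = []
    for root in sorted(graph):
        if root in seen:
            continue
        comp = _component(graph, root)
        seen |= comp
        comp_edges = [
            (rec["weight"], u, v)
            for (u, v), rec in adj.adjacencies.items()
            if u in comp
        ]
        selected, _ = _select_edges(comp_edges, exact_limit)
        cars.extend(_paths_from_edges(comp, selected, adj))
    paths = _repair_paths([list(c.genes) for c in cars], adj, depth=repair_depth)
    cars = []
    for path in paths:
        weights = [_edge_weight(adj, u, v) for u, v in itertools.pairwise(path)]
        cars.append(CAR("", path, _orient_path(path, adj), min(weights) if weights else 0.0))
    cars.sort(key=lambda c: (-len(c.genes), c.genes[0] if c.genes else ""))
    for i, car in enumerate(cars):
        car.id = f"CAR{i + 1:03d}"
    return cars


def _join_once(paths: list[list[str]], adj: AdjacencySet, banned: frozenset = frozenset()) -> bool:
    """Join two path endpoints connected by an attested adjacency (highest
    weight first).  Returns True when a join happened."""
    end_of: dict[str, int] = {}
    for idx, path in enumerate(paths):
        end_of[path[0]] = idx
        end_of[path[-1]] = idx
    for (u, v), rec in sorted(adj.adjacencies.items(), key=lambda kv: (-kv[1]["weight"], kv[0])):
        if (u, v) in banned:
            continue
        iu, iv = end_of.get(u), end_of.get(v)
        if iu is None or iv is None or iu == iv:
            continue
        a, b = paths[iu], paths[iv]
        if a[0] == u:
            a.reverse()
        if b[-1] == v:
            b.reverse()
        a.extend(b)
        del paths[iv]
        return True
    return False


def _repair_paths(
    paths: list[list[str]],
    adj: AdjacencySet,
    depth: int = 1,
    max_rounds: int = 100,
) -> list[list[str]]:
    """Reduce the number of paths in a path cover without leaving the
    attested adjacency set.

    Moves, iterated to a fixed point: (1) join two endpoints linked by an
    attested adjacency; (2) splice - break the weaker path edge at an
    interior node adjacent to a stranded endpoint and rejoin.  A composite
    move is kept when it lowers (path count, -selected weight)
    lexicographically; with ``depth`` > 1 splices may be chained, which
    resolves breakpoint conflicts (e.g. a subgenome-specific inversion
    giving one node two equal-weight neighbour sets) that no single splice
    can fix.  Greedy edge selection maximises weight, not path count, so
    this repair is what makes contiguous regions come out whole.
    """
    while _join_once(paths, adj):
        pass
    for _ in range(max_rounds):
        target = (len(paths), -_cover_weight(paths, adj))
        better = _search_improvement(paths, adj, target, depth, frozenset())
        if better is None:
            return paths
        paths[:] = better
    return paths


def _search_improvement(
    paths: list[list[str]],
    adj: AdjacencySet,
    target: tuple,
    depth: int,
    banned: frozenset,
    max_candidates: int = 30,
):
    """Depth-limited search for a splice(+joins) composite whose
    (path count, -weight) beats ``target``.  Returns the improved path
    list, or None."""
    interior: dict[str, tuple[int, int]] = {}
    for idx, path in enumerate(paths):
        for pos in range(1, len(path) - 1):
            interior[path[pos]] = (idx, pos)
    endpoints: list[tuple[str, int]] = []
    for idx, path in enumerate(paths):
        endpoints.append((path[0], idx))
        if len(path) > 1:
            endpoints.append((path[-1], idx))

    candidates: list[tuple[float, str, str]] = []
    for e, ei in endpoints:
        for (u, v), rec in adj.adjacencies.items():
            if e not in (u, v):
                continue
            x = v if u == e else u
            hit = interior.get(x)
            if hit is not None and hit[0] != ei:
                candidates.append((-rec["weight"], e, x))
    candidates.sort()

    for _, e, x in candidates[:max_candidates]:
        xi, xpos = interior[x]
        trial = [list(p) for p in paths]
        host = trial[xi]
        w_left = _edge_weight(adj, host[xpos - 1], host[xpos])
        w_right = _edge_weight(adj, host[xpos], host[xpos + 1])
        if w_left < w_right:
            left, right = host[:xpos], host[xpos:]
            broken = tuple(sorted((host[xpos - 1], host[xpos])))
        else:
            left, right = host[: xpos + 1], host[xpos + 1 :]
            broken = tuple(sorted((host[xpos], host[xpos + 1])))
        b2 = banned | {broken}
        trial[xi] = left
        trial.append(right)
        while _join_once(trial, adj, b2):
            pass
        if (len(trial), -_cover_weight(trial, adj)) < target:
            return trial
        if depth > 1:
            deeper = _search_improvement(trial, adj, target, depth - 1, b2, max_candidates=10)
            if deeper is not None:
                return deeper
    return None


def _cover_weight(paths: list[list[str]], adj: AdjacencySet) -> float:
    return sum(
        _edge_weight(adj, u, v) for path in paths for u, v in itertools.pairwise(path)
    )


def _edge_weight(adj: AdjacencySet, u: str, v: str) -> float:
    key = (u, v) if u < v else (v, u)
    rec = adj.adjacencies.get(key)
    return rec["weight"] if rec else 0.0


def _component(graph: Mapping[str, set[str]], root: str) -> set[str]:
    comp, stack = {root}, [root]
    while stack:
        x = stack.pop()
        for y in graph[x]:
            if y not in comp:
                comp.add(y)
                stack.append(y)
    return comp


def _paths_from_edges(
    comp: set[str], selected: list[tuple[float, str, str]], adj: AdjacencySet
) -> list[CAR]:
    nbr: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for w, u, v in selected:
        nbr[u].append((v, w))
        nbr[v].append((u, w))
    out: list[CAR] = []
    visited: set[str] = set()
    endpoints = sorted(n for n in comp if len(nbr[n]) <= 1)
    for start in endpoints:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        weights: list[float] = []
        cur = start
        while True:
            nxt = [(v, w) for v, w in nbr[cur] if v not in visited]
            if not nxt:
                break
            v, w = nxt[0]
            path.append(v)
            weights.append(w)
            visited.add(v)
            cur = v
        out.append(CAR("", path, _orient_path(path, adj), min(weights) if weights else 0.0))
    return out


def _orient_path(path: list[str], adj: AdjacencySet) -> list[int]:
    orient = [1] * len(path)
    for i in range(len(path) - 1):
        u, v = path[i], path[i + 1]
        key, flip = ((u, v), False) if u < v else ((v, u), True)
        rec = adj.adjacencies.get(key)
        if rec is None:
            continue
        ou, ov = rec["orientation"]
        if flip:
            ou, ov = -ov, -ou
        orient[i + 1] = ov if orient[i] == ou else -ov
    return orient


# ---------------------------------------------------------------------------
# pre-duplication order
# ---------------------------------------------------------------------------

def mutual_partners(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    """1-1 duplicate partner map; orthogroups with conflicting partners are
    resolved to the most frequent partner and kept only when mutual."""
    votes: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for u, v in pairs:
        if u == v:
            continue
        votes[u][v] += 1
        votes[v][u] += 1
    best = {u: sorted(c, key=lambda x: (-c[x], x))[0] for u, c in votes.items()}
    return {u: v for u, v in best.items() if best.get(v) == u}


def preduplication_order(
    postdup_cars: Sequence[CAR],
    duplicate_pairs: Iterable[tuple[str, str]],
    orders: Optional[OrderMap] = None,
    min_weight: float = 2.0,
    min_genes: int = 2,
) -> tuple[list[CAR], list[tuple[str, str, int]]]:
    """Merge sister CARs into the pre-WGD ancestral order.

    Only orthogroups whose duplicate partner survives in a sister CAR are
    kept (doubly-attested ancestral genes); duplicate pairs are folded onto
    a canonical id (the lexicographic minimum of the pair).  Adjacency votes
    come from every genome's restricted gene order when ``orders`` is given
    (both subgenome copies vote, so a deletion break on one side is bridged
    by its sister), else from the restricted CAR sequences; votes below
    ``min_weight`` are discarded, which removes single-genome junctions
    created by lineage-specific chromosome fusions.  Returns the merged CARs
    (paths with >= ``min_genes`` genes) and a sister-CAR pairing report of
    (car_id_a, car_id_b, shared duplicate count).
    """
    partner = mutual_partners(duplicate_pairs)
    car_of: dict[str, str] = {}
    for car in postdup_cars:
        for g in car.genes:
            car_of[g] = car.id
    attested = {
        u for u, v in partner.items() if u in car_of and v in car_of
    }
    canonical = {u: min(u, partner[u]) for u in attested}

    # sister-CAR pairing report
    share: dict[tuple[str, str], int] = defaultdict(int)
    for u in attested:
        if u > partner[u]:
            continue  # count each duplicate pair once
        a, b = sorted((car_of[u], car_of[partner[u]]))
        if a != b:
            share[(a, b)] += 1
    pairing = sorted(((a, b, n) for (a, b), n in share.items()), key=lambda t: (-t[2], t[0]))
    for car in postdup_cars:
        if not any(g in attested for g in car.genes):
            warnings.warn(f"{car.id}: no surviving duplicates in any sister CAR; skipped")

    votes = AdjacencySet()
    if orders is not None:
        for genome in sorted(orders):
            for chrom in sorted(orders[genome]):
                seq = [
                    (canonical[og], o)
                    for og, o in orders[genome][chrom]
                    if og in attested
                ]
                for (u, ou), (v, ov) in itertools.pairwise(seq):
                    if u != v:
                        votes.add(u, ou, v, ov, f"{genome}:{chrom}")
    else:
        for car in postdup_cars:
            seq = [
                (canonical[g], o)
                for g, o in zip(car.genes, car.orientations)
                if g in attested
            ]
            for (u, ou), (v, ov) in itertools.pairwise(seq):
                if u != v:
                    votes.add(u, ou, v, ov, car.id)

    kept = AdjacencySet()
    kept.adjacencies = {
        k: rec for k, rec in votes.adjacencies.items() if rec["weight"] >= min_weight
    }
    merged = [car for car in linearize_cars(kept, repair_depth=2) if len(car) >= min_genes]
    for i, car in enumerate(merged):
        car.id = f"preCAR{i + 1:02d}"
    return merged, pairing
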
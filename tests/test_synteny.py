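"""Collinear anchor chaining against an exhaustive-search oracle, and the
cleaning parameters (>5 anchors, 100 kb gap, 100 kb span) on edge cases."""

import itertools

import numpy as np
import pytest

from paleograss.synteny import Anchor, ChainParams, SyntenyBlock, assign_block_ancestry, chain_anchors


def mk_anchors(positions, genome_a="A", genome_b="B", chrom_a="a1", chrom_b="b1", source="ortholog"):
    return [
        Anchor(f"ga{i}", f"gb{i}", chrom_a, pa, chrom_b, pb, genome_a, genome_b, source)
        for i, (pa, pb) in enumerate(positions)
    ]


def chain_is_valid(chain, orientation, max_gap):
    sign = 1 if orientation == "same" else -1
    for p, q in zip(chain, chain[1:]):
        if not (q.pos_a > p.pos_a and sign * (q.pos_b - p.pos_b) > 0):
            return False
        if q.pos_a - p.pos_a > max_gap or abs(q.pos_b - p.pos_b) > max_gap:
            return False
    return True


def oracle_best(anchors, max_gap):
    """Exhaustive DFS over all valid chains; best by (size, side-a span,
    leftmost start), orientation 'same' preferred on full ties."""
    order = sorted(anchors, key=lambda a: a.pos_a)
    best = (0, 0.0, 0.0, "")  # (count, span, -start, orientation marker)
    for orientation in ("same", "inverted"):
        sign = 1 if orientation == "same" else -1

        def extend(last_idx, chain):
            nonlocal best
            count = len(chain)
            if count:
                span = chain[-1].pos_a - chain[0].pos_a
                key = (count, span, -chain[0].pos_a, 1.0 if orientation == "same" else 0.0)
                if key > best:
                    best = key
            for j in range(last_idx + 1, len(order)):
                nxt = order[j]
                if chain:
                    prev = chain[-1]
                    if not (nxt.pos_a > prev.pos_a and sign * (nxt.pos_b - prev.pos_b) > 0):
                        continue
                    if nxt.pos_a - prev.pos_a > max_gap or abs(nxt.pos_b - prev.pos_b) > max_gap:
                        continue
                chain.append(nxt)
                extend(j, chain)
                chain.pop()

        extend(-1, [])
    return best


class TestChaining:
    def test_perfect_diagonal_single_block(self):
        anchors = mk_anchors([(i * 20_000, i * 20_000) for i in range(10)])
        blocks = chain_anchors(anchors, ChainParams(6, 100_000, 100_000))
        assert len(blocks) == 1
        assert blocks[0].anchor_count == 10
        assert blocks[0].orientation == "same"

    def test_gap_splits_and_min_anchors_discards(self):
        # anchors 0..4 then a 150 kb jump to 5..9: two 5-anchor fragments
        pos = [(i * 20_000, i * 20_000) for i in range(5)]
        pos += [(230_000 + i * 20_000, 230_000 + i * 20_000) for i in range(5)]
        blocks = chain_anchors(mk_anchors(pos), ChainParams(6, 100_000, 0))
        assert blocks == []  # both fragments below min_anchors
        blocks = chain_anchors(mk_anchors(pos), ChainParams(5, 100_000, 0))
        assert sorted(b.anchor_count for b in blocks) == [5, 5]

    def test_span_rule_enforced_exactly(self):
        # 6 anchors spanning exactly 100 kb: kept; 6 spanning 90 kb: dropped
        keep = mk_anchors([(i * 20_000, i * 20_000) for i in range(6)])
        drop = mk_anchors([(i * 18_000, i * 18_000) for i in range(6)])
        params = ChainParams(6, 100_000, 100_000)
        assert len(chain_anchors(keep, params)) == 1
        assert chain_anchors(drop, params) == []

    def test_gap_rule_boundary(self):
        # exactly 100 kb gap allowed, 100 kb + 1 splits
        ok = mk_anchors([(0, 0), (100_000, 100_000), (200_000, 200_000)])
        split = mk_anchors([(0, 0), (100_001, 100_001), (200_002, 200_002)])
        params = ChainParams(2, 100_000, 0)
        assert chain_anchors(ok, params)[0].anchor_count == 3
        assert max((b.anchor_count for b in chain_anchors(split, params)), default=0) < 3

    def test_inverted_block_detected(self):
        anchors = mk_anchors([(i * 20_000, (9 - i) * 20_000) for i in range(10)])
        blocks = chain_anchors(anchors, ChainParams(6, 100_000, 100_000))
        assert blocks[0].orientation == "inverted"
        assert blocks[0].anchor_count == 10

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(99)
        params = ChainParams(1, 100_000, 0)
        for _ in range(100):
            n = int(rng.integers(6, 16))
            # domain-like instance: a noisy diagonal plus scattered anchors
            pos = []
            for i in range(n):
                if rng.random() < 0.7:
                    base = i * 30_000
                    pos.append((base, base + float(rng.integers(-15_000, 15_000))))
                else:
                    pos.append((float(rng.integers(0, 500_000)), float(rng.integers(0, 500_000))))
            anchors = mk_anchors(pos)
            blocks = chain_anchors(anchors, params)
            count, span, negstart, _ = oracle_best(anchors, params.max_gap_bp)
            assert blocks, "oracle found a chain but implementation returned none"
            top = max(blocks, key=lambda b: (b.anchor_count, b.span_a, -b.side_a[2]))
            assert top.anchor_count == count
            assert top.span_a == pytest.approx(span)
            assert -top.side_a[2] == pytest.approx(negstart)
            assert chain_is_valid(top.anchors, top.orientation, params.max_gap_bp)

    def test_no_anchor_in_two_blocks(self):
        rng = np.random.default_rng(5)
        pos = [(float(rng.integers(0, 400_000)), float(rng.integers(0, 400_000))) for _ in range(40)]
        blocks = chain_anchors(mk_anchors(pos), ChainParams(3, 100_000, 0))
        seen = set()
        for b in blocks:
            for a in b.anchors:
                assert a.gene_a not in seen
                seen.add(a.gene_a)

    def test_symmetry_under_side_swap(self):
        pos = [(i * 20_000, i * 20_000 + 3_000) for i in range(8)] + [(45_000, 310_000)]
        fwd = chain_anchors(mk_anchors(pos), ChainParams(3, 100_000, 0))
        swapped = [
            Anchor(a.gene_b, a.gene_a, a.chrom_b, a.pos_b, a.chrom_a, a.pos_a, a.genome_b, a.genome_a, a.source)
            for a in mk_anchors(pos)
        ]
        rev = chain_anchors(swapped, ChainParams(3, 100_000, 0))
        fwd_sets = sorted(sorted(a.gene_a for a in b.anchors) for b in fwd)
        rev_sets = sorted(sorted(a.gene_b for a in b.anchors) for b in rev)
        assert fwd_sets == rev_sets


class TestAncestry:
    def _block(self, ga, ca, pa0, gb, cb, pb0, source, n=6):
        anchors = [
            Anchor(f"{ga}{ca}{i}", f"{gb}{cb}{i}", ca, pa0 + i * 20_000, cb, pb0 + i * 20_000, ga, gb, source)
            for i in range(n)
        ]
        return SyntenyBlock(anchors, "same", source)

    def test_orthologous_duplicates_merge_into_one_component(self):
        # paralogous blocks at orthologous positions in two genomes: one ancestor
        blocks = [
            self._block("A", "a1", 0, "A", "a2", 0, "paralog"),
            self._block("B", "b1", 0, "B", "b2", 0, "paralog"),
            self._block("A", "a1", 0, "B", "b1", 0, "ortholog"),
            self._block("A", "a2", 0, "B", "b2", 0, "ortholog"),
        ]
        amap = assign_block_ancestry(blocks)
        assert len(set(amap.block_labels)) == 1
        label = amap.block_labels[0]
        assert amap.component_flags[label] == "ancestral_duplication"

    def test_single_genome_paralogy_is_lineage_specific(self):
        blocks = [self._block("A", "a1", 0, "A", "a2", 0, "paralog")]
        amap = assign_block_ancestry(blocks)
        assert list(amap.component_flags.values()) == ["lineage_specific"]

    def test_locate_and_hulls(self):
        blocks = [
            self._block("A", "a1", 0, "A", "a2", 0, "paralog"),
            self._block("A", "a1", 80_000, "A", "a2", 80_000, "paralog"),
        ]
        amap = assign_block_ancestry(blocks)
        assert len(set(amap.block_labels)) == 1  # overlapping sides merge
        label = amap.block_labels[0]
        assert amap.locate("A", "a1", 50_000) == label
        assert amap.locate("A", "a9", 50_000) is None
        hulls = amap.paralogon_hulls()
        (c1, lo1, hi1), (c2, lo2, hi2) = next(iter(hulls.values()))
        assert lo1 == 0 and hi1 >= 180_000  # merged span of both blocks
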
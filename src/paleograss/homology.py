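"""HSP-aggregate homology metrics (AL, CIP, CALP) and pair filtering.

Pairwise BLAST output for a gene pair usually consists of several high
scoring pairs (HSPs).  Rather than judging individual HSPs, the pair is
scored on their aggregate:

* ``AL``   - aligned length: the number of *distinct* query columns covered
  by HSPs.  Overlapping HSP query intervals are clipped so each query
  column counts once, with identities prorated by the clipped fraction.
* ``CIP``  - cumulative identity percentage: 100 * (sum of clipped
  identities) / AL.
* ``CALP`` - cumulative alignment length percentage: 100 * AL / query
  length.  Clipping guarantees CALP <= 100.

Acceptance thresholds depend on the divergence of the two genomes being
compared: closely related genomes (common ancestor < 50 Ma) use CIP/CALP
70/70, distant ones (> 50 Ma) use 50/50.  Both are configurable through
:class:`FilterPolicy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence


class MalformedInputError(ValueError):
    pass


class UndefinedMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class HSP:
    """One high scoring pair, coordinates 1-based inclusive as in BLAST tabular."""

    query_id: str
    subject_id: str
    aln_length: int
    identities: int
    query_start: int
    query_end: int
    subject_start: int = 0
    subject_end: int = 0
    bitscore: float = 0.0

    def normalized(self) -> "HSP":
        """Return an HSP with query_start <= query_end."""
        if self.query_start <= self.query_end:
            return self
        return HSP(
            self.query_id,
            self.subject_id,
            self.aln_length,
            self.identities,
            self.query_end,
            self.query_start,
            self.subject_end,
            self.subject_start,
            self.bitscore,
        )


@dataclass(frozen=True)
class HomologyMetrics:
    query_id: str
    subject_id: str
    AL: float
    CIP: float  # percent in [0, 100]
    CALP: float  # percent in [0, 100]
    bitscore: float = 0.0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.query_id, self.subject_id)

    @property
    def score(self) -> float:
        """Score used for best-hit selection: bit score when present, else CIP*CALP."""
        return self.bitscore if self.bitscore > 0 else self.CIP * self.CALP


@dataclass(frozen=True)
class FilterPolicy:
    """CIP/CALP acceptance thresholds for one genome-relationship class."""

    relationship_class: str  # "close" (<50 Ma) or "distant" (>50 Ma)
    cip_min: float
    calp_min: float

    def __post_init__(self) -> None:
        for t in (self.cip_min, self.calp_min):
            if not 0 < t <= 100:
                raise ValueError("thresholds must lie in (0, 100]")


#: Default policies: the 70%/50% thresholds read symmetrically for both metrics.
CLOSE_POLICY = FilterPolicy("close", 70.0, 70.0)
DISTANT_POLICY = FilterPolicy("distant", 50.0, 50.0)


def compute_homology_metrics(hsps: Sequence[HSP], query_length: int) -> HomologyMetrics:
    """Aggregate the HSPs of one gene pair into AL / CIP / CALP.

    HSPs are sorted by query start; query intervals already covered by an
    earlier HSP are clipped away and the HSP's identities are prorated by
    the surviving fraction of its query span.
    """
    if not hsps:
        raise UndefinedMetricsError("empty HSP set")
    if query_length <= 0:
        raise MalformedInputError("query_length must be positive")
    pairs = {(h.query_id, h.subject_id) for h in hsps}
    if len(pairs) != 1:
        raise MalformedInputError("all HSPs must share the same (query, subject) pair")

    al = 0.0
    ident = 0.0
    covered_end = 0  # rightmost query column already counted (1-based inclusive)
    for hsp in sorted((h.normalized() for h in hsps), key=lambda h: (h.query_start, h.query_end)):
        if hsp.identities > hsp.aln_length or hsp.identities < 0:
            raise MalformedInputError(
                f"identities {hsp.identities} > alignment length {hsp.aln_length}"
                if hsp.identities > hsp.aln_length
                else "negative identities"
            )
        q_lo = max(hsp.query_start, covered_end + 1)
        q_hi = min(hsp.query_end, query_length)
        if q_hi < q_lo:
            continue
        span = hsp.query_end - hsp.query_start + 1
        clipped = q_hi - q_lo + 1
        al += clipped
        ident += hsp.identities * (clipped / span)
        covered_end = max(covered_end, q_hi)

    q, s = next(iter(pairs))
    if al == 0:
        return HomologyMetrics(q, s, 0.0, 0.0, 0.0)
    cip = 100.0 * ident / al
    calp = 100.0 * al / query_length
    bits = max(h.bitscore for h in hsps)
    return HomologyMetrics(q, s, al, min(cip, 100.0), min(calp, 100.0), bits)


def filter_pairs(
    metrics: Iterable[HomologyMetrics], policy: FilterPolicy
) -> list[HomologyMetrics]:
    """Keep pairs with CIP >= cip_min and CALP >= calp_min; drop self-pairs."""
    return [
        m
        for m in metrics
        if m.query_id != m.subject_id
        and m.CIP >= policy.cip_min
        and m.CALP >= policy.calp_min
    ]


def reciprocal_best_pairs(
    accepted: Iterable[HomologyMetrics],
    scope: str = "inter_genome",
    genome_of: Optional[Mapping[str, str]] = None,
) -> set[frozenset]:
    """Reduce accepted pairs to candidate orthologs (inter) or paralogs (intra).

    ``inter_genome``: keep (a, b) iff b is a's best subject and a is b's best
    subject (reciprocal best hit), computed per genome pair when a
    ``genome_of`` mapping is supplied.  ``intra_genome``: keep each gene's
    best non-self hit, deduplicated to unordered pairs.  Ties are broken
    lexicographically by subject id.
    """
    if scope not in ("inter_genome", "intra_genome"):
        raise ValueError(f"unknown scope {scope!r}")

    # best[bucket][query] = (score, subject); bucket separates genome pairs
    best: dict[tuple, tuple[float, str]] = {}
    for m in accepted:
        if m.query_id == m.subject_id:
            continue
        if scope == "inter_genome" and genome_of is not None:
            bucket = (m.query_id, genome_of[m.subject_id])
        else:
            bucket = (m.query_id,)
        cur = best.get(bucket)
        cand = (m.score, m.subject_id)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[bucket] = cand

    best_of: dict[tuple, str] = {k: v[1] for k, v in best.items()}
    out: set[frozenset] = set()
    if scope == "intra_genome":
        for (q,), s in best_of.items():
            out.add(frozenset((q, s)))
        return out
    for (q, _), s in best_of.items():
        if genome_of is not None:
            back = best_of.get((s, genome_of[q]))
        else:
            back = best_of.get((s,))
        if back == q:
            out.add(frozenset((q, s)))
    return out
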
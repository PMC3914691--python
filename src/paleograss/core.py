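"""Core domain objects shared across the pipeline.

A :class:`Genome` is an ordered collection of :class:`Chromosome` objects,
each holding an ordered list of :class:`Gene` models.  Gene order is the
primary coordinate system during simulation; base-pair coordinates are laid
out on a uniform grid (``layout``) when a genome is finalised or written to
disk.  Every gene carries the identifier of the ancestral protogene it
descends from, together with the subgenome label (dominant ``D`` or
sensitive ``S``) acquired at whole-genome duplication, which is what makes
downstream truth-based recovery tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

EVENT_KINDS = frozenset(
    {
        "WGD",
        "CCF",
        "TCF",
        "fission",
        "inversion",
        "deletion",
        "transposition",
        "tandem_duplication",
        "segmental_deletion",
        "translocation",
    }
)


@dataclass
class Gene:
    """A gene model with ancestry bookkeeping.

    ``protogene`` is the index of the ancestral gene; ``anc_chrom`` the
    protochromosome (1-based) it sat on; ``subgenome`` the D/S label from the
    shared WGD; ``recent_copy`` the D/S label from a lineage-specific WGD if
    one occurred on the gene's lineage.
    """

    id: str
    protogene: int
    anc_chrom: int
    subgenome: Optional[str] = None
    recent_copy: Optional[str] = None
    strand: int = 1
    origin: str = "ancestral"  # ancestral | tandem
    exon_count: int = 8
    length: int = 3000
    cds_length: int = 450
    moved: bool = False
    chrom: Optional[str] = None
    start: int = -1
    end: int = -1

    @property
    def ancestral_id(self) -> tuple[int, Optional[str]]:
        """Identity of the post-WGD ancestral gene copy this gene descends from."""
        return (self.protogene, self.subgenome)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Centromere:
    pos: float  # position in gene-index units
    functional: bool = True


@dataclass
class Chromosome:
    name: str
    genes: list[Gene] = field(default_factory=list)
    centromeres: list[Centromere] = field(default_factory=list)
    subgenome: Optional[str] = None  # D/S of the shared WGD for the whole chromosome
    anc_chrom: Optional[int] = None

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def functional_centromeres(self) -> list[Centromere]:
        return [c for c in self.centromeres if c.functional]


@dataclass
class Genome:
    name: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def genes(self) -> Iterator[Gene]:
        for chrom in self.chromosomes:
            yield from chrom.genes

    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def get_chromosome(self, name: str) -> Chromosome:
        for chrom in self.chromosomes:
            if chrom.name == name:
                return chrom
        raise KeyError(f"no chromosome named {name!r} in genome {self.name!r}")

    def layout(self, spacing: int = 10_000, gene_length: int = 3_000) -> None:
        """Assign base-pair coordinates on a uniform grid: gene *i* starts at
        ``i * spacing`` (0-based half-open intervals)."""
        for chrom in self.chromosomes:
            for i, gene in enumerate(chrom.genes):
                gene.chrom = chrom.name
                gene.start = i * spacing
                gene.end = i * spacing + gene.length if gene.length else i * spacing + gene_length


@dataclass
class EvolutionEvent:
    """One event of the closed rearrangement grammar.

    ``operands`` holds kind-specific payload (chromosome names, gene ids,
    breakpoints); breakpoints are validated against operand bounds by the
    code that applies the event.
    """

    kind: str
    lineage: str
    time: float  # Myr before present
    operands: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
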
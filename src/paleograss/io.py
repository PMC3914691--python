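"""Readers and writers for the standard formats used by the pipeline.

Gene models travel as GFF3 (gene features, ``ID=`` attribute, 1-based
inclusive coordinates converted to 0-based half-open internally) or BED6
(already 0-based half-open); homology as 12-column BLAST tabular
(outfmt 6); everything tabular goes through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import Genome
from .homology import HSP

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand", "exons", "length", "cds_length"]


class FormatError(ValueError):
    pass


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            for gene in chrom.genes:
                attrs = f"ID={gene.id};exons={gene.exon_count};cds_length={gene.cds_length}"
                fh.write(
                    "\t".join(
                        [
                            chrom.name,
                            "paleograss",
                            "gene",
                            str(gene.start + 1),  # GFF3 is 1-based inclusive
                            str(gene.end),
                            ".",
                            "+" if gene.strand > 0 else "-",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_bed(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            for gene in chrom.genes:
                fh.write(
                    f"{chrom.name}\t{gene.start}\t{gene.end}\t{gene.id}\t0\t"
                    f"{'+' if gene.strand > 0 else '-'}\n"
                )


def load_genome(path: str | Path, fasta: Optional[str | Path] = None) -> pd.DataFrame:
    """Load gene models from GFF3 or BED into a normalized gene table.

    Coordinates are 0-based half-open; genes are sorted by (chrom, start).
    Exon counts come from an ``exons=`` attribute or exon child features
    when present, else 1.  CDS lengths come from the companion FASTA when
    given, else from a ``cds_length=`` attribute, else the genomic length.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"],
            comment="#",
        )
        df["exons"] = 1
        df["strand"] = df["strand"].map({"+": 1, "-": -1}).fillna(1).astype(int)
    else:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attrs"],
        )
        genes = raw[raw["type"] == "gene"].copy()
        genes["gene"] = genes["attrs"].str.extract(r"ID=([^;]+)")
        genes["exons"] = (
            genes["attrs"].str.extract(r"exons=(\d+)")[0].fillna("1").astype(int)
        )
        cds = genes["attrs"].str.extract(r"cds_length=(\d+)")[0]
        genes["cds_length"] = pd.to_numeric(cds, errors="coerce")
        genes["start"] = genes["start"].astype(int) - 1  # to 0-based half-open
        genes["end"] = genes["end"].astype(int)
        genes["strand"] = genes["strand"].map({"+": 1, "-": -1}).fillna(1).astype(int)
        exon_counts = raw[raw["type"] == "exon"]
        if len(exon_counts):
            parents = exon_counts["attrs"].str.extract(r"Parent=([^;]+)")[0].value_counts()
            genes["exons"] = genes["gene"].map(parents).fillna(genes["exons"]).astype(int)
        df = genes[["gene", "chrom", "start", "end", "strand", "exons", "cds_length"]]
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"duplicate gene ID {dups!r} in {path}")
    df = df.copy()
    df["length"] = df["end"] - df["start"]
    if "cds_length" not in df or df["cds_length"].isna().all():
        df["cds_length"] = df["length"]
    df["cds_length"] = df["cds_length"].fillna(df["length"]).astype(int)
    if fasta is not None:
        from Bio import SeqIO

        lens = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        df["cds_length"] = df["gene"].map(lens).fillna(df["cds_length"]).astype(int)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)[GENE_COLUMNS]


def load_hsps(path: str | Path) -> dict[tuple[str, str], list[HSP]]:
    """Read BLAST tabular (outfmt 6) and group HSPs by (query, subject).

    Identities are reconstituted as round(pident * length / 100);
    reverse-coordinate HSPs are normalized.  Malformed rows raise with the
    offending line number.
    """
    out: dict[tuple[str, str], list[HSP]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                bits = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            hsp = HSP(
                q, s, length, int(round(pident * length / 100.0)), qstart, qend, sstart, send, bits
            ).normalized()
            out.setdefault((q, s), []).append(hsp)
    if not out:
        import warnings

        warnings.warn(f"{path}: no HSP rows")
    return out


def read_ks_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene1", "gene2", "ks"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: Ks table needs columns {sorted(required)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
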
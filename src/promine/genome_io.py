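"""Genome sequence / annotation I/O and strand-aware coordinate algebra.

All coordinates inside the package are 0-based half-open; GFF3's 1-based
inclusive convention is converted at the parsing/writing boundary.  Upstream
regions are always returned 5'->3' in the gene's transcription orientation,
so downstream promoter scanning never has to think about strand.
"""

from __future__ import annotations

import io

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "GenomeRegion",
    "AnnotationError",
    "parse_annotation",
    "write_annotation",
    "upstream_region",
    "reverse_complement",
]


class AnnotationError(ValueError):
    """Raised for inconsistent annotation/sequence input."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Gene:
    """An annotated coding feature — the unit of promoter selection.

    ``start``/``end`` are 0-based half-open on the plus strand of ``contig``;
    ``strand`` is '+' or '-'.  ``product`` carries the free-text functional
    annotation (used for chaperone keyword matching); ``operon`` an optional
    operon tag carried through from the GFF3 attributes.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    operon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeRegion:
    """A strand-aware slice of the genome.

    ``start``/``end`` are plus-strand 0-based half-open coordinates;
    ``sequence`` is the region text read 5'->3' on ``strand`` (i.e. the
    reverse complement of the plus-strand text when ``strand`` is '-').
    ``truncated`` flags windows clipped at a contig boundary.
    """

    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"region {self.contig}:[{self.start},{self.end}) sequence length "
                f"{len(self.sequence)} != span {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def absolute_position(self, offset: int) -> int:
        """Plus-strand coordinate of the base at ``offset`` in transcription orientation."""
        if not 0 <= offset < len(self):
            raise IndexError(f"offset {offset} outside region of length {len(self)}")
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset


def _gene_from_feature(feat) -> Gene:
    attrs = feat.attributes
    gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
    if gene_id is None:
        raise AnnotationError(f"feature at {feat.seqid}:{feat.start}-{feat.end} has no ID")
    product = (attrs.get("product") or [""])[0]
    operon = (attrs.get("operon") or [None])[0]
    return Gene(
        gene_id=gene_id,
        contig=feat.seqid,
        start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
        end=feat.end,
        strand=feat.strand,
        product=product,
        operon=operon,
    )


def parse_annotation(
    gff: str | Path | io.StringIO,
    fasta: str | Path | io.StringIO,
) -> tuple[list[Gene], dict[str, str]]:
    """Read a GFF3 + FASTA pair into Gene records and contig sequences.

    Only CDS features are read.  Coordinates are converted to the internal
    0-based half-open convention, every gene is bounds-checked against its
    contig, and duplicate gene ids or missing contigs are hard errors.
    Returns ``(genes, contigs)`` with genes sorted by (contig, start).
    """
    if hasattr(fasta, "read"):
        fasta_handle = fasta
    else:
        fasta_handle = open(fasta)
    try:
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_handle, "fasta")}
    finally:
        if fasta_handle is not fasta:
            fasta_handle.close()

    if hasattr(gff, "read"):
        gff_text = gff.read()
    else:
        gff_text = Path(gff).read_text()

    try:
        db = gffutils.create_db(
            gff_text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:
        raise AnnotationError(f"duplicate or malformed feature in GFF3: {exc}") from exc
    genes: list[Gene] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene = _gene_from_feature(feat)
        if gene.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r} in annotation")
        seen.add(gene.gene_id)
        if gene.contig not in contigs:
            raise AnnotationError(
                f"gene {gene.gene_id!r}: contig {gene.contig!r} has no sequence in FASTA"
            )
        if gene.end > len(contigs[gene.contig]):
            raise AnnotationError(
                f"gene {gene.gene_id!r}: [{gene.start},{gene.end}) exceeds contig "
                f"{gene.contig!r} length {len(contigs[gene.contig])}"
            )
        genes.append(gene)
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes, contigs


def write_annotation(
    genes: Iterable[Gene],
    contigs: Mapping[str, str],
    gff_path: str | Path,
    fasta_path: str | Path,
    line_width: int = 70,
) -> None:
    """Write genes + contigs back out as GFF3 (CDS features) and FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(contigs):
            fh.write(f"##sequence-region {name} 1 {len(contigs[name])}\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.operon:
                attrs.append(f"operon={g.operon}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "promine",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    with open(fasta_path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def upstream_region(gene: Gene, window: int, contigs: Mapping[str, str]) -> GenomeRegion:
    """Extract the ``window`` bp immediately upstream of a gene's start codon.

    The region is returned 5'->3' in the gene's transcription orientation
    (reverse-complemented for minus-strand genes), truncated (and flagged) at
    contig boundaries.  A gene flush against a contig edge yields an empty,
    flagged region rather than an error.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    contig_seq = contigs[gene.contig]
    L = len(contig_seq)
    if gene.strand == "+":
        start = max(0, gene.start - window)
        end = gene.start
        seq = contig_seq[start:end]
    else:
        start = gene.end
        end = min(L, gene.end + window)
        seq = reverse_complement(contig_seq[start:end])
    truncated = (end - start) < window
    return GenomeRegion(
        contig=gene.contig,
        start=start,
        end=end,
        strand=gene.strand,
        sequence=seq,
        truncated=truncated,
    )


def write_regions_fasta(regions: Mapping[str, GenomeRegion], path: str | Path) -> None:
    """Write named regions as FASTA (ids are the mapping keys)."""
    with open(path, "w") as fh:
        for name in sorted(regions):
            r = regions[name]
            fh.write(f">{name} {r.contig}:{r.start}-{r.end}({r.strand})\n{r.sequence}\n")
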
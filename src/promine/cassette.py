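"""Assembly of cloning-ready promoter cassettes.

A cassette covers everything RNA polymerase and the ribosome need: a 60 bp
extension upstream of the most distal predicted -35 box (room for AT-rich
UP-elements), the predicted core promoter(s), and the native 5'-UTR up to —
and including — the base immediately before the start codon.  Tandem
promoters in the same window are all retained inside one cassette.  A
Shine-Dalgarno heuristic (>= 4/6 match to AGGAGG with its 3' end 5-15 nt
before the start codon) is a QC flag only; it never filters a cassette.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from promine.genome_io import Gene, GenomeRegion, reverse_complement
from promine.promoter_scan import PromoterHit

__all__ = [
    "PromoterCassette",
    "assemble_cassette",
    "find_sd",
    "write_cassettes",
    "SD_CONSENSUS",
]

SD_CONSENSUS = "AGGAGG"
SD_SEARCH_WINDOW = 20   # nt of cassette tail searched
SD_MIN_MATCHES = 4      # of 6 consensus positions
SD_OFFSET_RANGE = (5, 15)  # nt between match 3' end and the start codon


@dataclass(frozen=True)
class PromoterCassette:
    """The assembled promoter fragment for one gene.

    ``span`` is in transcription orientation; its last base is the nucleotide
    immediately adjacent to the first base of the start codon.  ``components``
    maps ``up_element`` / ``core_promoters`` / ``utr`` to cassette-local
    half-open intervals (core_promoters is a tuple of per-hit intervals).
    """

    gene_id: str
    span: GenomeRegion
    components: Mapping[str, object]
    hits: tuple[PromoterHit, ...]
    sd_found: bool
    sd_offset: int | None
    truncated: bool

    @property
    def sequence(self) -> str:
        return self.span.sequence

    def __len__(self) -> int:
        return len(self.span.sequence)


def find_sd(cassette_sequence: str) -> tuple[bool, int | None]:
    """Look for a Shine-Dalgarno motif in the cassette tail.

    Scans the final 20 nt for the best ungapped match to AGGAGG.  Found iff
    some 6-mer matches >= 4/6 consensus positions with its 3' end lying 5-15
    nt upstream of the start codon (the cassette's last base being 1 nt
    upstream).  Among qualifying windows the one with most matches wins, ties
    going to the most start-codon-proximal.  Returns (found, offset) where
    offset is the distance in nt from the match 3' end to the start codon.
    """
    seq = cassette_sequence.upper()
    n = len(seq)
    if n < SD_SEARCH_WINDOW:
        return False, None
    best: tuple[int, int] | None = None  # (matches, -offset) for max-comparison
    best_offset = None
    lo, hi = SD_OFFSET_RANGE
    for p in range(max(0, n - SD_SEARCH_WINDOW), n - 5):
        offset = n - (p + 5)  # 3' end at index p+5; last base is 1 nt upstream
        if not lo <= offset <= hi:
            continue
        matches = sum(1 for a, b in zip(seq[p : p + 6], SD_CONSENSUS) if a == b)
        if matches < SD_MIN_MATCHES:
            continue
        key = (matches, -offset)
        if best is None or key > best:
            best, best_offset = key, offset
    return (best is not None), best_offset


def assemble_cassette(
    gene: Gene,
    hits: Sequence[PromoterHit],
    window: GenomeRegion,
    contigs: Mapping[str, str],
    up_ext: int = 60,
) -> PromoterCassette | None:
    """Build the cassette for one gene from its scan hits.

    The span runs from ``up_ext`` bp upstream of the most distal hit's -35
    box (clamped to the contig, flagged when truncated) through the base
    1 bp before the start codon.  An empty hit list means a silent upstream
    region: returns None rather than raising.
    """
    if not hits:
        return None
    hits = tuple(sorted(hits, key=lambda h: (h.offset_minus35, -h.norm_score)))
    contig_seq = contigs[gene.contig]
    L = len(contig_seq)
    distal = hits[0]
    # plus-strand coordinate of the 5'-most base of the distal -35 box
    abs35 = window.absolute_position(distal.offset_minus35)
    truncated = window.truncated
    if gene.strand == "+":
        span_start = abs35 - up_ext
        if span_start < 0:
            span_start, truncated = 0, True
        span_end = gene.start
        seq = contig_seq[span_start:span_end]
    else:
        span_end = abs35 + 1 + up_ext
        if span_end > L:
            span_end, truncated = L, True
        span_start = gene.end
        seq = reverse_complement(contig_seq[span_start:span_end])
    span = GenomeRegion(
        contig=gene.contig,
        start=span_start,
        end=span_end,
        strand=gene.strand,
        sequence=seq,
        truncated=truncated,
    )
    # cassette-local coordinates (transcription orientation)
    shift = len(span) - len(window)  # offset of window base 0 inside the cassette
    cores = tuple(
        (h.offset_minus35 + shift, h.offset_minus10 + 6 + shift) for h in hits
    )
    up_element = (0, cores[0][0])
    utr = (max(c[1] for c in cores), len(span))
    sd_found, sd_offset = find_sd(seq)
    return PromoterCassette(
        gene_id=gene.gene_id,
        span=span,
        components={"up_element": up_element, "core_promoters": cores, "utr": utr},
        hits=hits,
        sd_found=sd_found,
        sd_offset=sd_offset,
        truncated=truncated,
    )


def write_cassettes(
    cassettes: Sequence[PromoterCassette],
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write cassettes as FASTA (ids = gene ids) plus a TSV report with the
    span, component coordinates, best score and SD flag; ordering is
    deterministic by gene id."""
    ordered = sorted(cassettes, key=lambda c: c.gene_id)
    with open(fasta_path, "w") as fh:
        for c in ordered:
            fh.write(
                f">{c.gene_id} {c.span.contig}:{c.span.start}-{c.span.end}"
                f"({c.span.strand})\n{c.sequence}\n"
            )
    header = [
        "gene_id", "contig", "span_start", "span_end", "strand", "length",
        "n_promoters", "best_norm_score", "up_element", "core_promoters",
        "utr", "sd_found", "sd_offset", "truncated",
    ]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in ordered:
            comps = c.components
            cores = ";".join(f"{a}-{b}" for a, b in comps["core_promoters"])
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.gene_id, c.span.contig, c.span.start, c.span.end,
                        c.span.strand, len(c),
                        len(c.hits),
                        f"{max(h.norm_score for h in c.hits):.4f}",
                        f"{comps['up_element'][0]}-{comps['up_element'][1]}",
                        cores,
                        f"{comps['utr'][0]}-{comps['utr'][1]}",
                        c.sd_found,
                        c.sd_offset if c.sd_offset is not None else "",
                        c.truncated,
                    ]
                )
                + "\n"
            )
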
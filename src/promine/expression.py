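"""Operon-aware expression ranking: RPKM, operon collapse, top-K intersection.

The selection flow mirrors common practice for promoter mining from
prokaryotic RNA-seq: keep expressed genes, collapse each operon to its first
(5'-most) gene because internal genes have no promoter of their own,
intersect the top-K rankings of two growth conditions, and keep the top-N by
mean RPKM.  Annotated molecular chaperones are pulled in separately,
regardless of expression, since chaperone promoters are a classically strong
class in coryneform bacteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from promine.genome_io import Gene

__all__ = [
    "ExpressionProfile",
    "Operon",
    "CandidateSet",
    "read_counts_tsv",
    "write_counts_tsv",
    "compute_rpkm",
    "expressed_genes",
    "operons_from_annotation",
    "infer_operons",
    "collapse_operons",
    "select_top_shared",
    "select_top_n_by_mean",
    "select_chaperones",
]

#: case-insensitive substrings matched against Gene.product
DEFAULT_CHAPERONE_KEYWORDS = (
    "molecular chaperone",
    "co-chaperone",
    "groel",
    "groes",
    "dnak",
    "dnaj",
)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-sample gene -> read-count map with its library size.

    ``library_size`` is the total number of mapped reads; it need not equal
    the sum of per-gene counts (multi-mapping reads), but must be positive.
    """

    sample_id: str
    counts: Mapping[str, int]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id!r}: library_size must be > 0")
        bad = [g for g, c in self.counts.items() if c < 0]
        if bad:
            raise ValueError(f"sample {self.sample_id!r}: negative counts for {bad[:5]}")


@dataclass(frozen=True)
class Operon:
    """Adjacent co-transcribed genes; members listed in transcription order."""

    operon_id: str
    member_gene_ids: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError(f"operon {self.operon_id!r}: needs >= 2 members")
        if len(set(self.member_gene_ids)) != len(self.member_gene_ids):
            raise ValueError(f"operon {self.operon_id!r}: duplicate members")


@dataclass(frozen=True)
class CandidateSet:
    """Genes that survived a selection filter, with their mean RPKM."""

    gene_ids: tuple[str, ...]
    provenance: str  # "top_expression" | "chaperone"
    mean_rpkm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("CandidateSet contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_counts_tsv(path: str | Path, sample_id: str | None = None) -> ExpressionProfile:
    """Read a two-column ``gene_id<TAB>count`` table.

    The library size is taken from a ``# library_size: N`` header line when
    present, else from the sum of counts.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    library_size: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("library_size"):
                    library_size = int(body.split(":", 1)[1].strip())
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene_id, count = fields
            if gene_id in counts:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            counts[gene_id] = int(count)
    if library_size is None:
        library_size = sum(counts.values())
    return ExpressionProfile(
        sample_id=sample_id or path.stem, counts=counts, library_size=library_size
    )


def write_counts_tsv(profile: ExpressionProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_size: {profile.library_size}\n")
        for gene_id in sorted(profile.counts):
            fh.write(f"{gene_id}\t{profile.counts[gene_id]}\n")


def compute_rpkm(profile: ExpressionProfile, genes: Sequence[Gene]) -> dict[str, float]:
    """Reads Per Kilobase per Million mapped reads for every counted gene.

    RPKM = counts * 1e9 / (gene_length_bp * library_size).  Counted genes
    missing from the annotation are a hard error; annotated genes without a
    count row get RPKM 0.
    """
    lengths = {g.gene_id: g.length for g in genes}
    missing = sorted(g for g in profile.counts if g not in lengths)
    if missing:
        raise ValueError(
            f"sample {profile.sample_id!r}: {len(missing)} counted gene(s) absent from "
            f"annotation: {missing[:10]}"
        )
    rpkm = {gene_id: 0.0 for gene_id in lengths}
    for gene_id, count in profile.counts.items():
        rpkm[gene_id] = count * 1e9 / (lengths[gene_id] * profile.library_size)
    return rpkm


def expressed_genes(rpkm_by_sample: Sequence[Mapping[str, float]], threshold: float = 0.0) -> set[str]:
    """Genes with RPKM above ``threshold`` in every sample (default: > 0)."""
    if not rpkm_by_sample:
        return set()
    expressed = None
    for rpkm in rpkm_by_sample:
        s = {g for g, v in rpkm.items() if v > threshold}
        expressed = s if expressed is None else expressed & s
    return expressed


def operons_from_annotation(genes: Sequence[Gene]) -> list[Operon]:
    """Build operons from ``operon=`` tags carried in the annotation.

    Members are ordered 5'->3' in transcription direction (rightmost gene
    first for minus-strand operons).  Tags shared across strands or contigs
    are a hard error; tags covering a single gene are ignored.
    """
    groups: dict[str, list[Gene]] = {}
    for g in genes:
        if g.operon:
            groups.setdefault(g.operon, []).append(g)
    operons = []
    for tag in sorted(groups):
        members = groups[tag]
        if len(members) < 2:
            continue
        strands = {g.strand for g in members}
        contigs = {g.contig for g in members}
        if len(strands) > 1 or len(contigs) > 1:
            raise ValueError(f"operon tag {tag!r} spans multiple strands/contigs")
        members.sort(key=lambda g: g.start, reverse=(members[0].strand == "-"))
        operons.append(
            Operon(
                operon_id=tag,
                member_gene_ids=tuple(g.gene_id for g in members),
                strand=members[0].strand,
            )
        )
    return operons


def infer_operons(genes: Sequence[Gene], max_gap: int = 50) -> list[Operon]:
    """Heuristic operon inference: maximal runs of adjacent same-strand genes
    whose intergenic gap is at most ``max_gap`` bp (a common prokaryotic
    co-transcription heuristic)."""
    operons: list[Operon] = []
    by_contig: dict[str, list[Gene]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        by_contig.setdefault(g.contig, []).append(g)
    n = 0
    for contig in sorted(by_contig):
        run: list[Gene] = []

        def flush(run: list[Gene]) -> None:
            nonlocal n
            if len(run) >= 2:
                n += 1
                members = list(run)
                if members[0].strand == "-":
                    members = members[::-1]
                operons.append(
                    Operon(
                        operon_id=f"inferred_{n:04d}",
                        member_gene_ids=tuple(g.gene_id for g in members),
                        strand=members[0].strand,
                    )
                )

        for g in by_contig[contig]:
            if run and g.strand == run[-1].strand and g.start - run[-1].end <= max_gap:
                run.append(g)
            else:
                flush(run)
                run = [g]
        flush(run)
    return operons


def collapse_operons(
    expressed_gene_ids: Iterable[str], operons: Sequence[Operon]
) -> list[str]:
    """Collapse each operon to its first (5'-most) expressed gene.

    Returns all expressed genes that belong to no operon, plus one
    representative per operon with at least one expressed member, sorted by
    gene id.  When all operon members are expressed this satisfies
    ``|result| = |expressed| - |genes in operons| + |operons|``.  A gene
    assigned to two operons is a hard error; operon members missing from the
    expressed set are flagged with a warning.
    """
    expressed = set(expressed_gene_ids)
    membership: dict[str, str] = {}
    for op in operons:
        for gid in op.member_gene_ids:
            if gid in membership:
                raise ValueError(
                    f"gene {gid!r} assigned to both operon {membership[gid]!r} and {op.operon_id!r}"
                )
            membership[gid] = op.operon_id
    not_expressed = [g for g in membership if g not in expressed]
    if not_expressed:
        warnings.warn(
            f"{len(not_expressed)} operon member(s) not in the expressed set "
            f"(e.g. {sorted(not_expressed)[:5]})",
            stacklevel=2,
        )
    candidates = {g for g in expressed if g not in membership}
    for op in operons:
        for gid in op.member_gene_ids:  # transcription order: first expressed member wins
            if gid in expressed:
                candidates.add(gid)
                break
    return sorted(candidates)


def _top_k(rpkm: Mapping[str, float], k: int) -> set[str]:
    ranked = sorted(rpkm, key=lambda g: (-rpkm[g], g))
    return set(ranked[:k])


def select_top_shared(
    rpkm_a: Mapping[str, float], rpkm_b: Mapping[str, float], k: int
) -> list[str]:
    """Genes ranked in the top ``k`` by RPKM in both samples (set intersection).

    Ties at the cutoff break deterministically by gene id.
    """
    if k <= 0:
        raise ValueError(f"K must be positive, got {k}")
    return sorted(_top_k(rpkm_a, k) & _top_k(rpkm_b, k))


def select_top_n_by_mean(
    shared_genes: Iterable[str],
    rpkm_a: Mapping[str, float],
    rpkm_b: Mapping[str, float],
    n: int,
    geometric: bool = False,
) -> CandidateSet:
    """Top ``n`` shared genes by mean RPKM across the two samples.

    The mean is arithmetic by default (``geometric=True`` switches to the
    geometric mean); ties break lexicographically by gene id.
    """
    shared = sorted(set(shared_genes))
    if n > len(shared):
        raise ValueError(f"N={n} exceeds the {len(shared)} shared genes")
    if geometric:
        means = {g: (rpkm_a[g] * rpkm_b[g]) ** 0.5 for g in shared}
    else:
        means = {g: (rpkm_a[g] + rpkm_b[g]) / 2.0 for g in shared}
    ranked = sorted(shared, key=lambda g: (-means[g], g))[:n]
    return CandidateSet(
        gene_ids=tuple(ranked),
        provenance="top_expression",
        mean_rpkm={g: means[g] for g in ranked},
    )


def select_chaperones(
    genes: Sequence[Gene],
    keywords: Sequence[str] = DEFAULT_CHAPERONE_KEYWORDS,
    rpkm_a: Mapping[str, float] | None = None,
    rpkm_b: Mapping[str, float] | None = None,
) -> CandidateSet:
    """All genes whose product annotation matches a chaperone keyword.

    Matching is case-insensitive substring; expression level is ignored
    (chaperone promoters are kept even far below the top-N cutoff).  An empty
    result is permitted, with a warning.
    """
    lowered = [k.lower() for k in keywords]
    hits = [g for g in genes if any(k in g.product.lower() for k in lowered)]
    if not hits:
        warnings.warn("no chaperone-annotated genes found", stacklevel=2)
    means: dict[str, float] = {}
    for g in hits:
        if rpkm_a is not None and rpkm_b is not None:
            means[g.gene_id] = (rpkm_a.get(g.gene_id, 0.0) + rpkm_b.get(g.gene_id, 0.0)) / 2.0
    return CandidateSet(
        gene_ids=tuple(sorted(g.gene_id for g in hits)),
        provenance="chaperone",
        mean_rpkm=means,
    )
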
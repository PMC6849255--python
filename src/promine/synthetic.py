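"""Synthetic bacterial genomes, annotations, expression counts and truth tables.

The generator emulates the statistical structure the mining pipeline assumes:
a single circular-chromosome-like contig carrying coding genes on both
strands, a configurable fraction of genes grouped into operons (geometric
size distribution truncated at 2), sigma70 promoter motifs planted upstream
of a chosen gene subset with a controlled number of mutations per hexamer,
and two-condition expression counts whose per-gene mean RPKM is log-normal
with a heavy upper tail (a handful of transcription units boosted by
explicit multipliers, emulating rRNA-scale abundances near 10^6 RPKM).
Counts are Poisson around the RPKM-implied means and operon members share
one transcription-unit mean (co-transcription).

Everything is driven by one integer seed through a single PCG64 generator,
so reruns are byte-identical.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from promine.genome_io import Gene, reverse_complement, upstream_region, write_annotation
from promine.expression import ExpressionProfile, Operon, write_counts_tsv

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_genome",
    "plant_promoters",
    "simulate_expression",
    "generate_dataset",
    "study_scale_fixture",
    "STUDY_SCALE",
]

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset; ``seed`` fully determines output."""

    seed: int
    n_genes: int = 200
    genome_gc: float = 0.54
    operon_fraction: float = 0.5
    operon_geometric_p: float = 0.5   # size ~ 2 + Geometric(p) - 1, truncated >= 2
    intergenic_gap: tuple[int, int] = (20, 200)
    intra_operon_gap: tuple[int, int] = (5, 30)
    gene_length: tuple[int, int] = (300, 1500)
    n_planted_promoters: int = 0
    motif_mutations: int = 0          # substitutions per hexamer, 0-3
    spacer_range: tuple[int, int] = (15, 21)
    planted_spacer: int | None = 17   # None -> draw uniformly from spacer_range
    planted_clearance: int = 340      # upstream gap reserved for planted genes
    expression_mu: float = 4.0        # ln mean-RPKM of background units
    expression_sigma: float = 1.2
    mean_rpkm_floor: float = 0.0
    mean_rpkm_cap: float = float("inf")
    boost_multipliers: tuple[float, ...] = ()
    condition_noise_sd: float = 0.2   # ln-scale between-condition wobble
    condition_correlation: float = 0.9
    library_sizes: tuple[int, int] = (5_000_000, 6_000_000)
    contig_name: str = "chr"

    def __post_init__(self) -> None:
        if not 0.0 < self.genome_gc < 1.0:
            raise ValueError("genome_gc must lie in (0, 1)")
        if not 0.0 <= self.operon_fraction <= 1.0:
            raise ValueError("operon_fraction must lie in [0, 1]")
        if not 0 <= self.motif_mutations <= 3:
            raise ValueError("motif_mutations must be 0-3 per hexamer")


@dataclass
class SyntheticDataset:
    """A generated genome + annotation + expression bundle with truth tables."""

    config: SyntheticConfig
    contigs: dict[str, str]
    genes: list[Gene]
    operons: list[Operon]
    planted: pd.DataFrame          # one row per planted (or skipped) promoter
    unit_means: pd.DataFrame       # transcription-unit mean RPKM truth
    gene_means: dict[str, float]   # per-gene designed mean RPKM
    condition_means: tuple[dict[str, float], dict[str, float]] | None = None
    profiles: tuple[ExpressionProfile, ExpressionProfile] | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/GFF3/counts/truth under ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff": outdir / "genome.gff3",
            "planted": outdir / "truth_planted_promoters.tsv",
            "unit_means": outdir / "truth_unit_means.tsv",
        }
        write_annotation(self.genes, self.contigs, paths["gff"], paths["fasta"])
        self.planted.to_csv(paths["planted"], sep="\t", index=False)
        self.unit_means.to_csv(paths["unit_means"], sep="\t", index=False)
        if self.profiles is not None:
            for tag, profile in zip(("a", "b"), self.profiles):
                p = outdir / f"counts_{tag}.tsv"
                write_counts_tsv(profile, p)
                paths[f"counts_{tag}"] = p
        return paths


def _operon_sizes(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    """Operon sizes (each >= 2) covering ~operon_fraction of the genes."""
    target = int(round(config.operon_fraction * config.n_genes))
    sizes: list[int] = []
    covered = 0
    while covered + 2 <= target:
        size = 1 + int(rng.geometric(config.operon_geometric_p))  # >= 2
        size = min(size, target - covered) if target - covered >= 2 else 2
        if size < 2:
            break
        sizes.append(size)
        covered += size
    return sizes


def _layout_units(
    config: SyntheticConfig,
    rng: np.random.Generator,
    operon_sizes: Sequence[int],
    clearance_singletons: int = 0,
) -> tuple[list[Gene], list[Operon], int]:
    """Place transcription units left-to-right; returns genes, operons, genome length.

    ``clearance_singletons`` asks for that many evenly spread singleton units
    whose gene gets an unobstructed upstream window (gap >=
    planted_clearance on the correct side for its strand).
    """
    n_in_operons = sum(operon_sizes)
    n_units = len(operon_sizes) + (config.n_genes - n_in_operons)
    unit_sizes = list(operon_sizes) + [1] * (config.n_genes - n_in_operons)
    order = rng.permutation(n_units)
    unit_sizes = [unit_sizes[i] for i in order]
    strands = rng.choice(np.array(["+", "-"]), size=n_units)
    clearance_units: set[int] = set()
    if clearance_singletons:
        singleton_idx = [u for u, s in enumerate(unit_sizes) if s == 1]
        if len(singleton_idx) < clearance_singletons:
            raise ValueError("fewer singleton units than requested clearances")
        step = len(singleton_idx) // clearance_singletons
        clearance_units = {singleton_idx[i * step] for i in range(clearance_singletons)}

    genes: list[Gene] = []
    operons: list[Operon] = []
    pos = int(rng.integers(*config.intergenic_gap))
    gene_no = 0
    op_no = 0
    for u, size in enumerate(unit_sizes):
        strand = str(strands[u])
        # clearance before a + unit protects its own first gene; clearance
        # before any unit also protects a preceding - unit's first gene
        need_clear = (u in clearance_units and strand == "+") or (
            u > 0 and (u - 1) in clearance_units and str(strands[u - 1]) == "-"
        )
        if u > 0:
            gap = int(rng.integers(*config.intergenic_gap))
            if need_clear:
                gap = max(gap, config.planted_clearance)
            pos += gap
        elif u in clearance_units and strand == "+":
            pos = max(pos, config.planted_clearance)
        members: list[Gene] = []
        for k in range(size):
            if k > 0:
                pos += int(rng.integers(*config.intra_operon_gap))
            length = int(rng.integers(*config.gene_length))
            gene_no += 1
            members.append(
                Gene(
                    gene_id=f"gene_{gene_no:05d}",
                    contig=config.contig_name,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    product="hypothetical protein",
                )
            )
            pos += length
        if size >= 2:
            op_no += 1
            tag = f"op_{op_no:04d}"
            members = [replace(g, operon=tag) for g in members]
            tx_order = members if strand == "+" else members[::-1]
            operons.append(
                Operon(
                    operon_id=tag,
                    member_gene_ids=tuple(g.gene_id for g in tx_order),
                    strand=strand,
                )
            )
        genes.extend(members)
    # trailing clearance for a last-unit minus-strand planted gene
    tail = int(rng.integers(*config.intergenic_gap))
    if (n_units - 1) in clearance_units and str(strands[-1]) == "-":
        tail = max(tail, config.planted_clearance)
    genome_length = pos + tail
    return genes, operons, genome_length


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return bytearray(_BASE_CODES[idx].tobytes())


def generate_genome(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    clearance_singletons: int = 0,
    operon_sizes: Sequence[int] | None = None,
) -> SyntheticDataset:
    """Generate the genome sequence + annotation + operon truth (no expression yet).

    Every gene begins with a start codon (ATG in its transcription
    orientation).  Raises if the configured genes cannot be packed.
    """
    rng = rng or np.random.default_rng(config.seed)
    if operon_sizes is None:
        operon_sizes = _operon_sizes(config, rng)
    if sum(operon_sizes) > config.n_genes:
        raise ValueError(
            "operon sizes exceed n_genes; lower operon_fraction or raise n_genes"
        )
    genes, operons, genome_length = _layout_units(
        config, rng, operon_sizes, clearance_singletons
    )
    seq = _random_sequence(genome_length, config.genome_gc, rng)
    for g in genes:
        if g.strand == "+":
            seq[g.start : g.start + 3] = b"ATG"
        else:
            seq[g.end - 3 : g.end] = b"CAT"  # revcomp of ATG
    contigs = {config.contig_name: seq.decode()}
    empty_planted = pd.DataFrame(
        columns=[
            "gene_id", "strand", "spacer", "mutations", "minus35_seq", "minus10_seq",
            "window_offset_minus35", "window_offset_minus10",
            "abs_minus35", "abs_minus10", "status",
        ]
    )
    empty_means = pd.DataFrame(columns=["unit_id", "mean_rpkm", "member_gene_ids"])
    return SyntheticDataset(
        config=config,
        contigs=contigs,
        genes=genes,
        operons=operons,
        planted=empty_planted,
        unit_means=empty_means,
        gene_means={},
    )


def _mutate_hexamer(hexamer: str, n: int, rng: np.random.Generator) -> str:
    out = list(hexamer)
    for pos in rng.choice(6, size=n, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def plant_promoters(
    dataset: SyntheticDataset,
    gene_ids: Sequence[str],
    mutations: int = 0,
    rng: np.random.Generator | None = None,
    window: int = 300,
) -> SyntheticDataset:
    """Write sigma70 motifs (TTGACA/TATAAT +- mutations) into the upstream
    windows of the named genes, in place on the dataset's contig.

    The spacer is the configured ``planted_spacer`` (default: the 17 bp
    sigma70 optimum, so pristine sites score 1.0 under the default model;
    set it to None to draw uniformly from ``spacer_range``) and the -10 box
    3' end lands 25-80 nt before the start codon.  A gene whose upstream
    window collides with a neighbouring gene is skipped with a truth-table
    note.  The truth table records offsets, absolute coordinates and the
    planted hexamer texts.
    """
    rng = rng or np.random.default_rng(dataset.config.seed + 1)
    cfg = dataset.config
    contig = bytearray(dataset.contigs[cfg.contig_name].encode())
    by_id = {g.gene_id: g for g in dataset.genes}
    intervals = sorted((g.start, g.end) for g in dataset.genes)
    starts = [iv[0] for iv in intervals]

    def collides(a: int, b: int, self_gene: Gene) -> bool:
        i = bisect.bisect_right(starts, b) - 1
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(intervals):
                s, e = intervals[j]
                if (s, e) == (self_gene.start, self_gene.end):
                    continue
                if a < e and s < b:
                    return True
        return False

    rows = []
    for gene_id in gene_ids:
        gene = by_id[gene_id]
        region = upstream_region(gene, window, {cfg.contig_name: contig.decode()})
        if cfg.planted_spacer is not None:
            spacer = cfg.planted_spacer
        else:
            spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
        d = int(rng.integers(25, 81))  # -10 box 3' end to start codon
        i10 = len(region) - d - 6
        i35 = i10 - spacer - 6
        row = {
            "gene_id": gene_id,
            "strand": gene.strand,
            "spacer": spacer,
            "mutations": mutations,
            "minus35_seq": "",
            "minus10_seq": "",
            "window_offset_minus35": i35,
            "window_offset_minus10": i10,
            "abs_minus35": -1,
            "abs_minus10": -1,
            "status": "planted",
        }
        if i35 < 0:
            row["status"] = "skipped_short_window"
            rows.append(row)
            continue
        m35 = _mutate_hexamer("TTGACA", mutations, rng)
        m10 = _mutate_hexamer("TATAAT", mutations, rng)
        # plus-strand interval touched by both hexamers
        if gene.strand == "+":
            a35 = region.start + i35
            a10 = region.start + i10
            lo, hi = a35, a10 + 6
        else:
            a35 = region.end - 1 - i35  # transcription-first base (max plus coord)
            a10 = region.end - 1 - i10
            lo, hi = a10 - 5, a35 + 1
        if collides(lo, hi, gene):
            row["status"] = "skipped_collision"
            rows.append(row)
            continue
        if gene.strand == "+":
            contig[a35 : a35 + 6] = m35.encode()
            contig[a10 : a10 + 6] = m10.encode()
        else:
            contig[a35 - 5 : a35 + 1] = reverse_complement(m35).encode()
            contig[a10 - 5 : a10 + 1] = reverse_complement(m10).encode()
        row.update(
            minus35_seq=m35, minus10_seq=m10, abs_minus35=a35, abs_minus10=a10
        )
        rows.append(row)
    dataset.contigs[cfg.contig_name] = contig.decode()
    new_rows = pd.DataFrame(rows, columns=dataset.planted.columns)
    dataset.planted = (
        new_rows
        if dataset.planted.empty
        else pd.concat([dataset.planted, new_rows], ignore_index=True)
    )
    return dataset


def simulate_expression(
    dataset: SyntheticDataset,
    rng: np.random.Generator | None = None,
    mean_overrides: Mapping[str, float] | None = None,
) -> SyntheticDataset:
    """Draw per-unit mean RPKM and Poisson counts for two correlated conditions.

    Operon members share their unit's mean (co-transcription); background
    unit means are log-normal, floored/capped per the config, and the first
    ``len(boost_multipliers)`` randomly chosen units get heavy-tail boosts.
    ``mean_overrides`` pins designed means for specific genes (their units
    take the override and receive no between-condition noise, so designed
    rankings survive any seed).
    """
    cfg = dataset.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    overrides = dict(mean_overrides or {})
    in_operon = {gid for op in dataset.operons for gid in op.member_gene_ids}
    units: list[tuple[str, tuple[str, ...]]] = [
        (op.operon_id, op.member_gene_ids) for op in dataset.operons
    ] + [(g.gene_id, (g.gene_id,)) for g in dataset.genes if g.gene_id not in in_operon]
    units.sort(key=lambda u: u[0])

    base_log = rng.normal(cfg.expression_mu, cfg.expression_sigma, size=len(units))
    boosted = set()
    if cfg.boost_multipliers:
        boosted_idx = rng.choice(len(units), size=len(cfg.boost_multipliers), replace=False)
        boosted = set(int(i) for i in boosted_idx)

    rho = cfg.condition_correlation
    tau = cfg.condition_noise_sd
    shared = rng.normal(0.0, 1.0, size=len(units))
    indep_a = rng.normal(0.0, 1.0, size=len(units))
    indep_b = rng.normal(0.0, 1.0, size=len(units))
    sq = np.sqrt(max(0.0, 1.0 - rho))
    eps_a = tau * (np.sqrt(rho) * shared + sq * indep_a)
    eps_b = tau * (np.sqrt(rho) * shared + sq * indep_b)

    lengths = {g.gene_id: g.length for g in dataset.genes}
    gene_means: dict[str, float] = {}
    mean_a: dict[str, float] = {}
    mean_b: dict[str, float] = {}
    unit_rows = []
    boost_iter = iter(cfg.boost_multipliers)
    for i, (unit_id, members) in enumerate(units):
        override = next((overrides[g] for g in members if g in overrides), None)
        if override is not None:
            m = ma = mb = float(override)
        else:
            m = float(np.exp(base_log[i]))
            if i in boosted:
                m *= next(boost_iter, 1.0)
            clip = lambda x: float(min(cfg.mean_rpkm_cap, max(cfg.mean_rpkm_floor, x)))
            ma = clip(m * float(np.exp(eps_a[i])))
            mb = clip(m * float(np.exp(eps_b[i])))
            m = clip(m)
        unit_rows.append(
            {"unit_id": unit_id, "mean_rpkm": m, "member_gene_ids": ",".join(members)}
        )
        for g in members:
            gene_means[g] = m
            mean_a[g] = ma
            mean_b[g] = mb

    lib_a, lib_b = cfg.library_sizes
    order = sorted(gene_means)
    lam_a = np.array([mean_a[g] * lengths[g] * lib_a / 1e9 for g in order])
    lam_b = np.array([mean_b[g] * lengths[g] * lib_b / 1e9 for g in order])
    counts_a = rng.poisson(lam_a)
    counts_b = rng.poisson(lam_b)
    dataset.profiles = (
        ExpressionProfile("cond_a", dict(zip(order, map(int, counts_a))), lib_a),
        ExpressionProfile("cond_b", dict(zip(order, map(int, counts_b))), lib_b),
    )
    dataset.gene_means = gene_means
    dataset.condition_means = (mean_a, mean_b)
    dataset.unit_means = pd.DataFrame(
        unit_rows, columns=["unit_id", "mean_rpkm", "member_gene_ids"]
    )
    return dataset


def generate_dataset(
    config: SyntheticConfig, planted_gene_ids: Sequence[str] | None = None
) -> SyntheticDataset:
    """Genome + planted promoters + expression in one deterministic call.

    When ``planted_gene_ids`` is None and ``config.n_planted_promoters`` > 0,
    the first genes (in transcription-unit order) of well-separated units are
    chosen automatically.
    """
    rng = np.random.default_rng(config.seed)
    dataset = generate_genome(config, rng)
    if planted_gene_ids is None and config.n_planted_promoters > 0:
        in_operon = {gid for op in dataset.operons for gid in op.member_gene_ids}
        firsts = [op.member_gene_ids[0] for op in dataset.operons] + [
            g.gene_id for g in dataset.genes if g.gene_id not in in_operon
        ]
        planted_gene_ids = sorted(firsts)[: config.n_planted_promoters]
    if planted_gene_ids:
        plant_promoters(dataset, planted_gene_ids, config.motif_mutations, rng)
    simulate_expression(dataset, rng)
    return dataset


# ---------------------------------------------------------------------------
# study-scale fixture

#: structural constants of the study-scale fixture (guaranteed by construction)
STUDY_SCALE = {
    "n_genes": 2411,
    "n_operons": 547,
    "genes_in_operons": 1508,
    "collapsed": 1450,       # 2411 - 1508 + 547
    "n_top_expression": 20,
    "n_chaperones": 6,
    "n_cassettes": 26,
}

_CHAPERONE_PRODUCTS = (
    "Molecular chaperone GroEL",
    "Molecular chaperone GroEL",
    "Molecular chaperone DnaJ",
    "Molecular chaperone DnaJ",
    "Co-chaperone GroES",
    "Molecular chaperone DnaK",
)
# designed mean RPKM: descending tiers for the 20 high-expression genes
# (top near 10^6, emulating rRNA-scale transcripts) and modest chaperone
# levels well below the 20th tier, so the designed top-20 is stable under
# Poisson noise for any seed
_HOT_MEANS = tuple(1_000_000 * 0.78 ** i for i in range(20))
_CHAPERONE_MEANS = (6594.0, 6261.0, 2215.0, 4523.0, 703.0, 239.0)


def study_scale_fixture(seed: int = 20260927) -> SyntheticDataset:
    """The study-scale synthetic stand-in for the unreleased inputs.

    2411 genes, of which 1508 sit in 547 operons (133 pairs + 414 triplets);
    903 singletons.  Twenty singleton genes carry designed high expression
    (means tiered down from ~10^6 RPKM) and six carry molecular-chaperone
    product annotations with modest expression; all 26 get a planted
    consensus promoter inside a cleared 300 bp upstream window, so the
    end-to-end mine yields 20 + 6 = 26 cassettes.  Background unit means are
    log-normal, floored at 20 RPKM (every gene expressed in both conditions)
    and capped at 2000 RPKM (the designed ranking is seed-independent).
    """
    config = SyntheticConfig(
        seed=seed,
        n_genes=STUDY_SCALE["n_genes"],
        genome_gc=0.54,
        gene_length=(300, 1500),
        intergenic_gap=(20, 200),
        expression_mu=4.2,
        expression_sigma=1.0,
        mean_rpkm_floor=20.0,
        mean_rpkm_cap=2000.0,
        condition_noise_sd=0.2,
        condition_correlation=0.9,
        library_sizes=(5_000_000, 6_000_000),
    )
    operon_sizes = [2] * 133 + [3] * 414  # 547 operons, 1508 members
    rng = np.random.default_rng(config.seed)
    dataset = generate_genome(
        config, rng, clearance_singletons=30, operon_sizes=operon_sizes
    )

    in_operon = {gid for op in dataset.operons for gid in op.member_gene_ids}
    singletons = [g for g in dataset.genes if g.gene_id not in in_operon]
    # keep singletons whose upstream window is clear of neighbours
    intervals = sorted((g.start, g.end) for g in dataset.genes)
    starts = [iv[0] for iv in intervals]

    def upstream_clear(g: Gene, need: int = 330) -> bool:
        if g.strand == "+":
            i = bisect.bisect_left(starts, g.start) - 1
            prev_end = intervals[i][1] if i >= 0 else 0
            return g.start - prev_end >= need
        i = bisect.bisect_right(starts, g.start)
        next_start = intervals[i][0] if i < len(intervals) else len(
            dataset.contigs[config.contig_name]
        )
        return next_start - g.end >= need

    clear = [g for g in singletons if upstream_clear(g)]
    if len(clear) < 26:
        raise RuntimeError("fixture layout produced too few cleared singletons")
    step = len(clear) // 26
    designated = [clear[i * step] for i in range(26)]
    hot, chap = designated[:20], designated[20:]

    # chaperone product annotations
    chap_ids = {g.gene_id: p for g, p in zip(chap, _CHAPERONE_PRODUCTS)}
    dataset.genes = [
        replace(g, product=chap_ids[g.gene_id]) if g.gene_id in chap_ids else g
        for g in dataset.genes
    ]

    plant_promoters(dataset, [g.gene_id for g in designated], mutations=0, rng=rng)
    if not (dataset.planted["status"] == "planted").all():
        raise RuntimeError("fixture failed to plant all 26 promoters")

    overrides = {g.gene_id: m for g, m in zip(hot, _HOT_MEANS)}
    overrides.update({g.gene_id: m for g, m in zip(chap, _CHAPERONE_MEANS)})
    simulate_expression(dataset, rng, mean_overrides=overrides)
    return dataset
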
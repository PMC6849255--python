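"""End-to-end orchestration: mine promoters from a genome + counts, and
summarise reporter / CoA assay tables.

``run_mine`` executes the full selection flow — RPKM, expressed-gene filter,
operon collapse, top-K intersection across the two conditions, top-N by mean
RPKM plus the chaperone set, sigma70 scanning of each 300 bp upstream
window, cassette assembly — and writes a candidate table, a hit table, the
cassette FASTA/TSV and a summary JSON holding every stage's counts, so the
audit trail (expressed -> collapsed -> shared -> top-N + chaperones ->
cassettes) is reconstructable for any dataset.  Both entry points are fully
deterministic; randomness lives only in the synthetic generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from promine import expression as ex
from promine import genome_io
from promine.assay import (
    fold_ratio,
    coa_units,
    normalize_fluorescence,
    rank_and_classify,
    read_assay_tsv,
    read_coa_tsv,
    summarize_replicates,
)
from promine.cassette import PromoterCassette, assemble_cassette, write_cassettes
from promine.promoter_scan import PromoterModel, build_default_model, scan_upstream

__all__ = ["RunConfig", "MiningResult", "run_mine", "run_assay"]


@dataclass
class RunConfig:
    """Paths and tunables of a mining run (defaults are the pipeline's
    standard operating point: top-100 intersection, top-20 by mean RPKM,
    300 bp scan window, 60 bp UP extension, score threshold 0.7)."""

    fasta: str | Path = ""
    gff: str | Path = ""
    counts_a: str | Path = ""
    counts_b: str | Path = ""
    outdir: str | Path = "promine_run"
    top_k: int = 100
    top_n: int = 20
    window: int = 300
    up_ext: int = 60
    threshold: float = 0.7
    expressed_threshold: float = 0.0
    chaperone_keywords: tuple[str, ...] = ex.DEFAULT_CHAPERONE_KEYWORDS
    operon_gap: int = 50
    strong_cutoff: float = 6000.0
    silent_factor: float = 1.5
    negative_control: str | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        for name in ("top_k", "top_n", "window", "up_ext"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "chaperone_keywords" in data:
            data["chaperone_keywords"] = tuple(data["chaperone_keywords"])
        return cls(**data)


@dataclass
class MiningResult:
    summary: dict
    candidates: list[dict]
    cassettes: list[PromoterCassette]
    paths: dict[str, Path] = field(default_factory=dict)


def _candidate_rows(
    selected: Sequence[str],
    provenance: Mapping[str, str],
    genes_by_id: Mapping[str, genome_io.Gene],
    mean_rpkm: Mapping[str, float],
    best_score: Mapping[str, float],
) -> list[dict]:
    rows = []
    order = sorted(selected, key=lambda g: (-mean_rpkm.get(g, 0.0), g))
    for gid in order:
        rows.append(
            {
                "name": f"P_{gid}",
                "gene_id": gid,
                "downstream_product": genes_by_id[gid].product,
                "average_rpkm": round(mean_rpkm.get(gid, 0.0), 1),
                "score": round(best_score[gid], 2) if gid in best_score else "",
                "provenance": provenance[gid],
            }
        )
    return rows


def run_mine(config: RunConfig, model: PromoterModel | None = None) -> MiningResult:
    """Run the full mining flow and write all outputs under ``config.outdir``."""
    model = model or build_default_model()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes, contigs = genome_io.parse_annotation(config.gff, config.fasta)
    genes_by_id = {g.gene_id: g for g in genes}
    profile_a = ex.read_counts_tsv(config.counts_a, "cond_a")
    profile_b = ex.read_counts_tsv(config.counts_b, "cond_b")
    rpkm_a = ex.compute_rpkm(profile_a, genes)
    rpkm_b = ex.compute_rpkm(profile_b, genes)

    expressed = ex.expressed_genes([rpkm_a, rpkm_b], config.expressed_threshold)
    operons = ex.operons_from_annotation(genes)
    if not operons:
        operons = ex.infer_operons(genes, config.operon_gap)
    operon_members = {gid for op in operons for gid in op.member_gene_ids}
    expressed_in_operons = expressed & operon_members
    operons_expressed = [
        op for op in operons if any(g in expressed for g in op.member_gene_ids)
    ]
    collapsed = ex.collapse_operons(expressed, operons)

    summary: dict = {
        "expressed": len(expressed),
        "genes_in_operons": len(expressed_in_operons),
        "operons": len(operons_expressed),
        "collapsed": len(collapsed),
    }
    top_expr = ex.CandidateSet(gene_ids=(), provenance="top_expression")
    shared: list[str] = []
    if collapsed:
        sub_a = {g: rpkm_a[g] for g in collapsed}
        sub_b = {g: rpkm_b[g] for g in collapsed}
        shared = ex.select_top_shared(sub_a, sub_b, config.top_k)
        n = min(config.top_n, len(shared))
        if n:
            top_expr = ex.select_top_n_by_mean(shared, sub_a, sub_b, n)
    chaperones = ex.select_chaperones(
        genes, config.chaperone_keywords, rpkm_a, rpkm_b
    )
    summary["shared_top_k"] = len(shared)
    summary["top_n"] = len(top_expr)
    summary["chaperones"] = len(chaperones)

    provenance = {g: "top_expression" for g in top_expr.gene_ids}
    for g in chaperones.gene_ids:
        provenance.setdefault(g, "chaperone")
    selected = sorted(provenance)
    summary["selected"] = len(selected)

    mean_rpkm = {g: (rpkm_a[g] + rpkm_b[g]) / 2.0 for g in selected}
    hit_rows: list[dict] = []
    best_score: dict[str, float] = {}
    cassettes: list[PromoterCassette] = []
    for gid in selected:
        gene = genes_by_id[gid]
        window = genome_io.upstream_region(gene, config.window, contigs)
        hits = scan_upstream(window, model, config.threshold, gene_id=gid)
        for h in hits:
            hit_rows.append(
                {
                    "gene_id": gid,
                    "contig": gene.contig,
                    "abs_minus35": window.absolute_position(h.offset_minus35),
                    "abs_minus10": window.absolute_position(h.offset_minus10),
                    "spacer": h.spacer,
                    "raw_score": round(h.raw_score, 4),
                    "norm_score": round(h.norm_score, 4),
                }
            )
        if hits:
            best_score[gid] = max(h.norm_score for h in hits)
            cassette = assemble_cassette(gene, hits, window, contigs, config.up_ext)
            if cassette is not None:
                cassettes.append(cassette)
    summary["cassettes"] = len(cassettes)

    candidates = _candidate_rows(selected, provenance, genes_by_id, mean_rpkm, best_score)
    paths = {
        "candidates": outdir / "candidates.tsv",
        "hits": outdir / "promoter_hits.tsv",
        "cassettes_fasta": outdir / "cassettes.fasta",
        "cassettes_tsv": outdir / "cassettes.tsv",
        "summary": outdir / "summary.json",
    }
    with open(paths["candidates"], "w") as fh:
        cols = ["name", "gene_id", "downstream_product", "average_rpkm", "score", "provenance"]
        fh.write("\t".join(cols) + "\n")
        for row in candidates:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(paths["hits"], "w") as fh:
        cols = ["gene_id", "contig", "abs_minus35", "abs_minus10", "spacer", "raw_score", "norm_score"]
        fh.write("\t".join(cols) + "\n")
        for row in sorted(hit_rows, key=lambda r: (r["gene_id"], r["abs_minus35"])):
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    write_cassettes(cassettes, paths["cassettes_fasta"], paths["cassettes_tsv"])
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return MiningResult(
        summary=summary, candidates=candidates, cassettes=cassettes, paths=paths
    )


def run_assay(
    plate_tsv: str | Path | None,
    coa_tsv: str | Path | None,
    config: RunConfig,
) -> dict:
    """Summarise reporter and CoA assay tables.

    Plate readings are normalised per well (RFU/OD600), averaged over
    replicates, ranked and classified strong/weak/silent against the
    negative control; CoA triples are converted to U/mL.  When
    ``config.reference`` names a strain/label, fold ratios against it are
    reported (1-decimal, half-away-from-zero).  Outputs are written under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    if plate_tsv is not None:
        records = read_assay_tsv(plate_tsv)
        per_strain: dict[str, list[float]] = {}
        for r in records:
            per_strain.setdefault(r.strain_id, []).append(normalize_fluorescence(r))
        stats = {s: summarize_replicates(v) for s, v in sorted(per_strain.items())}
        means = {s: m for s, (m, _) in stats.items()}
        negative = means.get(config.negative_control) if config.negative_control else None
        table = rank_and_classify(
            means, negative, config.strong_cutoff, config.silent_factor
        )
        table["sd"] = [
            ("" if stats[p][1] is None else round(stats[p][1], 2))
            for p in table["promoter"]
        ]
        if config.reference and config.reference in means:
            ref = means[config.reference]
            table["fold_vs_reference"] = [
                fold_ratio(means[p], ref) for p in table["promoter"]
            ]
        path = outdir / "promoter_activity.tsv"
        table.to_csv(path, sep="\t", index=False)
        out["promoter_activity"] = table
        out["promoter_activity_path"] = path

    if coa_tsv is not None:
        measurements = read_coa_tsv(coa_tsv)
        rows = []
        by_label: dict[str, list[float]] = {}
        for m in measurements:
            u, below = coa_units(m)
            by_label.setdefault(m.label, []).append(u)
            rows.append(
                {
                    "label": m.label,
                    "E0": m.E0,
                    "E1": m.E1,
                    "E2": m.E2,
                    "units_per_ml": round(u, 2),
                    "below_detection": below,
                }
            )
        coa_summary = []
        for label in sorted(by_label):
            mean, sd = summarize_replicates(by_label[label])
            entry = {
                "label": label,
                "mean_units_per_ml": round(max(mean, 0.0), 1),
                "raw_mean_units_per_ml": round(mean, 2),
                "sd": None if sd is None else round(sd, 1),
            }
            coa_summary.append(entry)
        if config.reference and config.reference in by_label:
            ref_mean = summarize_replicates(by_label[config.reference])[0]
            for entry in coa_summary:
                entry["fold_vs_reference"] = fold_ratio(
                    entry["raw_mean_units_per_ml"], ref_mean
                )
        raw = pd.DataFrame(rows)
        summary_df = pd.DataFrame(coa_summary)
        raw.to_csv(outdir / "coa_raw.tsv", sep="\t", index=False)
        summary_df.to_csv(outdir / "coa_summary.tsv", sep="\t", index=False)
        out["coa_raw"] = raw
        out["coa_summary"] = summary_df
    return out
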
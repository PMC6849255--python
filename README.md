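# promine

Transcriptome-guided mining of bacterial σ70 promoters.

Strong, well-characterised native promoters are a chronic bottleneck when
engineering non-model bacteria (coryneform industrial strains being the
classic case). `promine` implements the rational route to them: rank genes by
expression from two RNA-seq conditions, respect operon structure (only the
first gene of an operon owns a promoter), scan the upstream windows of the
best candidates for σ70 core promoters, and cut out cloning-ready promoter
cassettes. It also provides the downstream assay arithmetic used to
characterise the cloned promoters (growth-normalised reporter fluorescence
and the spectrophotometric phosphotransacetylase CoA assay), plus a fully
deterministic synthetic-data generator so the entire pipeline is testable
without any external dataset.

## The method

**Selection.** Expression of gene *g* in a sample with library size *N* is

    RPKM(g) = counts(g) · 10⁹ / (length_bp(g) · N)

Genes expressed in both conditions are collapsed operon-wise (all singletons
plus the 5′-most gene of each operon; operons come from annotation tags or a
same-strand gap ≤ 50 bp heuristic), the top-K (default 100) rankings of the
two conditions are intersected, and the top-N (default 20) by mean RPKM are
kept. Annotated molecular chaperones (GroEL/GroES/DnaK/DnaJ keywords) are
added regardless of expression — chaperone promoters are a classically
strong class in corynebacteria.

**Promoter scanning.** A core promoter is a −35 hexamer (consensus TTGACA)
and a −10 hexamer (TATAAT) separated by a 15–21 bp spacer. Each placement in
the 300 bp window upstream of the start codon scores

    raw = PWM₋₃₅ + PWM₋₁₀ − 0.5 bits/bp · |spacer − 17|

in log-odds bits against a uniform background (per-position match
probability 0.7), min-max normalised to [0, 1] against the model's best and
worst achievable scores, so the default acceptance threshold 0.7 has a
model-independent meaning. All placements above threshold are kept (tandem
promoters are real); placements sharing a −10 box are merged.

**Cassette assembly.** Each cassette runs from 60 bp upstream of the most
distal −35 box (room for AT-rich UP-elements) through the native 5′-UTR up
to the base immediately before the start codon, with a Shine–Dalgarno QC
flag (≥ 4/6 match to AGGAGG, 3′ end 5–15 nt before the start codon).

**Assays.** Reporter strength is fluorescence/OD600 with strong/weak/silent
classification; CoA titres come from absorbance triples at 233 nm via
U/mL = (2·E1 − E0 − E2) × 5.55 × 413.

## Worked example

Generate the bundled study-scale synthetic dataset (2411 genes, 1508 of them
in 547 operons, 6 chaperone-annotated genes, 26 planted consensus promoters)
and mine it:

```bash
promine generate --seed 1 --study-scale --outdir data
promine mine --fasta data/genome.fasta --gff data/genome.gff3 \
             --counts-a data/counts_a.tsv --counts-b data/counts_b.tsv \
             --outdir run
```

prints the stage-count audit trail:

```json
{
  "cassettes": 26,
  "chaperones": 6,
  "collapsed": 1450,
  "expressed": 2411,
  "genes_in_operons": 1508,
  "operons": 547,
  "selected": 26,
  "shared_top_k": 91,
  "top_n": 20
}
```

Reading: 2411 genes were expressed in both conditions; collapsing 1508
operon genes into their 547 operons leaves 2411 − 1508 + 547 = 1450 promoter
candidates; 91 of them rank in the top-100 of both conditions; the top 20 by
mean RPKM plus the 6 chaperone genes give 26 selected genes, each of which
yields one promoter cassette (`run/cassettes.fasta`). `run/candidates.tsv`
mirrors the familiar report shape — name, downstream product, average RPKM
and best promoter score:

```
name          gene_id     downstream_product    average_rpkm  score  provenance
P_gene_00001  gene_00001  hypothetical protein  1000023.0     1.0    top_expression
P_gene_00002  gene_00002  hypothetical protein  780038.1      1.0    top_expression
```

Assay tables are summarised with `promine assay --plate plate.tsv
--negative-control control --reference P_dnaK`; the same functions are
importable from `promine.assay` (e.g. `fold_ratio(43433, 19125) == 2.3`).

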
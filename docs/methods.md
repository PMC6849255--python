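# Methods

This note documents the models, parameter choices and numerical conventions
behind `promine`, and what the synthetic benchmark does and does not
establish about real data.

## Coordinates and strand handling

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at the I/O boundary. Upstream windows and
cassettes are always materialised 5′→3′ in the gene's transcription
orientation (minus-strand regions are reverse-complemented at extraction),
which makes every downstream step — scanning, SD detection, assembly —
strand-agnostic. "1 bp upstream of the start codon" therefore has an exact
meaning: the cassette's half-open span ends at the CDS start, so its last
base is the nucleotide adjacent to the A of ATG. Windows clipped by a contig
edge are flagged `truncated`, never errors; a gene flush against the edge
yields an empty flagged window.

## Expression selection

RPKM is used exactly as defined (counts · 10⁹ / (length · library size));
the library size is read from a `# library_size:` header when present and
otherwise taken as the column sum, since multi-mapped reads mean the two
need not agree. "Expressed" defaults to RPKM > 0 in *both* conditions — the
most permissive reading — with the cutoff exposed as a parameter.

Operon collapse keeps all non-operon genes plus the 5′-most expressed member
of each operon. When all members are expressed this satisfies the
conservation identity |collapsed| = |expressed| − |members| + |operons|,
which the test suite checks on random structures. Operons are taken from
`operon=` annotation tags when present; otherwise they are inferred as
maximal runs of adjacent same-strand genes with intergenic gaps ≤ 50 bp, a
standard prokaryotic heuristic — adequate for ranking purposes, not a
substitute for a real operon map.

The two-condition intersection uses top-K sets (K = 100) with deterministic
gene-id tie-breaking at every rank cut; the final ranking statistic is the
arithmetic mean of the two RPKM values (geometric mean behind a flag).
Chaperone selection is a case-insensitive substring match of the product
annotation against {molecular chaperone, co-chaperone, GroEL, GroES, DnaK,
DnaJ} and deliberately ignores expression: the point of that arm of the
strategy is that chaperone promoters are strong regardless of the sampled
conditions.

## Promoter model

The scanner is a transparent PWM-plus-spacer model of the σ70 core promoter,
not a reimplementation of any neural-network predictor; the contract it
preserves is the interface — a [0, 1] score, a 0.7 acceptance threshold,
multiple hits per window — because the pipeline logic, not the predictor
internals, is what this package rebuilds. Consequences: absolute scores are
not comparable to any other tool's scores, and published score tables from
other predictors are format references only, never numeric targets.

Defaults: consensus TTGACA/TATAAT with per-position match probability 0.7
(mismatches 0.1 each), log-odds in bits against a uniform background, spacer
range 15–21 bp, optimum 17 bp, penalty 0.5 bits/bp of deviation. The
normalisation anchors are the best and worst raw scores achievable at the
optimal spacer (S_max ≈ 17.83 bits, S_min ≈ −15.86 bits), so norm = 1.0 is
attained exactly by a consensus site at 17 bp spacing and norm 0.7
corresponds to roughly 9 of 12 consensus positions. `N` bases score the
column minimum (worst case). Alternative matrices are loadable from a
tab-delimited file.

Scanning enumerates every (−35 offset, spacer) placement — the suite proves
equality with a brute-force double loop — keeps placements ≥ threshold, and
merges placements sharing a −10 box, keeping the best raw score; on
numerical ties (identical score sets summed in different orders can differ
by ~1e-16) the earlier, more distal placement wins, with a 1e-9-bit margin
that is six orders of magnitude below the model's smallest real score
difference (~0.8 bits). Scanning is single-strand in transcription
orientation; the reverse complement of a window is never scanned.

## Cassette assembly

The cassette span is anchored at the *most distal* accepted −35 box so that
tandem promoters all land inside one fragment, extended 60 bp further
upstream for potential UP-elements, and closed 1 bp before the start codon.
The anchor choice (−35 box rather than a predictor-reported promoter start)
is one of the genuinely open design points; the −35 box is the only
model-defined landmark, so it is used. Extension clamping at contig edges
sets `truncated`. The Shine–Dalgarno check (best ungapped AGGAGG match in
the final 20 nt, found iff ≥ 4/6 positions match with the 3′ end 5–15 nt
before the start codon; more matches win, ties go proximal) is a QC flag
only and never filters a cassette, since inclusion of the native 5′-UTR
already carries the native RBS whatever its motif quality. All four
parameters (60 bp extension, 300 bp window, 5–15 nt SD offset, 4/6 match)
are configuration keys.

## Assay arithmetic

Reporter activity is raw fluorescence / OD600 per well, averaged over
replicates (sample SD, n−1). Classification cutoffs — silent ≤ 1.5× the
negative control, strong ≥ 6000 RFU/OD — are presentation defaults, not
science, and are exposed as parameters. Fold ratios round half-away-from-
zero to one decimal, matching how such ratios are conventionally reported.
The CoA unit formula U = (2·E1 − E0 − E2) × 5.55 × 413 is applied verbatim;
the constants fold path length, extinction and molarity conversions and are
not interpreted further. Negative U (baseline drift exceeding signal) is
flagged below-detection and floored at 0 only in the summary table, with raw
values preserved.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, on a
single contig:

- **Layout** — transcription units (operons of geometric size ≥ 2 covering a
  configurable gene fraction, plus singletons) placed on random strands with
  uniform 20–200 bp intergenic gaps and 5–30 bp intra-operon gaps; gene
  lengths uniform 300–1500 bp; every CDS starts with ATG in its orientation;
  background base composition at 54% GC (coryneform-like).
- **Planted promoters** — consensus TTGACA/TATAAT written into chosen
  upstream windows with a configurable number of substitutions per hexamer
  (0–3) at recorded positions. The planted spacer defaults to the 17 bp
  optimum so that pristine sites score exactly 1.0 and recovery is a sharp
  criterion; uniform 15–21 bp spacers are available via `planted_spacer=None`.
  With the default model, one substitution per hexamer keeps sites above the
  0.7 threshold (norm ≈ 0.77–0.83) while two per hexamer drops them below
  (≈ 0.67), so recall versus mutation count is a steep, informative curve.
- **Expression** — one log-normal mean RPKM per transcription unit (operon
  members co-transcribed, sharing it exactly), an explicit multiplier list
  for heavy-tail units (reproducing rRNA-scale ~10⁶ RPKM extremes), a shared
  log-normal between-condition wobble with correlation ρ (default 0.9,
  SD 0.2), and Poisson counts around the RPKM-implied means. Poisson was
  chosen over negative binomial because ranking is the only downstream
  consumer of the counts; over-dispersion would only widen the noise the
  recovery tests already quantify.

A single PCG64 generator seeded once drives everything; reruns are
byte-identical and free of hash-order dependence.

### The study-scale benchmark

`study_scale_fixture` pins the scale of the benchmark: 2411 genes with 1508
of them in 547 operons (133 pairs + 414 triplets — the operon-size mix is a
free choice constrained only by those two totals), 20 designed
high-expression singletons with means tiered from 10⁶ down by a factor 0.78
per rank (floor ≈ 8.9·10³ RPKM), and 6 chaperone-annotated singletons at
modest levels (239–6594 RPKM, echoing the spread typical of chaperone
transcripts). All 26 carry pristine planted promoters in upstream windows
laid out with ≥ 330 bp of clearance so no motif can touch coding sequence.
Background unit means are floored at 20 RPKM (expected counts ≥ 30, so
every gene is expressed in both conditions with near-certainty at any seed)
and capped at 2000 RPKM (so the designed top-20 is separated from the
background by at least fourfold and survives Poisson noise at any seed).
Designed genes take no between-condition wobble. These guards make the
benchmark's stage counts — 2411 expressed, 1450 collapsed, 20 + 6 selected,
26 cassettes — properties of the construction rather than of a particular
seed.

### What passing does and does not show

The generator's windows are i.i.d. background around planted motifs: real
upstream regions have composition bias, repeats, overlapping regulatory
sites and mis-annotated starts, so perfect planted-site recall here bounds
sensitivity only under the model's own assumptions. The expression model
has no between-replicate structure, batch effects or length bias beyond the
RPKM definition; passing the ranking tests shows the selection arithmetic
is correct, not that RPKM ranking identifies strong promoters in a real
organism — the wet-lab half of that claim is outside the package's scope.
Promoter scores are from a consensus PWM, so concordance with any specific
published score table is not expected and not tested.

## Problem sizes and runtime

Defaults were chosen so everything is desk-scale: the study-scale benchmark
(≈ 2.3 Mb genome, 2411 genes) generates and mines in a few seconds; the
property tests use 25–220 gene genomes, ≥ 200 planted sites per mutation
level for recall curves, 50–60 random 300-mers for brute-force scan
equivalence, and library size 10⁸ for the 3-standard-error RPKM recovery
check. The full test suite runs in well under a minute on one CPU.

## Known limitations

- Operon inference is a gap heuristic; internal promoters inside operons are
  invisible to the collapse step by design.
- The PWM scorer has no extended −10 (TGn) element, no UP-element scoring
  and no discriminator region; threshold 0.7 is calibrated only in the sense
  that its meaning is model-independent under min-max normalisation.
- Cassette assembly trusts the annotated CDS start; a mis-annotated start
  codon shifts the whole cassette.
- The CoA formula's constants are applied as given; no pathway modelling or
  enzyme kinetics is attempted.
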
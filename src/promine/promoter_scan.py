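"""Sigma70 core-promoter scanning with -35/-10 position weight matrices.

A core promoter is modelled as a -35 hexamer (consensus TTGACA) and a -10
hexamer (consensus TATAAT) separated by a 15-21 bp spacer with a 17 bp
optimum.  Each placement is scored in log-odds bits against a uniform
background, minus a linear penalty per bp of spacer deviation, and the raw
score is min-max normalised to [0, 1] against the model's best and worst
achievable scores at the optimal spacer — so a fixed threshold (default 0.7)
has a model-independent meaning.  Scanning is single-strand, in the
transcription orientation of the upstream window, and keeps every placement
above threshold (tandem promoters are real in bacteria), merging placements
that share a -10 box down to the best-scoring one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


from promine.genome_io import GenomeRegion

__all__ = [
    "PromoterModel",
    "PromoterHit",
    "build_default_model",
    "score_placement",
    "scan_upstream",
    "write_model",
    "read_model",
    "MINUS35_CONSENSUS",
    "MINUS10_CONSENSUS",
]

BASES = "ACGT"
MINUS35_CONSENSUS = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"
#: minimal window that can hold -35 + min spacer + -10
MIN_SPAN = 6 + 15 + 6


@dataclass(frozen=True)
class PromoterModel:
    """PWM pair + spacer geometry for core-promoter scoring.

    ``pwm_minus35``/``pwm_minus10`` are 6-tuples of per-position log-odds
    (bits, vs uniform background) keyed A,C,G,T.  ``spacer_penalty`` is in
    bits per bp of deviation from ``spacer_optimum``.
    """

    pwm_minus35: tuple[tuple[float, float, float, float], ...]
    pwm_minus10: tuple[tuple[float, float, float, float], ...]
    spacer_min: int = 15
    spacer_max: int = 21
    spacer_optimum: int = 17
    spacer_penalty: float = 0.5

    def __post_init__(self) -> None:
        if len(self.pwm_minus35) != 6 or len(self.pwm_minus10) != 6:
            raise ValueError("PWMs must have 6 positions")
        if not self.spacer_min <= self.spacer_optimum <= self.spacer_max:
            raise ValueError("need spacer_min <= spacer_optimum <= spacer_max")

    @property
    def max_raw_score(self) -> float:
        """Best achievable raw score (consensus boxes, optimal spacer)."""
        return sum(max(col) for col in self.pwm_minus35) + sum(
            max(col) for col in self.pwm_minus10
        )

    @property
    def min_raw_score(self) -> float:
        """Worst achievable hexamer score at the optimal spacer."""
        return sum(min(col) for col in self.pwm_minus35) + sum(
            min(col) for col in self.pwm_minus10
        )

    def normalize(self, raw: float) -> float:
        span = self.max_raw_score - self.min_raw_score
        norm = (raw - self.min_raw_score) / span
        return min(1.0, max(0.0, norm))

    def score_hexamer(self, hexamer: str, which: str) -> float:
        """Log-odds bits of a 6-mer against one box; N scores the column minimum."""
        pwm = self.pwm_minus35 if which == "-35" else self.pwm_minus10
        total = 0.0
        for pos, base in enumerate(hexamer):
            col = pwm[pos]
            idx = BASES.find(base)
            total += col[idx] if idx >= 0 else min(col)
        return total


@dataclass(frozen=True)
class PromoterHit:
    """A scored core-promoter placement inside an upstream window.

    Offsets are 0-based within the window, in transcription orientation
    (offset 0 is the most distal base from the start codon).
    """

    gene_id: str
    offset_minus35: int
    offset_minus10: int
    spacer: int
    raw_score: float
    norm_score: float

    def __post_init__(self) -> None:
        if self.offset_minus10 != self.offset_minus35 + 6 + self.spacer:
            raise ValueError("offset_minus10 inconsistent with offset_minus35 + 6 + spacer")
        if not 0.0 <= self.norm_score <= 1.0:
            raise ValueError(f"norm_score {self.norm_score} outside [0, 1]")


def _consensus_pwm(consensus: str, match_p: float = 0.7) -> tuple[tuple[float, ...], ...]:
    mismatch_p = (1.0 - match_p) / 3.0
    pwm = []
    for base in consensus:
        col = tuple(
            math.log2((match_p if b == base else mismatch_p) / 0.25) for b in BASES
        )
        pwm.append(col)
    return tuple(pwm)


def build_default_model(
    match_probability: float = 0.7,
    spacer_min: int = 15,
    spacer_max: int = 21,
    spacer_optimum: int = 17,
    spacer_penalty: float = 0.5,
) -> PromoterModel:
    """Consensus-derived sigma70 model: TTGACA / TATAAT with per-position
    match probability ``match_probability`` and the remainder spread evenly
    over the three mismatch bases."""
    return PromoterModel(
        pwm_minus35=_consensus_pwm(MINUS35_CONSENSUS, match_probability),
        pwm_minus10=_consensus_pwm(MINUS10_CONSENSUS, match_probability),
        spacer_min=spacer_min,
        spacer_max=spacer_max,
        spacer_optimum=spacer_optimum,
        spacer_penalty=spacer_penalty,
    )


def score_placement(
    window_sequence: str, i35: int, spacer: int, model: PromoterModel
) -> tuple[float, float]:
    """Score one (-35 offset, spacer) placement; returns (raw bits, norm score).

    raw = PWM(-35 hexamer) + PWM(-10 hexamer) - penalty * |spacer - optimum|.
    """
    if not model.spacer_min <= spacer <= model.spacer_max:
        raise ValueError(
            f"spacer {spacer} outside model range [{model.spacer_min}, {model.spacer_max}]"
        )
    i10 = i35 + 6 + spacer
    if i35 < 0 or i10 + 6 > len(window_sequence):
        raise ValueError("placement does not fit inside the window")
    raw = (
        model.score_hexamer(window_sequence[i35 : i35 + 6], "-35")
        + model.score_hexamer(window_sequence[i10 : i10 + 6], "-10")
        - model.spacer_penalty * abs(spacer - model.spacer_optimum)
    )
    return raw, model.normalize(raw)


def scan_upstream(
    window: GenomeRegion | str,
    model: PromoterModel,
    threshold: float = 0.7,
    gene_id: str = "",
) -> list[PromoterHit]:
    """Enumerate every legal (-35 offset, spacer) placement in the window and
    keep those with normalised score >= threshold.

    Placements sharing a -10 box are merged, keeping the best raw score (a
    single -10 element can pair with several upstream hexamers).  Hits are
    returned most-distal first, ties broken by descending score.  Windows too
    short to hold -35 + minimal spacer + -10 yield an empty list.
    """
    if isinstance(window, GenomeRegion):
        seq = window.sequence
    else:
        seq = window
    seq = seq.upper()
    n = len(seq)
    if n < MIN_SPAN:
        return []
    # hexamer scores for every offset, computed once per window
    s35 = [model.score_hexamer(seq[i : i + 6], "-35") for i in range(n - 5)]
    s10 = [model.score_hexamer(seq[i : i + 6], "-10") for i in range(n - 5)]
    best_by_minus10: dict[int, PromoterHit] = {}
    for i35 in range(0, n - MIN_SPAN + 1):
        for spacer in range(model.spacer_min, model.spacer_max + 1):
            i10 = i35 + 6 + spacer
            if i10 + 6 > n:
                break
            raw = s35[i35] + s10[i10] - model.spacer_penalty * abs(spacer - model.spacer_optimum)
            norm = model.normalize(raw)
            if norm < threshold:
                continue
            hit = PromoterHit(
                gene_id=gene_id,
                offset_minus35=i35,
                offset_minus10=i10,
                spacer=spacer,
                raw_score=raw,
                norm_score=norm,
            )
            prev = best_by_minus10.get(i10)
            # keep the earlier (more distal) placement on numerical ties
            if prev is None or hit.raw_score > prev.raw_score + 1e-9:
                best_by_minus10[i10] = hit
    return sorted(
        best_by_minus10.values(), key=lambda h: (h.offset_minus35, -h.norm_score)
    )


def write_model(model: PromoterModel, path: str | Path) -> None:
    """Serialise a model: a spacer header line then two 6x4 probability-like
    blocks (the stored numbers are the log-odds bits)."""
    with open(path, "w") as fh:
        fh.write(
            f"#spacer\t{model.spacer_min}\t{model.spacer_max}\t"
            f"{model.spacer_optimum}\t{model.spacer_penalty}\n"
        )
        for label, pwm in (("-35", model.pwm_minus35), ("-10", model.pwm_minus10)):
            fh.write(f"#box\t{label}\n")
            for col in pwm:
                fh.write("\t".join(f"{v:.6f}" for v in col) + "\n")


def read_model(path: str | Path) -> PromoterModel:
    spacer: tuple[int, int, int, float] | None = None
    blocks: list[list[tuple[float, float, float, float]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#spacer"):
                _, smin, smax, sopt, pen = line.split("\t")
                spacer = (int(smin), int(smax), int(sopt), float(pen))
            elif line.startswith("#box"):
                blocks.append([])
            else:
                vals = tuple(float(v) for v in line.split("\t"))
                if len(vals) != 4:
                    raise ValueError(f"model row must have 4 columns: {line!r}")
                blocks[-1].append(vals)
    if spacer is None or len(blocks) != 2:
        raise ValueError("model file must contain a #spacer line and two #box blocks")
    return PromoterModel(
        pwm_minus35=tuple(blocks[0]),
        pwm_minus10=tuple(blocks[1]),
        spacer_min=spacer[0],
        spacer_max=spacer[1],
        spacer_optimum=spacer[2],
        spacer_penalty=spacer[3],
    )
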
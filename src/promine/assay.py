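"""Reporter-assay and CoA-assay arithmetic.

Promoter strength is read out as RFP fluorescence normalised by culture
density (RFU/OD600); CoA is quantified spectrophotometrically with the
phosphotransacetylase method, where three absorbance readings at 233 nm
(baseline E0, post-enzyme peak E1, post-second-addition E2) give units per
millilitre as U = (2*E1 - E0 - E2) * 5.55 * 413.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AssayRecord",
    "CoAMeasurement",
    "normalize_fluorescence",
    "fold_ratio",
    "rank_and_classify",
    "coa_units",
    "summarize_replicates",
    "read_assay_tsv",
    "read_coa_tsv",
    "COA_SLOPE",
]

#: exact slope of the CoA unit formula in (2*E1 - E0 - E2)
COA_SLOPE = 5.55 * 413  # = 2292.15


@dataclass(frozen=True)
class AssayRecord:
    """One plate-reader well: raw RFP fluorescence (ex 554 / em 586 nm) and OD600."""

    strain_id: str
    raw_fluorescence: float
    od600: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError(f"strain {self.strain_id!r}: od600 must be > 0")
        if self.raw_fluorescence < 0:
            raise ValueError(f"strain {self.strain_id!r}: negative fluorescence")


@dataclass(frozen=True)
class CoAMeasurement:
    """Phosphotransacetylase absorbance triple at 233 nm."""

    E0: float
    E1: float
    E2: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.E0, self.E1, self.E2) < 0:
            raise ValueError(f"measurement {self.label!r}: negative absorbance")


def normalize_fluorescence(record: AssayRecord) -> float:
    """Growth-normalised reporter signal: raw fluorescence / OD600."""
    return record.raw_fluorescence / record.od600


def fold_ratio(value: float, reference: float, decimals: int = 1) -> float:
    """value / reference, rounded half-away-from-zero to ``decimals`` places."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    q = value / reference
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(q) * scale + 0.5), q) / scale


def coa_units(m: CoAMeasurement) -> tuple[float, bool]:
    """CoA units per mL: U = (2*E1 - E0 - E2) * 5.55 * 413.

    Returns (U, below_detection); a negative U is flagged, never raised.
    """
    u = (2.0 * m.E1 - m.E0 - m.E2) * COA_SLOPE
    return u, u < 0.0


def summarize_replicates(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation; SD is None for n = 1."""
    if not values:
        raise ValueError("no replicate values")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def rank_and_classify(
    rfu_od: Mapping[str, float],
    negative_control: float | None,
    strong_cutoff: float = 6000.0,
    silent_factor: float = 1.5,
) -> pd.DataFrame:
    """Rank promoters by RFU/OD and bucket them as strong / weak / silent.

    Silent: signal at most ``silent_factor`` times the negative control;
    strong: at least ``strong_cutoff`` RFU/OD; everything between is weak.
    Without a negative control the class column is left empty (warning).
    Sorted descending, ties broken by promoter name.
    """
    order = sorted(rfu_od, key=lambda p: (-rfu_od[p], p))
    rows = []
    if negative_control is None:
        warnings.warn("no negative control supplied; classification skipped", stacklevel=2)
    for name in order:
        v = rfu_od[name]
        if negative_control is None:
            cls = ""
        elif v <= negative_control * silent_factor:
            cls = "silent"
        elif v >= strong_cutoff:
            cls = "strong"
        else:
            cls = "weak"
        rows.append({"promoter": name, "rfu_od": v, "class": cls})
    return pd.DataFrame(rows, columns=["promoter", "rfu_od", "class"])


def read_assay_tsv(path: str | Path) -> list[AssayRecord]:
    """Read a plate-reader table: strain, raw_rfu, od600, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"strain", "raw_rfu", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                AssayRecord(
                    strain_id=str(row["strain"]),
                    raw_fluorescence=float(row["raw_rfu"]),
                    od600=float(row["od600"]),
                    replicate=int(row.get("replicate", 1)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_coa_tsv(path: str | Path) -> list[CoAMeasurement]:
    """Read a CoA assay table: label, E0, E1, E2."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "E0", "E1", "E2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CoAMeasurement(
                    E0=float(row["E0"]),
                    E1=float(row["E1"]),
                    E2=float(row["E2"]),
                    label=str(row["label"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out
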
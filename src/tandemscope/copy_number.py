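"""Gene copy-number estimation from read depth and from qPCR ΔCT.

Depth route: reads overlapping a gene region by at least 1 bp are counted,
normalized to reads-per-million-bases (RPM = reads x 10^6 / (library_size x
region_length)), and the copy number is the fold increase of the gene RPM
over the mean of single-copy control-gene RPMs.  Any common rescaling of
all RPM values cancels in this ratio.

qPCR route: a standard curve (CT against log2 dilution) gives each primer
set a slope; every CT is corrected multiplicatively by its primer's slope,
and the per-plant copy number is 2^(corrected reference CT - corrected
target CT).  Estimates are averaged across plants and primer combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DepthObservation",
    "QpcrRun",
    "QpcrParams",
    "region_read_count",
    "estimate_copies_depth",
    "fit_dilution_slope",
    "estimate_copies_qpcr",
    "aggregate_qpcr",
]


@dataclass(frozen=True)
class DepthObservation:
    """Normalized read depth over one region.

    ``rpm`` may be supplied directly (e.g. from a published table) via
    :meth:`from_rpm`, or derived from raw counts via :meth:`from_counts`.
    """

    label: str
    rpm: float
    seq_id: str = ""
    start: int = 0
    end: int = 0
    read_count: int = 0
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.rpm < 0:
            raise ValueError("rpm must be non-negative")
        if self.library_size and self.read_count > self.library_size:
            raise ValueError("read_count exceeds library_size")

    @classmethod
    def from_rpm(cls, label: str, rpm: float) -> "DepthObservation":
        return cls(label=label, rpm=rpm)

    @classmethod
    def from_counts(
        cls,
        label: str,
        read_count: int,
        library_size: int,
        region_length: int,
        seq_id: str = "",
        start: int = 0,
        end: int = 0,
    ) -> "DepthObservation":
        if library_size <= 0 or region_length <= 0:
            raise ValueError("library_size and region_length must be positive")
        rpm = read_count * 1e6 / (library_size * region_length)
        return cls(
            label=label,
            rpm=rpm,
            seq_id=seq_id,
            start=start,
            end=end,
            read_count=read_count,
            library_size=library_size,
        )


@dataclass(frozen=True)
class QpcrRun:
    """One qPCR reaction: raw CT plus the dilution factor of its template."""

    plant_id: str
    primer_id: str
    ct: float
    dilution: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("CT must be positive")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")

    def corrected_ct(self, slope: float) -> float:
        """Primer-efficiency correction: CT multiplied by the standard-curve
        slope."""
        return self.ct * slope


@dataclass(frozen=True)
class QpcrParams:
    dilution_series: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    replicates: int = 2

    def __post_init__(self) -> None:
        if list(self.dilution_series) != sorted(set(self.dilution_series)):
            raise ValueError("dilution_series must be strictly increasing")


def region_read_count(
    placements: Iterable[tuple[str, str, int, int]],
    region: tuple[str, int, int],
) -> int:
    """Count read placements overlapping ``region`` by at least 1 bp.

    Placements are (read_id, seq_id, start, end) with 0-based half-open
    coordinates; a placement ending exactly where the region starts does
    not overlap.
    """
    seq_id, rstart, rend = region
    return sum(
        1
        for _, sid, s, e in placements
        if sid == seq_id and s < rend and e > rstart
    )


def estimate_copies_depth(
    gene: DepthObservation,
    controls: Sequence[DepthObservation],
    ndigits: int | None = 1,
) -> float:
    """Copy number as fold increase of the gene RPM over the control mean.

    Reported to one decimal by default (``ndigits=None`` for the raw
    ratio).  Raises if no controls are given or any control RPM is zero.
    """
    if not controls:
        raise ValueError("at least one control observation is required")
    if any(c.rpm == 0 for c in controls):
        raise ValueError("control rpm of zero: fold increase undefined")
    estimate = gene.rpm / mean(c.rpm for c in controls)
    return round(estimate, ndigits) if ndigits is not None else estimate


def fit_dilution_slope(
    runs: Sequence[QpcrRun], params: QpcrParams | None = None
) -> float:
    """OLS slope of CT against log2(dilution) across a standard curve.

    Replicates at the same dilution are pooled into the regression.  At
    least two distinct dilutions are required.
    """
    if len({r.dilution for r in runs}) < 2:
        raise ValueError("standard curve needs >= 2 distinct dilutions")
    x = np.log2([r.dilution for r in runs])
    y = np.array([r.ct for r in runs])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def estimate_copies_qpcr(
    ref_runs: Sequence[QpcrRun],
    target_runs: Sequence[QpcrRun],
    ref_slope: float,
    target_slope: float,
) -> dict[str, float]:
    """Per-plant copy number: 2^(mean corrected reference CT - mean
    corrected target CT).

    Reference and target runs must cover the same plants; unmatched plant
    ids raise.
    """
    if not (math.isfinite(ref_slope) and math.isfinite(target_slope)):
        raise ValueError("slopes must be finite")
    ref_by_plant: dict[str, list[float]] = {}
    for r in ref_runs:
        ref_by_plant.setdefault(r.plant_id, []).append(r.corrected_ct(ref_slope))
    tgt_by_plant: dict[str, list[float]] = {}
    for r in target_runs:
        tgt_by_plant.setdefault(r.plant_id, []).append(
            r.corrected_ct(target_slope)
        )
    if set(ref_by_plant) != set(tgt_by_plant):
        missing = set(ref_by_plant) ^ set(tgt_by_plant)
        raise ValueError(f"unmatched plant ids: {sorted(missing)}")
    return {
        plant: 2.0 ** (mean(ref_by_plant[plant]) - mean(tgt_by_plant[plant]))
        for plant in sorted(ref_by_plant)
    }


def aggregate_qpcr(estimates: Sequence[float]) -> float:
    """Final genotype copy number: arithmetic mean over all (plant, primer
    combination) estimates."""
    if not estimates:
        raise ValueError("no estimates to aggregate")
    return float(mean(estimates))
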
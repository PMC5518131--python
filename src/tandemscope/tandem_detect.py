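"""Tandem repeat calling from genome self-alignments.

The "alignment-to-self" method: align an assembly (or reference) against
itself with a repeat-sensitive aligner, keep only same-sequence off-diagonal
alignments, drop each mirror duplicate, and retain alignments with high
identity (default >= 95%), non-overlapping repeat units, and nearby
midpoints (default <= 1 Mbp apart).  Each surviving alignment is a called
tandem repeat pair.  A 2 Kbp unit-length threshold separates gene-scale
("long") from short repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentRecord, AssemblyStats, assembly_stats

__all__ = [
    "DetectionParams",
    "RepeatPair",
    "canonicalize_self_alignments",
    "detect_tandem_repeats",
    "partition_by_length",
    "repeat_collection_stats",
]


@dataclass(frozen=True)
class DetectionParams:
    """Filter thresholds for tandem repeat calling.

    min_identity_pct
        Minimum alignment identity to call a pair (>= comparison).
    max_midpoint_sep
        Maximum separation of the two unit midpoints, in bases.
    long_unit_threshold
        Unit length (bases) at and above which a pair counts as "long".
    include_reverse_strand
        Whether inverted (reverse-strand) self-alignments are eligible.
    """

    min_identity_pct: float = 95.0
    max_midpoint_sep: int = 1_000_000
    long_unit_threshold: int = 2000
    include_reverse_strand: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity_pct <= 100.0):
            raise ValueError("min_identity_pct outside [0,100]")
        if self.max_midpoint_sep <= 0 or self.long_unit_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class RepeatPair:
    """A called tandem duplication: two non-overlapping intervals on one
    sequence, with alignment identity and midpoint separation."""

    seq_id: str
    unit1: tuple[int, int]
    unit2: tuple[int, int]
    identity_pct: float
    midpoint_sep: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.unit1[0] >= self.unit2[0] and self.unit1 != self.unit2:
            raise ValueError("unit1 must start before unit2")
        if self.unit1[1] > self.unit2[0]:
            raise ValueError("repeat units must not overlap")

    @property
    def unit_lengths(self) -> tuple[int, int]:
        return (self.unit1[1] - self.unit1[0], self.unit2[1] - self.unit2[0])


def _midpoint(interval: tuple[int, int]) -> int:
    return (interval[0] + interval[1]) // 2


def _ordered_units(
    rec: AlignmentRecord,
) -> tuple[tuple[int, int], tuple[int, int]]:
    a, b = rec.query_interval, rec.target_interval
    return (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)


def canonicalize_self_alignments(
    alignments: Iterable[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Reduce a raw self-alignment table to unique same-sequence pairs.

    Keeps only records of a sequence against itself, drops the trivial
    full-diagonal match (identical intervals), reorders each record so the
    earlier-starting interval comes first (as the query), and removes
    mirror/exact duplicates, keeping the highest identity seen for a given
    interval pair and strand.
    """
    best: dict[tuple, AlignmentRecord] = {}
    order: list[tuple] = []
    for rec in alignments:
        if rec.query_id != rec.target_id:
            continue
        if rec.query_interval == rec.target_interval:
            continue  # diagonal self-match
        unit1, unit2 = _ordered_units(rec)
        key = (rec.query_id, unit1, unit2, rec.strand)
        canon = AlignmentRecord(
            query_id=rec.query_id,
            target_id=rec.target_id,
            query_start=unit1[0],
            query_end=unit1[1],
            target_start=unit2[0],
            target_end=unit2[1],
            strand=rec.strand,
            identity_pct=rec.identity_pct,
        )
        if key not in best:
            best[key] = canon
            order.append(key)
        elif canon.identity_pct > best[key].identity_pct:
            best[key] = canon
    return [best[k] for k in sorted(order)]


def detect_tandem_repeats(
    alignments: Iterable[AlignmentRecord],
    params: DetectionParams | None = None,
) -> list[RepeatPair]:
    """Call tandem repeat pairs from a self-alignment table.

    Canonicalization is applied internally (idempotent), then each
    candidate must pass, in order: same-strand eligibility, identity >=
    ``min_identity_pct``, non-overlapping units, and midpoint separation
    <= ``max_midpoint_sep``.  Output is sorted by (seq_id, unit1, unit2).
    """
    params = params or DetectionParams()
    pairs: list[RepeatPair] = []
    for rec in canonicalize_self_alignments(alignments):
        if rec.strand == "-" and not params.include_reverse_strand:
            continue
        if rec.identity_pct < params.min_identity_pct:
            continue
        unit1, unit2 = rec.query_interval, rec.target_interval
        if unit1[1] > unit2[0]:  # overlap (units are start-ordered)
            continue
        sep = abs(_midpoint(unit2) - _midpoint(unit1))
        if sep > params.max_midpoint_sep:
            continue
        pairs.append(
            RepeatPair(
                seq_id=rec.query_id,
                unit1=unit1,
                unit2=unit2,
                identity_pct=rec.identity_pct,
                midpoint_sep=sep,
                strand=rec.strand,
            )
        )
    pairs.sort(key=lambda p: (p.seq_id, p.unit1, p.unit2, p.strand))
    return pairs


def partition_by_length(
    pairs: Iterable[RepeatPair], params: DetectionParams | None = None
) -> tuple[list[RepeatPair], list[RepeatPair]]:
    """Split pairs into (long, short) at the unit-length threshold.

    A pair is long iff the *smaller* of its two unit lengths is at or above
    ``long_unit_threshold`` (both units must be gene-scale).
    """
    params = params or DetectionParams()
    long_pairs: list[RepeatPair] = []
    short_pairs: list[RepeatPair] = []
    for p in pairs:
        if min(p.unit_lengths) >= params.long_unit_threshold:
            long_pairs.append(p)
        else:
            short_pairs.append(p)
    return long_pairs, short_pairs


def repeat_collection_stats(pairs: Sequence[RepeatPair]) -> AssemblyStats:
    """Size statistics over the multiset of all unit lengths (two per pair)."""
    if not pairs:
        raise ValueError("repeat_collection_stats requires at least one pair")
    lengths = [length for p in pairs for length in p.unit_lengths]
    return assembly_stats(lengths, genome_size=sum(lengths))
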
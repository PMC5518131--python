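"""Repeat-capture classification of tandem pairs against an assembly.

Given tandem repeat pairs called on a reference and alignments of assembly
scaffolds to that reference, each pair is classified as:

``one_scaffold``
    both repeat units are more than 50% covered by alignments from a single
    scaffold (checked first; a collapsed assembly copy can capture several
    reference repeats this way);
``two_scaffolds``
    each unit is more than 50% covered, but only by two different scaffolds;
``underrepresented``
    either unit fails to reach 50% coverage.

The same machinery runs with reference and assembly roles reversed
(``reciprocal_assessment``), where the categories read one-chromosome /
two-chromosomes / underrepresented and a two-chromosome call flags a false
duplication in the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentRecord
from .tandem_detect import RepeatPair

__all__ = [
    "CaptureParams",
    "CaptureCall",
    "unit_coverage",
    "classify_capture",
    "count_single_alignment_captures",
    "reciprocal_assessment",
    "ONE_SCAFFOLD",
    "TWO_SCAFFOLDS",
    "UNDERREPRESENTED",
]

ONE_SCAFFOLD = "one_scaffold"
TWO_SCAFFOLDS = "two_scaffolds"
UNDERREPRESENTED = "underrepresented"


@dataclass(frozen=True)
class CaptureParams:
    """Coverage threshold for capture calls; strictly greater-than, so a
    unit covered at exactly the threshold does not count."""

    coverage_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold < 1.0):
            raise ValueError("coverage_threshold must be in (0,1)")


@dataclass(frozen=True)
class CaptureCall:
    pair: RepeatPair
    category: str
    covering_ids: tuple[str, ...]
    unit_coverages: tuple[float, float]
    single_alignment: bool


def _union_covered(intervals: list[tuple[int, int]], unit: tuple[int, int]) -> int:
    """Bases of ``unit`` covered by the union of ``intervals``."""
    clipped = sorted(
        (max(s, unit[0]), min(e, unit[1]))
        for s, e in intervals
        if max(s, unit[0]) < min(e, unit[1])
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def unit_coverage(
    unit: tuple[int, int],
    seq_id: str,
    alignments: Iterable[AlignmentRecord],
    scaffold_id: str | None = None,
) -> float:
    """Fraction of ``unit`` (on reference sequence ``seq_id``) covered by
    the union of alignment target intervals, optionally restricted to one
    scaffold's alignments."""
    if unit[1] <= unit[0]:
        raise ValueError("zero-length unit")
    intervals = [
        rec.target_interval
        for rec in alignments
        if rec.target_id == seq_id
        and (scaffold_id is None or rec.query_id == scaffold_id)
    ]
    return _union_covered(intervals, unit) / (unit[1] - unit[0])


def classify_capture(
    pairs: Sequence[RepeatPair],
    assembly_alignments: Sequence[AlignmentRecord],
    params: CaptureParams | None = None,
) -> list[CaptureCall]:
    """Classify every reference pair by how assembly alignments cover it.

    Alignment query ids are assembly scaffolds; target ids are reference
    sequences.  When several scaffolds qualify for ``one_scaffold``, the
    one with the larger summed unit coverage wins (ties broken by
    lexicographic id).
    """
    params = params or CaptureParams()
    thr = params.coverage_threshold
    by_target: dict[str, dict[str, list[AlignmentRecord]]] = {}
    for rec in assembly_alignments:
        by_target.setdefault(rec.target_id, {}).setdefault(rec.query_id, []).append(rec)

    calls: list[CaptureCall] = []
    for pair in pairs:
        per_scaffold = by_target.get(pair.seq_id, {})
        cov: dict[str, tuple[float, float]] = {}
        for sid, recs in per_scaffold.items():
            ivals = [r.target_interval for r in recs]
            c1 = _union_covered(ivals, pair.unit1) / (pair.unit1[1] - pair.unit1[0])
            c2 = _union_covered(ivals, pair.unit2) / (pair.unit2[1] - pair.unit2[0])
            if c1 > 0 or c2 > 0:
                cov[sid] = (c1, c2)

        single = any(
            _union_covered([r.target_interval], pair.unit1)
            > thr * (pair.unit1[1] - pair.unit1[0])
            and _union_covered([r.target_interval], pair.unit2)
            > thr * (pair.unit2[1] - pair.unit2[0])
            for recs in per_scaffold.values()
            for r in recs
        )

        both = {s: c for s, c in cov.items() if c[0] > thr and c[1] > thr}
        if both:
            sid = min(both, key=lambda s: (-(both[s][0] + both[s][1]), s))
            calls.append(
                CaptureCall(pair, ONE_SCAFFOLD, (sid,), both[sid], single)
            )
            continue
        s1 = {s: c for s, c in cov.items() if c[0] > thr}
        s2 = {s: c for s, c in cov.items() if c[1] > thr}
        if s1 and s2:
            a = min(s1, key=lambda s: (-s1[s][0], s))
            b = min(s2, key=lambda s: (-s2[s][1], s))
            calls.append(
                CaptureCall(
                    pair,
                    TWO_SCAFFOLDS,
                    (a, b),
                    (s1[a][0], s2[b][1]),
                    single,
                )
            )
            continue
        best1 = max((c[0] for c in cov.values()), default=0.0)
        best2 = max((c[1] for c in cov.values()), default=0.0)
        calls.append(
            CaptureCall(pair, UNDERREPRESENTED, (), (best1, best2), single)
        )
    return calls


def count_single_alignment_captures(calls: Iterable[CaptureCall]) -> int:
    """Pairs captured within one alignment record: positional agreement of
    both units and any intervening sequence."""
    return sum(1 for c in calls if c.single_alignment)


def reciprocal_assessment(
    assembly_pairs: Sequence[RepeatPair],
    assembly_to_reference_alignments: Sequence[AlignmentRecord],
    params: CaptureParams | None = None,
) -> list[CaptureCall]:
    """Classify assembly-side pairs by coverage from reference chromosomes.

    Identical logic with roles swapped: pairs live on assembly scaffolds,
    and the covering entities are reference chromosomes.  Categories read
    one_chromosome / two_chromosomes / underrepresented; a two-chromosome
    call indicates a likely false duplicate in the assembly.
    """
    flipped = [rec.flipped() for rec in assembly_to_reference_alignments]
    return classify_capture(assembly_pairs, flipped, params)
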
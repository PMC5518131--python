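"""Synthetic genomes with planted tandem arrays, and the ground truth to
score every other stage against.

The generator plants arrays of near-identical units (substitution-only
divergence, so pairwise identity is exact Hamming arithmetic) in a uniform
random background, emits analytic self-alignments (diagonal, every
copy-vs-copy match, and all mirrors), corrupts assemblies in the three ways
that realize the capture categories (collapse, fragment, delete), and
simulates uniform long-read placements and tandem gene-family fixtures.

Alignment emission for corrupted assemblies is analytic, not an aligner
run.  Two documented policies bracket what real alignment pipelines
produce: a collapsed assembly copy aligns to every reference copy it
represents (all-matches semantics, which is what makes a collapsed repeat
land in the one-scaffold category), while fragmented and unit-deleted
assemblies are given true-origin alignments only (best-per-position
filtered semantics).  Each corruption operator is paired with the policy
under which its expected category is the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .capture_eval import ONE_SCAFFOLD, TWO_SCAFFOLDS, UNDERREPRESENTED
from .gene_clusters import GeneRecord
from .io_formats import AlignmentRecord, SequenceRecord
from .tandem_detect import DetectionParams, RepeatPair

__all__ = [
    "ArraySpec",
    "PlantedArray",
    "TruthSet",
    "CorruptionResult",
    "make_genome_with_arrays",
    "emit_self_alignments",
    "corrupt_assembly",
    "simulate_long_read_placements",
    "make_gene_fixture",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_ALPHABET, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _ALPHABET[_ALPHABET != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _hamming_identity_pct(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float(np.mean(xa == xb))


@dataclass(frozen=True)
class ArraySpec:
    """A tandem array to plant: ``copies`` units of ``unit_len`` bases,
    separated by spacers, starting ``position`` bases into the background,
    with substitution divergence per copy relative to the master unit."""

    unit_len: int
    copies: int
    spacer_len: int
    divergence: float = 0.0
    position: int = 0

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("an array needs >= 2 copies")
        if not (0.0 <= self.divergence <= 0.05):
            raise ValueError("divergence must be in [0, 0.05]")
        if self.unit_len < 1 or self.spacer_len < 0:
            raise ValueError("bad unit or spacer length")

    @property
    def span(self) -> int:
        return self.copies * self.unit_len + (self.copies - 1) * self.spacer_len


@dataclass(frozen=True)
class PlantedArray:
    spec: ArraySpec
    unit_intervals: tuple[tuple[int, int], ...]
    unit_seqs: tuple[str, ...]


@dataclass
class TruthSet:
    """A planted genome plus everything needed to score detection and
    capture classification on it."""

    genome: SequenceRecord
    arrays: list[PlantedArray]
    expected_pairs: list[RepeatPair] = field(default_factory=list)
    detection_params: DetectionParams = field(default_factory=DetectionParams)


def make_genome_with_arrays(
    background_len: int,
    specs: Sequence[ArraySpec],
    seed: int,
    detection_params: DetectionParams | None = None,
) -> TruthSet:
    """Build a genome with the given arrays planted over an i.i.d. uniform
    background (arrays overwrite the background in place; they must fit and
    must not overlap).

    ``expected_pairs`` holds every copy-vs-copy pair whose Hamming identity
    and midpoint separation pass the detection thresholds.
    """
    params = detection_params or DetectionParams()
    rng = np.random.default_rng(seed)
    placed = sorted(specs, key=lambda s: s.position)
    prev_end = 0
    for spec in placed:
        if spec.position < prev_end:
            raise ValueError("planted arrays overlap")
        prev_end = spec.position + spec.span
        if prev_end > background_len:
            raise ValueError("array extends past background end")

    genome = np.frombuffer(
        _random_seq(rng, background_len).encode(), dtype=np.uint8
    ).copy()
    arrays: list[PlantedArray] = []
    for spec in placed:
        master = _random_seq(rng, spec.unit_len)
        intervals = []
        seqs = []
        cursor = spec.position
        for c in range(spec.copies):
            copy_seq = _mutate(rng, master, spec.divergence)
            genome[cursor : cursor + spec.unit_len] = np.frombuffer(
                copy_seq.encode(), dtype=np.uint8
            )
            intervals.append((cursor, cursor + spec.unit_len))
            seqs.append(copy_seq)
            cursor += spec.unit_len
            if c < spec.copies - 1:
                spacer = _random_seq(rng, spec.spacer_len)
                genome[cursor : cursor + spec.spacer_len] = np.frombuffer(
                    spacer.encode(), dtype=np.uint8
                )
                cursor += spec.spacer_len
        arrays.append(PlantedArray(spec, tuple(intervals), tuple(seqs)))

    truth = TruthSet(
        genome=SequenceRecord("synth_genome", genome.tobytes().decode()),
        arrays=arrays,
        detection_params=params,
    )
    for arr in arrays:
        k = len(arr.unit_intervals)
        for i in range(k):
            for j in range(i + 1, k):
                u1, u2 = arr.unit_intervals[i], arr.unit_intervals[j]
                ident = _hamming_identity_pct(arr.unit_seqs[i], arr.unit_seqs[j])
                sep = (u2[0] + u2[1]) // 2 - (u1[0] + u1[1]) // 2
                if ident >= params.min_identity_pct and sep <= params.max_midpoint_sep:
                    truth.expected_pairs.append(
                        RepeatPair(
                            seq_id=truth.genome.id,
                            unit1=u1,
                            unit2=u2,
                            identity_pct=ident,
                            midpoint_sep=sep,
                        )
                    )
    truth.expected_pairs.sort(key=lambda p: (p.seq_id, p.unit1, p.unit2))
    return truth


def emit_self_alignments(truth: TruthSet) -> list[AlignmentRecord]:
    """Analytic stand-in for a self-alignment run: the full diagonal, every
    copy-vs-copy alignment with its exact Hamming identity, and every
    mirror record, so canonicalization has real work to do."""
    gid = truth.genome.id
    L = len(truth.genome)
    records = [
        AlignmentRecord(gid, gid, 0, L, 0, L, "+", 100.0)  # diagonal
    ]
    for arr in truth.arrays:
        k = len(arr.unit_intervals)
        for i in range(k):
            for j in range(i + 1, k):
                u1, u2 = arr.unit_intervals[i], arr.unit_intervals[j]
                ident = _hamming_identity_pct(arr.unit_seqs[i], arr.unit_seqs[j])
                records.append(
                    AlignmentRecord(gid, gid, u1[0], u1[1], u2[0], u2[1], "+", ident)
                )
                records.append(  # mirror
                    AlignmentRecord(gid, gid, u2[0], u2[1], u1[0], u1[1], "+", ident)
                )
    return records


@dataclass
class CorruptionResult:
    assembly: list[SequenceRecord]
    alignments: list[AlignmentRecord]  # assembly (query) vs reference (target)
    expected_calls: dict[tuple[tuple[int, int], tuple[int, int]], str]
    # keyed by (unit1, unit2) of each expected reference pair


def _origin_alignments(
    segments: list[tuple[str, int, int, int]], ref_id: str
) -> list[AlignmentRecord]:
    # segments: (assembly_id, asm_start, ref_start, length), identity 100
    return [
        AlignmentRecord(
            query_id=aid,
            target_id=ref_id,
            query_start=astart,
            query_end=astart + length,
            target_start=rstart,
            target_end=rstart + length,
            strand="+",
            identity_pct=100.0,
        )
        for aid, astart, rstart, length in segments
        if length > 0
    ]


def corrupt_assembly(
    truth: TruthSet, op: str, array_index: int = 0, unit_index: int = 1
) -> CorruptionResult:
    """Apply one corruption operator to the planted genome.

    ``op`` is one of:

    - ``"collapse"``: the array keeps only its first unit; the retained
      copy additionally aligns to every reference copy it stands in for
      (expected category: one_scaffold — collapsed capture);
    - ``"fragment"``: the genome is cut in the spacer after
      ``unit_index`` (1-based count of units on the left side), yielding
      two scaffolds (pairs straddling the cut: two_scaffolds);
    - ``"delete_unit"``: unit ``unit_index`` (0-based) is excised and only
      true-origin alignments are emitted (pairs involving it:
      underrepresented).

    Pairs untouched by the corruption stay one_scaffold.
    """
    if not (0 <= array_index < len(truth.arrays)):
        raise ValueError(f"unknown array index {array_index}")
    arr = truth.arrays[array_index]
    ref = truth.genome
    gid = ref.id
    L = len(ref)

    def baseline_calls() -> dict:
        return {(p.unit1, p.unit2): ONE_SCAFFOLD for p in truth.expected_pairs}

    if op == "collapse":
        # Drop everything from the end of unit 1 through the end of the array.
        cut_start = arr.unit_intervals[0][1]
        cut_end = arr.unit_intervals[-1][1]
        asm_id = "asm_0"
        asm_seq = ref.sequence[:cut_start] + ref.sequence[cut_end:]
        segments = [
            (asm_id, 0, 0, cut_start),
            (asm_id, cut_start, cut_end, L - cut_end),
        ]
        alignments = _origin_alignments(segments, gid)
        u0 = arr.unit_intervals[0]
        for j in range(1, len(arr.unit_intervals)):
            uj = arr.unit_intervals[j]
            alignments.append(
                AlignmentRecord(
                    query_id=asm_id,
                    target_id=gid,
                    query_start=u0[0],
                    query_end=u0[1],
                    target_start=uj[0],
                    target_end=uj[1],
                    strand="+",
                    identity_pct=_hamming_identity_pct(
                        arr.unit_seqs[0], arr.unit_seqs[j]
                    ),
                )
            )
        return CorruptionResult(
            [SequenceRecord(asm_id, asm_seq)], alignments, baseline_calls()
        )

    if op == "fragment":
        if not (1 <= unit_index < len(arr.unit_intervals)):
            raise ValueError("fragment cut must fall between units")
        left_end = arr.unit_intervals[unit_index - 1][1]
        right_start = arr.unit_intervals[unit_index][0]
        cut = (left_end + right_start) // 2
        segments = [
            ("asm_0", 0, 0, cut),
            ("asm_1", 0, cut, L - cut),
        ]
        assembly = [
            SequenceRecord("asm_0", ref.sequence[:cut]),
            SequenceRecord("asm_1", ref.sequence[cut:]),
        ]
        calls = baseline_calls()
        for p in truth.expected_pairs:
            if p.unit1[1] <= cut <= p.unit2[0]:
                calls[(p.unit1, p.unit2)] = TWO_SCAFFOLDS
        return CorruptionResult(
            assembly, _origin_alignments(segments, gid), calls
        )

    if op == "delete_unit":
        if not (0 <= unit_index < len(arr.unit_intervals)):
            raise ValueError("unknown unit index")
        u = arr.unit_intervals[unit_index]
        asm_id = "asm_0"
        assembly = [
            SequenceRecord(asm_id, ref.sequence[: u[0]] + ref.sequence[u[1] :])
        ]
        segments = [
            (asm_id, 0, 0, u[0]),
            (asm_id, u[0], u[1], L - u[1]),
        ]
        calls = baseline_calls()
        for p in truth.expected_pairs:
            if p.unit1 == u or p.unit2 == u:
                calls[(p.unit1, p.unit2)] = UNDERREPRESENTED
        return CorruptionResult(
            assembly, _origin_alignments(segments, gid), calls
        )

    raise ValueError(f"unknown corruption operator {op!r}")


def simulate_long_read_placements(
    length: int, coverage: float, read_len: int, seed: int
) -> list[tuple[int, int]]:
    """Uniform-start long-read placements over [0, length) at a target mean
    coverage.  Returns (start, end) tuples; empty for coverage 0."""
    if read_len > length:
        raise ValueError("read_len exceeds sequence length")
    n = int(round(coverage * length / read_len))
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, length - read_len + 1, size=n)
    return [(int(s), int(s) + read_len) for s in starts]


def make_gene_fixture(
    family_sizes: Sequence[int],
    te_density: float,
    seed: int,
    gene_len: int = 1000,
    gene_gap: int = 500,
) -> tuple[list[GeneRecord], list[tuple[str, str, float]], list[frozenset[str]]]:
    """Gene table + similarity hits + expected tandem clusters.

    Each family is laid out as a consecutive run of member genes on one
    scaffold; TE genes are interleaved between members with probability
    ``te_density`` (TEs never break tandem pairs).  Families are separated
    by two non-TE singleton genes, which do break pairs.  Within-family
    hits get strong E-values; there are no cross-family hits, so the
    expected tandem clusters are exactly the families of size >= 2.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    hits: list[tuple[str, str, float]] = []
    expected: list[frozenset[str]] = []
    pos = 0
    scaffold = "scf1"

    def add_gene(gene_id: str, is_te: bool) -> None:
        nonlocal pos
        genes.append(
            GeneRecord(gene_id, scaffold, pos, pos + gene_len, "+", is_te)
        )
        pos += gene_len + gene_gap

    te_count = 0
    for fi, size in enumerate(family_sizes):
        members = [f"fam{fi}_g{m}" for m in range(size)]
        for m, gene_id in enumerate(members):
            add_gene(gene_id, is_te=False)
            if m < size - 1 and rng.random() < te_density:
                add_gene(f"te_{te_count}", is_te=True)
                te_count += 1
        for a in range(size):
            for b in range(a + 1, size):
                evalue = 10.0 ** -float(rng.integers(60, 120))
                hits.append((members[a], members[b], evalue))
        if size >= 2:
            expected.append(frozenset(members))
        # Two non-TE spacer genes isolate this family from the next.
        add_gene(f"spacer_{fi}_a", is_te=False)
        add_gene(f"spacer_{fi}_b", is_te=False)
    return genes, hits, expected
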
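"""Synthetic-mate scaffolding and coverage-based scaffold QC.

The stages, at desk scale: sample synthetic 2 x 2000 bp innie mate pairs at
10/40/160 Kbp insert sizes (up to 200-fold per insert class) from guide
scaffolds; place the reads on contigs by unique exact matching; bundle
cross-contig pairs into weighted links with orientation and a median gap
estimate; lay contigs out greedily by link support with end-occupancy and
cycle checks; and finally filter scaffolds with fewer than 15 supporting
reads and split them wherever long-read coverage drops below 2-fold.

The greedy end-occupancy scaffolder is this package's own construction:
upstream pipelines delegate this step to an assembler whose internals are
not specified, so only its inputs (links) and outputs (scaffold layouts)
are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "ScaffoldParams",
    "MatePair",
    "MatePlacement",
    "MateLink",
    "QcParams",
    "ScaffoldLayout",
    "sample_synthetic_mates",
    "map_mates_exact",
    "bundle_links",
    "layout_scaffolds",
    "layout_to_sequences",
    "coverage_profile",
    "filter_and_split_scaffolds",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ScaffoldParams:
    """Synthetic-mate sampling and link-bundling parameters.

    coverage_per_insert is the target fold coverage contributed by each
    insert class separately; insert_sd_frac is the relative spread of the
    sampled insert size.
    """

    read_len: int = 2000
    insert_sizes: tuple[int, ...] = (10_000, 40_000, 160_000)
    coverage_per_insert: float = 200.0
    insert_sd_frac: float = 0.1
    min_link_support: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if any(i <= 2 * self.read_len for i in self.insert_sizes):
            raise ValueError("insert sizes must exceed 2 x read_len")


@dataclass(frozen=True)
class MatePair:
    """An innie pair sampled from a guide scaffold: the forward read starts
    at ``pos1``; the reverse read is the reverse complement of the guide
    ending at ``pos2 + read_len``."""

    pair_id: str
    origin_id: str
    insert_class: int
    pos1: int
    pos2: int
    read1: str
    read2: str


@dataclass(frozen=True)
class MatePlacement:
    pair_id: str
    mate: int  # 1 or 2
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MateLink:
    """Bundled evidence joining two contig ends.

    ``end_a``/``end_b`` are 'L' or 'R': the facing end of each contig in
    its own coordinates.  An R-L join means b follows a in the same
    orientation; R-R means b is reversed; etc.
    """

    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    gap_estimate: int
    support: int

    @property
    def orientation(self) -> str:
        return {"RL": "forward", "RR": "reverse", "LL": "reverse", "LR": "forward"}[
            self.end_a + self.end_b
        ]


@dataclass(frozen=True)
class QcParams:
    min_reads_per_scaffold: int = 15
    min_split_coverage: int = 2
    min_piece_len: int = 200

    def __post_init__(self) -> None:
        if min(
            self.min_reads_per_scaffold,
            self.min_split_coverage,
            self.min_piece_len,
        ) < 1:
            raise ValueError("QC parameters must all be >= 1")


@dataclass
class ScaffoldLayout:
    """Ordered, oriented contigs with estimated gaps after each one."""

    scaffold_id: str
    entries: list[tuple[str, str, int]] = field(default_factory=list)
    # (contig_id, orientation '+'/'-', gap after this contig; last gap 0)


# ---------------------------------------------------------------------------
# Mate sampling


def sample_synthetic_mates(
    scaffolds: Sequence[SequenceRecord], params: ScaffoldParams
) -> list[MatePair]:
    """Sample synthetic long-range innie mate pairs from guide scaffolds.

    Per insert class and scaffold, the pair count is
    floor(coverage x scaffold_len / (2 x read_len)).  Insert sizes are
    jittered (normal, sd = insert_sd_frac x insert); pairs that would
    overhang the scaffold are skipped, as are reads that are more than
    50% N.  Deterministic for a given rng_seed.
    """
    rng = np.random.default_rng(params.rng_seed)
    rl = params.read_len
    pairs: list[MatePair] = []
    for scaffold in scaffolds:
        L = len(scaffold)
        seq = scaffold.sequence
        for insert in params.insert_sizes:
            n_pairs = int(params.coverage_per_insert * L / (2 * rl))
            if insert > L or n_pairs == 0:
                continue
            sd = params.insert_sd_frac * insert
            starts = rng.integers(0, L, size=n_pairs)
            inserts = np.rint(rng.normal(insert, sd, size=n_pairs)).astype(int)
            for k in range(n_pairs):
                ins = int(inserts[k])
                if ins < 2 * rl:
                    continue
                p1 = int(starts[k])
                p2 = p1 + ins - rl  # start of the reverse read
                if p2 + rl > L:
                    continue
                read1 = seq[p1 : p1 + rl]
                read2 = _revcomp(seq[p2 : p2 + rl])
                if read1.count("N") * 2 > rl or read2.count("N") * 2 > rl:
                    continue
                pairs.append(
                    MatePair(
                        pair_id=f"{scaffold.id}:{insert}:{k}",
                        origin_id=scaffold.id,
                        insert_class=insert,
                        pos1=p1,
                        pos2=p2,
                        read1=read1,
                        read2=read2,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# Exact mapping

_MAX_KMER_HITS = 64


def _build_kmer_index(
    contigs: Sequence[SequenceRecord], k: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for contig in contigs:
        seq = contig.sequence
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            hits = index.setdefault(kmer, [])
            if len(hits) <= _MAX_KMER_HITS:
                hits.append((contig.id, pos))
    return index


def map_mates_exact(
    pairs: Sequence[MatePair],
    contigs: Sequence[SequenceRecord],
    k: int = 31,
) -> list[MatePlacement]:
    """Place mate reads on contigs by unique full-length exact match.

    Each read is anchored by its leading k-mer and verified by exact
    extension over the full read; both orientations are tried.  A read
    with zero or more than one full-length placement is left unmapped.
    """
    if not contigs:
        raise ValueError("no contigs to map against")
    index = _build_kmer_index(contigs, k)
    by_id = {c.id: c.sequence for c in contigs}

    def occurrences(read: str) -> list[tuple[str, int]]:
        anchor = read[:k]
        hits = index.get(anchor, [])
        if len(hits) > _MAX_KMER_HITS:
            return hits[: _MAX_KMER_HITS + 1]  # treated as ambiguous
        found = []
        for cid, pos in hits:
            if by_id[cid][pos : pos + len(read)] == read:
                found.append((cid, pos))
        return found

    placements: list[MatePlacement] = []
    for pair in pairs:
        for mate, read in ((1, pair.read1), (2, pair.read2)):
            fwd = occurrences(read)
            rev = occurrences(_revcomp(read))
            if len(fwd) + len(rev) != 1:
                continue  # unmapped: absent or ambiguous
            if fwd:
                cid, pos = fwd[0]
                strand = "+"
            else:
                cid, pos = rev[0]
                strand = "-"
            placements.append(
                MatePlacement(
                    pair_id=pair.pair_id,
                    mate=mate,
                    contig_id=cid,
                    start=pos,
                    end=pos + len(read),
                    strand=strand,
                )
            )
    return placements


# ---------------------------------------------------------------------------
# Link bundling


def bundle_links(
    pairs: Sequence[MatePair],
    placements: Sequence[MatePlacement],
    params: ScaffoldParams,
    contig_lengths: dict[str, int] | None = None,
) -> list[MateLink]:
    """Group cross-contig mate pairs into links.

    A placed mate on strand '+' points rightward, exiting its contig via
    the R end; on strand '-' it exits via the L end.  Pairs are grouped by
    the (contig end, contig end) they join; the gap estimate is the median
    over the group of insert_class minus both reads' distances to their
    facing ends.  Groups with support below ``min_link_support`` are
    dropped.
    """
    if contig_lengths is None:
        raise ValueError("contig_lengths is required for gap estimation")
    insert_of = {p.pair_id: p.insert_class for p in pairs}
    by_pair: dict[str, dict[int, MatePlacement]] = {}
    for pl in placements:
        by_pair.setdefault(pl.pair_id, {})[pl.mate] = pl

    groups: dict[tuple, list[int]] = {}
    for pair_id, mates in by_pair.items():
        if len(mates) != 2:
            continue
        a, b = mates[1], mates[2]
        if a.contig_id == b.contig_id:
            continue

        def end_and_tail(pl: MatePlacement) -> tuple[str, int]:
            if pl.strand == "+":
                return "R", contig_lengths[pl.contig_id] - pl.start
            return "L", pl.end

        end_a, tail_a = end_and_tail(a)
        end_b, tail_b = end_and_tail(b)
        gap = insert_of[pair_id] - tail_a - tail_b
        key_a, key_b = (a.contig_id, end_a), (b.contig_id, end_b)
        if key_b < key_a:
            key_a, key_b = key_b, key_a
        groups.setdefault((key_a, key_b), []).append(gap)

    links = []
    for ((ca, ea), (cb, eb)), gaps in sorted(groups.items()):
        if len(gaps) < params.min_link_support:
            continue
        links.append(
            MateLink(
                contig_a=ca,
                end_a=ea,
                contig_b=cb,
                end_b=eb,
                gap_estimate=int(median(gaps)),
                support=len(gaps),
            )
        )
    return links


# ---------------------------------------------------------------------------
# Layout


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


GAP_FLOOR = 20


def layout_scaffolds(
    contigs: Sequence[SequenceRecord], links: Sequence[MateLink]
) -> list[ScaffoldLayout]:
    """Greedy end-occupancy scaffold construction.

    Links are processed in decreasing support order (ties by ids); a link
    is accepted iff both facing contig ends are still free and joining
    would not close a cycle.  Accepted joins form simple paths, emitted as
    layouts with gaps floored at 20 bp; unlinked contigs become singleton
    layouts.
    """
    ordered = sorted(
        links,
        key=lambda l: (-l.support, l.contig_a, l.contig_b, l.end_a, l.end_b),
    )
    occupied: set[tuple[str, str]] = set()
    uf = _UnionFind()
    accepted: dict[tuple[str, str], tuple[str, str, int]] = {}
    for link in ordered:
        ka = (link.contig_a, link.end_a)
        kb = (link.contig_b, link.end_b)
        if ka in occupied or kb in occupied:
            continue
        if uf.find(link.contig_a) == uf.find(link.contig_b):
            continue  # would close a cycle
        occupied.add(ka)
        occupied.add(kb)
        uf.union(link.contig_a, link.contig_b)
        accepted[ka] = (link.contig_b, link.end_b, link.gap_estimate)
        accepted[kb] = (link.contig_a, link.end_a, link.gap_estimate)

    layouts: list[ScaffoldLayout] = []
    visited: set[str] = set()
    cids = sorted(c.id for c in contigs)

    def free_end(cid: str) -> list[str]:
        return [e for e in ("L", "R") if (cid, e) not in accepted]

    counter = 0
    for cid in cids:
        if cid in visited:
            continue
        free = free_end(cid)
        if len(free) == 2:
            layouts.append(ScaffoldLayout(f"scaffold_{counter}", [(cid, "+", 0)]))
            visited.add(cid)
            counter += 1
            continue
        if not free:
            continue  # interior contig; reached from a terminal
        # Path terminal: walk to the other end.
        entries: list[tuple[str, str, int]] = []
        cur = cid
        # Entering a contig via its L end leaves it forward.
        enter = free[0]
        orient = "+" if enter == "L" else "-"
        while True:
            visited.add(cur)
            exit_end = ("R" if orient == "+" else "L")
            nxt = accepted.get((cur, exit_end))
            if nxt is None:
                entries.append((cur, orient, 0))
                break
            nb, nb_end, gap = nxt
            entries.append((cur, orient, max(gap, GAP_FLOOR)))
            cur = nb
            orient = "+" if nb_end == "L" else "-"
        layouts.append(ScaffoldLayout(f"scaffold_{counter}", entries))
        counter += 1
    return layouts


def layout_to_sequences(
    layouts: Sequence[ScaffoldLayout], contigs: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Render layouts as gapped scaffold sequences (N runs of the estimated
    gap length, floored so the 20-N contig-extraction rule inverts them)."""
    by_id = {c.id: c.sequence for c in contigs}
    out = []
    for layout in layouts:
        parts = []
        for i, (cid, orient, gap) in enumerate(layout.entries):
            seq = by_id[cid]
            parts.append(seq if orient == "+" else _revcomp(seq))
            if i < len(layout.entries) - 1:
                parts.append("N" * max(gap, GAP_FLOOR))
        out.append(SequenceRecord(layout.scaffold_id, "".join(parts)))
    return out


# ---------------------------------------------------------------------------
# Coverage QC


def coverage_profile(
    read_placements: Iterable[tuple[int, int]], length: int
) -> np.ndarray:
    """Per-base coverage from (start, end) placements, by difference-array
    accumulation.  Out-of-bounds placements raise."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for start, end in read_placements:
        if start < 0 or end > length or start >= end:
            raise ValueError(f"placement [{start},{end}) out of bounds 0..{length}")
        diff[start] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def filter_and_split_scaffolds(
    scaffolds: Sequence[SequenceRecord],
    placements_by_scaffold: dict[str, list[tuple[int, int]]],
    params: QcParams | None = None,
) -> list[SequenceRecord]:
    """Apply the read-support filter and the low-coverage split rule.

    Scaffolds with fewer than ``min_reads_per_scaffold`` placements are
    removed.  In survivors, every position with coverage below
    ``min_split_coverage`` is deleted and the maximal kept runs are emitted
    as new sequences; pieces shorter than ``min_piece_len`` are dropped.
    Piece ids record the source scaffold and offset.
    """
    params = params or QcParams()
    out: list[SequenceRecord] = []
    for scaffold in scaffolds:
        placements = placements_by_scaffold.get(scaffold.id, [])
        if len(placements) < params.min_reads_per_scaffold:
            continue
        cov = coverage_profile(placements, len(scaffold))
        keep = cov >= params.min_split_coverage
        if keep.all():
            out.append(scaffold)
            continue
        boundaries = np.flatnonzero(np.diff(keep.astype(np.int8)))
        edges = np.concatenate(([0], boundaries + 1, [len(scaffold)]))
        piece = 0
        for s, e in zip(edges[:-1], edges[1:]):
            if not keep[s]:
                continue
            if e - s < params.min_piece_len:
                continue
            out.append(
                SequenceRecord(
                    f"{scaffold.id}_piece{piece}_{s}",
                    scaffold.sequence[s:e],
                )
            )
            piece += 1
    return out
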
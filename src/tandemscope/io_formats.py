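"""Readers/writers for the standard formats the toolkit touches.

Covers FASTA sequence I/O, pairwise-alignment tables in PAF and nucmer
``show-coords`` tabular dialects, contig extraction from gapped scaffolds,
and assembly size statistics (N50/NG50).

All coordinates are 0-based half-open internally.  The 1-based inclusive
convention of ``show-coords`` exists only at the format boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "read_alignments",
    "write_alignments",
    "extract_contigs",
    "assembly_stats",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (scaffold, contig, or reference)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment between two sequences.

    Intervals are 0-based half-open and always forward on both sequences;
    reverse-strand alignments carry ``strand == "-"``.  ``aln_len_target``
    is measured in target coordinates (``tend - tstart``).
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    identity_pct: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError(
                f"bad query interval [{self.query_start},{self.query_end})"
            )
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"bad target interval [{self.target_start},{self.target_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity {self.identity_pct} outside [0,100]")

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)

    @property
    def aln_len_target(self) -> int:
        return self.target_end - self.target_start

    def flipped(self) -> "AlignmentRecord":
        """Swap query and target roles (for reciprocal analyses)."""
        return replace(
            self,
            query_id=self.target_id,
            target_id=self.query_id,
            query_start=self.target_start,
            query_end=self.target_end,
            target_start=self.query_start,
            target_end=self.query_end,
        )


@dataclass(frozen=True)
class AssemblyStats:
    """Size statistics of a sequence collection."""

    n_sequences: int
    total_span: int
    n50: int
    ng50: int
    max_len: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased :class:`SequenceRecord` objects.

    Duplicate ids raise; an empty file returns ``[]`` with a warning.
    File order is preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Alignment tables

_COORDS_SKIP = re.compile(r"^\s*$|^/|^NUCMER|^=+$|^\[")


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"malformed PAF line {lineno}: expected >=12 columns")
    try:
        qstart, qend = int(f[2]), int(f[3])
        tstart, tend = int(f[7]), int(f[8])
        nmatch, alnlen = int(f[9]), int(f[10])
    except ValueError as exc:
        raise ValueError(f"malformed PAF line {lineno}: {exc}") from None
    strand = f[4]
    identity = 100.0 * nmatch / alnlen if alnlen else 0.0
    if not (0.0 <= identity <= 100.0):
        raise ValueError(f"PAF line {lineno}: identity {identity} outside [0,100]")
    return AlignmentRecord(
        query_id=f[0],
        target_id=f[5],
        query_start=qstart,
        query_end=qend,
        target_start=tstart,
        target_end=tend,
        strand=strand,
        identity_pct=identity,
    )


def _parse_coords_line(line: str, lineno: int) -> AlignmentRecord:
    # show-coords -T -l -c: S1 E1 S2 E2 LEN1 LEN2 %IDY ... REF_NAME QRY_NAME
    # S1/E1 on the reference (target), S2/E2 on the query; 1-based inclusive.
    f = line.rstrip("\n").split("\t")
    if len(f) < 9:
        raise ValueError(
            f"malformed coords line {lineno}: expected >=9 tab-separated columns"
        )
    try:
        s1, e1, s2, e2 = (int(x) for x in f[:4])
        identity = float(f[6])
    except ValueError as exc:
        raise ValueError(f"malformed coords line {lineno}: {exc}") from None
    if not (0.0 <= identity <= 100.0):
        raise ValueError(
            f"coords line {lineno}: identity {identity} outside [0,100]"
        )
    target_id, query_id = f[-2], f[-1]
    strand = "+"
    if s1 > e1:
        s1, e1 = e1, s1
        strand = "-" if strand == "+" else "+"
    if s2 > e2:
        s2, e2 = e2, s2
        strand = "-" if strand == "+" else "+"
    return AlignmentRecord(
        query_id=query_id,
        target_id=target_id,
        query_start=s2 - 1,
        query_end=e2,
        target_start=s1 - 1,
        target_end=e1,
        strand=strand,
        identity_pct=identity,
    )


def read_alignments(path: str | Path, dialect: str = "paf") -> list[AlignmentRecord]:
    """Read an alignment table.

    ``dialect="paf"`` expects standard 12+-column PAF.  ``dialect="coords"``
    expects ``show-coords -T -l -c`` tabular output (1-based inclusive
    coordinates, identity in column 7, sequence names in the last two
    columns); header lines are skipped.  Reverse-strand records (start >
    end on one side) are normalized to forward intervals with strand "-".
    """
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if dialect == "coords" and _COORDS_SKIP.match(line):
                continue
            if not line.strip():
                continue
            if dialect == "paf":
                out.append(_parse_paf_line(line, lineno))
            else:
                out.append(_parse_coords_line(line, lineno))
    return out


def write_alignments(
    records: Iterable[AlignmentRecord], path: str | Path, dialect: str = "paf"
) -> None:
    """Write alignment records in PAF or show-coords tabular form.

    PAF residue-match counts are reconstructed from the identity so that a
    write/read round trip preserves intervals and (approximately) identity.
    """
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for r in records:
            if dialect == "paf":
                alnlen = max(r.aln_len_target, r.query_end - r.query_start)
                nmatch = round(alnlen * r.identity_pct / 100.0)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            r.query_id,
                            r.query_end,  # qlen lower bound; not tracked
                            r.query_start,
                            r.query_end,
                            r.strand,
                            r.target_id,
                            r.target_end,
                            r.target_start,
                            r.target_end,
                            nmatch,
                            alnlen,
                            255,
                        )
                    )
                    + "\n"
                )
            else:
                s2, e2 = r.query_start + 1, r.query_end
                if r.strand == "-":
                    s2, e2 = e2, s2
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            r.target_start + 1,
                            r.target_end,
                            s2,
                            e2,
                            r.aln_len_target,
                            r.query_end - r.query_start,
                            f"{r.identity_pct:.2f}",
                            r.target_id,
                            r.query_id,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Contig extraction and size statistics


def extract_contigs(
    scaffold: SequenceRecord, min_n_run: int = 20
) -> list[SequenceRecord]:
    """Split a scaffold into contigs at every run of >= ``min_n_run`` Ns.

    The splitting Ns are removed; shorter N runs stay inside contigs.
    Contig ids carry the ordinal and the 0-based scaffold offset, e.g.
    ``scf1_ctg2_4020``.  Zero-length pieces are dropped.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    pattern = re.compile(f"N{{{min_n_run},}}")
    contigs: list[SequenceRecord] = []
    pos = 0
    ordinal = 0
    seq = scaffold.sequence
    for m in pattern.finditer(seq):
        piece = seq[pos : m.start()]
        if piece:
            contigs.append(
                SequenceRecord(f"{scaffold.id}_ctg{ordinal}_{pos}", piece)
            )
            ordinal += 1
        pos = m.end()
    piece = seq[pos:]
    if piece:
        contigs.append(SequenceRecord(f"{scaffold.id}_ctg{ordinal}_{pos}", piece))
    return contigs


def assembly_stats(lengths: Sequence[int], genome_size: int) -> AssemblyStats:
    """N50/NG50 and span statistics of a length list.

    N50 is the length of the sequence that first brings the cumulative sum
    (in descending length order) to at least half the total span; NG50 uses
    half of ``genome_size`` instead and is 0 when unreachable.
    """
    if not lengths:
        raise ValueError("assembly_stats requires a non-empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("all lengths must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    n50 = ng50 = 0
    cum = 0
    for length in desc:
        cum += length
        if n50 == 0 and 2 * cum >= total:
            n50 = length
        if ng50 == 0 and 2 * cum >= genome_size:
            ng50 = length
        if n50 and ng50:
            break
    return AssemblyStats(
        n_sequences=len(desc),
        total_span=total,
        n50=n50,
        ng50=ng50,
        max_len=desc[0],
    )
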
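"""Sequence, read, interval and tree I/O with shared coordinate conventions.

All intervals are 0-based half-open internally (BED-native); any 1-based
inclusive rendering happens only in human-readable reports.  Residues are
stored uppercase over the alphabet {A, C, G, T, N}; other IUPAC codes are
mapped to N with a warning, because downstream distance computations treat
N as missing data.  Sequences are never stored reverse-complemented:
reverse-strand features carry strand '-' and comparisons reverse-complement
on the fly.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One sequence with taxon/group metadata.

    ``group`` is a free taxon label (e.g. "Anura", "Platyhelminthes",
    "Nematoda", or a synthetic scenario label); it drives grouping in the
    similarity table and the incongruence scan.
    """

    id: str
    residues: str
    group: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"SequenceRecord {self.id!r} has empty residues")
        res = self.residues.upper()
        if _NON_ACGTN.search(res):
            logger.warning(
                "record %s: residues outside {A,C,G,T,N} mapped to N", self.id
            )
            res = _NON_ACGTN.sub("N", res)
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReadRecord:
    """A sequencing read; qualities are optional Phred scores."""

    id: str
    residues: str
    qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(f"read {self.id}: quality/residue length mismatch")

    def __len__(self) -> int:
        return len(self.residues)


_GROUP_TOKEN = re.compile(r"group=(\S+)")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The group label is parsed from an optional ``group=LABEL`` token in the
    header description; absent that, the group is empty.  Duplicate ids and
    empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        m = _GROUP_TOKEN.search(rec.description)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                group=m.group(1) if m else "",
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.group:
                header += f" group={rec.group}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    """Read Phred+33 FASTQ into ReadRecords (lossless for id/residues/quals)."""
    reads = [
        ReadRecord(
            id=rec.id,
            residues=str(rec.seq),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not reads:
        raise ValueError(f"no FASTQ records found in {path}")
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = [40] * len(read.residues)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.id}\n{read.residues}\n+\n{qstr}\n")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED3/BED6 (0-based half-open, native coordinates)."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            intervals.append(Interval(fields[0], start, end, strand=strand, name=name))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    """Read a Newick tree with branch lengths."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
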
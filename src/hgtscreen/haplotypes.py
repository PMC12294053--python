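"""Collapse sequence sets into distinct haplotypes before matrix construction.

Repeat-unit clone sets contain many identical copies; each species/type set
is reduced to its distinct haplotypes first, and only the haplotype
representatives enter the cross-taxon matrix.  A haplotype is defined by
exact residue identity after uppercasing (N compares as an ordinary symbol;
sequences of different lengths are always distinct haplotypes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .seqio import SequenceRecord


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with multiplicities and source-member ids."""

    haplotypes: list[SequenceRecord]
    counts: list[int]
    members: list[list[str]]

    def __len__(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(records: list[SequenceRecord]) -> HaplotypeSet:
    """Partition records into exact-identity haplotypes.

    The representative of each haplotype is its first-seen member, so the
    result is deterministic given input order; permuting the input changes
    only the representatives, never the partition.
    """
    if not records:
        raise ValueError("cannot collapse an empty record set")
    index: dict[str, int] = {}
    haplotypes: list[SequenceRecord] = []
    counts: list[int] = []
    members: list[list[str]] = []
    for rec in records:
        key = rec.residues
        if key in index:
            i = index[key]
            counts[i] += 1
            members[i].append(rec.id)
        else:
            index[key] = len(haplotypes)
            haplotypes.append(rec)
            counts.append(1)
            members.append([rec.id])
    return HaplotypeSet(haplotypes=haplotypes, counts=counts, members=members)


def write_haplotype_table(hset: HaplotypeSet, path: str | os.PathLike) -> None:
    """TSV: haplotype_id, count, comma-joined member ids."""
    with open(path, "w") as fh:
        fh.write("haplotype_id\tcount\tmembers\n")
        for rec, count, mem in zip(hset.haplotypes, hset.counts, hset.members):
            fh.write(f"{rec.id}\t{count}\t{','.join(mem)}\n")
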
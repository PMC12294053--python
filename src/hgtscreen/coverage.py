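"""Read mapping, windowed counting, and Poisson enrichment screening.

The contamination assessment maps the parasite's read libraries onto the
host genome, counts mapped-read starts in fixed-width windows (1 Mb at full
scale; the synthetic tests use 10 kb windows on ~2 Mb genomes), and asks
which windows are enriched relative to the genome-wide mapping rate with an
upper-tail Poisson test at a significance threshold of 0.01.  Under genuine
library-wide contamination every repeat class should light up in proportion
to its copy number; isolated 5S-only enrichment is the transfer-compatible
pattern.

The mapper is a deliberately small k-mer-seed + mismatch-verification
mapper (ungapped, Hamming distance, default <= 3 mismatches): adequate for
the substitution-only synthetic libraries and transparent to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .align import KmerIndex, encode_residues, kmer_codes, local_search
from .seqio import Interval, ReadRecord, SequenceRecord, reverse_complement


@dataclass
class Placement:
    """One mapped read: a 0-based start on a subject sequence.

    ``multiplicity`` records how many equally good positions existed; one of
    them was chosen uniformly at random under the run seed.
    """

    read_id: str
    seq_id: str
    position: int
    strand: str
    mismatches: int
    multiplicity: int = 1


@dataclass
class WindowStat:
    """Fixed-width window with its read count and Poisson enrichment test."""

    window: Interval
    count: int
    expected: Optional[float] = None
    p_value: Optional[float] = None
    significant: Optional[bool] = None


class GenomeIndex:
    """Concatenated k-mer index over a genome for seed lookup.

    Sequences are joined with an N spacer so no k-mer spans a boundary.
    """

    def __init__(self, genome: Sequence[SequenceRecord], k: int = 21):
        if any(len(rec) < k for rec in genome):
            raise ValueError(f"genome sequence shorter than seed length k={k}")
        self.k = k
        self.records = list(genome)
        parts = []
        self.offsets = []
        off = 0
        for rec in self.records:
            self.offsets.append(off)
            parts.append(encode_residues(rec.residues))
            parts.append(np.full(k, 4, dtype=np.uint8))  # N spacer
            off += len(rec) + k
        self.concat = np.concatenate(parts)
        self.total_len = sum(len(r) for r in self.records)
        codes = kmer_codes(self.concat, k)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = order.astype(np.int64)
        lo = np.searchsorted(self._codes, 0)
        self._codes, self._pos = self._codes[lo:], self._pos[lo:]
        self._bounds = np.array([0] + [o + len(r) for o, r in zip(self.offsets, self.records)])

    def positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def locate(self, concat_pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate back to (seq_id, position)."""
        idx = int(np.searchsorted(np.array(self.offsets), concat_pos, side="right")) - 1
        return self.records[idx].id, concat_pos - self.offsets[idx]


def map_reads(
    reads: Sequence[ReadRecord],
    genome: Sequence[SequenceRecord] | GenomeIndex,
    k: int = 21,
    max_mismatch: int = 3,
    seed: int = 0,
) -> tuple[list[Placement], int]:
    """Map reads by exact k-mer seeding and Hamming verification.

    Seeds are the read's non-overlapping k-length chunks on both strands
    (pigeonhole: with ceil(len/k) >= max_mismatch + 1 chunks a valid
    placement always retains an exact seed).  Every candidate start is
    verified by Hamming distance; among the equal-best placements one is
    chosen uniformly at random under ``seed``.  Returns the placements and
    the unmapped-read count.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k=k)
    rng = np.random.default_rng(seed)
    concat = index.concat
    placements: list[Placement] = []
    unmapped = 0
    for read in reads:
        rlen = len(read)
        if rlen < index.k:
            unmapped += 1
            continue
        best_mm = max_mismatch + 1
        best: list[tuple[int, str]] = []
        for strand in ("+", "-"):
            res = read.residues if strand == "+" else reverse_complement(read.residues)
            arr = encode_residues(res)
            codes = kmer_codes(arr, index.k)
            chunk_starts = range(0, rlen - index.k + 1, index.k)
            cand_parts = [
                index.positions(int(codes[cs])) - cs
                for cs in chunk_starts
                if codes[cs] >= 0
            ]
            if not cand_parts:
                continue
            starts = np.unique(np.concatenate(cand_parts))
            starts = starts[(starts >= 0) & (starts + rlen <= len(concat))]
            if len(starts) == 0:
                continue
            # vectorized Hamming verification of all candidate placements
            windows = concat[starts[:, None] + np.arange(rlen)[None, :]]
            mism = (windows != arr[None, :]) | (arr[None, :] >= 4)
            mm_counts = mism.sum(axis=1)
            strand_best = int(mm_counts.min())
            if strand_best < best_mm:
                best_mm = strand_best
                best = [(int(s), strand) for s in starts[mm_counts == strand_best]]
            elif strand_best == best_mm:
                best.extend((int(s), strand) for s in starts[mm_counts == strand_best])
        if best_mm > max_mismatch or not best:
            unmapped += 1
            continue
        best.sort()
        start, strand = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        seq_id, pos = index.locate(start)
        placements.append(
            Placement(
                read_id=read.id,
                seq_id=seq_id,
                position=pos,
                strand=strand,
                mismatches=best_mm,
                multiplicity=len(best),
            )
        )
    return placements, unmapped


def window_counts(
    placements: Sequence[Placement],
    genome_lengths: dict[str, int],
    width: int = 1_000_000,
) -> list[WindowStat]:
    """Tile each sequence with fixed windows and count read starts.

    The last window of each sequence may be truncated.  The window counts
    always sum to the number of placements.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    stats_out: list[WindowStat] = []
    by_seq: dict[str, list[int]] = {sid: [] for sid in genome_lengths}
    for p in placements:
        by_seq[p.seq_id].append(p.position)
    for sid, length in genome_lengths.items():
        n_windows = max(1, math.ceil(length / width))
        counts = np.bincount(
            np.asarray(by_seq[sid], dtype=np.int64) // width if by_seq[sid] else np.empty(0, np.int64),
            minlength=n_windows,
        )
        for w in range(n_windows):
            start = w * width
            end = min(length, start + width)
            stats_out.append(
                WindowStat(window=Interval(sid, start, end), count=int(counts[w]))
            )
    return stats_out


def poisson_enrichment(
    window_stats: Sequence[WindowStat],
    alpha: float = 0.01,
    rate: str = "length_proportional",
    bonferroni: bool = False,
) -> list[WindowStat]:
    """Upper-tail Poisson test of each window count against the genome rate.

    With the default length-proportional rate, window w of width L_w gets
    expectation lambda_w = N_total * L_w / L_genome (truncated windows get
    proportionally smaller expectations); the alternative ``per_window_mean``
    uses the plain mean count per window.  p = P(X >= count | Poisson(lambda));
    a count of zero always has p = 1.  No multiple-testing correction is
    applied unless ``bonferroni`` is set.
    """
    if not window_stats:
        raise ValueError("no windows to test")
    if rate not in ("length_proportional", "per_window_mean"):
        raise ValueError(f"unknown rate estimator {rate!r}")
    total = sum(w.count for w in window_stats)
    total_len = sum(len(w.window) for w in window_stats)
    threshold = alpha / len(window_stats) if bonferroni else alpha
    out = []
    for w in window_stats:
        if rate == "length_proportional":
            lam = total * len(w.window) / total_len
        else:
            lam = total / len(window_stats)
        p = float(stats.poisson.sf(w.count - 1, lam)) if total > 0 else 1.0
        out.append(
            WindowStat(
                window=w.window,
                count=w.count,
                expected=lam,
                p_value=min(p, 1.0),
                significant=bool(p <= threshold and w.count > 0),
            )
        )
    return out


@dataclass
class WindowAnnotation:
    """Feature content of one significant window."""

    window: Interval
    labels: list[str]  # e.g. ["5S_somatic", "TE_Tc1"], or ["unexplained"]
    details: list[str]


def annotate_windows(
    significant: Sequence[WindowStat],
    genome: Sequence[SequenceRecord],
    feature_probes: Optional[dict[str, Sequence[SequenceRecord]]] = None,
    feature_beds: Optional[Sequence[Interval]] = None,
    min_identity: float = 0.8,
    min_probe_cover: float = 0.5,
    k: int = 11,
) -> list[WindowAnnotation]:
    """Label significant windows with the features they contain.

    FASTA probes are searched against the window sequence with the local
    aligner; BED features are overlap-tested.  A window with no qualifying
    feature is labeled "unexplained".
    """
    by_id = {rec.id: rec for rec in genome}
    annotations = []
    for wstat in significant:
        win = wstat.window
        seq = by_id[win.seq_id].residues[win.start : win.end]
        window_rec = SequenceRecord(id=f"{win.seq_id}:{win.start}-{win.end}", residues=seq)
        labels: list[str] = []
        details: list[str] = []
        for name, probes in (feature_probes or {}).items():
            found = False
            for probe in probes:
                if len(probe) < k:
                    continue
                hits = local_search(
                    probe, [window_rec], k=k, min_identity=min_identity, min_score=10.0
                )
                for h in hits:
                    if h.query_cover >= min_probe_cover:
                        found = True
                        details.append(
                            f"{name}:{probe.id}@{h.subject_iv.start}-{h.subject_iv.end}"
                            f" id={h.identity:.2f}"
                        )
                        break
                if found:
                    break
            if found:
                labels.append(name)
        for iv in feature_beds or []:
            if iv.overlaps(win):
                labels.append(iv.name or "bed_feature")
                details.append(f"bed:{iv.name}@{iv.start}-{iv.end}")
        if not labels:
            labels = ["unexplained"]
        annotations.append(WindowAnnotation(window=win, labels=labels, details=details))
    return annotations


def write_window_tsv(window_stats: Sequence[WindowStat], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tcount\tlambda\tp_value\tsignificant\n")
        for w in window_stats:
            lam = f"{w.expected:.4f}" if w.expected is not None else "NA"
            p = f"{w.p_value:.6g}" if w.p_value is not None else "NA"
            sig = int(bool(w.significant)) if w.significant is not None else "NA"
            fh.write(
                f"{w.window.seq_id}\t{w.window.start}\t{w.window.end}\t"
                f"{w.count}\t{lam}\t{p}\t{sig}\n"
            )


def plot_coverage(window_stats: Sequence[WindowStat], path: str) -> None:
    """Per-chromosome read-density plot with significant windows circled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    seqs = sorted({w.window.seq_id for w in window_stats})
    fig, axes = plt.subplots(len(seqs), 1, figsize=(8, 2.2 * len(seqs)), squeeze=False)
    for ax, sid in zip(axes.ravel(), seqs):
        ws = [w for w in window_stats if w.window.seq_id == sid]
        mids = [(w.window.start + w.window.end) / 2 for w in ws]
        counts = [w.count for w in ws]
        ax.plot(mids, counts, lw=0.8, color="steelblue")
        sig = [(m, c) for m, c, w in zip(mids, counts, ws) if w.significant]
        if sig:
            ax.scatter(*zip(*sig), facecolors="none", edgecolors="crimson", s=40)
        ax.set_ylabel("reads")
        ax.set_title(sid, fontsize=9)
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
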
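"""Pairwise global alignment, progressive multiple alignment, and local search.

Three alignment engines back the pipeline:

* :func:`global_align` — affine-gap global alignment (Gotoh's three-state
  recursion) with a deterministic traceback preferring diagonal > up > left;
* :func:`progressive_msa` — k-mer-distance guide tree plus profile–profile
  global alignment, the desk-scale stand-in for a progressive aligner;
* :func:`local_search` — exact k-mer seeding on both strands followed by
  ungapped maximal-segment extension per diagonal, with collinear hits
  merged into gapped hits by realignment.  This is the query-against-genome
  search used wherever the workflow interrogates an assembly with a probe.

Scoring is DNA-conventional: match +1, mismatch −1, gap open −2, gap extend
−0.5 by default.  An ambiguous N never counts as a match (N/N scores as a
mismatch), and gap cost for a run of length L is open + (L−1)·extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .seqio import Interval, SequenceRecord, reverse_complement

NEG = -1e18
GAP = 5  # column symbol index for '-'

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.array(list("ACGTN-"))


def encode_residues(residues: str) -> np.ndarray:
    """Map residues to integer codes A=0 C=1 G=2 T=3, anything else = 4 (N)."""
    return _ENC[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode_residues(codes: np.ndarray) -> str:
    return "".join(_DEC[codes])


def substitution_matrix(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    """5x5 score matrix over {A,C,G,T,N}; N scores as mismatch against all."""
    s = np.full((5, 5), mismatch, dtype=float)
    for i in range(4):
        s[i, i] = match
    return s


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of a coded sequence; windows with N get -1.

    Uses a rolling Horner evaluation so no (n, k) intermediate is allocated;
    safe up to k = 31 in int64.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        col = arr[off : off + n]
        codes = codes * 4 + col
        valid &= col < 4
    codes[~valid] = -1
    return codes


# ---------------------------------------------------------------------------
# Global (Gotoh) alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A gapped, equal-length block of rows (id, gapped residues)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def get(self, row_id: str) -> str:
        for i, r in self.rows:
            if i == row_id:
                return r
        raise KeyError(row_id)

    def degapped(self, row_id: str) -> str:
        return self.get(row_id).replace("-", "")


def _gotoh_forward(
    pair_scores: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three Gotoh state matrices for precomputed column-pair scores.

    M = a-column aligned to b-column; X = gap in b (consumes a, "up");
    Y = gap in a (consumes b, "left").  Gap runs may restart from any state
    with the open cost; terminal gaps are penalized (true global alignment).
    """
    n, m = pair_scores.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    js = np.arange(m)
    Y[0, 1:] = gap_open + gap_extend * js
    for i in range(1, n + 1):
        X[i, :] = np.maximum(
            np.maximum(M[i - 1, :] + gap_open, Y[i - 1, :] + gap_open),
            X[i - 1, :] + gap_extend,
        )
        M[i, 1:] = pair_scores[i - 1, :] + np.maximum(
            np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1]
        )
        # Y[i, j] = max over t < j of max(M, X)[i, t] + open + (j-1-t)*extend,
        # computed with a running-max trick to keep the row vectorized.
        h = np.maximum(M[i, :-1], X[i, :-1])
        cm = np.maximum.accumulate(h - gap_extend * np.arange(m))
        Y[i, 1:] = gap_open + gap_extend * js + cm
    return M, X, Y


def _gotoh_traceback(
    pair_scores: np.ndarray,
    M: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[str]:
    """Recover one optimal path; ties broken diagonal > up > left."""
    tol = 1e-6
    n, m = pair_scores.shape
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax prefers M on ties
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            ops.append("D")
            target = M[i, j] - pair_scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, mat in ((0, M), (1, X), (2, Y)):
                if abs(mat[i, j] - target) < tol:
                    state = cand
                    break
        elif state == 1:  # X: gap in b, consumes a
            ops.append("U")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - val) < tol:
                state = 0
            elif abs(X[i, j] + gap_extend - val) < tol:
                state = 1
            else:
                state = 2
        else:  # Y: gap in a, consumes b
            ops.append("L")
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - val) < tol:
                state = 0
            elif abs(X[i, j] + gap_open - val) < tol:
                state = 1
            else:
                state = 2
    ops.reverse()
    return ops


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    id_a: str = "a",
    id_b: str = "b",
) -> tuple[Alignment, float]:
    """Optimal affine-gap global alignment of two sequences.

    Returns the alignment and its score.  The score is symmetric in the
    arguments; the traceback is deterministic (diagonal > up > left).
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    ca, cb = encode_residues(a), encode_residues(b)
    sub = substitution_matrix(match, mismatch)
    pair_scores = sub[ca[:, None], cb[None, :]]
    M, X, Y = _gotoh_forward(pair_scores, gap_open, gap_extend)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    ops = _gotoh_traceback(pair_scores, M, X, Y, gap_open, gap_extend)
    ra, rb = [], []
    ia = ib = 0
    for op in ops:
        if op == "D":
            ra.append(a[ia])
            rb.append(b[ib])
            ia += 1
            ib += 1
        elif op == "U":
            ra.append(a[ia])
            rb.append("-")
            ia += 1
        else:
            ra.append("-")
            rb.append(b[ib])
            ib += 1
    return Alignment(rows=[(id_a, "".join(ra)), (id_b, "".join(rb))]), score


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _profile(rows: Sequence[str], sub: np.ndarray) -> np.ndarray:
    """(L, 5) per-column residue frequencies; gaps dilute the column weight."""
    block = np.stack([encode_residues(r.replace("-", "N")) for r in rows])
    gaps = np.stack([np.frombuffer(r.encode(), dtype=np.uint8) == ord("-") for r in rows])
    freqs = np.zeros((block.shape[1], 5))
    for sym in range(5):
        freqs[:, sym] = ((block == sym) & ~gaps).sum(axis=0)
    return freqs / len(rows)


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    sa = {a[i : i + k] for i in range(max(1, len(a) - k + 1))}
    sb = {b[i : i + k] for i in range(max(1, len(b) - k + 1))}
    shared = len(sa & sb)
    return 1.0 - shared / max(1, min(len(sa), len(sb)))


def _merge_alignments(
    block_a: list[tuple[str, str]],
    block_b: list[tuple[str, str]],
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    fa = _profile([r for _, r in block_a], sub)
    fb = _profile([r for _, r in block_b], sub)
    pair_scores = fa @ sub @ fb.T
    M, X, Y = _gotoh_forward(pair_scores, gap_open, gap_extend)
    ops = _gotoh_traceback(pair_scores, M, X, Y, gap_open, gap_extend)
    out: list[tuple[str, str]] = []
    for rid, row in block_a:
        ia = 0
        chars = []
        for op in ops:
            if op in ("D", "U"):
                chars.append(row[ia])
                ia += 1
            else:
                chars.append("-")
        out.append((rid, "".join(chars)))
    for rid, row in block_b:
        ib = 0
        chars = []
        for op in ops:
            if op in ("D", "L"):
                chars.append(row[ib])
                ib += 1
            else:
                chars.append("-")
        out.append((rid, "".join(chars)))
    return out


def progressive_msa(
    records: Sequence[SequenceRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    guide_k: int = 6,
) -> Alignment:
    """Progressive multiple alignment along an average-linkage k-mer guide tree.

    Deterministic given input order.  Pairwise-identical inputs produce a
    gap-free block.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa requires at least 2 records")
    sub = substitution_matrix(match, mismatch)
    n = len(records)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(_kmer_distance(records[i].residues, records[j].residues, guide_k))
    link = hierarchy.linkage(np.asarray(condensed), method="average")
    blocks: dict[int, list[tuple[str, str]]] = {
        i: [(rec.id, rec.residues)] for i, rec in enumerate(records)
    }
    for step, (ia, ib, _, _) in enumerate(link):
        merged = _merge_alignments(
            blocks.pop(int(ia)), blocks.pop(int(ib)), sub, gap_open, gap_extend
        )
        blocks[n + step] = merged
    (final,) = blocks.values()
    order = {rec.id: i for i, rec in enumerate(records)}
    final.sort(key=lambda pair: order[pair[0]])
    return Alignment(rows=final)


# ---------------------------------------------------------------------------
# Local seed-and-extend search
# ---------------------------------------------------------------------------


@dataclass
class LocalHit:
    """One local alignment of a query against a subject sequence."""

    query_id: str
    subject_id: str
    query_iv: Interval
    subject_iv: Interval
    strand: str
    identity: float
    query_cover: float
    score: float
    matches: int
    mismatches: int
    gaps: int


class KmerIndex:
    """Sorted k-mer index over a set of subject sequences.

    Built once per subject set and reused across queries; lookup is a pair
    of binary searches per query k-mer.
    """

    def __init__(self, subjects: Sequence[SequenceRecord], k: int = 11):
        self.k = k
        self.subjects = list(subjects)
        self.arrays = [encode_residues(s.residues) for s in self.subjects]
        self._sorted_codes: list[np.ndarray] = []
        self._sorted_pos: list[np.ndarray] = []
        for arr in self.arrays:
            codes = kmer_codes(arr, k)
            order = np.argsort(codes, kind="stable")
            self._sorted_codes.append(codes[order])
            self._sorted_pos.append(order.astype(np.int64))

    def positions(self, subject_idx: int, code: int) -> np.ndarray:
        codes = self._sorted_codes[subject_idx]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return self._sorted_pos[subject_idx][lo:hi]


def _best_segment(scorevec: np.ndarray) -> tuple[int, int, float]:
    """Maximal-scoring contiguous segment (Kadane via prefix minima).

    Deterministic: earliest-ending, then longest, optimum is returned.
    """
    prefix = np.concatenate(([0.0], np.cumsum(scorevec)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    best = float(gains[end])
    start = int(np.nonzero(prefix[: end + 1] == run_min[end])[0][0])
    return start, end + 1, best


def _extend_diagonal(
    qarr: np.ndarray,
    sarr: np.ndarray,
    diag: int,
    match: float,
    mismatch: float,
) -> Optional[tuple[int, int, float, int, int]]:
    """Best ungapped segment on one diagonal: (q0, q1, score, matches, mism)."""
    q0 = max(0, -diag)
    q1 = min(len(qarr), len(sarr) - diag)
    if q1 - q0 <= 0:
        return None
    qs = qarr[q0:q1]
    ss = sarr[q0 + diag : q1 + diag]
    is_match = (qs == ss) & (qs < 4) & (ss < 4)
    scorevec = np.where(is_match, match, mismatch)
    s0, s1, best = _best_segment(scorevec)
    if s1 <= s0:
        return None
    nmatch = int(is_match[s0:s1].sum())
    return q0 + s0, q0 + s1, best, nmatch, (s1 - s0) - nmatch


def local_search(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord] | KmerIndex,
    k: int = 11,
    x_drop: float = 20.0,
    min_identity: float = 0.6,
    min_score: float = 20.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    max_chain_gap: int = 30,
) -> list[LocalHit]:
    """Seed-and-extend search of a query against subject sequences.

    Exact k-mer seeds are collected on both strands; every seeded diagonal
    is extended to its maximal-scoring ungapped segment (an exact
    computation, at least as sensitive as classic x-drop extension at the
    same scoring; ``x_drop`` is retained as the admissible-drop parameter of
    the API).  Collinear segments separated by at most ``max_chain_gap``
    on nearly the same diagonal are merged into a gapped hit by realigning
    the spanned region.  Hits below ``min_identity`` or ``min_score`` are
    discarded; the result is sorted by score descending.
    """
    if len(query) < k:
        raise ValueError(f"query {query.id!r} shorter than seed length k={k}")
    index = subjects if isinstance(subjects, KmerIndex) else KmerIndex(subjects, k=k)
    if index.k != k:
        index = KmerIndex(index.subjects, k=k)
    lq = len(query)
    hits: list[LocalHit] = []
    for strand in ("+", "-"):
        qres = query.residues if strand == "+" else reverse_complement(query.residues)
        qarr = encode_residues(qres)
        qcodes = kmer_codes(qarr, k)
        for si, subject in enumerate(index.subjects):
            sarr = index.arrays[si]
            diags: set[int] = set()
            for qpos in range(len(qcodes)):
                code = qcodes[qpos]
                if code < 0:
                    continue
                for spos in index.positions(si, int(code)):
                    diags.add(int(spos) - qpos)
            segments = []
            for diag in sorted(diags):
                seg = _extend_diagonal(qarr, sarr, diag, match, mismatch)
                if seg is not None and seg[2] > 0:
                    segments.append((diag,) + seg)
            segments = _chain_segments(
                segments, qres, subject.residues, match, mismatch, max_chain_gap
            )
            for diag, q0, q1, score, nmatch, nmism, ngap in segments:
                aligned_cols = nmatch + nmism
                if aligned_cols == 0:
                    continue
                identity = nmatch / aligned_cols
                if identity < min_identity or score < min_score:
                    continue
                s0, s1 = q0 + diag, q1 + diag
                if strand == "+":
                    q_iv = Interval(query.id, q0, q1, strand="+")
                else:
                    q_iv = Interval(query.id, lq - q1, lq - q0, strand="+")
                hits.append(
                    LocalHit(
                        query_id=query.id,
                        subject_id=subject.id,
                        query_iv=q_iv,
                        subject_iv=Interval(subject.id, s0, s1, strand="+"),
                        strand=strand,
                        identity=identity,
                        query_cover=(q1 - q0) / lq,
                        score=score,
                        matches=nmatch,
                        mismatches=nmism,
                        gaps=ngap,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_iv.start, h.strand))
    return hits


def _chain_segments(
    segments: list[tuple[int, int, int, float, int, int]],
    qres: str,
    sres: str,
    match: float,
    mismatch: float,
    max_chain_gap: int,
) -> list[tuple[int, int, int, float, int, int, int]]:
    """Merge collinear ungapped segments into gapped hits by realignment.

    Input tuples: (diag, q0, q1, score, matches, mismatches); output adds a
    gap-column count.  Non-mergeable segments pass through with gaps=0.
    """
    expanded = [(d, q0, q1, sc, ma, mi, 0) for d, q0, q1, sc, ma, mi in segments]
    expanded.sort(key=lambda t: (t[1], t[0]))
    merged: list[tuple[int, int, int, float, int, int, int]] = []
    for seg in expanded:
        if merged:
            d0, a0, a1, *_ = merged[-1]
            d1, b0, b1, *_ = seg
            q_gap = b0 - a1
            s_gap = (b0 + d1) - (a1 + d0)
            if (
                0 <= q_gap <= max_chain_gap
                and 0 <= s_gap <= max_chain_gap
                and d0 != d1
            ):
                qsub = qres[a0:b1]
                ssub = sres[a0 + d0 : b1 + d1]
                aln, score = global_align(qsub, ssub, match, mismatch)
                ra, rb = aln.rows[0][1], aln.rows[1][1]
                nmatch = sum(
                    1
                    for x, y in zip(ra, rb)
                    if x == y and x not in "N-" and y not in "N-"
                )
                ngapcols = sum(1 for x, y in zip(ra, rb) if x == "-" or y == "-")
                nmism = len(ra) - nmatch - ngapcols
                merged[-1] = (d0, a0, b1, score, nmatch, nmism, ngapcols)
                continue
        merged.append(seg)
    # drop duplicate spans kept from different seeds
    unique: dict[tuple[int, int, int], tuple] = {}
    for seg in merged:
        unique[(seg[0], seg[1], seg[2])] = seg
    return list(unique.values())


def write_hits_tsv(hits: Iterable[LocalHit], path: str) -> None:
    """Tabular hit output; column order and names are part of the interface."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\tsubject_id\tidentity\tquery_cover\tscore\t"
            "q_start\tq_end\ts_start\ts_end\tstrand\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.4f}\t"
                f"{h.query_cover:.4f}\t{h.score:g}\t{h.query_iv.start}\t"
                f"{h.query_iv.end}\t{h.subject_iv.start}\t{h.subject_iv.end}\t"
                f"{h.strand}\n"
            )
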
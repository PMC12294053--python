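"""p-distance and Kimura-2-parameter distance with pairwise deletion.

Sites where either sequence of a pair carries a gap ('-') or missing data
('N') are excluded pair-by-pair ("pairwise deletion") before any distance
is computed.  The p-distance is the proportion of differing retained sites;
the K2P distance corrects it for multiple hits while distinguishing
transitions from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over retained
sites.  A pair with no retained sites is undefined (NaN, never 0); a pair
whose log arguments are non-positive is saturated (+inf), and tree building
replaces saturated entries with a configurable cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, encode_residues

_PURINE_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def _site_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a < 4) & (b < 4)


def _encode_gapped(row: str) -> np.ndarray:
    # '-' and 'N' both encode to >=4 and are masked out downstream
    return encode_residues(row.replace("-", "N"))


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites over retained (non-gap, non-N) sites.

    Returns NaN when no site is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("p_distance requires equal-length (aligned) rows")
    a, b = _encode_gapped(row_a), _encode_gapped(row_b)
    mask = _site_mask(a, b)
    retained = int(mask.sum())
    if retained == 0:
        return math.nan
    return float((a[mask] != b[mask]).sum() / retained)


def transition_transversion(row_a: str, row_b: str) -> tuple[float, float, int]:
    """(P, Q, retained sites): transition and transversion proportions."""
    if len(row_a) != len(row_b):
        raise ValueError("equal-length (aligned) rows required")
    a, b = _encode_gapped(row_a), _encode_gapped(row_b)
    mask = _site_mask(a, b)
    retained = int(mask.sum())
    if retained == 0:
        return math.nan, math.nan, 0
    am, bm = a[mask], b[mask]
    diff = am != bm
    transitions = diff & (((am == 0) & (bm == 2)) | ((am == 2) & (bm == 0))
                          | ((am == 1) & (bm == 3)) | ((am == 3) & (bm == 1)))
    p = float(transitions.sum() / retained)
    q = float(diff.sum() / retained) - p
    return p, q, retained


def k2p_distance(row_a: str, row_b: str) -> float:
    """Kimura-2-parameter distance in substitutions/site.

    NaN = undefined (no comparable sites); +inf = saturated (a log argument
    reached zero or below).
    """
    p, q, retained = transition_transversion(row_a, row_b)
    if retained == 0:
        return math.nan
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.inf
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def similarity_percent(row_a: str, row_b: str) -> float:
    """100 x (1 - p_distance); NaN when the p-distance is undefined."""
    return 100.0 * (1.0 - p_distance(row_a, row_b))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with an ordered id list.

    ``saturated`` marks entries that were capped; ``undefined`` marks pairs
    with no comparable sites (also capped for tree building, but flagged).
    """

    ids: list[str]
    d: np.ndarray
    saturated: np.ndarray
    undefined: np.ndarray

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(list(ids), self.d[sel], self.saturated[sel], self.undefined[sel])


def distance_matrix(
    alignment: Alignment,
    method: str = "k2p",
    saturation_cap: float = 5.0,
) -> DistanceMatrix:
    """All-pairs distance matrix from an alignment.

    Saturated K2P pairs (and undefined pairs) are replaced by
    ``saturation_cap`` so that downstream tree building always sees finite
    entries; the flags record which entries were capped.
    """
    if method not in ("k2p", "p"):
        raise ValueError(f"unknown distance method {method!r}")
    fn = k2p_distance if method == "k2p" else p_distance
    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    undefined = np.zeros((n, n), dtype=bool)
    rows = [r for _, r in alignment.rows]
    for i in range(n):
        for j in range(i + 1, n):
            val = fn(rows[i], rows[j])
            if math.isnan(val):
                undefined[i, j] = undefined[j, i] = True
                val = saturation_cap
            elif math.isinf(val):
                saturated[i, j] = saturated[j, i] = True
                val = saturation_cap
            d[i, j] = d[j, i] = val
    return DistanceMatrix(ids=ids, d=d, saturated=saturated, undefined=undefined)


def group_similarity_table(alignment: Alignment, groups: dict[str, str]) -> pd.DataFrame:
    """Mean pairwise similarity (%) within and between groups.

    The diagonal holds the mean within-group similarity over distinct pairs
    (NaN for a singleton group, conventionally rendered "-"); off-diagonals
    hold the mean across-group similarity.  Undefined pairs are excluded
    from the means.  Group order follows first appearance in the alignment.
    """
    missing = [i for i in alignment.ids if i not in groups]
    if missing:
        raise ValueError(f"rows without a group label: {missing}")
    labels: list[str] = []
    for rid in alignment.ids:
        if groups[rid] not in labels:
            labels.append(groups[rid])
    sums = {(a, b): [0.0, 0] for a in labels for b in labels}
    rows = alignment.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            sim = similarity_percent(rows[i][1], rows[j][1])
            if math.isnan(sim):
                continue
            ga, gb = groups[rows[i][0]], groups[rows[j][0]]
            for key in {(ga, gb), (gb, ga)}:
                sums[key][0] += sim
                sums[key][1] += 1
    table = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            total, count = sums[(a, b)]
            table.loc[a, b] = total / count if count else math.nan
    return table


def write_group_table(table: pd.DataFrame, path: str) -> None:
    """TSV rendering to 2 decimals; undefined cells printed as '-'."""
    out = table.round(2).astype(object)
    out = out.where(~table.isna(), "-")
    out.to_csv(path, sep="\t")


def write_phylip(dm: DistanceMatrix, path: str) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            vals = " ".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{name:<12s} {vals}\n")
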
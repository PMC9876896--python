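"""Pairwise and progressive multiple alignment helpers.

Global pairwise alignment uses Biopython's ``PairwiseAligner`` with a
simple scoring scheme (match +1, mismatch -1, gap -2, linear), which is
all the identity clustering and the center-star MSA need. The multiple
alignment is center-star progressive: the center is the sequence with the
highest summed pairwise score against all others, every other sequence is
aligned to the center, and the pairwise alignments are merged under the
once-a-gap-always-a-gap rule.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

from Bio import Align

__all__ = ["global_align", "identity", "center_star_msa"]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Best global alignment of two sequences: (gapped_a, gapped_b, score)."""
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def identity(a: str, b: str) -> float:
    """Fraction of identical aligned pairs, terminal-gap columns excluded.

    Columns where either sequence has a leading or trailing gap do not
    count toward the denominator, so a short sequence contained in a long
    one is judged on the aligned core only.
    """
    ga, gb = global_align(a, b)[:2]
    n = len(ga)
    # Terminal-gap region: leading/trailing runs of '-' in either row.
    start, end = 0, n
    for row in (ga, gb):
        i = 0
        while i < n and row[i] == "-":
            i += 1
        start = max(start, i)
        j = n
        while j > 0 and row[j - 1] == "-":
            j -= 1
        end = min(end, j)
    if start >= end:
        return 0.0
    same = sum(1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-")
    return same / (end - start)


def _merge_into_master(master: str, new_center: str) -> tuple[str, list[int], list[int]]:
    """Merge two gapped copies of the same center sequence.

    Returns the union center (gaps of both) and, for each input, the
    mapping from its columns to the union's columns.
    """
    i = j = 0
    union: list[str] = []
    map_a: list[int] = []
    map_b: list[int] = []
    na, nb = len(master), len(new_center)
    while i < na or j < nb:
        ca = master[i] if i < na else None
        cb = new_center[j] if j < nb else None
        if ca == cb and ca is not None:
            map_a.append(len(union))
            map_b.append(len(union))
            union.append(ca)
            i += 1
            j += 1
        elif ca == "-":
            map_a.append(len(union))
            union.append("-")
            i += 1
        elif cb == "-":
            map_b.append(len(union))
            union.append("-")
            j += 1
        elif ca is None:
            map_b.append(len(union))
            union.append(cb)  # pragma: no cover - only hit on malformed input
            j += 1
        else:
            map_a.append(len(union))
            union.append(ca)  # pragma: no cover
            i += 1
    return "".join(union), map_a, map_b


def _repad(row: str, colmap: list[int], width: int) -> str:
    out = ["-"] * width
    for k, col in enumerate(colmap):
        out[col] = row[k]
    return "".join(out)


def center_star_msa(seqs: Sequence[str]) -> list[str]:
    """Center-star progressive multiple alignment.

    Rows come back in input order, all of equal length. With one input
    sequence the MSA is the sequence itself. Ties for the center go to
    the lowest input index (deterministic).
    """
    n = len(seqs)
    if n == 0:
        raise ValueError("no sequences to align")
    if n == 1:
        return [seqs[0]]
    # choose center: maximal summed pairwise score
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = global_align(seqs[i], seqs[j])[2]
            scores[i][j] = scores[j][i] = s
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))

    master = seqs[center]  # gapped center accumulated so far
    rows: dict[int, str] = {center: master}
    for idx in range(n):
        if idx == center:
            continue
        gc, gs = global_align(seqs[center], seqs[idx])[:2]
        master2, map_old, map_new = _merge_into_master(master, gc)
        width = len(master2)
        for k in list(rows):
            rows[k] = _repad(rows[k], map_old, width)
        rows[idx] = _repad(gs, map_new, width)
        master = master2
    return [rows[i] for i in range(n)]
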
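"""Domain-hit filtering and most-likely architecture resolution.

A protein's raw domain hits usually disagree: several profiles match the
same stretch of sequence. The most-likely domain architecture is defined
as the subset of hits of maximum total score in which no two hits overlap,
where two hits overlap when the shared region covers at least 40% of the
shorter hit (envelope coordinates by default). Each hit scores
-log10(independent E-value), clamped at zero, with the HMMER bit score
substituted when the E-value underflows to exactly 0.

The 40%-of-the-shorter rule makes compatibility non-transitive (a short
hit can overlap two long hits that do not overlap each other), so the
problem is maximum-weight independent set on a general conflict graph,
not interval scheduling. Per-protein hit counts are small; an exact
branch-and-bound with a suffix-sum bound solves it optimally, and ties
are broken deterministically (more domains first, then lexicographically
smallest (env_from, query_name) sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import UsageError
from .hmmerio import DomainHit

__all__ = [
    "FilterParams",
    "Architecture",
    "filter_hits",
    "overlap_fraction",
    "is_overlapping",
    "hit_score",
    "best_architecture",
]


@dataclass(frozen=True)
class FilterParams:
    """Hit retention and overlap thresholds.

    evalue_max:
        Both the conditional and the independent per-domain E-value must
        be strictly below this. Default 0.01.
    acc_min:
        Expected per-residue alignment accuracy must be >= this.
        Default 0.6.
    overlap_threshold:
        Two hits conflict when the shared span covers >= this fraction of
        the shorter hit. Default 0.4.
    overlap_on:
        Coordinate system for the overlap test: "env" (envelope, default)
        or "ali" (alignment proper).
    """

    evalue_max: float = 0.01
    acc_min: float = 0.6
    overlap_threshold: float = 0.4
    overlap_on: Literal["env", "ali"] = "env"

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not (0.0 <= self.acc_min <= 1.0):
            raise ValueError("acc_min must be in [0,1]")
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in (0,1]")
        if self.overlap_on not in ("env", "ali"):
            raise ValueError("overlap_on must be 'env' or 'ali'")


def filter_hits(
    hits: Iterable[DomainHit], params: FilterParams = FilterParams()
) -> list[DomainHit]:
    """Retain hits with c-Evalue AND i-Evalue < evalue_max and acc >= acc_min.

    E-value cuts are strict ("less than"), the accuracy cut is inclusive
    ("above or equal to"). Input order is preserved; the operation is
    idempotent and monotone in its thresholds.
    """
    return [
        h
        for h in hits
        if h.c_evalue < params.evalue_max
        and h.i_evalue < params.evalue_max
        and h.acc >= params.acc_min
    ]


def _span(h: DomainHit, on: str) -> tuple[int, int]:
    return (h.env_from, h.env_to) if on == "env" else (h.ali_from, h.ali_to)


def overlap_fraction(a: DomainHit, b: DomainHit, on: str = "env") -> float:
    """Shared positions divided by the length of the shorter hit.

    Spans are 1-based inclusive; disjoint spans give 0.0. Symmetric.
    """
    if a.target_id != b.target_id:
        raise UsageError(
            f"overlap between different targets {a.target_id!r} and {b.target_id!r}"
        )
    a_from, a_to = _span(a, on)
    b_from, b_to = _span(b, on)
    shared = min(a_to, b_to) - max(a_from, b_from) + 1
    if shared <= 0:
        return 0.0
    shorter = min(a_to - a_from + 1, b_to - b_from + 1)
    return shared / shorter


def is_overlapping(
    a: DomainHit, b: DomainHit, threshold: float = 0.4, on: str = "env"
) -> bool:
    """True when at least ``threshold`` of the shorter hit is shared."""
    return overlap_fraction(a, b, on=on) >= threshold


def hit_score(h: DomainHit) -> float:
    """Score of one hit: -log10(i-Evalue), clamped at 0; bit score at E=0.

    The clamp keeps scores non-negative so that the maximum-total-score
    objective never prefers dropping a weak-but-valid hit; the bit-score
    fallback covers E-values that underflow to exactly zero, where the
    logarithm is undefined.
    """
    if h.i_evalue == 0.0:
        return h.bitscore
    return max(0.0, -math.log10(h.i_evalue))


@dataclass(frozen=True)
class Architecture:
    """A protein's most-likely domain architecture.

    ``hits`` are sorted by env_from and pairwise non-overlapping at the
    threshold used to build the architecture; ``total_score`` is the sum
    of hit_score over them.
    """

    protein_id: str
    hits: tuple[DomainHit, ...] = ()
    total_score: float = 0.0

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(h.query_name for h in self.hits)

    def domain_string(self, sep: str = "|") -> str:
        return sep.join(self.domain_names)


def _tie_key(indices: Sequence[int], hits: Sequence[DomainHit]) -> tuple:
    chosen = sorted(
        ((hits[i].env_from, hits[i].query_name) for i in indices)
    )
    return (-len(indices), tuple(chosen))


def best_architecture(
    hits: Sequence[DomainHit],
    threshold: float = 0.4,
    on: str = "env",
    protein_id: str | None = None,
) -> Architecture:
    """Exact maximum-total-score set of pairwise non-overlapping hits.

    All hits must share one target_id (group by protein upstream) and are
    expected to be pre-filtered. Among equal-score optima the result with
    more domains wins, then the lexicographically smallest sequence of
    (env_from, query_name); this makes the output deterministic across
    platforms.
    """
    hits = list(hits)
    if not hits:
        return Architecture(protein_id=protein_id or "", hits=(), total_score=0.0)
    ids = {h.target_id for h in hits}
    if len(ids) > 1:
        raise UsageError(f"mixed target ids in one resolution call: {sorted(ids)}")
    pid = protein_id or hits[0].target_id

    # Stable processing order so the branch-and-bound and the tie rule are
    # deterministic regardless of input order.
    order = sorted(
        range(len(hits)),
        key=lambda i: (
            hits[i].env_from,
            hits[i].env_to,
            hits[i].query_name,
            hits[i].i_evalue,
        ),
    )
    hs = [hits[i] for i in order]
    n = len(hs)
    scores = [hit_score(h) for h in hs]
    conflict = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if is_overlapping(hs[i], hs[j], threshold=threshold, on=on):
                conflict[i] |= 1 << j
                conflict[j] |= 1 << i
    # suffix[i] = sum of scores[i:] — admissible bound for pruning
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + scores[i]

    best_set: list[int] = []
    best_score = -1.0
    best_key: tuple = ()
    eps = 1e-12

    def canonical_sum(indices: Iterable[int]) -> float:
        # One summation order (env_from, query_name) everywhere, so that
        # the reported total is bit-identical to naive re-enumeration.
        total = 0.0
        for i in sorted(indices, key=lambda k: (hs[k].env_from, hs[k].query_name)):
            total += scores[i]
        return total

    def consider(chosen: list[int], _raw_score: float) -> None:
        nonlocal best_set, best_score, best_key
        score = canonical_sum(chosen)
        if score > best_score + eps:
            best_set, best_score, best_key = list(chosen), score, _tie_key(chosen, hs)
        elif abs(score - best_score) <= eps * max(1.0, abs(best_score)):
            key = _tie_key(chosen, hs)
            if key < best_key:
                best_set, best_key = list(chosen), key

    def walk(i: int, banned: int, chosen: list[int], score: float) -> None:
        if i == n:
            consider(chosen, score)
            return
        # prune only when strictly worse — ties must still be explored
        if score + suffix[i] < best_score - eps:
            return
        if not (banned >> i) & 1:
            chosen.append(i)
            walk(i + 1, banned | conflict[i], chosen, score + scores[i])
            chosen.pop()
        walk(i + 1, banned, chosen, score)

    walk(0, 0, [], 0.0)

    selected = sorted(best_set, key=lambda i: (hs[i].env_from, hs[i].query_name))
    return Architecture(
        protein_id=pid,
        hits=tuple(hs[i] for i in selected),
        total_score=canonical_sum(selected),
    )
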
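"""Deterministic synthetic fixtures: proteomes with planted domains.

Every other module is exercised against data generated here, so no
external proteome, profile database or HMMER run is needed. Proteins are
built as random linkers surrounding mutated copies of per-domain
consensus sequences; decoys are residue-shuffled proteins with a matched
length distribution. The matching per-domain hit table is emitted
directly from the ground truth with configurable noise, simulating the
annotation step's output.

Domain consensi are pseudo-random sequences keyed by (domain_name,
consensus_seed), so the same domain name yields the same consensus in
every fixture of a test session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmmerio import DomainHit, quantize_evalue
from .seqio import SequenceRecord

__all__ = [
    "PlantSpec",
    "TruthSpan",
    "TruthRow",
    "TruthTable",
    "NoiseSpec",
    "domain_consensus",
    "plant_proteome",
    "emit_domtblout",
    "plant_family_dataset",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantSpec:
    """One planted family: its architecture and how many copies to make."""

    family_name: str
    architecture: tuple[tuple[str, int], ...]  # (domain_name, length)
    count: int = 1
    substitution_rate: float = 0.0
    linker_length_range: tuple[int, int] = (15, 40)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not (0.0 <= self.substitution_rate <= 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5]")
        for name, length in self.architecture:
            if length < 10:
                raise ValueError(f"domain {name}: length must be >= 10")


@dataclass(frozen=True)
class TruthSpan:
    domain_name: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class TruthRow:
    protein_id: str
    family_name: str
    spans: tuple[TruthSpan, ...]


@dataclass(frozen=True)
class TruthTable:
    rows: tuple[TruthRow, ...]
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for the emitted hit table.

    True hits draw E-values log-uniform in [true_evalue_range] (below the
    0.01 retention cut) and acc in [acc_range]. Spurious hits appear at
    ``spurious_rate`` per protein with E-values above the cut, so the
    default filter removes them. ``duplicate_rate`` adds, per true span,
    a second lower-scoring hit overlapping at least 40% of it —
    architecture resolution must prefer the true one.
    """

    true_evalue_range: tuple[float, float] = (1e-30, 1e-3)
    acc_range: tuple[float, float] = (0.7, 1.0)
    spurious_rate: float = 0.0
    spurious_evalue_range: tuple[float, float] = (0.02, 1.0)
    spurious_acc_range: tuple[float, float] = (0.3, 1.0)
    duplicate_rate: float = 0.0


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from heterogeneous parts (no hash())."""
    h = 2166136261
    for part in parts:
        for b in str(part).encode():
            h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h & 0x7FFFFFFF


def domain_consensus(name: str, length: int, consensus_seed: int = 0) -> str:
    """The fixed consensus sequence of a named synthetic domain."""
    rng = np.random.default_rng(_stable_seed("consensus", name, length, consensus_seed))
    return "".join(rng.choice(list(_AA), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_AA), size=n))


def plant_proteome(
    specs: Sequence[PlantSpec],
    n_decoys: int = 0,
    rng_seed: int = 0,
    consensus_seed: int = 0,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Build a proteome with planted architectures plus shuffled decoys.

    Proteins are named ``<family>_<k>``; decoys ``decoy_<k>`` and are
    shuffles of randomly chosen planted proteins (matched length
    distribution, no intact domain). Fully deterministic under
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    records: list[SequenceRecord] = []
    truth_rows: list[TruthRow] = []
    lengths: dict[str, int] = {}
    for spec in specs:
        for k in range(spec.count):
            pid = f"{spec.family_name}_{k + 1}"
            lo, hi = spec.linker_length_range
            parts = [_random_linker(rng, lo, hi)]
            spans: list[TruthSpan] = []
            pos = len(parts[0])
            for dom_name, dom_len in spec.architecture:
                consensus = domain_consensus(dom_name, dom_len, consensus_seed)
                mutated = _mutate(consensus, spec.substitution_rate, rng)
                spans.append(TruthSpan(dom_name, pos + 1, pos + dom_len))
                parts.append(mutated)
                pos += dom_len
                linker = _random_linker(rng, lo, hi)
                parts.append(linker)
                pos += len(linker)
            residues = "".join(parts)
            records.append(SequenceRecord(pid, f"planted {spec.family_name}", residues))
            truth_rows.append(TruthRow(pid, spec.family_name, tuple(spans)))
            lengths[pid] = len(residues)
    planted = list(records)
    for k in range(n_decoys):
        if planted:
            template = planted[int(rng.integers(len(planted)))].residues
        else:
            template = _random_linker(rng, 100, 400)
        shuffled = "".join(rng.permutation(list(template)))
        pid = f"decoy_{k + 1}"
        records.append(SequenceRecord(pid, "shuffled decoy", shuffled))
        lengths[pid] = len(shuffled)
    return records, TruthTable(tuple(truth_rows), lengths)


def _draw_loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))


def emit_domtblout(
    truth: TruthTable,
    noise: NoiseSpec = NoiseSpec(),
    rng_seed: int = 0,
    query_lengths: dict[str, int] | None = None,
) -> list[DomainHit]:
    """Emit a per-domain hit table consistent with the ground truth.

    Every truth span yields one hit that passes the default retention
    filter; spurious and overlapping-duplicate hits are added per the
    noise spec. All hit invariants hold and the values are quantized at
    the table's printed precision, so the table round-trips losslessly.
    """
    rng = np.random.default_rng(rng_seed)
    hits: list[DomainHit] = []
    qlens = query_lengths or {}
    for row in truth.rows:
        tlen = truth.protein_lengths[row.protein_id]
        for span in row.spans:
            dom_len = span.end - span.start + 1
            qlen = qlens.get(span.domain_name, dom_len)
            ev = quantize_evalue(
                _draw_loguniform(rng, *noise.true_evalue_range)
            )
            acc = round(float(rng.uniform(*noise.acc_range)), 2)
            bits = round(float(-math.log10(ev) * 2.0 + rng.uniform(0, 5)), 1)
            hits.append(
                DomainHit(
                    target_id=row.protein_id,
                    target_len=tlen,
                    query_name=span.domain_name,
                    query_len=qlen,
                    full_evalue=ev,
                    bitscore=bits,
                    c_evalue=ev,
                    i_evalue=ev,
                    hmm_from=1,
                    hmm_to=qlen,
                    ali_from=span.start,
                    ali_to=span.end,
                    env_from=span.start,
                    env_to=span.end,
                    acc=min(acc, 1.0),
                )
            )
            if rng.random() < noise.duplicate_rate:
                # weaker competitor overlapping >= 40% of the true span:
                # same span shifted right by up to half the domain length
                shift = int(rng.integers(0, dom_len // 2 + 1))
                dup_from = min(span.start + shift, tlen)
                dup_to = min(span.end + shift, tlen)
                if dup_to - dup_from + 1 >= 10:
                    # weaker than the true hit but still below the 0.01
                    # retention cut, so resolution (not filtering) must
                    # reject it
                    dup_ev = quantize_evalue(
                        min(9e-3, hits[-1].i_evalue * 10 ** float(rng.uniform(1, 4)))
                    )
                    if dup_ev > hits[-1].i_evalue:
                        hits.append(
                            DomainHit(
                                target_id=row.protein_id,
                                target_len=tlen,
                                query_name=span.domain_name + "_alt",
                                query_len=dup_to - dup_from + 1,
                                full_evalue=dup_ev,
                                bitscore=round(bits / 2, 1),
                                c_evalue=dup_ev,
                                i_evalue=dup_ev,
                                hmm_from=1,
                                hmm_to=dup_to - dup_from + 1,
                                ali_from=dup_from,
                                ali_to=dup_to,
                                env_from=dup_from,
                                env_to=dup_to,
                                acc=round(float(rng.uniform(0.6, 1.0)), 2),
                            )
                        )
        if rng.random() < noise.spurious_rate:
            start = int(rng.integers(1, max(2, tlen - 30)))
            end = min(start + 29, tlen)
            ev = quantize_evalue(_draw_loguniform(rng, *noise.spurious_evalue_range))
            hits.append(
                DomainHit(
                    target_id=row.protein_id,
                    target_len=tlen,
                    query_name="SPUR",
                    query_len=30,
                    full_evalue=ev,
                    bitscore=round(float(rng.uniform(1, 10)), 1),
                    c_evalue=ev,
                    i_evalue=ev,
                    hmm_from=1,
                    hmm_to=end - start + 1,
                    ali_from=start,
                    ali_to=end,
                    env_from=start,
                    env_to=end,
                    acc=round(float(rng.uniform(*noise.spurious_acc_range)), 2),
                )
            )
    return hits


def plant_family_dataset(
    seed_count: int = 3,
    member_count: int = 20,
    decoy_count: int = 80,
    divergence_ladder: Sequence[float] = (0.05, 0.15, 0.25),
    rng_seed: int = 0,
    domain_length: int = 80,
    linker_length_range: tuple[int, int] = (20, 60),
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthTable]:
    """Dataset for the enrichment loop: one family at graded divergence.

    Seeds are drawn at low (2%) divergence from a root consensus; members
    are stratified across the ladder's substitution rates; decoys are
    shuffles. Returns (seeds, dataset, truth): the dataset holds members
    plus decoys, never the seeds themselves.
    """
    if list(divergence_ladder) != sorted(divergence_ladder):
        raise ValueError("divergence_ladder must be increasing")
    rng = np.random.default_rng(rng_seed)
    root = domain_consensus("FAMROOT", domain_length, consensus_seed=rng_seed)
    lo, hi = linker_length_range

    def make(pid: str, rate: float, desc: str) -> tuple[SequenceRecord, TruthSpan]:
        left = _random_linker(rng, lo, hi)
        core = _mutate(root, rate, rng)
        right = _random_linker(rng, lo, hi)
        rec = SequenceRecord(pid, desc, left + core + right)
        return rec, TruthSpan("FAMROOT", len(left) + 1, len(left) + domain_length)

    # seeds are domain sequences (no flanking linkers), matching the
    # protocol where seed files carry the domain of interest itself
    seeds: list[SequenceRecord] = []
    for k in range(seed_count):
        seeds.append(
            SequenceRecord(f"seed_{k + 1}", "seed domain", _mutate(root, 0.02, rng))
        )
    dataset: list[SequenceRecord] = []
    rows: list[TruthRow] = []
    lengths: dict[str, int] = {}
    ladder = list(divergence_ladder) or [0.1]
    for k in range(member_count):
        rate = ladder[k % len(ladder)]
        rec, span = make(f"member_{k + 1}", rate, f"family member rate={rate}")
        dataset.append(rec)
        rows.append(TruthRow(rec.id, "FAMROOT", (span,)))
        lengths[rec.id] = len(rec.residues)
    for k in range(decoy_count):
        template = dataset[int(rng.integers(len(dataset)))].residues if dataset else root
        shuffled = "".join(rng.permutation(list(template)))
        rec = SequenceRecord(f"decoy_{k + 1}", "shuffled decoy", shuffled)
        dataset.append(rec)
        lengths[rec.id] = len(rec.residues)
    return seeds, dataset, TruthTable(tuple(rows), lengths)
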
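"""Iterative profile enrichment with counter-based convergence.

Starting from a handful of seed sequences, the loop builds a profile,
searches it against a larger dataset (e.g. a proteome), merges the
matching sequences into the seed set, removes redundancy by greedy
identity clustering at 90%, and rebuilds the profile — repeating until
the seed count stabilizes. Convergence is declared when the seed count
is unchanged between iterations (diff == 0), or when a counter — which
increments every iteration whose count difference is negative or equal
to 1 — reaches its limit (default 3). The counter exists to cut off long
tails of iterations that each recover at most one new sequence; it never
resets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .align import identity
from .backends import ProfileModel, SearchParams, get_backend
from .errors import UsageError
from .hmmerio import concat_profiles
from .seqio import SequenceRecord, write_fasta

__all__ = [
    "EnrichParams",
    "EnrichState",
    "pairwise_identity",
    "cluster_identity",
    "update_convergence",
    "enrich",
    "enrich_directory",
    "write_clustal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichParams:
    """Knobs of the enrichment loop (defaults are the standard protocol).

    identity_threshold:
        Redundancy cutoff for seed clustering (fraction identity, 0.90).
    counter_increment_diff:
        The counter increments when the iteration-to-iteration change in
        seed count is negative or equal to this (default 1).
    counter_limit:
        Convergence is declared when the counter reaches this (default 3).
    evalue_max / acc_min:
        Hit retention thresholds of the per-iteration search.
    max_iterations:
        Safety valve; exceeding it reports non-convergence, never success.
    """

    identity_threshold: float = 0.90
    counter_increment_diff: int = 1
    counter_limit: int = 3
    evalue_max: float = 0.01
    acc_min: float = 0.6
    max_iterations: int = 50
    rng_seed: int = 0
    null_shuffles: int = 200

    def search_params(self) -> SearchParams:
        return SearchParams(
            evalue_max=self.evalue_max,
            acc_min=self.acc_min,
            null_shuffles=self.null_shuffles,
            rng_seed=self.rng_seed,
        )


@dataclass(frozen=True)
class EnrichState:
    """Progress record of one enrichment run."""

    iteration: int = 0
    seed_count_history: tuple[int, ...] = ()
    counter: int = 0
    converged: bool = False
    reason: str | None = None  # diff-zero | counter-limit | max-iterations


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment identity between two records, in [0, 1].

    Identical aligned pairs over alignment columns, excluding terminal-gap
    columns (so containment of a short sequence in a longer one is judged
    on the aligned core).
    """
    return identity(a.residues, b.residues)


def cluster_identity(
    records: Sequence[SequenceRecord], threshold: float = 0.90
) -> list[SequenceRecord]:
    """Greedy centroid clustering; returns one representative per cluster.

    Records are processed in decreasing length order (ties broken by id);
    each joins the first centroid it matches at >= threshold identity,
    otherwise it founds a new cluster. Centroids come back in the order
    they were founded.
    """
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    centroids: list[SequenceRecord] = []
    for rec in ordered:
        if not any(pairwise_identity(rec, c) >= threshold for c in centroids):
            centroids.append(rec)
    return centroids


def update_convergence(
    state: EnrichState, new_count: int, params: EnrichParams = EnrichParams()
) -> EnrichState:
    """Fold one iteration's seed count into the convergence state.

    diff == 0 stops immediately; diff < 0 or diff == counter_increment_diff
    bumps the counter, and reaching counter_limit also stops. The first
    count simply opens the history.
    """
    if state.converged:
        raise UsageError("update_convergence called on a converged state")
    history = state.seed_count_history + (new_count,)
    if not state.seed_count_history:
        return replace(state, iteration=state.iteration + 1, seed_count_history=history)
    diff = new_count - state.seed_count_history[-1]
    counter = state.counter
    converged = False
    reason = None
    if diff == 0:
        converged, reason = True, "diff-zero"
    else:
        if diff < 0 or diff == params.counter_increment_diff:
            counter += 1
        if counter >= params.counter_limit:
            converged, reason = True, "counter-limit"
    return EnrichState(
        iteration=state.iteration + 1,
        seed_count_history=history,
        counter=counter,
        converged=converged,
        reason=reason,
    )


def write_clustal(ids: Sequence[str], rows: Sequence[str], path: str | Path) -> Path:
    """Write an alignment in Clustal-style text (60-column blocks)."""
    path = Path(path)
    width = max((len(i) for i in ids), default=0) + 3
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("CLUSTAL multiple sequence alignment (archminer)\n\n")
        if rows:
            total = len(rows[0])
            for start in range(0, total, 60):
                for rec_id, row in zip(ids, rows):
                    fh.write(f"{rec_id:<{width}}{row[start:start + 60]}\n")
                fh.write("\n")
    return path


def _snapshot(
    out_dir: Path, iteration: int, name: str, seeds: Sequence[SequenceRecord],
    profile: ProfileModel,
) -> None:
    it_dir = out_dir / f"iter_{iteration}"
    it_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(seeds, it_dir / f"{name}_seed.fa")
    profile.save(it_dir / f"{name}.hmm")


def enrich(
    seeds: Sequence[SequenceRecord],
    dataset: Sequence[SequenceRecord],
    name: str,
    params: EnrichParams = EnrichParams(),
    backend: str | object = "builtin",
    out_dir: str | Path | None = None,
) -> tuple[ProfileModel, list[SequenceRecord], EnrichState]:
    """Run the full enrichment loop for one seed family.

    Returns the final profile (built from the final seed set), the final
    seed set, and the convergence record. With ``out_dir`` set, per-
    iteration snapshots (seed FASTA + profile) are written to
    ``iter_<i>/`` and the final artifacts (<name>.hmm, <name>_seed.fa,
    <name>_seed.clw, info.log) at the top level.
    """
    if not seeds:
        raise UsageError("enrich needs at least one seed sequence")
    if not dataset:
        raise UsageError("enrich needs a non-empty dataset")
    be = get_backend(backend) if isinstance(backend, str) else backend
    sp = params.search_params()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    dataset_by_id = {rec.id: rec for rec in dataset}
    current = cluster_identity(seeds, params.identity_threshold)
    state = update_convergence(EnrichState(), len(current), params)
    log_lines = [f"initial seeds: {len(seeds)} ({len(current)} after redundancy clustering)"]

    profile = be.build(current, name)
    while not state.converged and state.iteration <= params.max_iterations:
        hits = be.search(profile, dataset, sp)
        # per matching sequence keep the strongest hit and feed back its
        # envelope region: the profile models a domain, so the matched
        # window — not the whole protein — is what enriches the seeds
        best_hit: dict[str, object] = {}
        for h in hits:
            prev = best_hit.get(h.target_id)
            if prev is None or (h.i_evalue, -h.bitscore) < (prev.i_evalue, -prev.bitscore):
                best_hit[h.target_id] = h
        seed_ids = {r.id for r in current}
        new_members = []
        for tid in sorted(set(best_hit) - seed_ids):
            h = best_hit[tid]
            rec = dataset_by_id[tid]
            new_members.append(
                SequenceRecord(
                    rec.id, rec.description, rec.residues[h.env_from - 1 : h.env_to]
                )
            )
        merged = list(current) + new_members
        current = cluster_identity(merged, params.identity_threshold)
        state = update_convergence(state, len(current), params)
        log_lines.append(
            f"iteration {state.iteration - 1}: {len(best_hit)} matches, "
            f"{len(new_members)} new, seed count {len(current)} "
            f"(counter {state.counter})"
        )
        profile = be.build(current, name)
        if out_path is not None:
            _snapshot(out_path, state.iteration - 1, name, current, profile)

    if not state.converged:
        state = replace(state, converged=True, reason="max-iterations")
        log_lines.append(
            f"stopped at max_iterations={params.max_iterations} without convergence"
        )
        logger.warning("enrichment of %s hit max_iterations", name)
    else:
        log_lines.append(f"converged at iteration {state.iteration} ({state.reason})")

    if out_path is not None:
        profile.save(out_path / f"{name}.hmm")
        write_fasta(current, out_path / f"{name}_seed.fa")
        if profile.msa_rows and len(profile.msa_rows) == len(current):
            write_clustal([r.id for r in current], list(profile.msa_rows), out_path / f"{name}_seed.clw")
        (out_path / "info.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return profile, list(current), state


def enrich_directory(
    seed_sets: dict[str, Sequence[SequenceRecord]],
    dataset: Sequence[SequenceRecord],
    params: EnrichParams = EnrichParams(),
    backend: str | object = "builtin",
    out_dir: str | Path = "iterhmm_out",
) -> Path:
    """Enrich several seed families independently and build database.hmm.

    ``seed_sets`` maps family name to its seed records (one FASTA file
    each in the CLI). Each family is enriched in its own subdirectory and
    the final profiles are concatenated into <out_dir>/database.hmm.
    """
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    profile_files: list[Path] = []
    for fam_name in sorted(seed_sets):
        fam_dir = out_path / fam_name
        enrich(
            seed_sets[fam_name], dataset, fam_name,
            params=params, backend=backend, out_dir=fam_dir,
        )
        profile_files.append(fam_dir / f"{fam_name}.hmm")
    concat_profiles(profile_files, out_path / "database.hmm")
    return out_path / "database.hmm"
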
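"""Protein annotation pipeline: search, resolve, classify, write.

Given a protein dataset, a profile database (or a precomputed per-domain
hit table) and a rules file, the pipeline filters the hits, resolves
each protein's most-likely domain architecture, matches the rules, and
writes one XML summary plus one FASTA file per matching protein under
``results/<rule_name>/``, alongside the hit table and a run log.

The ``hits`` bypass — annotating from an existing domtblout without any
search backend — is a first-class path: it lets users post-process prior
HMMER runs and is guaranteed to give results identical to an in-process
search producing the same hit set.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .backends import SearchParams, get_backend
from .domarch import Architecture, FilterParams, best_architecture, filter_hits, hit_score
from .errors import DatasetIntegrityError
from .hmmerio import DomainHit, read_domtblout, profile_names, write_domtblout
from .rules import Rule, classify, parse_rules
from .seqio import SequenceRecord, read_fasta, write_fasta

__all__ = [
    "AnnotatedProtein",
    "annotate_dataset",
    "run_prosecda",
    "write_protein_xml",
    "read_protein_xml",
    "write_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotatedProtein:
    """One protein with its surviving hits, architecture and families."""

    record: SequenceRecord
    all_hits: tuple[DomainHit, ...]
    architecture: Architecture
    matched_rules: tuple[str, ...]


def annotate_dataset(
    dataset: Sequence[SequenceRecord],
    hits: Sequence[DomainHit],
    rule_set: Sequence[Rule],
    params: FilterParams = FilterParams(),
) -> list[AnnotatedProtein]:
    """Filter, resolve and classify; keep proteins matching >= 1 rule.

    Proteins with hits but no family match are only counted (logged),
    mirroring the tool's log-and-drop behavior. A hit naming an unknown
    protein id is an integrity error.
    """
    by_id = {rec.id: rec for rec in dataset}
    grouped: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        if h.target_id not in by_id:
            raise DatasetIntegrityError(
                f"hit references unknown protein id {h.target_id!r}"
            )
        grouped[h.target_id].append(h)

    results: list[AnnotatedProtein] = []
    n_with_hits = 0
    unmatched_missing: Counter[str] = Counter()
    for rec in dataset:
        raw = grouped.get(rec.id, [])
        kept = filter_hits(raw, params)
        if not kept:
            continue
        n_with_hits += 1
        arch = best_architecture(
            kept, threshold=params.overlap_threshold, on=params.overlap_on,
            protein_id=rec.id,
        )
        matched = classify(arch, rule_set)
        if matched:
            results.append(
                AnnotatedProtein(rec, tuple(kept), arch, tuple(matched))
            )
        else:
            # nearest missing domain: for the rule(s) missing fewest
            # mandatory domains, count what was absent (rule debugging aid)
            present = set(arch.domain_names)
            best_missing: list[str] = []
            best_n = None
            for rule in rule_set:
                missing = [m.name for m in rule.mandatory if m.name not in present]
                if missing and (best_n is None or len(missing) < best_n):
                    best_n, best_missing = len(missing), missing
            unmatched_missing.update(best_missing)
    logger.info(
        "annotated %d/%d proteins with hits; %d matched a rule",
        n_with_hits, len(dataset), len(results),
    )
    if unmatched_missing:
        logger.info(
            "nearest missing domains among unmatched proteins: %s",
            dict(unmatched_missing.most_common()),
        )
    return results


# ---------------------------------------------------------------------------
# writers

def _hit_element(tag: str, h: DomainHit) -> ET.Element:
    el = ET.Element(tag)
    el.set("name", h.query_name)
    for attr in (
        "target_len", "query_len", "hmm_from", "hmm_to",
        "ali_from", "ali_to", "env_from", "env_to",
    ):
        el.set(attr, str(getattr(h, attr)))
    el.set("full_evalue", repr(h.full_evalue))
    el.set("c_evalue", repr(h.c_evalue))
    el.set("i_evalue", repr(h.i_evalue))
    el.set("bitscore", repr(h.bitscore))
    el.set("acc", repr(h.acc))
    el.set("score", repr(hit_score(h)))
    return el


def write_protein_xml(p: AnnotatedProtein, path: str | Path) -> Path:
    """Write one protein's annotation summary as XML.

    Numeric attributes are serialized with ``repr`` so parse-back is
    exact; the document validates against the shipped schema
    (``data/protein_annotation.xsd``).
    """
    root = ET.Element("protein", id=p.record.id)
    ET.SubElement(root, "length").text = str(len(p.record.residues))
    ET.SubElement(root, "description").text = p.record.description
    ET.SubElement(root, "sequence").text = p.record.residues
    fams = ET.SubElement(root, "families")
    for name in p.matched_rules:
        ET.SubElement(fams, "family", name=name)
    arch = ET.SubElement(
        root, "architecture", total_score=repr(p.architecture.total_score)
    )
    for h in p.architecture.hits:
        arch.append(_hit_element("domain", h))
    allhits = ET.SubElement(root, "hits")
    for h in p.all_hits:
        allhits.append(_hit_element("hit", h))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


def _parse_hit(el: ET.Element, target_id: str, description: str = "") -> DomainHit:
    return DomainHit(
        target_id=target_id,
        target_len=int(el.get("target_len")),
        query_name=el.get("name"),
        query_len=int(el.get("query_len")),
        full_evalue=float(el.get("full_evalue")),
        bitscore=float(el.get("bitscore")),
        c_evalue=float(el.get("c_evalue")),
        i_evalue=float(el.get("i_evalue")),
        hmm_from=int(el.get("hmm_from")),
        hmm_to=int(el.get("hmm_to")),
        ali_from=int(el.get("ali_from")),
        ali_to=int(el.get("ali_to")),
        env_from=int(el.get("env_from")),
        env_to=int(el.get("env_to")),
        acc=float(el.get("acc")),
        description=description,
    )


def read_protein_xml(path: str | Path) -> AnnotatedProtein:
    """Parse a protein summary back; inverse of write_protein_xml."""
    root = ET.parse(Path(path)).getroot()
    pid = root.get("id")
    record = SequenceRecord(
        pid,
        root.findtext("description") or "",
        root.findtext("sequence"),
    )
    matched = tuple(el.get("name") for el in root.find("families"))
    arch_el = root.find("architecture")
    arch_hits = tuple(_parse_hit(el, pid) for el in arch_el)
    arch = Architecture(
        protein_id=pid,
        hits=arch_hits,
        total_score=float(arch_el.get("total_score")),
    )
    all_hits = tuple(_parse_hit(el, pid) for el in root.find("hits"))
    return AnnotatedProtein(record, all_hits, arch, matched)


def write_summary(results: Sequence[AnnotatedProtein], path: str | Path) -> Path:
    """Write a TSV: one row per (protein, matched rule), sorted."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\trule\tn_domains\ttotal_score\tdomain_string\n")
        for p in sorted(results, key=lambda p: p.record.id):
            for rule_name in p.matched_rules:
                fh.write(
                    f"{p.record.id}\t{rule_name}\t{len(p.architecture.hits)}\t"
                    f"{p.architecture.total_score:.6g}\t"
                    f"{p.architecture.domain_string()}\n"
                )
    return path


def run_prosecda(
    dataset_path: str | Path,
    rules_path: str | Path,
    out_dir: str | Path,
    hmmdb_path: str | Path | None = None,
    hits_path: str | Path | None = None,
    params: FilterParams = FilterParams(),
    backend: str = "hmmer",
    rng_seed: int = 0,
    null_shuffles: int = 200,
) -> Path:
    """Run the full pipeline and write the output directory.

    Either ``hmmdb_path`` (search in-process with the chosen backend) or
    ``hits_path`` (ingest an existing domtblout) must be given. Output:
    ``info.log``, ``dataset.domtblout``, ``summary.tsv`` and
    ``results/<rule>/<protein>.xml|.fa`` per match.
    """
    if hmmdb_path is None and hits_path is None:
        raise DatasetIntegrityError("need a profile database or a hits table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    dataset = read_fasta(dataset_path)
    rule_set = parse_rules(rules_path)
    log_lines.append(f"dataset: {len(dataset)} proteins")
    log_lines.append(f"rules: {len(rule_set)} ({', '.join(r.name for r in rule_set)})")

    if hits_path is not None:
        hits = read_domtblout(hits_path)
        log_lines.append(f"hits ingested from {Path(hits_path).name}: {len(hits)}")
    else:
        be = get_backend(backend)
        sp = SearchParams(
            evalue_max=params.evalue_max, acc_min=params.acc_min,
            null_shuffles=null_shuffles, rng_seed=rng_seed,
        )
        if backend == "hmmer":
            hits = be.search_db(hmmdb_path, dataset, sp)
        else:
            from .backends import _load_builtin_profile

            hits = be.search(_load_builtin_profile(hmmdb_path), dataset, sp)
        log_lines.append(f"search produced {len(hits)} hits")

    # warn on rule domains absent from both the database and the hit table
    known = {h.query_name for h in hits}
    if hmmdb_path is not None:
        try:
            known |= set(profile_names(hmmdb_path))
        except Exception:
            pass
    unknown = sorted(
        {m.name for r in rule_set for m in r.mandatory} - known
        | set().union(*(set(r.forbidden) for r in rule_set)) - known
    )
    if unknown:
        logger.warning("rule domains never seen in profiles or hits: %s", unknown)
        log_lines.append(f"warning: unknown rule domains: {', '.join(unknown)}")

    write_domtblout(hits, out / "dataset.domtblout")
    results = annotate_dataset(dataset, hits, rule_set, params)
    log_lines.append(f"proteins matching >=1 rule: {len(results)}")

    results_dir = out / "results"
    results_dir.mkdir(exist_ok=True)
    for p in sorted(results, key=lambda p: p.record.id):
        for rule_name in p.matched_rules:
            rule_dir = results_dir / rule_name
            rule_dir.mkdir(exist_ok=True)
            write_protein_xml(p, rule_dir / f"{p.record.id}.xml")
            write_fasta([p.record], rule_dir / f"{p.record.id}.fa")
    write_summary(results, out / "summary.tsv")
    per_rule = Counter(name for p in results for name in p.matched_rules)
    for name, n in sorted(per_rule.items()):
        log_lines.append(f"  {name}: {n} proteins")
    (out / "info.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
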
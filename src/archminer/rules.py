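"""Family rules: YAML parsing and architecture matching.

A rule names a protein family by the domains its members must carry
(mandatory list, optionally with a per-domain E-value ceiling) and the
domains they must not (forbidden list). A protein belongs to a family
when its most-likely domain architecture contains every mandatory domain,
none of the forbidden ones, and each thresholded mandatory domain has at
least one hit with independent E-value strictly below its ceiling.

Accepted YAML layouts (both produce the same rules, file order kept)::

    rules:                      # or a bare top-level list
      - name: PKS
        comment: polyketide synthase, all three essential domains
        mandatory: [KS, AT, PP-binding]
        forbidden: [C, A]
      - name: DMATS
        mandatory:
          - Trp_DMAT
          - {name: XYZ, evalue: 1.0e-20}   # per-domain ceiling

Listing the same mandatory name twice requires two distinct hits of that
domain (multi-module rules); forbidden entries are plain names.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml

from .domarch import Architecture
from .errors import SchemaError

__all__ = ["MandatoryDomain", "Rule", "parse_rules", "match_rule", "classify"]


@dataclass(frozen=True)
class MandatoryDomain:
    name: str
    evalue_max: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("mandatory domain with empty name")
        if self.evalue_max is not None and self.evalue_max <= 0:
            raise SchemaError(
                f"mandatory domain {self.name!r}: evalue threshold must be positive"
            )


@dataclass(frozen=True)
class Rule:
    name: str
    mandatory: tuple[MandatoryDomain, ...]
    forbidden: tuple[str, ...] = ()
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("rule with empty name")
        if not self.mandatory:
            raise SchemaError(f"rule {self.name!r} has no mandatory domains")
        both = {m.name for m in self.mandatory} & set(self.forbidden)
        if both:
            raise SchemaError(
                f"rule {self.name!r}: domains in both mandatory and forbidden: "
                + ", ".join(sorted(both))
            )


def _parse_mandatory_entry(entry: Any, rule_name: str) -> MandatoryDomain:
    if isinstance(entry, str):
        return MandatoryDomain(entry)
    if isinstance(entry, dict):
        if "name" not in entry:
            raise SchemaError(f"rule {rule_name!r}: mandatory entry missing 'name'")
        extra = set(entry) - {"name", "evalue"}
        if extra:
            raise SchemaError(
                f"rule {rule_name!r}: unknown mandatory keys {sorted(extra)}"
            )
        ev = entry.get("evalue")
        return MandatoryDomain(str(entry["name"]), float(ev) if ev is not None else None)
    raise SchemaError(
        f"rule {rule_name!r}: mandatory entry must be a name or a name/evalue map"
    )


def _parse_rule(body: Any) -> Rule:
    if not isinstance(body, dict):
        raise SchemaError(f"rule entry must be a mapping, got {type(body).__name__}")
    name = body.get("name")
    if not name:
        raise SchemaError("rule entry without a name")
    name = str(name)
    unknown = set(body) - {"name", "comment", "mandatory", "forbidden"}
    if unknown:
        raise SchemaError(f"rule {name!r}: unknown keys {sorted(unknown)}")
    mandatory = body.get("mandatory")
    if not mandatory:
        raise SchemaError(f"rule {name!r} has no mandatory domains")
    if not isinstance(mandatory, list):
        raise SchemaError(f"rule {name!r}: mandatory must be a list")
    forbidden = body.get("forbidden") or []
    if not isinstance(forbidden, list):
        raise SchemaError(f"rule {name!r}: forbidden must be a list")
    return Rule(
        name=name,
        mandatory=tuple(_parse_mandatory_entry(e, name) for e in mandatory),
        forbidden=tuple(str(f) for f in forbidden),
        comment=str(body.get("comment") or ""),
    )


def parse_rules(path: str | Path) -> list[Rule]:
    """Parse a rules YAML file into an ordered list of Rule objects.

    Raises SchemaError on a rule without mandatory domains, duplicate
    rule names, or a domain listed as both mandatory and forbidden.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        try:
            doc = yaml.safe_load(handle)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: invalid YAML: {exc}") from exc
    if doc is None:
        return []
    if isinstance(doc, dict) and "rules" in doc:
        doc = doc["rules"]
    if not isinstance(doc, list):
        raise SchemaError(f"{path}: expected a list of rules (or a 'rules:' key)")
    out: list[Rule] = []
    seen: set[str] = set()
    for body in doc:
        rule = _parse_rule(body)
        if rule.name in seen:
            raise SchemaError(f"{path}: duplicate rule name {rule.name!r}")
        seen.add(rule.name)
        out.append(rule)
    return out


def match_rule(arch: Architecture, rule: Rule) -> bool:
    """Does this most-likely architecture satisfy the rule?

    Multiplicity counts: a name listed k times among the mandatory
    domains needs k distinct hits with that name. Per-domain E-value
    ceilings are strict (<) on the independent E-value and need only one
    qualifying hit of that name.
    """
    present = Counter(h.query_name for h in arch.hits)
    required = Counter(m.name for m in rule.mandatory)
    for name, k in required.items():
        if present[name] < k:
            return False
    if any(h.query_name in rule.forbidden for h in arch.hits):
        return False
    for m in rule.mandatory:
        if m.evalue_max is not None:
            if not any(
                h.query_name == m.name and h.i_evalue < m.evalue_max
                for h in arch.hits
            ):
                return False
    return True


def classify(arch: Architecture, rule_set: Sequence[Rule]) -> list[str]:
    """Names of all rules the architecture matches, in rule-file order."""
    return [r.name for r in rule_set if match_rule(arch, r)]
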
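"""HMMER3 per-domain table (domtblout) I/O and profile-database handling.

The domtblout dialect is the 23-column whitespace table written by
``hmmsearch --domtblout``: 22 fixed fields followed by a free-text target
description. All coordinates are 1-based inclusive, exactly as HMMER
prints them; the package keeps that convention internally so no off-by-one
translation happens outside the writers.

Profile files are treated as opaque named blocks (``HMMER3/f`` header
line .. ``//`` terminator, name on the ``NAME`` line); only NAME is parsed,
which is all that database concatenation and integrity checking need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DatasetIntegrityError, FormatError

__all__ = [
    "DomainHit",
    "read_domtblout",
    "write_domtblout",
    "concat_profiles",
    "profile_names",
]


@dataclass(frozen=True)
class DomainHit:
    """One domain match of a profile on a target protein.

    Field names follow the domtblout column headers. E-values:
    ``full_evalue`` is the full-sequence E-value, ``c_evalue`` /
    ``i_evalue`` the per-domain conditional / independent E-values.
    ``acc`` is HMMER's expected per-residue alignment accuracy in [0,1].
    """

    target_id: str
    target_len: int
    query_name: str
    query_len: int
    full_evalue: float
    bitscore: float
    c_evalue: float
    i_evalue: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int
    acc: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.env_from <= self.env_to <= self.target_len):
            raise FormatError(
                f"hit {self.query_name} on {self.target_id}: envelope "
                f"{self.env_from}-{self.env_to} outside 1-{self.target_len}"
            )
        if not (1 <= self.ali_from <= self.ali_to <= self.target_len):
            raise FormatError(
                f"hit {self.query_name} on {self.target_id}: alignment "
                f"{self.ali_from}-{self.ali_to} outside 1-{self.target_len}"
            )
        if not (self.env_from <= self.ali_from and self.ali_to <= self.env_to):
            raise FormatError(
                f"hit {self.query_name} on {self.target_id}: alignment "
                "not contained in envelope"
            )
        if not (1 <= self.hmm_from <= self.hmm_to <= self.query_len):
            raise FormatError(
                f"hit {self.query_name} on {self.target_id}: hmm coords "
                f"{self.hmm_from}-{self.hmm_to} outside 1-{self.query_len}"
            )
        for name in ("full_evalue", "c_evalue", "i_evalue"):
            v = getattr(self, name)
            if not (v >= 0.0) or math.isinf(v) or math.isnan(v):
                raise FormatError(f"hit {self.query_name}: {name} must be >= 0")
        if not (0.0 <= self.acc <= 1.0):
            raise FormatError(f"hit {self.query_name}: acc {self.acc} outside [0,1]")

    @property
    def env_len(self) -> int:
        return self.env_to - self.env_from + 1

    @property
    def ali_len(self) -> int:
        return self.ali_to - self.ali_from + 1

    def with_description(self, description: str) -> "DomainHit":
        return replace(self, description=description)


_HEADER = (
    "#%-19s %10s %5s %20s %10s %5s %9s %6s %5s %3s %3s %9s %9s %6s %5s "
    "%5s %5s %5s %5s %5s %5s %4s %s"
) % (
    " target name", "accession", "tlen", "query name", "accession", "qlen",
    "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
    "bias", "from", "to", "from", "to", "from", "to", "acc",
    "description of target",
)


def _fmt_e(v: float) -> str:
    if v == 0.0:
        return "0"
    return f"{v:.3g}" if 1e-3 <= v < 1e4 else f"{v:.2e}"


def quantize_evalue(v: float) -> float:
    """Round an E-value to the precision the domtblout writer prints.

    Hits whose numeric fields carry this precision (as all HMMER-produced
    tables do) round-trip bit-exactly through write/read.
    """
    return float(_fmt_e(v))


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table into DomainHit records.

    Comment lines ('#') are skipped. Rows must carry at least 22 fields;
    the remainder of the line after the 22nd field is kept as the target
    description. Invariant violations (e.g. ali_to > tlen) raise
    FormatError with the offending line number.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open("r", encoding="utf-8", newline=None) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 22:
                raise FormatError(
                    f"{path}:{lineno}: expected >=22 fields, got {len(fields)}"
                )
            desc = fields[22].rstrip("\n") if len(fields) > 22 else ""
            if desc == "-":
                desc = ""
            try:
                hit = DomainHit(
                    target_id=fields[0],
                    target_len=int(fields[2]),
                    query_name=fields[3],
                    query_len=int(fields[5]),
                    full_evalue=float(fields[6]),
                    bitscore=float(fields[13]),
                    c_evalue=float(fields[11]),
                    i_evalue=float(fields[12]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                    env_from=int(fields[19]),
                    env_to=int(fields[20]),
                    acc=float(fields[21]),
                    description=desc,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> Path:
    """Write hits in domtblout column order; read_domtblout inverts it.

    Hits on the same target are numbered in input order (the '# of'
    columns); accession and bias columns, which the data model does not
    carry, are written as '-' and 0.0 as hmmsearch does for unannotated
    profiles.
    """
    path = Path(path)
    hits = list(hits)
    per_target: dict[str, int] = {}
    for h in hits:
        per_target[h.target_id] = per_target.get(h.target_id, 0) + 1
    counter: dict[str, int] = {}
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write(_HEADER + "\n")
        for h in hits:
            counter[h.target_id] = counter.get(h.target_id, 0) + 1
            row = (
                f"{h.target_id:<20} {'-':>10} {h.target_len:>5} "
                f"{h.query_name:<20} {'-':>10} {h.query_len:>5} "
                f"{_fmt_e(h.full_evalue):>9} {h.bitscore:>6.1f} {0.0:>5.1f} "
                f"{counter[h.target_id]:>3} {per_target[h.target_id]:>3} "
                f"{_fmt_e(h.c_evalue):>9} {_fmt_e(h.i_evalue):>9} "
                f"{h.bitscore:>6.1f} {0.0:>5.1f} "
                f"{h.hmm_from:>5} {h.hmm_to:>5} "
                f"{h.ali_from:>5} {h.ali_to:>5} "
                f"{h.env_from:>5} {h.env_to:>5} {h.acc:>4.2f} "
                f"{h.description if h.description else '-'}"
            )
            handle.write(row + "\n")
    return path


def profile_names(path: str | Path) -> list[str]:
    """Extract profile NAMEs from a HMMER3 ASCII profile file, in order."""
    path = Path(path)
    names: list[str] = []
    in_block = False
    with path.open("r", encoding="utf-8", newline=None) as handle:
        for line in handle:
            if line.startswith("HMMER") or line.startswith("ARCHMINER-PSSM"):
                in_block = True
            elif in_block and line.startswith("NAME"):
                parts = line.split()
                if len(parts) >= 2:
                    names.append(parts[1])
            elif line.strip() == "//":
                in_block = False
    if not names:
        raise FormatError(f"{path}: no named profile blocks found")
    return names


def concat_profiles(
    profile_paths: Sequence[str | Path], out_path: str | Path
) -> Path:
    """Concatenate profile files into one database, byte-wise and in order.

    Raises DatasetIntegrityError naming the profile if the same NAME occurs
    in more than one block across the inputs.
    """
    seen: dict[str, Path] = {}
    paths = [Path(p) for p in profile_paths]
    for p in paths:
        for name in profile_names(p):
            if name in seen:
                raise DatasetIntegrityError(
                    f"duplicate profile name {name!r} in {p} (already in {seen[name]})"
                )
            seen[name] = p
    out_path = Path(out_path)
    with out_path.open("wb") as out:
        for p in paths:
            out.write(p.read_bytes())
    return out_path
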
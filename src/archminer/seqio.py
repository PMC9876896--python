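"""Protein FASTA input/output with strict identifier hygiene.

Records are plain dataclasses rather than Biopython ``SeqRecord`` objects:
the rest of the package only needs (id, description, residues) and the
round-trip guarantee, and a frozen dataclass keeps that contract explicit.
Parsing is delegated to Biopython's ``SimpleFastaParser``; validation
(duplicate ids, alphabet, gap stripping) is layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import DatasetIntegrityError, FormatError

#: The 20 standard amino acids plus ambiguity codes (X, B, Z), the rare
#: translated residues (U selenocysteine, O pyrrolysine) and '*' (stop).
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    Attributes
    ----------
    id:
        Unique identifier, no whitespace (text up to the first whitespace
        of the FASTA header, matching HMMER's target-name convention).
    description:
        Remainder of the header line; may be empty.
    residues:
        Upper-case amino-acid string, length >= 1.
    """

    id: str
    description: str = ""
    residues: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise FormatError(f"empty sequence body for id {self.id!r}")
        bad = set(self.residues) - AMINO_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-amino-acid characters: "
                + "".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)


def _clean_residues(raw: str, rec_id: str) -> str:
    # '-' is an alignment artifact and is silently stripped; anything else
    # outside the alphabet is rejected by SequenceRecord itself.
    return raw.replace("-", "").upper()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of records, in file order.

    Headers are split at the first whitespace into id + description;
    multi-line sequences are joined; residues are upper-cased and
    alignment gaps ('-') stripped.

    Raises
    ------
    FormatError
        Non-FASTA content, empty sequence body, or illegal characters.
    DatasetIntegrityError
        Two records share an id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8", newline=None) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: not FASTA (first character {first!r})")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: record with empty header")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise DatasetIntegrityError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            residues = _clean_residues(seq, rec_id)
            if not residues:
                raise FormatError(f"{path}: empty sequence body for {rec_id!r}")
            records.append(SequenceRecord(rec_id, desc, residues))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> Path:
    """Write records as FASTA with sequence lines wrapped at ``width``.

    ``read_fasta(write_fasta(x))`` reproduces ids, descriptions and
    residues exactly.
    """
    if width < 1:
        raise ValueError("width must be positive")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    return path


def check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    """Raise DatasetIntegrityError if any id occurs twice."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DatasetIntegrityError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
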
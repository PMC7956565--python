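"""Validated protein sequences and FASTA / coding-sequence input.

The central type is :class:`ProteinSequence`, an immutable record holding an
uppercase sequence over the 20 canonical amino acids together with an
identifier and a provenance tag.  All downstream metrics consume it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import CANONICAL_AA

_CANONICAL = frozenset(CANONICAL_AA)

SOURCES = ("user", "translated-cds", "synthetic")


class SequenceError(ValueError):
    """Raised for empty input or non-canonical residues."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus a validated canonical amino-acid string.

    Attributes
    ----------
    id : str
        Free-text identifier (FASTA header word).
    residues : str
        Uppercase string over ``ACDEFGHIKLMNPQRSTVWY``.
    source : str
        One of ``user``, ``translated-cds``, ``synthetic``.
    """

    id: str
    residues: str
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _CANONICAL:
                raise SequenceError(
                    f"illegal character {ch!r} at position {pos} in {self.id!r}"
                )
        if self.source not in SOURCES:
            raise SequenceError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    @property
    def n(self) -> int:
        """Residue count N, the length all per-residue metrics divide by."""
        return len(self.residues)


def normalize_sequence(raw: str, id: str = "seq", source: str = "user") -> ProteinSequence:
    """Build a :class:`ProteinSequence` from free-form text.

    Whitespace, digits and ``*``/``-`` (stop and gap marks) are stripped and
    letters are uppercased; any remaining non-canonical character raises
    :class:`SequenceError` reporting its 1-based position in the cleaned
    sequence.
    """
    cleaned = []
    for ch in raw:
        if ch.isspace() or ch.isdigit() or ch in "*-":
            continue
        cleaned.append(ch.upper())
    if not cleaned:
        raise SequenceError("empty sequence after normalization")
    return ProteinSequence(id=id, residues="".join(cleaned), source=source)


def read_fasta(path: str | Path | io.TextIOBase, source: str = "user") -> list[ProteinSequence]:
    """Read a multi-record protein FASTA into validated sequences."""
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise SequenceError("no FASTA records found")
    return [normalize_sequence(str(r.seq), id=r.id, source=source) for r in records]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as wrapped (60-column) FASTA."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def translate_cds(nt: str, id: str = "cds") -> ProteinSequence:
    """Translate a coding nucleotide sequence (standard code, stop-trimmed)."""
    cleaned = "".join(ch for ch in nt if not ch.isspace()).upper()
    if not cleaned:
        raise SequenceError("empty nucleotide sequence")
    if len(cleaned) % 3:
        cleaned = cleaned[: len(cleaned) - len(cleaned) % 3]
    aa = str(Seq(cleaned).translate(to_stop=True))
    return normalize_sequence(aa, id=id, source="translated-cds")


def read_cds_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a nucleotide FASTA and translate each record."""
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise SequenceError("no FASTA records found")
    return [translate_cds(str(r.seq), id=r.id) for r in records]


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> tuple[float, list[tuple[int, str, str]]]:
    """Ungapped percent identity plus the substitution list.

    Returns ``(percent, substitutions)`` where each substitution is a
    ``(position, residue_in_a, residue_in_b)`` triple with 1-based positions.
    Sequences must be equal length; alignment is out of scope here.
    """
    if len(a) != len(b):
        raise SequenceError(
            f"length mismatch: {a.id} has {len(a)} residues, {b.id} has {len(b)}"
        )
    subs = [
        (i, ra, rb)
        for i, (ra, rb) in enumerate(zip(a.residues, b.residues), start=1)
        if ra != rb
    ]
    matches = len(a) - len(subs)
    return 100.0 * matches / len(a), subs
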
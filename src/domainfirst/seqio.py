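"""Sequence and identifier I/O.

Reads and writes the FASTA files the pipeline touches and defines the
frame-suffixed identifier grammar (``<accession>_<frame>``, e.g.
``TSAX02003111.1_-1``) used to name six-frame translation records
throughout the annotation workflow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "Transcript",
    "FramedId",
    "FastaFormatError",
    "DuplicateIdError",
    "FramedIdError",
    "FRAMES",
    "read_fasta",
    "write_fasta",
    "parse_framed_id",
]

#: Canonical frame order: three forward frames, then three reverse.
FRAMES: tuple[int, ...] = (1, 2, 3, -1, -2, -3)


class FastaFormatError(ValueError):
    """A FASTA record is malformed (empty sequence, bad header)."""


class DuplicateIdError(ValueError):
    """Identifiers must be unique within one collection or file."""


class FramedIdError(ValueError):
    """Text does not follow the ``<accession>_<signed frame>`` grammar."""


@dataclass(frozen=True)
class Transcript:
    """One nucleotide record of an assembled transcriptome.

    The sequence is stored uppercase with U mapped to T (the assembly is
    cDNA); IUPAC ambiguity codes are retained and handled at translation
    time.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaFormatError("transcript accession must be non-empty")
        if not self.sequence:
            raise FastaFormatError(
                f"transcript {self.accession!r} has an empty sequence"
            )
        norm = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", norm)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reverse_complement(self) -> str:
        return str(Seq(self.sequence).reverse_complement())


_FRAMED_RE = re.compile(r"^(?P<acc>.+)_(?P<frame>[+-][123])$")


@dataclass(frozen=True, order=True)
class FramedId:
    """A transcript accession plus one of the six reading frames."""

    accession: str
    frame: int

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise FramedIdError(f"frame must be one of {FRAMES}, got {self.frame}")
        if not self.accession:
            raise FramedIdError("accession must be non-empty")

    def render(self) -> str:
        """Text form with an explicit sign: ``TSAX02003111.1_-1``."""
        return f"{self.accession}_{self.frame:+d}"

    def __str__(self) -> str:
        return self.render()


def parse_framed_id(text: str) -> FramedId:
    """Parse ``<accession>_<signed frame>`` back into its parts.

    Inverse of :meth:`FramedId.render`: the accession is everything before
    the final underscore; the suffix must be a signed digit 1-3.
    """
    m = _FRAMED_RE.match(text)
    if m is None:
        raise FramedIdError(
            f"{text!r} does not end in _<signed frame 1-3> (e.g. '_-1', '_+2')"
        )
    return FramedId(m.group("acc"), int(m.group("frame")))


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a nucleotide FASTA into :class:`Transcript` records, in file order.

    Sequences are uppercased (U -> T); duplicate accessions are rejected.
    """
    records: list[Transcript] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FastaFormatError(f"record {i} has an empty identifier")
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"record {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate accession {rec.id!r} at record {i}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(Transcript(rec.id, seq, desc))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]] | Sequence[Transcript],
    path: str | Path,
    width: int = 60,
) -> Path:
    """Write (identifier, sequence) pairs as FASTA, 60-column wrapped.

    Accepts either bare pairs or :class:`Transcript` objects.  Round-trips
    exactly through :func:`read_fasta` for any alphabet used here
    (nucleotide, protein, including ``*`` stops).
    """
    path = Path(path)
    seen: set[str] = set()
    with path.open("w") as fh:
        for item in records:
            if isinstance(item, Transcript):
                ident, seq = item.accession, item.sequence
            else:
                ident, seq = item
            if ident in seen:
                raise DuplicateIdError(f"duplicate identifier {ident!r}")
            seen.add(ident)
            fh.write(f">{ident}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")
    return path


def to_seqrecords(pairs: Iterable[tuple[str, str]]) -> list[SeqRecord]:
    """Convenience adapter to Biopython records (used by the CLI)."""
    return [SeqRecord(Seq(s), id=i, description="") for i, s in pairs]
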
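"""Six-frame conceptual translation with exact coordinate bookkeeping.

Every transcript is translated in all six reading frames — three on the
forward strand (starting at nucleotide 1, 2, 3) and three on the reverse
complement — producing the in-silico proteome that the domain scan is run
against.  Translation runs *through* internal stop codons (emitted as
``*``); segmentation into ORFs happens downstream.  A
:class:`CoordinateMap` converts 1-based protein positions on any frame back
to 1-based inclusive forward-strand nucleotide intervals, and back.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.Data import CodonTable

from .seqio import FRAMES, FramedId, Transcript

__all__ = [
    "FrameTranslation",
    "CoordinateMap",
    "six_frame_translate",
    "frame_offset",
]


def frame_offset(frame: int) -> int:
    """0-based offset of a frame on its own strand: +1/-1 -> 0, +2/-2 -> 1, ..."""
    return abs(frame) - 1


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional protein <-> nucleotide coordinate map for one frame.

    Protein position ``p`` (1-based) on frame ``+k`` occupies forward-strand
    nucleotides ``[(k-1) + 3(p-1) + 1, (k-1) + 3p]``, 1-based inclusive.
    Reverse frames apply the same formula on the reverse complement and the
    result is reported in forward-strand coordinates (start <= end always).
    """

    frame: int
    source_length: int

    @property
    def protein_length(self) -> int:
        return max(0, (self.source_length - frame_offset(self.frame)) // 3)

    def protein_to_nucleotide(self, a: int, b: int | None = None) -> tuple[int, int]:
        """Forward-strand nt interval covered by protein positions [a, b]."""
        if b is None:
            b = a
        n = self.protein_length
        if not (1 <= a <= b <= n):
            raise IndexError(
                f"protein interval [{a},{b}] out of range for frame "
                f"{self.frame:+d} of length {n}"
            )
        off = frame_offset(self.frame)
        # coordinates on the reading strand, 1-based
        s_start = off + 3 * (a - 1) + 1
        s_end = off + 3 * b
        if self.frame > 0:
            return s_start, s_end
        # reverse strand: position j on the reverse complement is forward
        # position L - j + 1; the interval flips.
        L = self.source_length
        return L - s_end + 1, L - s_start + 1

    def nucleotide_to_protein(self, nt_start: int, nt_end: int) -> tuple[int, int]:
        """Inverse of :meth:`protein_to_nucleotide` on codon-aligned intervals."""
        if not (1 <= nt_start <= nt_end <= self.source_length):
            raise IndexError(
                f"nt interval [{nt_start},{nt_end}] outside [1,{self.source_length}]"
            )
        off = frame_offset(self.frame)
        if self.frame > 0:
            s_start, s_end = nt_start, nt_end
        else:
            L = self.source_length
            s_start, s_end = L - nt_end + 1, L - nt_start + 1
        if (s_start - off - 1) % 3 != 0 or (s_end - off) % 3 != 0:
            raise ValueError(
                f"nt interval [{nt_start},{nt_end}] is not codon-aligned on "
                f"frame {self.frame:+d}"
            )
        a = (s_start - off - 1) // 3 + 1
        b = (s_end - off) // 3
        return a, b


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual protein sequences of a transcript.

    ``protein`` is over the 20 residues plus ``*`` (stop) and ``X``
    (ambiguous codon); its length is exactly
    ``floor((source_length - offset) / 3)``.
    """

    id: FramedId
    protein: str
    source_length: int

    @property
    def coordinate_map(self) -> CoordinateMap:
        return CoordinateMap(self.id.frame, self.source_length)


def _translate_strand(seq: str, table) -> list[str]:
    """Translate one strand in frames 1..3, trimming partial codons."""
    out = []
    for off in range(3):
        sub = seq[off:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate(table=table)) if sub else "")
    return out


def six_frame_translate(
    t: Transcript, table: int | str = 1
) -> list[FrameTranslation]:
    """Translate a transcript in all six frames.

    Returns exactly six records in frame order +1, +2, +3, -1, -2, -3.
    Trailing partial codons are dropped; internal stops render as ``*``;
    codons with unresolved ambiguity codes render as ``X``.  ``table`` is a
    genetic-code table number or name (default: the standard code).
    """
    try:
        CodonTable.ambiguous_dna_by_id[int(table)] if str(table).isdigit() \
            else CodonTable.ambiguous_dna_by_name[str(table)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown genetic-code table {table!r}") from exc

    fwd = _translate_strand(t.sequence, table)
    rev = _translate_strand(t.reverse_complement, table)
    proteins = fwd + rev
    return [
        FrameTranslation(FramedId(t.accession, f), p, len(t))
        for f, p in zip(FRAMES, proteins)
    ]


def translate_all(
    transcripts, table: int | str = 1
) -> list[FrameTranslation]:
    """Six-frame translate a whole collection (6x as many records out)."""
    out: list[FrameTranslation] = []
    for t in transcripts:
        out.extend(six_frame_translate(t, table))
    return out
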
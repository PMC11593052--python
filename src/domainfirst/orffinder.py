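"""Open-reading-frame enumeration over six-frame translations.

Two usage styles mirror the two annotation strategies: the classic route
keeps only the longest ORF per transcript, while the domain-first route
evaluates *all* ORFs, because a conserved domain can sit on an ORF that is
not the longest one on its transcript.

Conventions: an ORF is the maximal coding stretch within one stop-delimited
segment of a frame translation — from the first qualifying start (ATG rule)
or the segment start (any-codon rule) to the residue before the stop.
Nested sub-ORFs sharing a stop are not reported.  The reported nucleotide
span *excludes* the stop codon, so span == 3 x protein length (a 951-nt
coding stretch yields a 317-residue protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .seqio import FRAMES, FramedId
from .sixframe import FrameTranslation

__all__ = ["OrfPolicy", "Orf", "find_orfs", "find_all_orfs", "longest_orf"]

_FRAME_RANK = {f: i for i, f in enumerate(FRAMES)}


@dataclass(frozen=True)
class OrfPolicy:
    """Start rule, minimum length and 3' handling for ORF calling.

    Defaults mirror common ORF-finder settings: ATG starts, a 25-residue
    (~75 nt) minimum, and unterminated 3' ORFs allowed.
    """

    atg_start: bool = True
    min_protein_length: int = 25
    allow_unterminated: bool = True


@dataclass(frozen=True)
class Orf:
    """A start-to-stop protein-coding interval within one frame.

    ``protein_start``/``protein_end`` are 1-based positions on the frame
    translation; ``nt_start``/``nt_end`` the corresponding forward-strand
    interval (stop codon excluded).  ``protein`` never contains ``*``.
    """

    id: FramedId
    protein_start: int
    protein_end: int
    nt_start: int
    nt_end: int
    protein: str
    has_terminal_stop: bool

    def __len__(self) -> int:
        return len(self.protein)

    @property
    def sort_key(self):
        # descending length, then frame order +1..+3,-1..-3, then 5' position
        return (-len(self.protein), _FRAME_RANK[self.id.frame], self.protein_start)


def find_orfs(ft: FrameTranslation, policy: OrfPolicy = OrfPolicy()) -> list[Orf]:
    """Enumerate ORFs in one frame translation under a policy.

    Returns the frame's ORFs sorted by descending protein length (ties by 5'
    position).  The empty list is a valid result.
    """
    cmap = ft.coordinate_map
    orfs: list[Orf] = []
    pos = 0  # 0-based cursor into the protein string
    n = len(ft.protein)
    while pos < n:
        stop = ft.protein.find("*", pos)
        if stop == -1:
            seg_end, terminated, nxt = n, False, n
        else:
            seg_end, terminated, nxt = stop, True, stop + 1
        segment = ft.protein[pos:seg_end]
        if not terminated and not policy.allow_unterminated:
            pos = nxt
            continue
        if policy.atg_start:
            m = segment.find("M")
            start = pos + m if m != -1 else None
        else:
            start = pos if segment else None
        if start is not None:
            protein = ft.protein[start:seg_end]
            if len(protein) >= policy.min_protein_length:
                a, b = start + 1, seg_end  # 1-based inclusive protein coords
                nt_a, nt_b = cmap.protein_to_nucleotide(a, b)
                orfs.append(
                    Orf(ft.id, a, b, nt_a, nt_b, protein, terminated)
                )
        pos = nxt
    return sorted(orfs, key=lambda o: o.sort_key)


def find_all_orfs(
    translations: Iterable[FrameTranslation], policy: OrfPolicy = OrfPolicy()
) -> list[Orf]:
    """ORFs across several frame translations, in the canonical sort order."""
    out: list[Orf] = []
    for ft in translations:
        out.extend(find_orfs(ft, policy))
    return sorted(out, key=lambda o: o.sort_key)


def longest_orf(orfs: Iterable[Orf]) -> Optional[Orf]:
    """The maximal-length ORF under the canonical order; None if empty.

    Length ties break by frame order (+1, +2, +3, -1, -2, -3), then by 5'
    position within the frame.
    """
    orfs = list(orfs)
    if not orfs:
        return None
    return min(orfs, key=lambda o: o.sort_key)
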
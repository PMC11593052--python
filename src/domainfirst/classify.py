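"""Category assignment, assembly-error detection and funnel accounting.

Every transcript whose six-frame translation carries a target-domain hit is
classified into one of three categories:

1. matched to a known protein — the best homology hit passes the match
   criteria and the candidate ORF carries *all* of the reference protein's
   domains in the same order;
2. assembly error or truncated RNA — a passing hit whose architecture is
   incomplete, explained (when possible) by an exact suffix-prefix overlap
   with a partner transcript, or by the reference domains being split across
   two reading frames of the same transcript;
3. no match — no homology hit passes the criteria.

A target-domain hit must lie inside an ORF for a transcript to be
classified at all; otherwise it is excluded with the reason recorded.  The
funnel report accounts for every input transcript in exactly one terminal
bin, because the published stage counts deliberately do not form a
subtraction chain (categories overlap).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .domainscan import DomainHit
from .homology import Architecture, ArchVerdict, HomologyHit
from .orffinder import Orf
from .seqio import Transcript

__all__ = [
    "TranscriptCall",
    "TranscriptEvidence",
    "FunnelReport",
    "MergeResult",
    "FrameSplit",
    "domain_in_orf",
    "merge_split_transcripts",
    "detect_frame_split",
    "assign_category",
    "dedup_unique_orfs",
    "contamination_filter",
]

CATEGORY_LABELS = {
    1: "matched-known-protein",
    2: "assembly-error-or-truncated",
    3: "no-match",
}


@dataclass(frozen=True)
class MergeResult:
    """An exact suffix-prefix polypeptide overlap between two ORFs."""

    merged_protein: str
    overlap_peptide: str
    first: str  # accession contributing the N-terminal part
    second: str

    @property
    def overlap_length(self) -> int:
        return len(self.overlap_peptide)


@dataclass(frozen=True)
class FrameSplit:
    """Reference domains covered by ORFs in >= 2 frames of one transcript.

    ``assignments`` maps each frame to the contiguous block of reference
    domains it covers; ``missing`` lists reference domains covered by no
    frame (the uncovered gap an internal indel leaves behind).
    """

    assignments: Mapping[int, tuple[str, ...]]
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class TranscriptCall:
    """The classified result for one domain-bearing transcript."""

    accession: str
    category: Optional[int]  # 1/2/3, or None when excluded
    best_match: Optional[str] = None
    architecture_verdict: Optional[ArchVerdict] = None
    domain_in_orf: bool = False
    on_longest_orf: bool = True
    merge_partner: Optional[str] = None
    overlap_peptide: Optional[str] = None
    frame_split: Optional[FrameSplit] = None
    orf_protein: Optional[str] = None  # domain-bearing ORF, dedup key
    reasons: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def category_label(self) -> str:
        if self.category is None:
            return "excluded"
        return CATEGORY_LABELS[self.category]


@dataclass
class TranscriptEvidence:
    """Everything known about one transcript before category assignment."""

    accession: str
    domain_hits: Sequence[DomainHit]
    orfs: Sequence[Orf]
    best_match: Optional[HomologyHit] = None
    architecture_verdict: Optional[ArchVerdict] = None
    on_longest_orf: bool = True
    orf_protein: Optional[str] = None
    merge: Optional[MergeResult] = None
    frame_split: Optional[FrameSplit] = None
    truncated: bool = False


def domain_in_orf(
    hit: DomainHit, orfs: Iterable[Orf]
) -> tuple[bool, Optional[Orf]]:
    """Does the hit's protein interval lie entirely within an ORF?

    Only ORFs on the hit's own transcript and frame count; among multiple
    containing ORFs the longest wins.
    """
    containers = [
        o
        for o in orfs
        if o.id == hit.query
        and o.protein_start <= hit.hit_start
        and hit.hit_end <= o.protein_end
    ]
    if not containers:
        return False, None
    return True, max(containers, key=len)


def _longest_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with suffix(left, k) == prefix(right, k).

    The overlap must be proper (shorter than both fragments): containment of
    one polypeptide in the other is redundancy, not a split-protein junction.
    """
    for k in range(min(len(left), len(right)) - 1, min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def merge_split_transcripts(
    a: Orf, b: Orf, min_overlap: int = 8
) -> Optional[MergeResult]:
    """Merge two ORFs whose polypeptides share an exact suffix-prefix overlap.

    Tries both orderings; the longest exact overlap of at least
    ``min_overlap`` residues wins and is counted once in the merged protein.
    Returns None when no such junction exists.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    k_ab = _longest_overlap(a.protein, b.protein, min_overlap)
    k_ba = _longest_overlap(b.protein, a.protein, min_overlap)
    if k_ab == 0 and k_ba == 0:
        return None
    if k_ab >= k_ba:
        first, second, k = a, b, k_ab
    else:
        first, second, k = b, a, k_ba
    merged = first.protein + second.protein[k:]
    return MergeResult(
        merged_protein=merged,
        overlap_peptide=second.protein[:k],
        first=first.id.accession,
        second=second.id.accession,
    )


def detect_frame_split(
    accession: str,
    hits: Sequence[DomainHit],
    orfs: Sequence[Orf],
    reference: Architecture,
) -> Optional[FrameSplit]:
    """Detect a reference protein split across reading frames of one transcript.

    Returns a split when the reference domains are covered by in-ORF hits in
    at least two distinct frames, each frame covering a contiguous,
    non-overlapping block of the reference order.  Reference domains covered
    by no frame are reported as the gap.
    """
    if not reference:
        raise ValueError("reference architecture must be non-empty")
    my_hits = [h for h in hits if h.query.accession == accession]
    # frame -> set of reference indices covered by an in-ORF hit of that name
    coverage: dict[int, set[int]] = defaultdict(set)
    for h in my_hits:
        inside, _ = domain_in_orf(h, orfs)
        if not inside:
            continue
        for i, name in enumerate(reference):
            if name == h.domain_name:
                coverage[h.query.frame].add(i)
    frames = {f: idx for f, idx in coverage.items() if idx}
    if len(frames) < 2:
        return None
    # each frame must cover a contiguous block, blocks pairwise disjoint
    blocks: dict[int, tuple[int, int]] = {}
    for f, idx in frames.items():
        lo, hi = min(idx), max(idx)
        if idx != set(range(lo, hi + 1)):
            return None
        blocks[f] = (lo, hi)
    spans = sorted(blocks.values())
    for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
        if b_lo <= a_hi:
            return None
    covered = set().union(*frames.values())
    missing = tuple(d for i, d in enumerate(reference) if i not in covered)
    assignments = {
        f: tuple(reference[i] for i in range(lo, hi + 1))
        for f, (lo, hi) in blocks.items()
    }
    return FrameSplit(assignments=assignments, missing=missing)


def assign_category(ev: TranscriptEvidence) -> TranscriptCall:
    """Assign category 1/2/3 to one transcript's evidence bundle.

    The target-domain hit must lie inside an ORF; otherwise the transcript
    is excluded with reason ``hit-outside-orf``.  Category 1 requires a
    passing best hit *and* a full architecture match; a passing hit with an
    incomplete or disjoint architecture is category 2 (with the explaining
    evidence recorded); no passing hit is category 3.
    """
    inside = any(domain_in_orf(h, ev.orfs)[0] for h in ev.domain_hits)
    common = dict(
        accession=ev.accession,
        best_match=ev.best_match.subject if ev.best_match else None,
        architecture_verdict=ev.architecture_verdict,
        domain_in_orf=inside,
        on_longest_orf=ev.on_longest_orf,
        merge_partner=_partner(ev),
        overlap_peptide=ev.merge.overlap_peptide if ev.merge else None,
        frame_split=ev.frame_split,
        orf_protein=ev.orf_protein,
    )
    if not inside:
        return TranscriptCall(category=None, reasons=("hit-outside-orf",), **common)
    if ev.best_match is None:
        return TranscriptCall(category=3, reasons=("no-passing-hit",), **common)
    verdict = ev.architecture_verdict
    if verdict is not None and verdict.is_full:
        warnings = ()
        if ev.merge is not None:
            warnings = ("full-match-despite-merge-partner",)
        return TranscriptCall(
            category=1, reasons=("full-architecture-match",), warnings=warnings,
            **common,
        )
    reasons: list[str] = []
    if verdict is None:
        reasons.append("no-architecture-available")
    elif verdict.verdict == "partial-subsequence":
        reasons.append("architecture-partial")
    else:
        reasons.append("architecture-disjoint")
        reasons.append("review")
    if ev.merge is not None:
        reasons.append("merge-partner")
    if ev.frame_split is not None:
        reasons.append("frame-split")
    if ev.truncated:
        reasons.append("truncated")
    return TranscriptCall(category=2, reasons=tuple(reasons), **common)


def _partner(ev: TranscriptEvidence) -> Optional[str]:
    if ev.merge is None:
        return None
    return ev.merge.second if ev.merge.first == ev.accession else ev.merge.first


def dedup_unique_orfs(
    calls: Sequence[TranscriptCall],
) -> tuple[list[TranscriptCall], dict[str, list[str]]]:
    """Collapse calls whose domain-bearing ORF proteins are identical.

    Calls without an ORF protein are kept as-is.  The representative of each
    group is the lexicographically smallest accession; the duplicate map
    records every member under the representative.
    """
    groups: dict[str, list[TranscriptCall]] = defaultdict(list)
    passthrough: list[TranscriptCall] = []
    for c in calls:
        if c.orf_protein is None:
            passthrough.append(c)
        else:
            groups[c.orf_protein].append(c)
    unique: list[TranscriptCall] = list(passthrough)
    dup_map: dict[str, list[str]] = {}
    for members in groups.values():
        members = sorted(members, key=lambda c: c.accession)
        rep = members[0]
        unique.append(rep)
        dup_map[rep.accession] = [m.accession for m in members]
    unique.sort(key=lambda c: c.accession)
    return unique, dup_map


def contamination_filter(
    records: Sequence[Transcript],
    remove_list: Iterable[str],
    trim_list: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[list[Transcript], dict[str, int]]:
    """Apply a contamination screen: remove listed records, trim others.

    ``trim_list`` maps accession to the retained 1-based inclusive interval.
    A record on both lists is removed (removal dominates).  Returns the
    filtered collection and the screen's counts.
    """
    trim_list = dict(trim_list or {})
    remove = set(remove_list)
    known = {t.accession for t in records}
    for acc in remove | set(trim_list):
        if acc not in known:
            raise KeyError(f"screen references unknown accession {acc!r}")
    for acc, (lo, hi) in trim_list.items():
        if lo < 1 or lo > hi:
            raise ValueError(f"invalid trim interval [{lo},{hi}] for {acc!r}")
    out: list[Transcript] = []
    n_trimmed = 0
    for t in records:
        if t.accession in remove:
            continue
        if t.accession in trim_list:
            lo, hi = trim_list[t.accession]
            if hi > len(t):
                raise ValueError(
                    f"trim interval [{lo},{hi}] exceeds length of {t.accession!r}"
                )
            t = Transcript(t.accession, t.sequence[lo - 1 : hi], t.description)
            n_trimmed += 1
        out.append(t)
    counts = {
        "n_input": len(records),
        "n_removed": len(remove),
        "n_trimmed": n_trimmed,
        "n_output": len(out),
    }
    return out, counts


@dataclass
class FunnelReport:
    """Stage counts of one annotation run, plus per-transcript terminal bins.

    Stage counts can overlap (a transcript can be both a duplicate and
    truncated), so no subtraction identity is asserted between them; the
    ``terminal_bins`` mapping instead places every input transcript in
    exactly one of: no-domain, outside-orf, duplicate, truncated, unique.
    """

    n_input_transcripts: int = 0
    n_translated: int = 0
    n_domain_hit_transcripts: int = 0
    n_duplicates_removed: int = 0
    n_truncated_removed: int = 0
    n_hits_outside_orf: int = 0
    n_unique_orfs: int = 0
    n_unique_merged_collapsed: int = 0  # alternative counting: merge pairs as one
    n_on_non_longest_orf: int = 0
    seed: Optional[int] = None
    terminal_bins: dict[str, str] = field(default_factory=dict)

    def bin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for b in self.terminal_bins.values():
            counts[b] += 1
        return dict(counts)
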
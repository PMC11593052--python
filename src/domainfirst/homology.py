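"""Homology-match criteria and domain-architecture comparison.

Candidate ORFs are matched to reference proteins under three explicit
thresholds — query coverage >= 50%, identity >= 30%, e-value <= 1e-5, all
boundaries inclusive — and a match is only accepted as a full identification
when the candidate carries *all* domains of the reference in the same
N-to-C arrangement.  The aligner itself is external (BLAST tabular input);
a small built-in pairwise search over a reference panel keeps synthetic
runs self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MatchCriteria",
    "HomologyHit",
    "Architecture",
    "ArchVerdict",
    "parse_blast_tab",
    "passes_criteria",
    "best_hit",
    "compare_architecture",
    "naive_homology_search",
]


@dataclass(frozen=True)
class MatchCriteria:
    """The three inclusive thresholds that define an accepted match."""

    min_query_coverage: float = 50.0
    min_identity: float = 30.0
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 <= self.min_query_coverage <= 100):
            raise ValueError("coverage threshold must be a percentage")
        if not (0 <= self.min_identity <= 100):
            raise ValueError("identity threshold must be a percentage")
        if self.max_evalue <= 0:
            raise ValueError("max e-value must be positive")


@dataclass(frozen=True)
class HomologyHit:
    """One alignment of a query ORF against a reference protein."""

    query: str
    subject: str
    percent_identity: float
    query_coverage: float  # percent; nan when not derivable from the input
    evalue: float
    bitscore: float
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0


#: Ordered N-terminal to C-terminal list of domain names (tandem repeats allowed).
Architecture = tuple[str, ...]


@dataclass(frozen=True)
class ArchVerdict:
    """Outcome of comparing a candidate architecture to a reference one."""

    verdict: str  # "full-match" | "partial-subsequence" | "disjoint"
    missing: tuple[str, ...] = ()

    @property
    def is_full(self) -> bool:
        return self.verdict == "full-match"


def parse_blast_tab(
    path: str | Path,
    query_lengths: Optional[Mapping[str, int]] = None,
) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (optional 13th = query coverage).

    Without a coverage column, coverage is computed as
    100 * (query alignment span / query length) using ``query_lengths``;
    if the length is unknown the hit's coverage is NaN and it can never
    pass the criteria.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}: row {lineno} has {len(parts)} columns, "
                    "expected 12 (or 13 with query coverage)"
                )
            (qid, sid, pident, _length, _mm, _go,
             qstart, qend, sstart, send, evalue, bitscore) = parts[:12]
            qstart, qend = int(qstart), int(qend)
            if len(parts) == 13:
                cov = float(parts[12])
            elif query_lengths is not None and qid in query_lengths:
                cov = 100.0 * (abs(qend - qstart) + 1) / query_lengths[qid]
            else:
                cov = float("nan")
            hits.append(
                HomologyHit(
                    query=qid, subject=sid,
                    percent_identity=float(pident), query_coverage=cov,
                    evalue=float(evalue), bitscore=float(bitscore),
                    query_start=qstart, query_end=qend,
                    subject_start=int(sstart), subject_end=int(send),
                )
            )
    return hits


def passes_criteria(h: HomologyHit, c: MatchCriteria = MatchCriteria()) -> bool:
    """True iff coverage, identity and e-value all meet their (inclusive) bounds."""
    return (
        h.query_coverage >= c.min_query_coverage
        and h.percent_identity >= c.min_identity
        and h.evalue <= c.max_evalue
    )


def best_hit(
    hits: Iterable[HomologyHit], c: MatchCriteria = MatchCriteria()
) -> Optional[HomologyHit]:
    """Best passing hit: lowest e-value, then highest bitscore, then identity."""
    passing = [h for h in hits if passes_criteria(h, c)]
    if not passing:
        return None
    return min(
        passing, key=lambda h: (h.evalue, -h.bitscore, -h.percent_identity)
    )


def _embed(candidate: Sequence[str], reference: Sequence[str]) -> Optional[list[int]]:
    """Greedy leftmost embedding of candidate into reference as an ordered
    sublist; returns matched reference indices or None."""
    idx: list[int] = []
    j = 0
    for d in candidate:
        while j < len(reference) and reference[j] != d:
            j += 1
        if j == len(reference):
            return None
        idx.append(j)
        j += 1
    return idx


def compare_architecture(
    candidate: Sequence[str], reference: Sequence[str]
) -> ArchVerdict:
    """Compare two ordered domain lists.

    full-match: identical lists.  partial-subsequence: the candidate is a
    proper ordered sublist (gaps allowed, so an internally truncated
    candidate still registers); missing reference domains are reported in
    order.  disjoint: anything else, including an empty candidate.
    """
    cand, ref = tuple(candidate), tuple(reference)
    if not ref:
        raise ValueError("reference architecture must be non-empty")
    if cand == ref:
        return ArchVerdict("full-match")
    if cand:
        matched = _embed(cand, ref)
        if matched is not None:
            used = set(matched)
            missing = tuple(d for i, d in enumerate(ref) if i not in used)
            return ArchVerdict("partial-subsequence", missing)
    return ArchVerdict("disjoint", tuple(ref))


# --- built-in pairwise search (self-contained stand-in for BLASTp) ---------

# Karlin-Altschul parameters for gapped BLOSUM62 (BLAST defaults).
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _hsp_trim(aln, query: str, ref: str, matrix):
    """Reduce an optimal local alignment to its maximal-scoring contiguous
    segment (an HSP).

    A full optimal local alignment has no X-drop cutoff, so a strong anchor
    can afford long gap bridges to distant chance segments, inflating the
    aligned region far beyond the genuinely homologous block.  Trimming to
    the best contiguous sub-alignment restores HSP-like statistics.

    Returns ``(score, identities, aligned_cols, qstart, qend, sstart,
    send)`` with half-open 0-based coordinates, or ``None`` if no positive
    segment exists.
    """
    qspans, sspans = aln.aligned
    # Flatten the alignment into atomic events: one per aligned column, one
    # per inter-block gap run (affine penalty as a unit).
    events = []  # (score, identities, aligned_cols, q_advance, s_advance)
    prev_qb = prev_sb = None
    for (qa, qb), (sa, sb) in zip(
        ((int(a), int(b)) for a, b in qspans),
        ((int(a), int(b)) for a, b in sspans),
    ):
        if prev_qb is not None:
            gq, gs = qa - prev_qb, sa - prev_sb
            pen = sum(-11.0 - (g - 1) for g in (gq, gs) if g > 0)
            events.append((pen, 0, 0, gq, gs))
        for k in range(qb - qa):
            a, b = query[qa + k], ref[sa + k]
            events.append((float(matrix[a, b]), int(a == b), 1, 1, 1))
        prev_qb, prev_sb = qb, sb
    # Kadane over events, tracking coordinates.
    q0 = int(qspans[0][0])
    s0 = int(sspans[0][0])
    best = None  # (score, ident, cols, qstart, qend, sstart, send)
    run = None
    q, s = q0, s0
    for score, ident, cols, dq, ds in events:
        if run is None or run[0] <= 0:
            run = (score, ident, cols, q, q + dq, s, s + ds)
        else:
            run = (run[0] + score, run[1] + ident, run[2] + cols,
                   run[3], q + dq, run[5], s + ds)
        q += dq
        s += ds
        if run[2] > 0 and (best is None or run[0] > best[0]):
            best = run
    if best is None or best[0] <= 0:
        return None
    return best


def naive_homology_search(
    query: str,
    query_id: str,
    references: Mapping[str, str],
) -> list[HomologyHit]:
    """Local-align a query protein against a small reference panel.

    Uses BLOSUM62 with affine gaps (open 11, extend 1), trims each optimal
    local alignment to its maximal-scoring contiguous segment (see
    :func:`_hsp_trim`), and converts raw scores to bitscores and e-values
    with standard Karlin-Altschul parameters.  Intended for synthetic
    panels of a handful of references, not as a database search engine.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    hits: list[HomologyHit] = []
    for name, ref in references.items():
        alignments = aligner.align(query, ref)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if aln.score <= 0:
            continue
        hsp = _hsp_trim(aln, query, ref, matrix)
        if hsp is None:
            continue
        score, identities, aligned_cols, qstart, qend, sstart, send = hsp
        identity = 100.0 * identities / aligned_cols
        # Coverage counts query residues inside the trimmed segment.
        coverage = 100.0 * (qend - qstart) / len(query)
        bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
        evalue = len(query) * len(ref) * 2.0 ** (-bits)
        hits.append(
            HomologyHit(
                query=query_id, subject=name,
                percent_identity=identity, query_coverage=coverage,
                evalue=evalue, bitscore=bits,
                query_start=qstart + 1, query_end=qend,
                subject_start=sstart + 1, subject_end=send,
            )
        )
    return sorted(hits, key=lambda h: (h.evalue, -h.bitscore))
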
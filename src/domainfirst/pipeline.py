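"""End-to-end annotation runs: the domain-first and classic strategies.

``run_novel`` executes the unbiased, domain-first route: six-frame
translation of every transcript, random batching, conserved-domain
detection, selection of target-domain hits, mapping back to ORFs, homology
matching against a reference panel, category assignment, merge/frame-split
detection, deduplication to unique domain-bearing ORFs and a full funnel
audit.  ``run_classic`` executes the conventional route: the longest ORF
per transcript aligned against each reference protein.  ``venn`` compares
the two call sets.

Domain detection comes either from the built-in scanner (synthetic
profiles) or from a parsed Batch CD-Search table; homology comes either
from the built-in pairwise search against a small panel or from a parsed
BLAST tabular file.  The external engines are never invoked.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

import pandas as pd

from .classify import (
    FunnelReport,
    MergeResult,
    TranscriptCall,
    TranscriptEvidence,
    assign_category,
    dedup_unique_orfs,
    detect_frame_split,
    domain_in_orf,
    merge_split_transcripts,
)
from .domainscan import (
    DomainHit,
    DomainProfile,
    builtin_scan,
    select_target_hits,
    split_batches,
)
from .homology import (
    Architecture,
    HomologyHit,
    MatchCriteria,
    best_hit,
    compare_architecture,
    naive_homology_search,
)
from .orffinder import Orf, OrfPolicy, find_all_orfs, longest_orf
from .seqio import Transcript
from .sixframe import FrameTranslation, six_frame_translate

__all__ = ["RunConfig", "NovelResult", "ClassicResult", "VennResult",
           "run_novel", "run_classic", "venn"]

logger = logging.getLogger(__name__)


class Reference(Protocol):
    """Anything with a name, a protein sequence and a domain architecture."""

    name: str
    protein: str
    architecture: Architecture


@dataclass(frozen=True)
class RunConfig:
    """All tunable settings of one annotation run.

    Defaults reproduce the workflow's stated settings: target domain
    ``SH2``, match criteria >=50% coverage / >=30% identity / e <= 1e-5,
    batch size 4000, ATG-start ORFs of >= 25 residues, merge overlap >= 8
    exact residues.
    """

    target: str = "SH2"
    orf_policy: OrfPolicy = field(default_factory=OrfPolicy)
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    batch_size: int = 4000
    min_merge_overlap: int = 8
    seed: int = 0
    genetic_code: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def write_snapshot(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class NovelResult:
    calls: list[TranscriptCall]          # all classifiable + excluded calls
    unique_calls: list[TranscriptCall]   # after ORF-protein deduplication
    duplicate_map: dict[str, list[str]]
    funnel: FunnelReport
    merged_proteins: dict[str, str]      # rep accession -> merged protein

    @property
    def accessions(self) -> set[str]:
        return {c.accession for c in self.calls if c.category is not None}


@dataclass
class ClassicResult:
    calls: list[TranscriptCall]                    # accepted full matches
    per_reference: dict[str, Optional[TranscriptCall]]

    @property
    def accessions(self) -> set[str]:
        return {c.accession for c in self.calls}


@dataclass(frozen=True)
class VennResult:
    shared: frozenset[str]
    novel_only: frozenset[str]
    classic_only: frozenset[str]


def _translations_by_acc(
    transcripts: Sequence[Transcript], code: int
) -> dict[str, list[FrameTranslation]]:
    return {t.accession: six_frame_translate(t, code) for t in transcripts}


def run_novel(
    transcripts: Sequence[Transcript],
    panel: Sequence[Reference],
    config: RunConfig = RunConfig(),
    profiles: Optional[Sequence[DomainProfile]] = None,
    domain_hits: Optional[Sequence[DomainHit]] = None,
    homology_hits: Optional[Mapping[str, Sequence[HomologyHit]]] = None,
) -> NovelResult:
    """The domain-first annotation route, start to finish.

    Domain evidence comes from ``domain_hits`` (a parsed external table) or
    is computed with ``profiles`` via the built-in scanner — one of the two
    must be provided.  Homology evidence is computed with the built-in
    pairwise search against ``panel`` unless ``homology_hits`` supplies a
    pre-computed mapping from accession to alignment hits.
    """
    if domain_hits is None and profiles is None:
        raise ValueError("provide either domain profiles or parsed domain hits")

    by_acc = _translations_by_acc(transcripts, config.genetic_code)
    n_translated = sum(len(v) for v in by_acc.values())
    logger.info("translated %d transcripts -> %d records",
                len(transcripts), n_translated)

    if domain_hits is None:
        all_translations = [ft for fts in by_acc.values() for ft in fts]
        batches = split_batches(all_translations, config.batch_size, config.seed)
        logger.info("scanning %d batches of <= %d records",
                    len(batches), config.batch_size)
        domain_hits = [
            h for batch in batches for ft in batch
            for h in builtin_scan(ft, profiles)
        ]
    target_hits = select_target_hits(domain_hits, config.target)
    hits_by_acc: dict[str, list[DomainHit]] = defaultdict(list)
    for h in domain_hits:
        hits_by_acc[h.query.accession].append(h)
    target_by_acc: dict[str, list[DomainHit]] = defaultdict(list)
    for h in target_hits:
        target_by_acc[h.query.accession].append(h)
    logger.info("%d target-domain hits on %d transcripts",
                len(target_hits), len(target_by_acc))

    ref_by_name = {r.name: r for r in panel}
    ref_seqs = {r.name: r.protein for r in panel}

    evidences: dict[str, TranscriptEvidence] = {}
    for acc in sorted(target_by_acc):
        orfs = find_all_orfs(by_acc[acc], config.orf_policy)
        ev = TranscriptEvidence(
            accession=acc,
            domain_hits=target_by_acc[acc],
            orfs=orfs,
        )
        containing = [
            domain_in_orf(h, orfs)[1] for h in target_by_acc[acc]
            if domain_in_orf(h, orfs)[0]
        ]
        if containing:
            primary = max(containing, key=len)
            ev.orf_protein = primary.protein
            ev.on_longest_orf = primary == longest_orf(orfs)
            in_orf_hits = sorted(
                (
                    h for h in hits_by_acc[acc]
                    if h.query == primary.id
                    and primary.protein_start <= h.hit_start
                    and h.hit_end <= primary.protein_end
                ),
                key=lambda h: h.hit_start,
            )
            candidate_arch = tuple(h.domain_name for h in in_orf_hits)
            if homology_hits is not None:
                hom = list(homology_hits.get(acc, ()))
            else:
                hom = naive_homology_search(primary.protein, acc, ref_seqs)
            best = best_hit(hom, config.criteria)
            ev.best_match = best
            if best is not None and best.subject in ref_by_name:
                ref = ref_by_name[best.subject]
                ev.architecture_verdict = compare_architecture(
                    candidate_arch, ref.architecture
                )
                ev.frame_split = detect_frame_split(
                    acc, hits_by_acc[acc], orfs, ref.architecture
                )
        evidences[acc] = ev

    _attach_merges(evidences, config.min_merge_overlap)

    calls = [assign_category(ev) for ev in evidences.values()]
    classifiable = [c for c in calls if c.category is not None]
    excluded = [c for c in calls if c.category is None]

    unique_calls, dup_map = dedup_unique_orfs(classifiable)
    merged_proteins = _merged_proteins(evidences, unique_calls)

    funnel = _build_funnel(
        transcripts, n_translated, target_by_acc, excluded,
        classifiable, unique_calls, dup_map, config,
    )
    return NovelResult(
        calls=calls, unique_calls=unique_calls, duplicate_map=dup_map,
        funnel=funnel, merged_proteins=merged_proteins,
    )


def _attach_merges(
    evidences: dict[str, TranscriptEvidence], min_overlap: int
) -> None:
    """Pairwise merge attempts among partial matches to the same reference."""
    by_subject: dict[str, list[str]] = defaultdict(list)
    for acc, ev in evidences.items():
        if (
            ev.best_match is not None
            and ev.architecture_verdict is not None
            and not ev.architecture_verdict.is_full
            and ev.orf_protein is not None
        ):
            by_subject[ev.best_match.subject].append(acc)
    for accs in by_subject.values():
        accs = sorted(accs)
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                ea, eb = evidences[a], evidences[b]
                if ea.merge is not None or eb.merge is not None:
                    continue
                oa = _primary_orf(ea)
                ob = _primary_orf(eb)
                if oa is None or ob is None:
                    continue
                merge = merge_split_transcripts(oa, ob, min_overlap)
                if merge is not None:
                    ea.merge = merge
                    eb.merge = merge
                    ea.truncated = eb.truncated = True


def _primary_orf(ev: TranscriptEvidence) -> Optional[Orf]:
    for o in ev.orfs:
        if o.protein == ev.orf_protein:
            return o
    return None


def _merged_proteins(
    evidences: dict[str, TranscriptEvidence],
    unique_calls: Sequence[TranscriptCall],
) -> dict[str, str]:
    out: dict[str, str] = {}
    for c in unique_calls:
        ev = evidences.get(c.accession)
        if ev is not None and ev.merge is not None:
            rep = min(ev.merge.first, ev.merge.second)
            if c.accession == rep:
                out[rep] = ev.merge.merged_protein
    return out


def _build_funnel(
    transcripts, n_translated, target_by_acc, excluded,
    classifiable, unique_calls, dup_map, config,
) -> FunnelReport:
    bins: dict[str, str] = {}
    for t in transcripts:
        if t.accession not in target_by_acc:
            bins[t.accession] = "no-domain"
    for c in excluded:
        bins[c.accession] = "outside-orf"
    reps = {c.accession for c in unique_calls}
    for c in classifiable:
        if c.accession not in reps:
            bins[c.accession] = "duplicate"
    # merge pairs among representatives: the larger partner counts as the
    # truncated record, the smaller one represents the merged protein
    n_merge_pairs = 0
    for c in unique_calls:
        if c.merge_partner is not None and c.merge_partner in reps:
            if c.accession > c.merge_partner:
                bins[c.accession] = "truncated"
                n_merge_pairs += 1
            else:
                bins[c.accession] = "unique"
        else:
            bins[c.accession] = "unique"
    n_dup_removed = sum(len(m) - 1 for m in dup_map.values())
    report = FunnelReport(
        n_input_transcripts=len(transcripts),
        n_translated=n_translated,
        n_domain_hit_transcripts=len(target_by_acc),
        n_duplicates_removed=n_dup_removed,
        n_truncated_removed=n_merge_pairs,
        n_hits_outside_orf=len(excluded),
        n_unique_orfs=len(unique_calls),
        n_unique_merged_collapsed=len(unique_calls) - n_merge_pairs,
        n_on_non_longest_orf=sum(
            1 for c in unique_calls if not c.on_longest_orf
        ),
        seed=config.seed,
        terminal_bins=bins,
    )
    return report


def run_classic(
    transcripts: Sequence[Transcript],
    panel: Sequence[Reference],
    config: RunConfig = RunConfig(),
    profiles: Optional[Sequence[DomainProfile]] = None,
) -> ClassicResult:
    """The classic annotation route: longest ORF per transcript vs targets.

    For each reference protein, the best transcript under the match criteria
    (coverage measured on the reference, as in a translated search with the
    reference as query) is kept only when the longest ORF carries all of the
    reference's domains in the same arrangement.  ``profiles`` (needed for
    the architecture check) default to nothing — without them, architecture
    is not verified and any passing hit is accepted.
    """
    if not panel:
        raise ValueError("target panel must be non-empty")
    by_acc = _translations_by_acc(transcripts, config.genetic_code)
    longest: dict[str, Orf] = {}
    for acc, fts in by_acc.items():
        lo = longest_orf(find_all_orfs(fts, config.orf_policy))
        if lo is not None:
            longest[acc] = lo

    per_reference: dict[str, Optional[TranscriptCall]] = {}
    calls: list[TranscriptCall] = []
    orf_prots = {acc: o.protein for acc, o in longest.items()}
    for ref in panel:
        hom = naive_homology_search(ref.protein, ref.name, orf_prots)
        best = best_hit(hom, config.criteria)
        if best is None:
            per_reference[ref.name] = None
            continue
        acc = best.subject  # subjects are transcript ORFs in this direction
        orf = longest[acc]
        if profiles is not None:
            ft = next(f for f in by_acc[acc] if f.id == orf.id)
            in_orf = sorted(
                (
                    h for h in builtin_scan(ft, profiles)
                    if orf.protein_start <= h.hit_start
                    and h.hit_end <= orf.protein_end
                ),
                key=lambda h: h.hit_start,
            )
            verdict = compare_architecture(
                tuple(h.domain_name for h in in_orf), ref.architecture
            )
        else:
            verdict = None
        call = TranscriptCall(
            accession=acc,
            category=1 if (verdict is None or verdict.is_full) else 2,
            best_match=ref.name,
            architecture_verdict=verdict,
            domain_in_orf=True,
            orf_protein=orf.protein,
            reasons=("classic-longest-orf",),
        )
        per_reference[ref.name] = call
        if call.category == 1:
            calls.append(call)
    return ClassicResult(calls=calls, per_reference=per_reference)


def venn(
    novel: Iterable[str] | NovelResult,
    classic: Iterable[str] | ClassicResult,
) -> VennResult:
    """Disjoint partition of the two call sets: shared / novel-only / classic-only."""
    n = novel.accessions if isinstance(novel, NovelResult) else set(novel)
    c = classic.accessions if isinstance(classic, ClassicResult) else set(classic)
    return VennResult(
        shared=frozenset(n & c),
        novel_only=frozenset(n - c),
        classic_only=frozenset(c - n),
    )


def calls_to_frame(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    """Flatten calls into the TSV-ready report table."""
    rows = []
    for c in calls:
        rows.append({
            "accession": c.accession,
            "category": c.category if c.category is not None else "",
            "category_label": c.category_label,
            "best_match": c.best_match or "",
            "architecture": (
                c.architecture_verdict.verdict if c.architecture_verdict else ""
            ),
            "missing_domains": (
                ";".join(c.architecture_verdict.missing)
                if c.architecture_verdict else ""
            ),
            "domain_in_orf": c.domain_in_orf,
            "on_longest_orf": c.on_longest_orf,
            "merge_partner": c.merge_partner or "",
            "overlap_peptide": c.overlap_peptide or "",
            "frame_split": (
                ";".join(
                    f"{f:+d}:{'|'.join(doms)}"
                    for f, doms in sorted(c.frame_split.assignments.items())
                )
                if c.frame_split else ""
            ),
            "reasons": ";".join(c.reasons),
            "warnings": ";".join(c.warnings),
        })
    return pd.DataFrame(rows)


def funnel_to_frame(report: FunnelReport) -> pd.DataFrame:
    d = dataclasses.asdict(report)
    d.pop("terminal_bins")
    rows = [{"stage": k, "count": v} for k, v in d.items() if v is not None]
    for b, n in sorted(report.bin_counts().items()):
        rows.append({"stage": f"bin:{b}", "count": n})
    return pd.DataFrame(rows)
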
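"""Category assignment, overlap merging, frame-split detection and dedup."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from domainfirst.classify import (
    FunnelReport,
    MergeResult,
    TranscriptCall,
    TranscriptEvidence,
    assign_category,
    contamination_filter,
    dedup_unique_orfs,
    detect_frame_split,
    domain_in_orf,
    merge_split_transcripts,
)
from domainfirst.domainscan import DomainHit
from domainfirst.homology import ArchVerdict, HomologyHit
from domainfirst.orffinder import Orf
from domainfirst.seqio import FramedId, Transcript

AA = "ACDEFGHIKLNPQRSTVWY"


def _orf(protein, acc="t", frame=1, start=1):
    end = start + len(protein) - 1
    return Orf(FramedId(acc, frame), start, end,
               3 * (start - 1) + abs(frame), 3 * end + abs(frame) - 1,
               protein, True)


def _hit(name="SH2", acc="t", frame=1, start=10, end=105):
    return DomainHit(FramedId(acc, frame), name, start, end, 1e-10, 100.0)


def _hom(subject="REF", cov=90.0, ident=95.0, ev=1e-20):
    return HomologyHit("q", subject, ident, cov, ev, 150.0)


class TestDomainInOrf:
    def test_contained_hit_found(self):
        orf = _orf("M" + "K" * 316)
        ok, container = domain_in_orf(_hit(start=10, end=105), [orf])
        assert ok and container is orf

    def test_no_orf_on_frame(self):
        orf = _orf("M" + "K" * 316, frame=2)
        ok, container = domain_in_orf(_hit(start=10, end=105, frame=1), [orf])
        assert not ok and container is None

    def test_straddling_hit_excluded(self):
        orf = _orf("M" + "K" * 316)  # spans 1..317
        ok, _ = domain_in_orf(_hit(start=300, end=330), [orf])
        assert not ok

    def test_longest_container_wins(self):
        short = _orf("M" + "K" * 119)
        long = _orf("M" + "K" * 316)
        _, got = domain_in_orf(_hit(start=10, end=105), [short, long])
        assert got is long


class TestMergeSplitTranscripts:
    def test_published_junction_merges_with_overlap_12(self):
        junction = "HERKMRIAKEFS"
        a = _orf("M" + "A" * 50 + junction, acc="x")
        b = _orf(junction + "G" * 60, acc="y")
        m = merge_split_transcripts(a, b)
        assert m is not None
        assert m.overlap_peptide == junction
        assert m.overlap_length == 12
        assert m.merged_protein == "M" + "A" * 50 + junction + "G" * 60

    def test_ordering_is_detected_automatically(self):
        junction = "HERKMRIAKEFS"
        a = _orf("M" + "A" * 50 + junction, acc="x")
        b = _orf(junction + "G" * 60, acc="y")
        assert merge_split_transcripts(b, a).merged_protein == \
            merge_split_transcripts(a, b).merged_protein

    def test_unrelated_proteins_do_not_merge(self):
        a = _orf("M" + "A" * 40, acc="x")
        b = _orf("M" + "G" * 40, acc="y")
        assert merge_split_transcripts(a, b) is None

    def test_short_overlap_below_minimum_rejected(self):
        a = _orf("M" + "A" * 40 + "HERK", acc="x")
        b = _orf("HERK" + "G" * 40, acc="y")
        assert merge_split_transcripts(a, b, min_overlap=8) is None
        assert merge_split_transcripts(a, b, min_overlap=4) is not None

    def test_containment_is_not_a_junction(self):
        whole = "M" + "".join(random.Random(1).choice(AA) for _ in range(80))
        prefix = whole[:40]
        assert merge_split_transcripts(_orf(prefix, acc="x"),
                                       _orf(whole, acc="y")) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(8, 20))
    def test_fragment_and_reassemble_oracle(self, seed, k):
        rng = random.Random(seed)
        protein = "M" + "".join(rng.choice(AA) for _ in range(rng.randint(60, 150)))
        cut = rng.randint(k + 1, len(protein) - k - 1)
        part1, part2 = protein[: cut + k], protein[cut:]
        m = merge_split_transcripts(_orf(part1, acc="a"), _orf(part2, acc="b"),
                                    min_overlap=8)
        assert m is not None
        assert m.merged_protein == protein
        assert m.overlap_length >= k  # a longer coincidental overlap is allowed


class TestDetectFrameSplit:
    REF = ("SAM", "PHA02682", "SH2")

    def test_two_frame_coverage_detected(self):
        orf_a = _orf("M" + "K" * 200, acc="t", frame=-3)
        orf_b = _orf("M" + "K" * 300, acc="t", frame=-1)
        hits = [
            _hit("SAM", frame=-3, start=5, end=70),
            _hit("PHA02682", frame=-1, start=5, end=84),
            _hit("SH2", frame=-1, start=100, end=199),
        ]
        fs = detect_frame_split("t", hits, [orf_a, orf_b], self.REF)
        assert fs is not None
        assert fs.assignments == {-3: ("SAM",), -1: ("PHA02682", "SH2")}
        assert fs.missing == ()

    def test_single_frame_is_not_a_split(self):
        orf = _orf("M" + "K" * 400, acc="t", frame=-1)
        hits = [
            _hit("SAM", frame=-1, start=5, end=70),
            _hit("PHA02682", frame=-1, start=80, end=159),
            _hit("SH2", frame=-1, start=170, end=269),
        ]
        assert detect_frame_split("t", hits, [orf], self.REF) is None

    def test_uncovered_reference_gap_reported(self):
        orf_a = _orf("M" + "K" * 100, acc="t", frame=-3)
        orf_b = _orf("M" + "K" * 300, acc="t", frame=-1)
        hits = [
            _hit("SAM", frame=-3, start=5, end=70),
            _hit("SH2", frame=-1, start=100, end=199),
        ]
        fs = detect_frame_split("t", hits, [orf_a, orf_b], self.REF)
        assert fs.missing == ("PHA02682",)

    def test_hits_outside_orfs_do_not_count(self):
        orf_b = _orf("M" + "K" * 300, acc="t", frame=-1)
        hits = [
            _hit("SAM", frame=-3, start=5, end=70),  # no ORF on -3
            _hit("SH2", frame=-1, start=100, end=199),
        ]
        assert detect_frame_split("t", hits, [orf_b], self.REF) is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            detect_frame_split("t", [], [], ())


def _evidence(acc="t", **kw):
    orf = _orf("M" + "K" * 316, acc=acc)
    defaults = dict(
        accession=acc,
        domain_hits=[_hit(acc=acc)],
        orfs=[orf],
        orf_protein=orf.protein,
    )
    defaults.update(kw)
    return TranscriptEvidence(**defaults)


class TestAssignCategory:
    def test_full_match_is_category_1(self):
        call = assign_category(_evidence(
            best_match=_hom("AAS01045.1"),
            architecture_verdict=ArchVerdict("full-match"),
        ))
        assert call.category == 1
        assert call.best_match == "AAS01045.1"

    def test_partial_with_merge_partner_is_category_2(self):
        merge = MergeResult("MAAA", "AA", "t", "u")
        call = assign_category(_evidence(
            best_match=_hom(),
            architecture_verdict=ArchVerdict("partial-subsequence", ("C2",)),
            merge=merge,
        ))
        assert call.category == 2
        assert call.merge_partner == "u"
        assert "merge-partner" in call.reasons

    def test_no_passing_hit_is_category_3(self):
        call = assign_category(_evidence(best_match=None))
        assert call.category == 3
        assert call.best_match is None

    def test_hit_outside_orf_excluded_with_reason(self):
        ev = _evidence(orfs=[], orf_protein=None)
        call = assign_category(ev)
        assert call.category is None
        assert call.reasons == ("hit-outside-orf",)
        assert call.category_label == "excluded"

    def test_disjoint_architecture_flagged_for_review(self):
        call = assign_category(_evidence(
            best_match=_hom(),
            architecture_verdict=ArchVerdict("disjoint", ("Kinase",)),
        ))
        assert call.category == 2
        assert "review" in call.reasons

    def test_conflicting_evidence_keeps_category_1_with_warning(self):
        merge = MergeResult("MAAA", "AA", "t", "u")
        call = assign_category(_evidence(
            best_match=_hom(),
            architecture_verdict=ArchVerdict("full-match"),
            merge=merge,
        ))
        assert call.category == 1
        assert call.warnings == ("full-match-despite-merge-partner",)


def _call(acc, protein):
    return TranscriptCall(accession=acc, category=1, orf_protein=protein)


class TestDedup:
    def test_identical_proteins_collapse(self):
        unique, dmap = dedup_unique_orfs([_call("b", "MKK"), _call("a", "MKK")])
        assert [c.accession for c in unique] == ["a"]
        assert dmap == {"a": ["a", "b"]}

    def test_single_residue_difference_kept_apart(self):
        unique, _ = dedup_unique_orfs([_call("a", "MKK"), _call("b", "MKR")])
        assert len(unique) == 2

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_n_copies_collapse_to_one(self, n):
        calls = [_call(f"t{i}", "MWWK") for i in range(n)]
        unique, dmap = dedup_unique_orfs(calls)
        assert len(unique) == 1
        assert len(dmap["t0"]) == n

    def test_dedup_never_increases_count(self):
        calls = [_call(f"t{i}", "MK" * (i % 3 + 1)) for i in range(9)]
        unique, _ = dedup_unique_orfs(calls)
        assert len(unique) <= len(calls)


class TestContaminationFilter:
    def _records(self, n, length=30):
        return [Transcript(f"t{i}", "ACGT" * (length // 4)) for i in range(n)]

    def test_remove_and_trim_counts(self):
        recs = self._records(10)
        out, counts = contamination_filter(
            recs, ["t0", "t1"], {"t2": (1, 8)}
        )
        assert counts == {"n_input": 10, "n_removed": 2, "n_trimmed": 1,
                          "n_output": 8}
        assert len(out) == 8
        trimmed = next(t for t in out if t.accession == "t2")
        assert trimmed.sequence == "ACGTACGT"

    def test_empty_lists_are_identity(self):
        recs = self._records(4)
        out, counts = contamination_filter(recs, [], {})
        assert [t.sequence for t in out] == [t.sequence for t in recs]
        assert counts["n_output"] == 4

    def test_removal_dominates_trimming(self):
        recs = self._records(3)
        out, _ = contamination_filter(recs, ["t1"], {"t1": (1, 4)})
        assert [t.accession for t in out] == ["t0", "t2"]

    def test_unknown_accession_rejected(self):
        with pytest.raises(KeyError):
            contamination_filter(self._records(2), ["nope"], {})
        with pytest.raises(KeyError):
            contamination_filter(self._records(2), [], {"nope": (1, 2)})

    def test_invalid_trim_interval_rejected(self):
        with pytest.raises(ValueError):
            contamination_filter(self._records(2), [], {"t0": (5, 2)})
        with pytest.raises(ValueError):
            contamination_filter(self._records(2), [], {"t0": (1, 999)})
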
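"""Proteome batching, CD-Search table parsing, and the built-in scanner."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from domainfirst.domainscan import (
    AMINO_ACIDS,
    DomainHit,
    DomainProfile,
    builtin_scan,
    parse_cdd_hits,
    select_target_hits,
    split_batches,
)
from domainfirst.seqio import FramedId
from domainfirst.sixframe import FrameTranslation


def _ft(protein: str, acc: str = "t", frame: int = 1):
    return FrameTranslation(FramedId(acc, frame),
                            protein, 3 * len(protein) + abs(frame) - 1)


def _records(n):
    return [_ft("KLMNP", acc=f"t{i}") for i in range(n)]


class TestSplitBatches:
    def test_exact_fit_is_one_batch(self):
        assert len(split_batches(_records(40), 40)) == 1

    def test_one_over_spills_into_second_batch(self):
        sizes = sorted(len(b) for b in split_batches(_records(41), 40))
        assert sizes == [1, 40]

    def test_invalid_batch_size_rejected(self):
        with pytest.raises(ValueError):
            split_batches(_records(3), 0)

    def test_same_seed_reproduces_partition(self):
        recs = _records(100)
        a = split_batches(recs, 7, seed=3)
        b = split_batches(recs, 7, seed=3)
        assert [[r.id for r in batch] for batch in a] == \
               [[r.id for r in batch] for batch in b]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(1, 50), st.integers(0, 5))
    def test_partition_property(self, n, size, seed):
        recs = _records(n)
        batches = split_batches(recs, size, seed)
        assert all(len(b) <= size for b in batches)
        got = sorted(str(r.id) for b in batches for r in b)
        assert got == sorted(str(r.id) for r in recs)


CDD_TABLE = """\
#Batch CD-search tool\tNIH/NLM/NCBI
#Start time\t2024-01-01T00:00:00
Query\tHit type\tPSSM-ID\tFrom\tTo\tE-Value\tBitscore\tAccession\tShort name\tIncomplete\tSuperfamily
Q#1 - >TSAX02085024.1_+2\tspecific\t214570\t10\t105\t1.2e-30\t115.3\tcd09941\tSH2\t-\tcl15255
Q#2 - >TSAX02003111.1_-1\tsuperfamily\t295229\t50\t140\t3e-10\t60.1\tcl15255\tSH2 superfamily\t-\t-
Q#3 - >badquery\tspecific\t1\t1\t5\t0.1\t10\tx\tWW\t-\t-
TSAX02029025.1_+2\tspecific\t214569\t20\t115\t2e-40\t140\tcd10365\tSH2\t-\tcl15255
"""


class TestParseCddHits:
    def test_parses_rows_and_framed_queries(self, tmp_path):
        p = tmp_path / "hits.txt"
        p.write_text(CDD_TABLE)
        unparsed: list[str] = []
        hits = parse_cdd_hits(p, unparsed=unparsed)
        assert len(hits) == 3
        h = hits[0]
        assert h.query == FramedId("TSAX02085024.1", 2)
        assert (h.domain_name, h.hit_start, h.hit_end) == ("SH2", 10, 105)
        assert h.source == "cdd-batch" and h.hit_type == "specific"
        # bare (non Q#) queries parse too
        assert hits[2].query == FramedId("TSAX02029025.1", 2)
        # bad rows are reported, not silently dropped
        assert unparsed == ["Q#3 - >badquery"]

    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("#only\n#comments\n")
        assert parse_cdd_hits(p) == []

    def test_missing_mandatory_column_named_in_error(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Query\tHit type\tFrom\tTo\tE-Value\tShort name\nx_+1\ts\t1\t2\t0\tSH2\n")
        with pytest.raises(ValueError, match="Bitscore"):
            parse_cdd_hits(p)


def brute_force_scan(protein, profile):
    """Independent oracle: score every window with explicit loops."""
    w = profile.width
    hits = []
    for i in range(len(protein) - w + 1):
        window = protein[i:i + w]
        if any(c not in AMINO_ACIDS for c in window):
            continue
        if profile.motif is not None:
            score = 0
            for a, b in zip(window, profile.motif):
                if a == b:
                    score += 1
            ok = score >= len(profile.motif) - profile.max_mismatches
        else:
            score = 0.0
            for col, c in zip(profile.pwm, window):
                score += col[c]
            ok = score >= profile.threshold
        if ok:
            hits.append((i + 1, i + w, float(score)))
    return hits


protein_st = st.text(alphabet=AMINO_ACIDS + "X*", min_size=1, max_size=200)


class TestBuiltinScan:
    def test_planted_exact_motif_yields_one_spanning_hit(self):
        motif = "WEDCHKNQRSTV"
        prof = DomainProfile("D1", motif=motif)
        (hit,) = builtin_scan(_ft("AAAA" + motif + "GGG"), [prof])
        assert (hit.hit_start, hit.hit_end) == (5, 4 + len(motif))
        assert hit.source == "builtin"

    def test_all_x_protein_yields_nothing(self):
        prof = DomainProfile("D1", motif="AC")
        assert builtin_scan(_ft("X" * 30), [prof]) == []

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            builtin_scan(_ft("ACDEF"), [])

    def test_pwm_profile_threshold(self):
        cols = [
            {a: (2.0 if a == want else -1.0) for a in AMINO_ACIDS}
            for want in "CHW"
        ]
        prof = DomainProfile("P", pwm=cols, threshold=5.0)
        hits = builtin_scan(_ft("AACHWAA"), [prof])
        assert [(h.hit_start, h.hit_end) for h in hits] == [(3, 5)]

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            DomainProfile("bad", motif="AC", pwm=[{a: 0.0 for a in AMINO_ACIDS}])
        with pytest.raises(ValueError):
            DomainProfile("bad", pwm=[{"A": 1.0}])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(protein_st, st.integers(0, 10_000))
    def test_equals_brute_force_oracle(self, protein, seed):
        rng = random.Random(seed)
        w = rng.randint(1, 8)
        motif = "".join(rng.choice(AMINO_ACIDS) for _ in range(w))
        prof = DomainProfile("M", motif=motif, max_mismatches=rng.randint(0, 2))
        got = [(h.hit_start, h.hit_end, h.bitscore)
               for h in builtin_scan(_ft(protein), [prof])]
        assert got == brute_force_scan(protein, prof)


def _hit(name, acc="t"):
    return DomainHit(FramedId(acc, 1), name, 1, 10, 1e-6, 50.0)


class TestSelectTargetHits:
    def test_selects_matching_short_names(self):
        hits = [_hit("SH2"), _hit("WW"), _hit("SAM")]
        assert [h.domain_name for h in select_target_hits(hits, "SH2")] == ["SH2"]

    def test_superfamily_hits_retained_by_substring(self):
        hits = [_hit("SH2 superfamily"), _hit("sh2"), _hit("SH3")]
        got = {h.domain_name for h in select_target_hits(hits, "SH2")}
        assert got == {"SH2 superfamily", "sh2"}

    def test_empty_inputs(self):
        assert select_target_hits([], "SH2") == []
        with pytest.raises(ValueError):
            select_target_hits([_hit("SH2")], "")

    def test_idempotent_and_monotone(self):
        hits = [_hit(n) for n in ("SH2", "SH2 superfamily", "WW", "C2")]
        once = select_target_hits(hits, "SH2")
        assert select_target_hits(once, "SH2") == once
        subset = select_target_hits(hits[:2], "SH2")
        assert set(h.domain_name for h in subset) <= set(
            h.domain_name for h in once
        )
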
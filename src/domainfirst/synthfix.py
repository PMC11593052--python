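"""Seeded synthetic transcriptomes with planted ground truth.

Every pipeline stage is testable without downloads: this module emits
nucleotide transcripts with domain-encoding ORFs embedded in chosen reading
frames on either strand, together with a ground-truth table stating what was
planted where and which category the classifier should assign.

The planted "domains" are fixed consensus peptides (generated once from a
module-level seed, deliberately methionine-free so ORF starts stay where
they are planted) paired with exact-motif :class:`~domainfirst.domainscan.
DomainProfile` detectors, which removes any aligner dependence from the
detection step.  Background composition is uniform over {A,C,G,T}; no
attempt is made to model real codon usage, UTR structure or expression —
the pipeline is composition-agnostic.

Supported planted error types mirror the assembly pathologies the category
system describes: a protein split across two transcripts with an exact
suffix-prefix overlap, a single-nucleotide deletion splitting one protein
across two frames of one transcript, a truncation at a domain boundary, an
exact duplicate transcript, and a domain signal outside any ORF.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .domainscan import DomainProfile
from .homology import Architecture
from .seqio import Transcript

__all__ = [
    "DOMAIN_CONSENSUS",
    "default_profiles",
    "ReferenceProtein",
    "plant_reference_panel",
    "Plant",
    "PlantSpec",
    "GroundTruth",
    "generate",
]

# Synonymous codons per residue (standard code, stops excluded).  Reverse
# translation samples uniformly among them so off-frame and reverse-strand
# readings of a coding cassette carry the natural stop density, keeping
# spurious ORFs short.
_SYN_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

_NO_MET = "ACDEFGHIKLNPQRSTVWY"  # 19 residues, no M

_DOMAIN_LENGTHS = {
    "SH2": 100, "SH3": 58, "Kinase": 250, "PH": 105,
    "PI-PLC": 145, "C2": 95, "SAM": 68, "WW": 38, "PHA02682": 80,
}


def _make_consensus() -> dict[str, str]:
    rng = random.Random(20241118)
    return {
        name: "".join(rng.choice(_NO_MET) for _ in range(n))
        for name, n in _DOMAIN_LENGTHS.items()
    }


#: Fixed consensus peptide per synthetic domain model (methionine-free).
DOMAIN_CONSENSUS: dict[str, str] = _make_consensus()


def default_profiles() -> list[DomainProfile]:
    """Exact-motif detectors for every synthetic domain model."""
    return [DomainProfile(name=n, motif=p) for n, p in DOMAIN_CONSENSUS.items()]


@dataclass(frozen=True)
class ReferenceProtein:
    """A synthetic reference protein with a known domain architecture."""

    name: str
    architecture: Architecture
    protein: str  # starts with M; domains joined by linkers

    def domain_intervals(self) -> list[tuple[str, int, int]]:
        """1-based (name, start, end) of each domain within the protein."""
        out = []
        pos = 0
        for d in self.architecture:
            pep = DOMAIN_CONSENSUS[d]
            i = self.protein.index(pep, pos)
            out.append((d, i + 1, i + len(pep)))
            pos = i + len(pep)
        return out


def _linker(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NO_MET) for _ in range(n))


def _build_protein(arch: Sequence[str], rng: random.Random,
                   extra_cterm: int = 0) -> str:
    parts = ["M", _linker(rng, rng.randint(5, 10))]
    for d in arch:
        parts.append(DOMAIN_CONSENSUS[d])
        parts.append(_linker(rng, rng.randint(6, 12)))
    if extra_cterm:
        parts.append(_linker(rng, extra_cterm))
    return "".join(parts)


_PANEL_ARCHS: list[tuple[str, tuple[str, ...]]] = [
    ("SFK-like", ("SH3", "SH2", "Kinase")),
    ("PLCG-like", ("PH", "SH2", "SH2", "SH3", "PI-PLC", "C2")),
    ("ADAPTOR-like", ("SH2",)),
    ("WW-ADAPTOR-like", ("WW", "SH2")),
    ("BLNK-like", ("SAM", "PHA02682", "SH2")),
]


def plant_reference_panel(n: int = 5) -> list[ReferenceProtein]:
    """A small panel of reference proteins with mutually distinct architectures.

    A scaled-down stand-in for a curated target list (kinase-like,
    phospholipase-like, adaptor-like, ...).  ``n`` must be between 1 and the
    number of built-in architectures; the panel is deterministic.
    """
    if n < 1:
        raise ValueError("reference panel must be non-empty")
    if n > len(_PANEL_ARCHS):
        raise ValueError(f"at most {len(_PANEL_ARCHS)} distinct references available")
    rng = random.Random(7)
    return [
        ReferenceProtein(name, arch, _build_protein(arch, rng))
        for name, arch in _PANEL_ARCHS[:n]
    ]


@dataclass(frozen=True)
class Plant:
    """One planted feature: a reference protein embedded in a transcript.

    ``frame`` is the reading frame the intact coding cassette lands on
    (+1..+3 forward strand, -1..-3 reverse).  ``error`` selects an assembly
    pathology: None (intact, category 1), "split" (two transcripts sharing
    an exact ``overlap``-residue junction, category 2), "frameshift" (a
    single-nucleotide deletion splitting the protein across two frames of
    one transcript, category 2), "truncate" (only the first
    ``keep_domains`` domains planted, category 2), "duplicate" (a second
    transcript with the identical ORF), "novel" (the architecture is
    planted inside a long unique protein so no reference passes the match
    criteria, category 3), "outside-orf" (domain codons planted with no
    start codon, so the hit lies in no ORF and the transcript is excluded).
    """

    reference: str
    frame: int = 1
    error: Optional[str] = None
    overlap: int = 12
    split_after_domain: int = 1  # split/frameshift: domains kept in part 1
    keep_domains: int = 1  # truncate: leading domains kept
    # novel: unique C-terminal residues.  A local alignment anchored on the
    # shared domain can extend into random padding at net-positive score,
    # but the aligned region is bounded by the subject's length (largest
    # panel reference ~810 aa).  Padding of 3000 caps attainable query
    # coverage near 35%, keeping the category-3 coverage failure structural
    # rather than marginal.
    novel_padding: int = 3000


@dataclass(frozen=True)
class PlantSpec:
    """Full recipe for one synthetic transcriptome."""

    n_background: int = 20
    length_range: tuple[int, int] = (300, 900)
    plants: tuple[Plant, ...] = ()
    n_contaminants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        valid = {None, "split", "frameshift", "truncate", "duplicate",
                 "novel", "outside-orf"}
        for p in self.plants:
            if p.error not in valid:
                raise ValueError(f"unknown error operation {p.error!r}")
            if p.frame not in (1, 2, 3, -1, -2, -3):
                raise ValueError(f"invalid frame {p.frame}")


@dataclass
class GroundTruth:
    """Generator output: transcripts, per-feature truth, contaminant list."""

    transcripts: list[Transcript]
    truth: pd.DataFrame
    contaminants: list[str]
    panel: list[ReferenceProtein]


def _revtrans(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_SYN_CODONS[a]) for a in protein)


_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _embed(cassette: str, frame: int, rng: random.Random,
           min_flank: int = 15) -> tuple[str, int]:
    """Place a cassette so it starts in the requested frame.

    Returns (transcript sequence, 0-based cassette start on the *sense*
    strand).  For reverse frames the sense construct is built in frame
    ``|frame|`` and the transcript is its reverse complement.
    """
    k = abs(frame)
    pre = min_flank + rng.randint(0, 30)
    pre += (k - 1 - pre) % 3  # pre % 3 == k - 1
    sense = _random_nt(rng, pre) + cassette + _random_nt(rng, min_flank + rng.randint(0, 30))
    if frame < 0:
        return _rc(sense), pre
    return sense, pre


class _Generator:
    def __init__(self, spec: PlantSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.panel = {r.name: r for r in plant_reference_panel()}
        self.transcripts: list[Transcript] = []
        self.rows: list[dict] = []
        self._n = 0

    def _acc(self) -> str:
        self._n += 1
        return f"SYN{self._n:07d}.1"

    def _add(self, seq: str, **row) -> str:
        acc = self._acc()
        self.transcripts.append(Transcript(acc, seq))
        if row:
            self.rows.append({"accession": acc, **row})
        return acc

    # -- plant builders -----------------------------------------------------

    def _cassette(self, protein: str) -> str:
        # in-frame stop fences the ORF segment on both sides
        return "TAA" + _revtrans(protein, self.rng) + "TAA"

    def plant(self, p: Plant) -> None:
        ref = self.panel.get(p.reference)
        if ref is None:
            raise ValueError(f"unknown reference {p.reference!r}")
        handler = {
            None: self._plant_intact,
            "duplicate": self._plant_duplicate,
            "truncate": self._plant_truncate,
            "split": self._plant_split,
            "frameshift": self._plant_frameshift,
            "novel": self._plant_novel,
            "outside-orf": self._plant_outside_orf,
        }[p.error]
        handler(p, ref)

    def _plant_intact(self, p: Plant, ref: ReferenceProtein) -> None:
        seq, _ = _embed(self._cassette(ref.protein), p.frame, self.rng)
        if len(ref.protein) * 3 + 6 > len(seq):
            raise ValueError(f"protein {ref.name} longer than its transcript")
        self._add(
            seq, reference=ref.name, frame=p.frame, error="",
            expected_category=1, orf_protein=ref.protein,
            partner="", overlap_peptide="",
        )

    def _plant_duplicate(self, p: Plant, ref: ReferenceProtein) -> None:
        cassette = self._cassette(ref.protein)
        accs = []
        for _ in range(2):
            seq, _ = _embed(cassette, p.frame, self.rng)
            accs.append(
                self._add(seq, reference=ref.name, frame=p.frame,
                          error="duplicate", expected_category=1,
                          orf_protein=ref.protein, partner="",
                          overlap_peptide="")
            )
        # record the pairing on both rows
        self.rows[-1]["partner"] = accs[0]
        self.rows[-2]["partner"] = accs[1]

    def _plant_truncate(self, p: Plant, ref: ReferenceProtein) -> None:
        kept = ref.architecture[: p.keep_domains]
        if not kept:
            raise ValueError("truncate must keep at least one domain")
        _, _, end = ref.domain_intervals()[p.keep_domains - 1]
        protein = ref.protein[:end]
        seq, _ = _embed(self._cassette(protein), p.frame, self.rng)
        self._add(
            seq, reference=ref.name, frame=p.frame, error="truncate",
            expected_category=2, orf_protein=protein, partner="",
            overlap_peptide="",
        )

    def _plant_split(self, p: Plant, ref: ReferenceProtein) -> None:
        # Engineer the protein so the overlap region starts with M: the
        # second fragment's ORF then begins exactly at the junction.
        ivals = ref.domain_intervals()
        if not (1 <= p.split_after_domain < len(ref.architecture)):
            raise ValueError("split point must leave domains on both sides")
        cut_lo = ivals[p.split_after_domain - 1][2]  # end of last kept domain
        cut_hi = ivals[p.split_after_domain][1] - 1  # before next domain
        if cut_hi <= cut_lo:
            raise ValueError("no linker between the split domains")
        if p.overlap < 1:
            raise ValueError("overlap must be >= 1 residue")
        junction_start = cut_lo + 1  # 1-based position of overlap start
        protein = (
            ref.protein[: junction_start - 1]
            + "M"
            + ref.protein[junction_start:]
        )
        split_at = junction_start - 1 + p.overlap  # part1 = protein[:split_at]
        part1 = protein[:split_at]
        part2 = protein[junction_start - 1 :]
        overlap_pep = protein[junction_start - 1 : split_at]
        assert part1.endswith(overlap_pep) and part2.startswith(overlap_pep)
        seq1, _ = _embed(self._cassette(part1), p.frame, self.rng)
        seq2, _ = _embed(self._cassette(part2), p.frame, self.rng)
        a1 = self._add(
            seq1, reference=ref.name, frame=p.frame, error="split",
            expected_category=2, orf_protein=part1, partner="",
            overlap_peptide=overlap_pep,
        )
        a2 = self._add(
            seq2, reference=ref.name, frame=p.frame, error="split",
            expected_category=2, orf_protein=part2, partner=a1,
            overlap_peptide=overlap_pep,
        )
        self.rows[-2]["partner"] = a2
        self.rows[-2]["merged_protein"] = part1 + part2[len(overlap_pep):]

    def _plant_frameshift(self, p: Plant, ref: ReferenceProtein) -> None:
        # Intact coding, then delete one nucleotide in the linker just
        # before an engineered internal ATG: upstream domains stay in the
        # planted frame, the internal ATG and downstream domains shift.
        ivals = ref.domain_intervals()
        if not (1 <= p.split_after_domain < len(ref.architecture)):
            raise ValueError("frameshift point must leave domains on both sides")
        cut = ivals[p.split_after_domain - 1][2] + 2  # inside the linker
        protein = ref.protein[: cut] + "M" + ref.protein[cut + 1 :]
        coding = _revtrans(protein, self.rng)
        del_at = 3 * cut - 1  # last nt of the codon before the internal ATG
        shifted = coding[:del_at] + coding[del_at + 1 :]
        cassette = "TAA" + shifted + "TAA"
        seq, pre = _embed(cassette, p.frame, self.rng)
        up = ref.architecture[: p.split_after_domain]
        down = ref.architecture[p.split_after_domain :]
        # frame of the shifted downstream block on the sense strand
        k = abs(p.frame)
        down_sense_frame = (pre + 3 + del_at) % 3 + 1
        sign = 1 if p.frame > 0 else -1
        self._add(
            seq, reference=ref.name, frame=p.frame, error="frameshift",
            expected_category=2, orf_protein="M" + protein[cut + 1 :],
            partner="", overlap_peptide="",
            frame_up=sign * k, frame_down=sign * down_sense_frame,
            domains_up=";".join(up), domains_down=";".join(down),
        )

    def _plant_novel(self, p: Plant, ref: ReferenceProtein) -> None:
        # The reference's domains inside a long unique protein: identity in
        # the shared region is perfect but query coverage falls below the
        # match threshold, so no reference passes -> category 3.
        protein = _build_protein(ref.architecture, self.rng,
                                 extra_cterm=p.novel_padding)
        seq, _ = _embed(self._cassette(protein), p.frame, self.rng)
        self._add(
            seq, reference=ref.name, frame=p.frame, error="novel",
            expected_category=3, orf_protein=protein, partner="",
            overlap_peptide="",
        )

    def _plant_outside_orf(self, p: Plant, ref: ReferenceProtein) -> None:
        # Domain codons fenced by stops with no start codon anywhere in the
        # segment (consensus peptides are methionine-free), so the hit can
        # lie in no ORF.
        pep = DOMAIN_CONSENSUS[ref.architecture[0]]
        cassette = "TAA" + _revtrans(pep, self.rng) + "TAA"
        seq, _ = _embed(cassette, p.frame, self.rng)
        self._add(
            seq, reference=ref.name, frame=p.frame, error="outside-orf",
            expected_category=0, orf_protein="", partner="",
            overlap_peptide="",
        )

    # -- assembly ------------------------------------------------------------

    def run(self) -> GroundTruth:
        spec = self.spec
        for p in spec.plants:
            self.plant(p)
        lo, hi = spec.length_range
        for _ in range(spec.n_background):
            self._add(_random_nt(self.rng, self.rng.randint(lo, hi)))
        contaminants = [
            self._add(_random_nt(self.rng, self.rng.randint(lo, hi)))
            for _ in range(spec.n_contaminants)
        ]
        cols = ["accession", "reference", "frame", "error",
                "expected_category", "orf_protein", "partner",
                "overlap_peptide"]
        truth = pd.DataFrame(self.rows)
        if not truth.empty:
            extra = [c for c in truth.columns if c not in cols]
            truth = truth[cols + extra]
        return GroundTruth(
            transcripts=self.transcripts,
            truth=truth,
            contaminants=contaminants,
            panel=list(self.panel.values()),
        )


def generate(spec: PlantSpec) -> GroundTruth:
    """Generate a synthetic transcriptome from a plant recipe.

    Deterministic: the same spec (including seed) yields byte-identical
    transcripts and ground truth.
    """
    return _Generator(spec).run()
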
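"""Conserved-domain detection on the six-frame proteome.

The real search engine is external (NCBI Batch CD-Search / RPS-BLAST): this
module batches the proteome the way the original workflow did (random files
of 4000 sequences), parses the Batch CD-Search tabular output, and selects
the target-domain hits.  A built-in window scanner over explicit domain
profiles provides a self-contained detector for synthetic data, so the whole
pipeline runs without any web service.
"""

from __future__ import annotations

import io
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .seqio import FramedId, FramedIdError, parse_framed_id
from .sixframe import FrameTranslation

__all__ = [
    "DomainHit",
    "DomainProfile",
    "split_batches",
    "parse_cdd_hits",
    "builtin_scan",
    "select_target_hits",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DomainHit:
    """A scored domain-model interval on one frame translation.

    Positions are 1-based inclusive protein coordinates on the frame.
    ``hit_type`` preserves the CD-Search classification (specific,
    non-specific, superfamily) when the hit came from a parsed table.
    """

    query: FramedId
    domain_name: str
    hit_start: int
    hit_end: int
    evalue: float
    bitscore: float
    source: str = "builtin"
    hit_type: str = ""

    def __post_init__(self) -> None:
        if self.hit_start < 1 or self.hit_end < self.hit_start:
            raise ValueError(
                f"invalid hit interval [{self.hit_start},{self.hit_end}]"
            )
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class DomainProfile:
    """A self-contained domain detector: exact/approximate motif or PWM.

    Exactly one of ``motif`` or ``pwm`` is set.  A motif window scores one
    point per matching residue and hits when matches >= len(motif) -
    ``max_mismatches``.  A PWM is a per-column residue->score mapping; a
    window hits when its summed score >= ``threshold``.  Windows containing
    residues outside the 20-letter alphabet (X, *) never hit.
    """

    name: str
    motif: Optional[str] = None
    max_mismatches: int = 0
    pwm: Optional[Sequence[Mapping[str, float]]] = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if (self.motif is None) == (self.pwm is None):
            raise ValueError("profile needs exactly one of motif or pwm")
        if self.pwm is not None:
            for i, col in enumerate(self.pwm):
                missing = set(AMINO_ACIDS) - set(col)
                if missing:
                    raise ValueError(
                        f"pwm column {i} lacks scores for {sorted(missing)}"
                    )

    @property
    def width(self) -> int:
        return len(self.motif) if self.motif is not None else len(self.pwm)

    def window_score(self, window: str) -> float:
        """Score one window of length :attr:`width`; -inf if non-standard."""
        if any(c not in AMINO_ACIDS for c in window):
            return float("-inf")
        if self.motif is not None:
            return sum(a == b for a, b in zip(window, self.motif))
        return sum(col[c] for col, c in zip(self.pwm, window))

    @property
    def score_threshold(self) -> float:
        if self.motif is not None:
            return len(self.motif) - self.max_mismatches
        return self.threshold


def split_batches(
    records: Sequence[FrameTranslation],
    batch_size: int = 4000,
    seed: int = 0,
) -> list[list[FrameTranslation]]:
    """Randomly partition translation records into batches of <= batch_size.

    The partition is a true partition (no record lost or duplicated) and is
    reproducible for a fixed seed.  Batch size 4000 matches the upload limit
    the original workflow worked around.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    order = list(records)
    random.Random(seed).shuffle(order)
    return [order[i : i + batch_size] for i in range(0, len(order), batch_size)]


_CDD_REQUIRED = ["Query", "Hit type", "From", "To", "E-Value", "Bitscore", "Short name"]


def parse_cdd_hits(
    path: str | Path, unparsed: Optional[list[str]] = None
) -> list[DomainHit]:
    """Parse an NCBI Batch CD-Search "hits" table into :class:`DomainHit`.

    Accepts the tab-separated dialect with ``#`` comment lines.  The Query
    column may be a bare framed id or the Batch CD-Search form
    ``Q#1 - >TSAX02085024.1_+2``; rows whose query cannot be parsed are
    reported (logged, and appended to ``unparsed`` if a list is given), not
    silently dropped.
    """
    # Filter comment lines ourselves: pandas' comment='#' would also truncate
    # data lines at the '#' inside Batch CD-Search queries like "Q#1 - >id".
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if not lines:
        return []
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)
    missing = [c for c in _CDD_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"CD-Search table missing column(s): {', '.join(missing)}")
    hits: list[DomainHit] = []
    for _, row in df.iterrows():
        qtext = str(row["Query"])
        if ">" in qtext:  # "Q#1 - >accession_+2"
            qtext = qtext.split(">", 1)[1].strip()
        try:
            query = parse_framed_id(qtext)
        except FramedIdError:
            logger.warning("unparsable query %r in %s", row["Query"], path)
            if unparsed is not None:
                unparsed.append(str(row["Query"]))
            continue
        hits.append(
            DomainHit(
                query=query,
                domain_name=str(row["Short name"]),
                hit_start=int(row["From"]),
                hit_end=int(row["To"]),
                evalue=float(row["E-Value"]),
                bitscore=float(row["Bitscore"]),
                source="cdd-batch",
                hit_type=str(row["Hit type"]),
            )
        )
    return hits


def builtin_scan(
    ft: FrameTranslation, profiles: Sequence[DomainProfile]
) -> list[DomainHit]:
    """Scan one frame translation with explicit profiles.

    Every window whose score reaches the profile threshold yields a hit;
    deterministic for fixed input.  Hit bitscore is the window score and the
    e-value is 0 (the detector is exact, not statistical).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    hits: list[DomainHit] = []
    prot = ft.protein
    for prof in profiles:
        w = prof.width
        thr = prof.score_threshold
        for i in range(len(prot) - w + 1):
            score = prof.window_score(prot[i : i + w])
            if score >= thr:
                hits.append(
                    DomainHit(
                        query=ft.id,
                        domain_name=prof.name,
                        hit_start=i + 1,
                        hit_end=i + w,
                        evalue=0.0,
                        bitscore=float(score),
                        source="builtin",
                    )
                )
    return hits


def scan_all(
    translations: Iterable[FrameTranslation], profiles: Sequence[DomainProfile]
) -> list[DomainHit]:
    """:func:`builtin_scan` over a whole proteome."""
    hits: list[DomainHit] = []
    for ft in translations:
        hits.extend(builtin_scan(ft, profiles))
    return hits


def select_target_hits(hits: Iterable[DomainHit], target: str) -> list[DomainHit]:
    """Keep hits whose model short name contains the target, case-insensitive.

    The substring rule means a target of ``SH2`` retains both specific
    ``SH2`` hits and ``SH2 superfamily`` hits, matching how superfamily-only
    transcripts stay in the analysis downstream.
    """
    if not target:
        raise ValueError("target domain name must be non-empty")
    t = target.lower()
    return [h for h in hits if t in h.domain_name.lower()]
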
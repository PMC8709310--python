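"""Conserved-segment detection and architecture assignment for dehydrins.

Dehydrins (group-2 LEA proteins) are built from a small vocabulary of short
conserved motifs — the family-defining K-segment plus Y, S, ϕ, F and NLS
segments — separated by low-complexity linkers.  This module locates those
segments in protein sequences by ungapped Hamming scanning against the
consensus queries, decides whether a protein is a dehydrin (a K-segment
within 4 mismatches of the consensus), and renders the ordered segment
composition as an architecture string such as ``Y3SϕK2`` or ``NLS-K*S``.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SEGMENT_CONSENSUS",
    "PHI",
    "SegmentConsensus",
    "SegmentHit",
    "ArchitectureCall",
    "find_segment_hits",
    "annotate_protein",
    "is_dehydrin",
    "assign_architecture",
    "annotate_panel",
]

#: Canonical token for the polar interpatter segment.
PHI = "ϕ"  # ϕ

#: Consensus queries for the six conserved dehydrin segments.
#: S is a run pattern (five or more serines), not a fixed-length query.
SEGMENT_CONSENSUS: dict[str, str] = {
    "K": "EKKGIMDKIKEKLPG",
    "Y": "VDEYGNP",
    "S": "SSSSS",
    PHI: "EDDGQGR",
    "F": "DRGLFDKFIGKK",
    "NLS": "KKDKKKKKEKK",
}

#: Default mismatch tolerance of the dehydrin rule.
DEFAULT_MAX_MISMATCH = 4
#: Upper mismatch bound of the relaxed K* tier (degraded K-segments of
#: HIRD11-type dehydrins, which fail the 4-mismatch rule yet remain K-derived).
DEFAULT_RELAXED_MAX_MISMATCH = 8

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class SegmentConsensus:
    """A segment query with its mismatch tolerance."""

    segment_type: str
    query: str
    max_mismatch: int = DEFAULT_MAX_MISMATCH

    def __post_init__(self) -> None:
        if not self.query:
            raise ValueError("consensus query must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True, order=True)
class SegmentHit:
    """A located conserved segment: half-open span plus mismatch count.

    ``relaxed`` marks K-segment hits in the 5–8 mismatch tier (K*).
    """

    start: int
    end: int
    segment_type: str = field(compare=False)
    mismatches: int = field(compare=False)
    relaxed: bool = field(default=False, compare=False)

    @property
    def token(self) -> str:
        return "K*" if self.relaxed else self.segment_type

    def overlaps(self, other: "SegmentHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ArchitectureCall:
    protein_id: str
    is_dehydrin: bool
    architecture: str
    hits: list[SegmentHit]


def _hamming(a: str, b: str) -> int:
    # X never matches anything, including X.
    return sum(1 for x, y in zip(a, b) if x != y or x == "X")


def _candidate_windows(seq: str, query: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) windows of ``len(query)`` within tolerance."""
    w = len(query)
    out = []
    for i in range(len(seq) - w + 1):
        mm = _hamming(seq[i : i + w], query)
        if mm <= max_mismatch:
            out.append((i, mm))
    return out


def _greedy_select(candidates: list[SegmentHit]) -> list[SegmentHit]:
    """Resolve overlapping candidates: lowest mismatch first, then leftmost.

    Equivalent to repeatedly accepting the best remaining candidate and
    re-scanning the uncovered remainder, because rejected windows are exactly
    those overlapping an accepted one.
    """
    chosen: list[SegmentHit] = []
    for h in sorted(candidates, key=lambda h: (h.mismatches, h.start, -(h.end - h.start), h.segment_type)):
        if not any(h.overlaps(c) for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen


def _validate_seq(seq: str) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    if not _AA_RE.match(seq):
        bad = sorted(set(seq) - set("ACDEFGHIKLMNPQRSTVWYX"))
        raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    return seq


def find_segment_hits(
    seq: str,
    consensus: SegmentConsensus,
    *,
    relaxed_max_mismatch: int | None = None,
) -> list[SegmentHit]:
    """Locate one segment type in ``seq``.

    Fixed-length queries are slid as ungapped windows and scored by Hamming
    distance; windows within tolerance are resolved greedily (lowest
    mismatch, then leftmost).  The S segment is instead reported as every
    maximal run of >= 5 serines (mismatches always 0).

    For the K segment a second, relaxed tier up to ``relaxed_max_mismatch``
    can be scanned; hits above the strict tolerance carry ``relaxed=True``.
    A sequence shorter than the query yields an empty list.
    """
    seq = _validate_seq(seq)
    stype = consensus.segment_type

    if stype == "S":
        return [
            SegmentHit(m.start(), m.end(), "S", 0)
            for m in re.finditer(r"S{5,}", seq)
        ]

    ceiling = consensus.max_mismatch
    if stype == "K" and relaxed_max_mismatch is not None:
        ceiling = max(ceiling, relaxed_max_mismatch)
    cands = [
        SegmentHit(i, i + len(consensus.query), stype, mm,
                   relaxed=(mm > consensus.max_mismatch))
        for i, mm in _candidate_windows(seq, consensus.query, ceiling)
    ]
    return _greedy_select(cands)


def annotate_protein(
    seq: str,
    *,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    relaxed_max_mismatch: int = DEFAULT_RELAXED_MAX_MISMATCH,
    mode: str = "extended",
    protein_id: str = "",
) -> ArchitectureCall:
    """Scan all six consensus segments and assign the architecture.

    Hits of different segment types compete for sequence: overlaps are
    resolved globally by the same lowest-mismatch-then-leftmost rule used
    within a type, so the final hit list is non-overlapping and
    position-sorted.
    """
    seq = _validate_seq(seq)
    cands: list[SegmentHit] = []
    for stype, query in SEGMENT_CONSENSUS.items():
        cons = SegmentConsensus(stype, query, max_mismatch)
        relaxed = relaxed_max_mismatch if stype == "K" else None
        cands.extend(find_segment_hits(seq, cons, relaxed_max_mismatch=relaxed))
    hits = _greedy_select(cands)
    call = assign_architecture(hits)
    return ArchitectureCall(
        protein_id=protein_id,
        is_dehydrin=is_dehydrin(hits, mode=mode),
        architecture=call,
        hits=hits,
    )


def is_dehydrin(hits: Iterable[SegmentHit], mode: str = "strict") -> bool:
    """Apply the dehydrin characterization rule to a hit list.

    strict:   at least one K-segment within the 4-mismatch tolerance.
    extended: additionally admits HIRD11-like proteins — a relaxed K* hit
              co-occurring with an S run or an NLS hit.
    """
    hits = list(hits)
    if any(h.segment_type == "K" and not h.relaxed for h in hits):
        return True
    if mode == "strict":
        return False
    if mode != "extended":
        raise ValueError(f"unknown mode {mode!r}")
    has_kstar = any(h.segment_type == "K" and h.relaxed for h in hits)
    has_companion = any(h.segment_type in ("S", "NLS") for h in hits)
    return has_kstar and has_companion


def assign_architecture(hits: Sequence[SegmentHit]) -> str:
    """Render position-sorted hits as an architecture string.

    Consecutive identical tokens collapse with a multiplicity suffix
    (K,K → ``K2``; Y,Y,Y → ``Y3``); runs of ϕ collapse to a single ϕ token;
    an NLS token is joined to what follows with a dash (``NLS-K*S``).
    Overlapping hits are a caller error.
    """
    hits = sorted(hits, key=lambda h: h.start)
    for a, b in zip(hits, hits[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping hits: {a} / {b}")
    parts: list[str] = []
    i = 0
    while i < len(hits):
        tok = hits[i].token
        j = i
        while j < len(hits) and hits[j].token == tok:
            j += 1
        count = j - i
        if tok == PHI or count == 1:
            parts.append(tok)
        else:
            parts.append(f"{tok}{count}")
        i = j
    out = ""
    for k, part in enumerate(parts):
        out += part
        if part.startswith("NLS") and k + 1 < len(parts):
            out += "-"
    return out


def annotate_panel(
    records: Iterable[tuple[str, str]] | dict[str, str],
    *,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    mode: str = "extended",
) -> pd.DataFrame:
    """Annotate a panel of proteins; one row per record, sorted by id.

    ``records`` is an ``(id, sequence)`` iterable or mapping.  Duplicate ids
    raise.  Returns columns protein_id, is_dehydrin, architecture, hits
    (semicolon-joined ``type:start-end:mm``).
    """
    if isinstance(records, dict):
        records = records.items()
    rows = []
    seen: set[str] = set()
    for pid, seq in records:
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r}")
        seen.add(pid)
        call = annotate_protein(seq, max_mismatch=max_mismatch, mode=mode, protein_id=pid)
        rows.append(
            {
                "protein_id": pid,
                "is_dehydrin": call.is_dehydrin,
                "architecture": call.architecture,
                "hits": ";".join(
                    f"{h.token}:{h.start}-{h.end}:{h.mismatches}" for h in call.hits
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("protein_id").reset_index(drop=True)
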
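"""Promoter-window extraction and PWM scanning for cis-regulatory elements.

Promoter windows span −500..+200 bp around the transcription start site
(minus-strand genes mirrored and reverse-complemented so positions read
5'→3' relative to the gene).  Windows are scanned on both strands with a
position weight matrix scored as log2 odds against a background base
composition; hits at or above the bit-score threshold (default 9) are
reported with TSS-relative 0-based positions (negative = upstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UPSTREAM",
    "DOWNSTREAM",
    "DEFAULT_SCAN_THRESHOLD",
    "PWM",
    "PromoterWindow",
    "CREHit",
    "extract_promoter",
    "scan_pwm",
    "scan_panel",
    "hits_table",
]

logger = logging.getLogger(__name__)

UPSTREAM = 500
DOWNSTREAM = 200
DEFAULT_SCAN_THRESHOLD = 9.0

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: 4 x width base probabilities (rows A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.25, 0.25, 0.25])
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A,C,G,T)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Column-normalized probabilities after pseudocounting."""
        p = self.matrix + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p_base / bg_base) per column."""
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1],
                   self.pseudocount, self.background[::-1])

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=0, keepdims=True), **kw)


@dataclass
class PromoterWindow:
    """A TSS-anchored promoter sequence in gene orientation.

    ``offset_start`` is the TSS-relative coordinate of the first window
    base (−500 for a full window; less negative when truncated at a contig
    edge).
    """

    gene_id: str
    sequence: str
    strand: str = "+"
    offset_start: int = -UPSTREAM
    truncated: bool = False


@dataclass(frozen=True)
class CREHit:
    gene_id: str
    motif_id: str
    position: int  # TSS-relative, 0-based, start of the site in gene orientation
    strand: str
    score: float


def extract_promoter(
    contig_seq: str,
    gene_id: str,
    tss: int,
    strand: str = "+",
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
) -> PromoterWindow:
    """Cut the −upstream..+downstream window around the TSS.

    Plus strand: ``[tss-upstream, tss+downstream)``.  Minus strand: the
    mirrored interval ``[tss-downstream+1, tss+upstream+1)`` reverse-
    complemented, so the returned sequence always reads 5'→3' along the
    gene with the TSS ``upstream`` bases in.  Windows truncated at contig
    edges are returned with a warning.
    """
    n = len(contig_seq)
    if not 0 <= tss < n:
        raise ValueError(f"{gene_id}: TSS {tss} outside contig of length {n}")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
        clo, chi = max(0, lo), min(n, hi)
        seq = contig_seq[clo:chi].upper()
        offset_start = clo - tss
    elif strand == "-":
        lo, hi = tss - downstream + 1, tss + upstream + 1
        clo, chi = max(0, lo), min(n, hi)
        seq = reverse_complement(contig_seq[clo:chi].upper())
        offset_start = tss + 1 - chi
    else:
        raise ValueError(f"bad strand {strand!r}")
    truncated = (chi - clo) < (upstream + downstream)
    if truncated:
        warnings.warn(
            f"{gene_id}: promoter window truncated to {chi - clo} bp at contig edge",
            stacklevel=2,
        )
    return PromoterWindow(gene_id, seq, strand, offset_start, truncated)


def _strand_scores(seq: str, lom: np.ndarray) -> np.ndarray:
    """Score every offset of ``seq`` with log-odds matrix ``lom``.

    Offsets containing a degenerate base score NaN (skipped, logged).
    """
    w = lom.shape[1]
    idx = np.full(len(seq), -1, dtype=int)
    for i, b in enumerate(_BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    n_off = len(seq) - w + 1
    scores = np.full(max(n_off, 0), np.nan)
    for o in range(n_off):
        window = idx[o : o + w]
        if (window < 0).any():
            logger.debug("degenerate base: offset %d skipped", o)
            continue
        scores[o] = lom[window, np.arange(w)].sum()
    return scores


def scan_pwm(
    window: PromoterWindow,
    pwm: PWM,
    threshold: float = DEFAULT_SCAN_THRESHOLD,
) -> list[CREHit]:
    """Report PWM hits with log2-odds score >= ``threshold`` on both strands.

    Positions are TSS-relative starts in gene orientation; overlapping hits
    on opposite strands are both reported.
    """
    seq = window.sequence.upper()
    if len(seq) < pwm.width:
        raise ValueError(
            f"{window.gene_id}: window ({len(seq)} bp) shorter than PWM ({pwm.width})"
        )
    hits: list[CREHit] = []
    lom = pwm.log_odds
    fwd = _strand_scores(seq, lom)
    rev = _strand_scores(seq, pwm.reverse_complement().log_odds)
    for o, s in enumerate(fwd):
        if s >= threshold:
            hits.append(CREHit(window.gene_id, pwm.motif_id, window.offset_start + o, "+", float(s)))
    for o, s in enumerate(rev):
        if s >= threshold:
            hits.append(CREHit(window.gene_id, pwm.motif_id, window.offset_start + o, "-", float(s)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_panel(
    windows: Iterable[PromoterWindow],
    pwms: Sequence[PWM],
    threshold: float = DEFAULT_SCAN_THRESHOLD,
) -> pd.DataFrame:
    hits: list[CREHit] = []
    for window in windows:
        for pwm in pwms:
            hits.extend(scan_pwm(window, pwm, threshold))
    return hits_table(hits)


def hits_table(hits: Iterable[CREHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "motif_id": h.motif_id,
                "position": h.position,
                "strand": h.strand,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["gene_id", "motif_id", "position", "strand", "score"],
    )
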
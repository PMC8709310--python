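"""ProtParam-style biochemical descriptors for protein sequences.

Molecular weight (average masses), Kyte–Doolittle GRAVY and the Guruprasad
instability index are delegated to Biopython's ProtParam implementation.
The isoelectric point is computed here by bisection on the
Henderson–Hasselbalch net charge using the EMBOSS pKa set — a named,
swappable constant table (the Expasy/Bjellqvist variant differs slightly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "EMBOSS_PKA",
    "PropertySet",
    "molecular_weight",
    "gravy",
    "isoelectric_point",
    "net_charge",
    "instability_index",
    "properties_table",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: EMBOSS pKa values for ionizable groups (iep defaults).
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

# Positively ionizable groups (protonated form charged): N-terminus, H, K, R.
_POSITIVE = ("Nterm", "H", "K", "R")
# Negatively ionizable groups (deprotonated form charged): C-terminus, C, D, E, Y.
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")


@dataclass
class PropertySet:
    protein_id: str
    length: int
    mol_wt: float
    pI: float
    gravy: float
    instability: float


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    for i, aa in enumerate(seq):
        if aa not in _STANDARD_AA:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    return ProteinAnalysis(_check(seq)).molecular_weight()


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle index per residue."""
    return ProteinAnalysis(_check(seq)).gravy()


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    seq = _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    return ProteinAnalysis(seq).instability_index()


def net_charge(seq: str, pH: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson–Hasselbalch net charge of ``seq`` at ``pH``.

    Termini plus D, E, C, Y, H, K, R side chains; monotonically decreasing
    in pH, so the isoelectric point is its unique root.
    """
    seq = _check(seq)
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    pos = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (pH - pka[g])) for g in _POSITIVE
    )
    neg = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - pH)) for g in _NEGATIVE
    )
    return pos - neg


def isoelectric_point(
    seq: str,
    pka: Mapping[str, float] = EMBOSS_PKA,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero.

    Bisection runs the interval down to 1e-7 pH units (so the result also
    lands on the true root, not merely somewhere inside a flat |q| < tol
    region of a shallow titration curve) and the returned pH satisfies
    |charge| < ``tol``.
    """
    seq = _check(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    assert abs(net_charge(seq, mid, pka)) < tol
    return mid


def properties_table(records: Iterable[tuple[str, str]] | dict[str, str]) -> pd.DataFrame:
    """One PropertySet row per protein, sorted by id."""
    if isinstance(records, dict):
        records = records.items()
    rows = []
    for pid, seq in records:
        seq = _check(seq)
        rows.append(
            {
                "protein_id": pid,
                "length": len(seq),
                "mol_wt": molecular_weight(seq),
                "pI": isoelectric_point(seq),
                "gravy": gravy(seq),
                "instability": instability_index(seq),
            }
        )
    return pd.DataFrame(rows).sort_values("protein_id").reset_index(drop=True)
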
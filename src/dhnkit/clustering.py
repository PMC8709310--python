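"""Greedy centroid clustering of ecotype dehydrin panels at 95% similarity.

Sequences from many ecotypes are grouped into gene-type clusters: a
sequence joins the first cluster whose representative it matches at or
above the similarity threshold, else founds a new cluster (seeds processed
in descending length order, ties by id, so the outcome is deterministic).
Clusters below the minimum size dissolve, and their members get a second
chance against the surviving representatives (the rescue pass).

Similarity is the identity fraction of a BLOSUM62 global alignment
(gap columns included in the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SimilarityRecord",
    "GeneCluster",
    "pairwise_similarity",
    "cluster_panel",
    "assignments_table",
    "ecotype_completeness",
]


@dataclass(frozen=True)
class SimilarityRecord:
    id_a: str
    id_b: str
    similarity: float
    alignment_length: int


@dataclass
class GeneCluster:
    cluster_id: str
    representative: str
    members: list[str]
    status: str  # "primary" once >= min_size is confirmed


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_similarity(
    id_a: str,
    seq_a: str,
    id_b: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> SimilarityRecord:
    """Identity fraction of the optimal BLOSUM62 global alignment.

    similarity = identical aligned positions / alignment length, where the
    alignment length counts gap columns; symmetric by construction.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return SimilarityRecord(id_a, id_b, counts.identities / length, length)


def cluster_panel(
    seqs: Mapping[str, str],
    threshold: float = 0.95,
    min_size: int = 3,
    screen_margin: float = 0.10,
) -> tuple[list[GeneCluster], pd.DataFrame]:
    """Two-pass greedy clustering with within-cluster linkage.

    Pass 1: sequences in descending length order (ties by id) join the
    first existing cluster (founding order) containing a member they match
    at >= ``threshold`` — the representative is tried first and the
    remaining members only when the representative similarity falls within
    ``screen_margin`` of the threshold (members of one cluster are mutually
    close, so a representative far below the threshold rules the whole
    cluster out).  Unmatched sequences found new clusters.  Clusters below
    ``min_size`` dissolve.
    Pass 2: dissolved/unmatched sequences are re-compared to the surviving
    clusters and rescued at >= ``threshold``; the rest stay unclassified.

    Returns the clusters plus a per-sequence assignment frame with columns
    seq_id, cluster_id ('.' if none), status in {primary, rescued,
    unclassified} and an ``ambiguous`` flag set when two clusters both
    pass the threshold within 1% similarity of each other (mirrors gene
    pairs that real panels co-annotate and need manual curation).
    """
    ids = list(seqs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    aligner = _make_aligner()
    order = sorted(ids, key=lambda i: (-len(seqs[i]), i))

    clusters: list[GeneCluster] = []
    assignment: dict[str, tuple[str | None, str, bool]] = {}

    def cluster_similarity(sid: str, cl: GeneCluster) -> float:
        """Best similarity of ``sid`` to the cluster, representative first."""
        best = pairwise_similarity(
            sid, seqs[sid], cl.representative, seqs[cl.representative], aligner
        ).similarity
        if best >= threshold or best < threshold - screen_margin:
            return best
        for member in cl.members:
            if member == cl.representative:
                continue
            s = pairwise_similarity(sid, seqs[sid], member, seqs[member], aligner).similarity
            best = max(best, s)
            if best >= threshold:
                break
        return best

    def best_match(sid: str, pool: list[GeneCluster]) -> tuple[GeneCluster | None, bool]:
        scored = [
            (sim, cl)
            for cl in pool
            if (sim := cluster_similarity(sid, cl)) >= threshold
        ]
        if not scored:
            return None, False
        top = max(s for s, _ in scored)
        ambiguous = sum(1 for s, _ in scored if top - s < 0.01) > 1
        # first passing cluster in founding order
        return scored[0][1], ambiguous

    for sid in order:
        cl, amb = best_match(sid, clusters)
        if cl is None:
            cl = GeneCluster(f"cluster{len(clusters) + 1:03d}", sid, [sid], "primary")
            clusters.append(cl)
        else:
            cl.members.append(sid)
        assignment[sid] = (cl.cluster_id, "primary", amb)

    surviving = [cl for cl in clusters if len(cl.members) >= min_size]
    dissolved = [cl for cl in clusters if len(cl.members) < min_size]
    leftovers = [sid for cl in dissolved for sid in cl.members]
    for sid in leftovers:
        assignment[sid] = (None, "unclassified", False)

    for sid in sorted(leftovers, key=lambda i: (-len(seqs[i]), i)):
        cl, amb = best_match(sid, surviving)
        if cl is not None:
            cl.members.append(sid)
            assignment[sid] = (cl.cluster_id, "rescued", amb)

    frame = pd.DataFrame(
        [
            {
                "seq_id": sid,
                "cluster_id": assignment[sid][0] or ".",
                "status": assignment[sid][1],
                "ambiguous": assignment[sid][2],
            }
            for sid in sorted(ids)
        ]
    )
    return surviving, frame


def assignments_table(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.copy()


def ecotype_completeness(
    frame: pd.DataFrame,
    n_expected_clusters: int,
    sep: str = "|",
) -> float:
    """Fraction of ecotypes represented in all expected clusters.

    Sequence ids follow the ``ecotype|gene`` convention; unclassified
    sequences do not count toward representation.
    """
    df = frame[frame["cluster_id"] != "."].copy()
    if df.empty:
        return 0.0
    df["ecotype"] = df["seq_id"].str.split(sep, regex=False).str[0]
    per_eco = df.groupby("ecotype")["cluster_id"].nunique()
    ecotypes = frame["seq_id"].str.split(sep, regex=False).str[0].unique()
    if len(ecotypes) == 0:
        return 0.0
    complete = (per_eco >= n_expected_clusters).sum()
    return complete / len(ecotypes)
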
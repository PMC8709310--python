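"""Chromosomal mapping and tandem/segmental duplication calling.

A pair of homologous dehydrin genes within one genome is a tandem
duplication when both lie on the same chromosome with an intergenic gap of
at most 50 kb (adjacency implies gap 0), and a segmental duplication
otherwise (different chromosomes, or same chromosome beyond the gap).
Homology means same family label, or a family pair declared homologous in
the configuration (defaults: Bdhn1–Bdhn2, Bdhn4–Bdhn5, Bdhn7–Bdhn8).
Identical calls from genomes of one genome group (e.g., the D-type genomes
Bd21 and the ABR113 D subgenome) merge into a single duplication event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_HOMOLOG_PAIRS",
    "DEFAULT_TANDEM_MAX_GAP",
    "GeneLocus",
    "DuplicationCall",
    "DuplicationEvent",
    "call_duplications",
    "merge_duplication_events",
    "calls_table",
    "events_table",
]

DEFAULT_TANDEM_MAX_GAP = 50_000

#: Cross-family pairs treated as homologous (same-family pairs always are).
DEFAULT_HOMOLOG_PAIRS: tuple[tuple[str, str], ...] = (
    ("Bdhn1", "Bdhn2"),
    ("Bdhn4", "Bdhn5"),
    ("Bdhn7", "Bdhn8"),
)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    family: str
    genome_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    genome_group: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative coordinate")
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: empty chromosome")


@dataclass(frozen=True)
class DuplicationCall:
    """Per-genome family-pair classification."""

    family_a: str
    family_b: str
    kind: str  # "tandem" | "segmental"
    genome_id: str
    gene_ids: tuple[str, ...] = field(compare=False, default=())

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.family_a, self.family_b)))


@dataclass
class DuplicationEvent:
    family_a: str
    family_b: str
    kind: str
    genome_group: str
    supporting_genomes: list[str]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _gap(x: GeneLocus, y: GeneLocus) -> int:
    """Intergenic distance between the nearer interval ends (0 if overlapping)."""
    if x.start > y.start:
        x, y = y, x
    return max(0, y.start - x.end)


def call_duplications(
    loci: Sequence[GeneLocus],
    tandem_max_gap: int = DEFAULT_TANDEM_MAX_GAP,
    homolog_pairs: Iterable[tuple[str, str]] = DEFAULT_HOMOLOG_PAIRS,
) -> list[DuplicationCall]:
    """Classify homologous gene pairs within each genome.

    Genes in different genomes are never compared.  A family pair with
    several locus combinations is tandem if any combination satisfies the
    tandem rule (an adjacent homolog exists), else segmental.  The gap
    boundary is inclusive: exactly ``tandem_max_gap`` is still tandem.
    """
    homolog_set = {_canonical_pair(*p) for p in homolog_pairs}

    by_genome: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_genome.setdefault(loc.genome_id, []).append(loc)

    calls: list[DuplicationCall] = []
    for genome_id in sorted(by_genome):
        genome_loci = sorted(by_genome[genome_id], key=lambda l: l.gene_id)
        # same-gene-id sanity: overlapping duplicates of one id are input errors
        by_id: dict[str, GeneLocus] = {}
        for loc in genome_loci:
            if loc.gene_id in by_id:
                other = by_id[loc.gene_id]
                if loc.chromosome == other.chromosome and _gap(loc, other) == 0:
                    raise ValueError(
                        f"overlapping loci for gene id {loc.gene_id!r} in {genome_id}"
                    )
                raise ValueError(f"duplicate gene id {loc.gene_id!r} in {genome_id}")
            by_id[loc.gene_id] = loc

        pair_combos: dict[tuple[str, str], list[tuple[GeneLocus, GeneLocus]]] = {}
        for i, x in enumerate(genome_loci):
            for y in genome_loci[i + 1 :]:
                pair = _canonical_pair(x.family, y.family)
                homologous = x.family == y.family or pair in homolog_set
                if homologous:
                    pair_combos.setdefault(pair, []).append((x, y))

        for pair in sorted(pair_combos):
            combos = pair_combos[pair]
            tandem_pairs = [
                (x, y)
                for x, y in combos
                if x.chromosome == y.chromosome and _gap(x, y) <= tandem_max_gap
            ]
            if tandem_pairs:
                genes = tuple(sorted({g.gene_id for xy in tandem_pairs for g in xy}))
                kind = "tandem"
            else:
                genes = tuple(sorted({g.gene_id for xy in combos for g in xy}))
                kind = "segmental"
            calls.append(DuplicationCall(pair[0], pair[1], kind, genome_id, genes))
    return calls


def merge_duplication_events(
    calls: Iterable[DuplicationCall],
    genome_groups: Mapping[str, str],
) -> list[DuplicationEvent]:
    """Collapse identical (pair, kind) calls within one genome group.

    ``genome_groups`` maps every genome id to its group label; a genome
    without a group is an error.  Events are returned sorted by
    (group, kind, pair).
    """
    merged: dict[tuple[str, str, str, str], list[str]] = {}
    for call in calls:
        if call.genome_id not in genome_groups:
            raise ValueError(f"genome {call.genome_id!r} has no genome group")
        group = genome_groups[call.genome_id]
        key = (group, call.kind, *call.pair)
        merged.setdefault(key, []).append(call.genome_id)
    events = [
        DuplicationEvent(a, b, kind, group, sorted(genomes))
        for (group, kind, a, b), genomes in merged.items()
    ]
    events.sort(key=lambda e: (e.genome_group, e.kind, e.family_a, e.family_b))
    return events


def calls_table(calls: Iterable[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "family_a": c.pair[0],
                "family_b": c.pair[1],
                "kind": c.kind,
                "gene_ids": ",".join(c.gene_ids),
            }
            for c in calls
        ]
    )


def events_table(events: Iterable[DuplicationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_group": e.genome_group,
                "family_a": e.family_a,
                "family_b": e.family_b,
                "kind": e.kind,
                "supporting_genomes": ",".join(e.supporting_genomes),
            }
            for e in events
        ]
    )
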
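"""Gene-census arithmetic over annotated dehydrin panels.

The packaged reference panel transcribes the published dehydrin gene
inventory of the four Brachypodium reference genomes (five genomes
counting the two allotetraploid subgenomes separately).  Orthologs of the
six outgroup grasses are carried as per-species counts (Aegilops tauschii
9, Hordeum vulgare 8, Zea mays 7, Oryza sativa 6, Sorghum bicolor 5,
Triticum aestivum 19); individual outgroup accession ids are not part of
the inventory.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["OUTGROUP_ORTHOLOG_COUNTS", "GeneCensus", "load_reference_panel", "gene_census"]

#: Dehydrin orthologs retrieved per outgroup grass species.
OUTGROUP_ORTHOLOG_COUNTS: dict[str, int] = {
    "Aegilops_tauschii": 9,
    "Hordeum_vulgare": 8,
    "Zea_mays": 7,
    "Oryza_sativa": 6,
    "Sorghum_bicolor": 5,
    "Triticum_aestivum": 19,
}


@dataclass
class GeneCensus:
    n_brachypodium: int
    per_genome: dict[str, int]
    n_outgroup: int
    n_families: int


def load_reference_panel() -> pd.DataFrame:
    """The packaged reference gene inventory (one row per gene copy)."""
    with resources.files("dhnkit.data").joinpath("reference_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def gene_census(
    panel: pd.DataFrame | None = None,
    outgroup_counts: dict[str, int] | None = None,
) -> GeneCensus:
    """Count dehydrin genes per genome and in total.

    ``panel`` needs columns gene_id, family, genome_id; duplicated gene ids
    raise.  Defaults to the packaged reference inventory with the published
    outgroup counts.
    """
    if panel is None:
        panel = load_reference_panel()
    if outgroup_counts is None:
        outgroup_counts = OUTGROUP_ORTHOLOG_COUNTS
    if panel["gene_id"].duplicated().any():
        dup = panel.loc[panel["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in panel: {dup[:5]}")
    per_genome = panel.groupby("genome_id")["gene_id"].count().to_dict()
    return GeneCensus(
        n_brachypodium=int(len(panel)),
        per_genome={k: int(v) for k, v in per_genome.items()},
        n_outgroup=int(sum(outgroup_counts.values())),
        n_families=int(panel["family"].nunique()),
    )
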
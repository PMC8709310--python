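"""Readers and writers for the formats the pipeline consumes and emits.

FASTA goes through Biopython, trees through dendropy, tables through
pandas (tab-separated, ``.`` for missing).  GFF3 gene coordinates are
converted to 0-based half-open on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .loci import GeneLocus
from .promoters import PWM

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_loci_tsv",
    "write_loci_tsv",
    "read_loci_gff3",
    "read_jaspar_pwms",
    "write_jaspar_pwms",
    "read_tree",
    "write_tree",
]

_TSV_KWARGS = dict(sep="\t", na_values=["."], keep_default_na=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an id -> sequence mapping; duplicate ids raise."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path: str | Path, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, **_TSV_KWARGS)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep=".", index=index)


_LOCUS_COLUMNS = ["gene_id", "family", "genome_id", "genome_group",
                  "chromosome", "start", "end", "strand"]


def read_loci_tsv(path: str | Path) -> list[GeneLocus]:
    df = read_tsv(path)
    missing = [c for c in _LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    return [
        GeneLocus(
            gene_id=r.gene_id, family=r.family, genome_id=r.genome_id,
            genome_group=r.genome_group if isinstance(r.genome_group, str) else "",
            chromosome=r.chromosome, start=int(r.start), end=int(r.end),
            strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_loci_tsv(loci: Iterable[GeneLocus], path: str | Path) -> None:
    frame = pd.DataFrame([l.__dict__ for l in loci])[_LOCUS_COLUMNS]
    write_tsv(frame, path)


_GFF_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def read_loci_gff3(
    path: str | Path,
    genome_id: str,
    genome_group: str = "",
    family_attribute: str = "family",
    feature_type: str = "gene",
) -> list[GeneLocus]:
    """Gene features of a GFF3 file as loci (coordinates made 0-based).

    The family label is taken from ``family_attribute`` in column 9,
    falling back to ``Name``; the gene id from ``ID``.
    """
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != feature_type:
                continue
            attrs = dict(_GFF_ATTR.findall(parts[8]))
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            family = attrs.get(family_attribute) or attrs.get("Name") or gene_id
            loci.append(
                GeneLocus(
                    gene_id=gene_id, family=family, genome_id=genome_id,
                    genome_group=genome_group, chromosome=parts[0],
                    start=int(parts[3]) - 1, end=int(parts[4]),
                    strand=parts[6] if parts[6] in "+-" else "+",
                )
            )
    return loci


def read_jaspar_pwms(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """JASPAR-style PWM text: ``>motif_id`` then 4 rows ``A [ 1 2 3 ]`` ..."""
    pwms: list[PWM] = []
    motif_id, rows = None, {}

    def flush() -> None:
        nonlocal motif_id, rows
        if motif_id is not None:
            if set(rows) != set("ACGT"):
                raise ValueError(f"{motif_id}: need A,C,G,T rows, got {sorted(rows)}")
            counts = np.array([rows[b] for b in "ACGT"], dtype=float)
            pwms.append(PWM.from_counts(motif_id, counts, pseudocount=pseudocount))
        motif_id, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
            else:
                m = re.match(r"([ACGTacgt])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?$", line)
                if not m:
                    raise ValueError(f"unparseable PWM line: {line!r}")
                rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
    flush()
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_jaspar_pwms(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for b, row in zip("ACGT", pwm.matrix):
                fh.write(f"{b} [ " + " ".join(f"{v:.6g}" for v in row) + " ]\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")
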
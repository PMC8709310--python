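"""Synthetic data generators with known ground truth for every pipeline stage.

The generators emulate the study conditions of the dehydrin analysis:

* proteins assembled from the consensus conserved segments with a
  controlled per-residue mutation load and low-complexity linkers;
* gene locus tables with planted tandem (same chromosome, gap <= 50 kb)
  and segmental (cross-chromosome) duplicate pairs;
* multi-ecotype protein panels with controlled divergence and dropout;
* promoter sets with planted PWM consensus sites;
* TPM expression matrices with multiplicative drought effects
  (log-normal replicate noise) under a W/D x C/H design;
* phenotypic trait tables linearly coupled to expression;
* random Yule trees with tip traits drawn under a λ-scaled Brownian
  covariance.

Identical seeds and parameters give byte-identical output, and at zero
mutation/noise every downstream stage recovers the planted truth exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .loci import GeneLocus
from .promoters import PWM
from .segments import PHI, SEGMENT_CONSENSUS

__all__ = [
    "AA_ALPHABET",
    "LINKER_ALPHABET",
    "DEFAULT_GENE_ARCHITECTURES",
    "DEFAULT_DROUGHT_EFFECTS",
    "DEFAULT_TRAIT_SLOPES",
    "SimProteinTruth",
    "SimLocusTruth",
    "SimExpressionTruth",
    "gen_dehydrin_protein",
    "gen_protein_panel",
    "gen_locus_table",
    "gen_ecotype_panel",
    "gen_promoter_set",
    "gen_expression_matrix",
    "gen_trait_table",
    "gen_tree_with_trait",
    "gen_climate_table",
    "brachypodium_reference_locus_truths",
    "reference_locus_table",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Linkers use small/polar residues typical of the disordered inter-segment
#: regions, restricted to letters that occur in none of the consensus
#: queries (and excluding S, which would seed spurious S runs): a window
#: lying inside a linker can then never satisfy a mismatch threshold.
LINKER_ALPHABET = "THA"

#: Number of substitutions planted in a K* (degraded K) segment: above the
#: 4-mismatch dehydrin rule, inside the relaxed <= 8 annotation tier.
KSTAR_SUBSTITUTIONS = 6

#: Canonical gene -> architecture panel covering the eight-string
#: architecture vocabulary, with YSϕK2 carried by the four genes that share
#: it (Bdhn3/6/7/8).
DEFAULT_GENE_ARCHITECTURES: dict[str, str] = {
    "Bdhn1a": "FSK2",
    "Bdhn1b": "FSK3",
    "Bdhn2": f"S{PHI}K2",
    "Bdhn3": f"YS{PHI}K2",
    "Bdhn4": f"YS{PHI}K",
    "Bdhn5": f"Y3S{PHI}K",
    "Bdhn6": f"YS{PHI}K2",
    "Bdhn7": f"YS{PHI}K2",
    "Bdhn8": f"YS{PHI}K2",
    "Bdhn9": f"Y3S{PHI}K2",
    "Bdhn10": "NLS-K*S",
}

#: Mean drought-induced percent increases (as fractions) of the four
#: dehydrins expressed in mature leaves.
DEFAULT_DROUGHT_EFFECTS: dict[str, float] = {
    "Bdhn1a": 0.0574,
    "Bdhn2": 0.39,
    "Bdhn3": 0.678,
    "Bdhn7": 0.978,
}

#: Sign pattern of the trait ~ expression coupling: positive for proline,
#: below-ground biomass, root mass ratio, WUE (delta13c), leaf carbon and
#: C/N; negative for leaf water contents and leaf nitrogen; zero
#: (uncoupled) for total/above-ground mass and lma.
DEFAULT_TRAIT_SLOPES: dict[str, float] = {
    "leaf_rwc": -0.5, "leaf_wc": -0.8, "lma": 0.0, "pro": 1.0,
    "abvgrd": 0.0, "blwgrd": 0.6, "ttlmass": 0.0, "rmr": 0.4,
    "delta13c": 0.3, "leafc": 0.5, "leafn": -0.6, "cn": 0.9,
}

_TOKEN_RE = re.compile(r"(NLS|K\*|[FSKYϕφ])(\d*)|(phi)(\d*)", re.IGNORECASE)


@dataclass
class SimProteinTruth:
    protein_id: str
    architecture: str
    segments: list[tuple[str, int, int]]  # (type, start, end) 0-based half-open
    mutation_rate: float
    seed: int


@dataclass
class SimLocusTruth:
    genome_id: str
    genome_group: str
    planted_events: list[tuple[str, str, str, tuple[str, ...]]]
    # (family_a, family_b, kind, chromosomes); tandem events name 1 chromosome,
    # segmental events 2 distinct ones.
    decoy_families: tuple[str, ...] = ()


@dataclass
class SimExpressionTruth:
    gene_ids: tuple[str, ...]
    drought_effect: Mapping[str, float]  # theta_g, multiplicative (fraction)
    baseline_tpm: Mapping[str, float]
    dispersion: float                    # sd of log-normal replicate noise
    n_ecotypes: int
    n_replicates: int                    # per (ecotype, water) cell
    seed: int


def parse_architecture(architecture: str) -> list[str]:
    """Expand an architecture string into a flat token list.

    Tokens: F, S, K, K*, Y, ϕ (or 'phi'), NLS, each with an optional integer
    multiplicity; dashes are separators.  Unknown tokens raise with the
    offending text.
    """
    tokens: list[str] = []
    pos = 0
    text = architecture.replace("-", "")
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ValueError(f"unknown architecture token at {text[pos:]!r}")
        tok = (m.group(1) or m.group(3))
        count = m.group(2) or m.group(4) or "1"
        if tok.lower() == "phi" or tok in ("φ", PHI):
            tok = PHI
        else:
            tok = tok.upper()
        tokens.extend([tok] * int(count))
        pos = m.end()
    if not tokens:
        raise ValueError("empty architecture string")
    return tokens


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            choices = [c for c in AA_ALPHABET if c != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_dehydrin_protein(
    architecture: str,
    linker_length: int = 10,
    mutation_rate: float = 0.0,
    seed: int = 0,
    protein_id: str = "",
) -> tuple[str, SimProteinTruth]:
    """Assemble a dehydrin-like protein from consensus segments.

    Segments follow the architecture token order, separated by random
    linkers of ``linker_length`` residues from the low-complexity
    alphabet; S renders as SSSSS and K* as the K consensus with exactly
    six planted substitutions.  The whole sequence is then mutated at
    ``mutation_rate`` per residue.  Truth records the exact segment spans.
    """
    if not 0 <= mutation_rate < 4 / len(SEGMENT_CONSENSUS["K"]):
        raise ValueError(
            "mutation_rate must be in [0, 4/15) so the K segment survives "
            "the 4-mismatch rule in expectation"
        )
    tokens = parse_architecture(architecture)
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: list[tuple[str, int, int]] = []
    pos = 0
    for i, tok in enumerate(tokens):
        if i > 0 and linker_length > 0:
            linker = "".join(
                LINKER_ALPHABET[j]
                for j in rng.integers(len(LINKER_ALPHABET), size=linker_length)
            )
            parts.append(linker)
            pos += linker_length
        if tok == "K*":
            base = SEGMENT_CONSENSUS["K"]
            sites = rng.choice(len(base), size=KSTAR_SUBSTITUTIONS, replace=False)
            seg = list(base)
            for s in sites:
                choices = [c for c in AA_ALPHABET if c != base[s]]
                seg[s] = choices[rng.integers(len(choices))]
            seg = "".join(seg)
        else:
            seg = SEGMENT_CONSENSUS[tok]
        parts.append(seg)
        segments.append((tok, pos, pos + len(seg)))
        pos += len(seg)
    seq = _mutate("".join(parts), mutation_rate, rng)
    truth = SimProteinTruth(protein_id or architecture, architecture, segments,
                            mutation_rate, seed)
    return seq, truth


def gen_protein_panel(
    gene_architectures: Mapping[str, str] | None = None,
    linker_length: int = 10,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, SimProteinTruth]]:
    """One protein per gene of the canonical architecture panel."""
    if gene_architectures is None:
        gene_architectures = DEFAULT_GENE_ARCHITECTURES
    seqs: dict[str, str] = {}
    truths: dict[str, SimProteinTruth] = {}
    for i, (gene, arch) in enumerate(sorted(gene_architectures.items())):
        seq, truth = gen_dehydrin_protein(
            arch, linker_length, mutation_rate, seed + i, protein_id=gene
        )
        seqs[gene] = seq
        truths[gene] = truth
    return seqs, truths


def gen_locus_table(
    spec: SimLocusTruth,
    gap_tandem: int = 10_000,
    seed: int = 0,
    gene_length: int = 2_000,
) -> list[GeneLocus]:
    """Materialize planted duplication events as gene loci.

    Tandem pairs share a chromosome with an intergenic gap of
    ``gap_tandem`` (must be <= 50 kb); segmental pairs sit on their two
    distinct chromosomes.  Decoy families become singleton loci.
    """
    if gap_tandem < 0:
        raise ValueError("negative gap")
    if gap_tandem > 50_000:
        raise ValueError("planted tandem gap must be <= 50 kb")
    rng = np.random.default_rng(seed)
    loci: list[GeneLocus] = []
    counter: dict[str, int] = {}

    def add(family: str, chrom: str, start: int) -> None:
        counter[family] = counter.get(family, 0) + 1
        suffix = "" if counter[family] == 1 else f".{counter[family]}"
        loci.append(
            GeneLocus(
                gene_id=f"{spec.genome_id}:{family}{suffix}",
                family=family,
                genome_id=spec.genome_id,
                genome_group=spec.genome_group,
                chromosome=chrom,
                start=start,
                end=start + gene_length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )

    cursor: dict[str, int] = {}

    def place(chrom: str, span: int) -> int:
        start = cursor.get(chrom, 100_000)
        cursor[chrom] = start + span + 200_000
        return start

    for fam_a, fam_b, kind, chroms in spec.planted_events:
        if kind == "tandem":
            (chrom,) = chroms
            start = place(chrom, 2 * gene_length + gap_tandem)
            add(fam_a, chrom, start)
            add(fam_b, chrom, start + gene_length + gap_tandem)
        elif kind == "segmental":
            chrom_a, chrom_b = chroms
            # reuse an existing copy of the family on that chromosome, so a
            # family in both a tandem and a segmental event keeps one locus set
            for fam, chrom in ((fam_a, chrom_a), (fam_b, chrom_b)):
                if not any(l.family == fam and l.chromosome == chrom for l in loci):
                    add(fam, chrom, place(chrom, gene_length))
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    for fam in spec.decoy_families:
        chrom = f"chr_dec{1 + rng.integers(5)}"
        add(fam, chrom, place(chrom, gene_length))
    return loci


def brachypodium_reference_locus_truths() -> tuple[list[SimLocusTruth], dict[str, str]]:
    """The five-genome duplication layout of the reference genomes.

    D-type genomes (Bd21 and the ABR113 D subgenome) carry the
    Bdhn7–Bdhn8 tandem on Bd3 and the Bdhn1–Bdhn2 segmental pair on
    Bd3/Bd5; Bd21 additionally carries the Bdhn4–Bdhn5 tandem on Bd4.
    S-type genomes (ABR114, ABR113 S subgenome, Ain-1) carry the
    Bdhn7–Bdhn8 tandem and the Bdhn1–Bdhn2 segmental pair; Ain-1 also
    carries the Bdhn1a–Bdhn1b tandem.  Merged by genome group this layout
    yields four tandem and two segmental duplication events.

    Returns (locus truths, genome -> group map).
    """
    d = "D-type"
    s = "S-type"
    truths = [
        SimLocusTruth("Bd21", d, [
            ("Bdhn7", "Bdhn8", "tandem", ("Bd3",)),
            ("Bdhn4", "Bdhn5", "tandem", ("Bd4",)),
            ("Bdhn1", "Bdhn2", "segmental", ("Bd3", "Bd5")),
        ], decoy_families=("Bdhn3", "Bdhn6", "Bdhn9", "Bdhn10")),
        SimLocusTruth("ABR113-D", d, [
            ("Bdhn7", "Bdhn8", "tandem", ("Bd3",)),
            ("Bdhn1", "Bdhn2", "segmental", ("Bd3", "Bd5")),
        ], decoy_families=("Bdhn3", "Bdhn5", "Bdhn6", "Bdhn9", "Bdhn10")),
        SimLocusTruth("ABR114", s, [
            ("Bdhn7", "Bdhn8", "tandem", ("Bs4",)),
            ("Bdhn1", "Bdhn2", "segmental", ("Bs4", "Bs9")),
        ], decoy_families=("Bdhn3", "Bdhn5", "Bdhn6", "Bdhn9", "Bdhn10")),
        SimLocusTruth("ABR113-S", s, [
            ("Bdhn7", "Bdhn8", "tandem", ("Bs4",)),
            ("Bdhn1", "Bdhn2", "segmental", ("Bs4", "Bs9")),
        ], decoy_families=("Bdhn3", "Bdhn5", "Bdhn6", "Bdhn9", "Bdhn10")),
        SimLocusTruth("Ain-1", s, [
            ("Bdhn7", "Bdhn8", "tandem", ("Bsy4",)),
            ("Bdhn1", "Bdhn1", "tandem", ("Bsy9",)),   # Bdhn1a/Bdhn1b
            ("Bdhn1", "Bdhn2", "segmental", ("Bsy9", "Bsy4")),
        ], decoy_families=("Bdhn3", "Bdhn5", "Bdhn6", "Bdhn9", "Bdhn10")),
    ]
    groups = {t.genome_id: t.genome_group for t in truths}
    return truths, groups


def reference_locus_table(gap_tandem: int = 10_000, seed: int = 0) -> tuple[list[GeneLocus], dict[str, str]]:
    """Loci for the five-genome reference layout, plus the group map."""
    truths, groups = brachypodium_reference_locus_truths()
    loci: list[GeneLocus] = []
    for i, truth in enumerate(truths):
        loci.extend(gen_locus_table(truth, gap_tandem=gap_tandem, seed=seed + i))
    return loci, groups


def gen_ecotype_panel(
    base_seqs: Mapping[str, str],
    n_ecotypes: int = 54,
    divergence: float = 0.02,
    dropout: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Spawn per-ecotype mutated copies of each base sequence.

    Every base sequence yields ``n_ecotypes`` copies (ids
    ``eco<NN>|<gene>``) mutated at ``divergence`` per residue; ``dropout``
    removes copies at random.  Returns (sequences, truth map copy -> base).
    Divergence should stay below 0.05 so planted members remain above the
    95% identity threshold.
    """
    if divergence >= 1:
        raise ValueError("divergence must be < 1")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    truth: dict[str, str] = {}
    for gene in sorted(base_seqs):
        for e in range(1, n_ecotypes + 1):
            if rng.random() < dropout:
                continue
            cid = f"eco{e:02d}|{gene}"
            seqs[cid] = _mutate(base_seqs[gene], divergence, rng)
            truth[cid] = gene
    return seqs, truth


def gen_promoter_set(
    pwm: PWM,
    n_prom: int = 10,
    sites_per_prom: int = 1,
    length: int = 700,
    seed: int = 0,
    background: Sequence[float] = (0.3, 0.2, 0.2, 0.3),
    max_retries: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background promoters with the PWM consensus planted at known sites.

    Background bases are sampled from an AT-rich plant-like composition
    (A,C,G,T given by ``background``); each planted site is the PWM
    consensus written at a random non-overlapping position on a random
    strand.  Returns (sequences keyed promN, planted-site frame with
    columns gene_id, position (window start offset, 0-based), strand).
    """
    if length < pwm.width:
        raise ValueError("promoter length must be >= PWM width")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    bases = np.array(list("ACGT"))
    consensus = pwm.consensus
    from .promoters import reverse_complement

    seqs: dict[str, str] = {}
    rows = []
    for p in range(1, n_prom + 1):
        pid = f"prom{p:02d}"
        seq = list(rng.choice(bases, size=length, p=bg))
        placed: list[tuple[int, int]] = []
        for _ in range(sites_per_prom):
            for attempt in range(max_retries):
                start = int(rng.integers(length - pwm.width + 1))
                if all(start + pwm.width <= s or start >= e for s, e in placed):
                    break
            else:
                raise RuntimeError(f"{pid}: could not place non-overlapping sites")
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else reverse_complement(consensus)
            seq[start : start + pwm.width] = list(site)
            placed.append((start, start + pwm.width))
            rows.append({"gene_id": pid, "position": start, "strand": strand})
        seqs[pid] = "".join(seq)
    sites = pd.DataFrame(rows, columns=["gene_id", "position", "strand"])
    return seqs, sites


def default_expression_truth(
    n_ecotypes: int = 32,
    n_replicates: int = 4,
    dispersion: float = 0.2,
    seed: int = 0,
) -> SimExpressionTruth:
    """The study-design defaults: four drought-responsive dehydrins at the
    observed effect sizes plus six silent decoy genes."""
    effects = dict(DEFAULT_DROUGHT_EFFECTS)
    decoys = ["Bdhn4", "Bdhn5", "Bdhn6", "Bdhn8", "Bdhn9", "Bdhn10"]
    for g in decoys:
        effects[g] = 0.0
    genes = tuple(sorted(effects))
    baselines = {g: 50.0 + 10.0 * i for i, g in enumerate(genes)}
    return SimExpressionTruth(
        gene_ids=genes,
        drought_effect=effects,
        baseline_tpm=baselines,
        dispersion=dispersion,
        n_ecotypes=n_ecotypes,
        n_replicates=n_replicates,
        seed=seed,
    )


def gen_expression_matrix(truth: SimExpressionTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix (genes x samples) plus a design table.

    Watered samples fluctuate log-normally around the gene baseline;
    dry samples around baseline x (1 + theta_g).  Replicates within each
    (ecotype, water) cell are split evenly between the cool and hot
    temperature regimes (temperature has no planted effect, matching the
    observed dominance of the drought response).
    """
    if truth.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    for g in truth.gene_ids:
        theta = truth.drought_effect[g]
        if 1 + theta <= 0:
            raise ValueError(f"{g}: multiplicative effect must keep TPM positive")
        if truth.baseline_tpm[g] <= 0:
            raise ValueError(f"{g}: non-positive baseline TPM")
    rng = np.random.default_rng(truth.seed)
    samples, design_rows = [], []
    data: dict[str, list[float]] = {}
    for e in range(1, truth.n_ecotypes + 1):
        eco = f"eco{e:02d}"
        for water in ("W", "D"):
            for r in range(1, truth.n_replicates + 1):
                temp = "C" if r <= (truth.n_replicates + 1) // 2 else "H"
                sid = f"{eco}_{water}{temp}_r{r}"
                samples.append(sid)
                design_rows.append(
                    {"sample": sid, "ecotype": eco, "water": water,
                     "temperature": temp, "replicate": r}
                )
                col = []
                for g in truth.gene_ids:
                    mean = truth.baseline_tpm[g]
                    if water == "D":
                        mean *= 1 + truth.drought_effect[g]
                    noise = (
                        np.exp(rng.normal(0.0, truth.dispersion))
                        if truth.dispersion > 0
                        else 1.0
                    )
                    col.append(mean * noise)
                data[sid] = col
    tpm = pd.DataFrame(data, index=list(truth.gene_ids))
    design = pd.DataFrame(design_rows).set_index("sample")
    return tpm, design


def gen_trait_table(
    expression_summary: pd.Series,
    slopes: Mapping[str, float] | None = None,
    intercepts: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Traits linearly coupled to expression.

    ``expression_summary`` is indexed by (ecotype, treatment) and holds
    the mean expression driving the traits.  Each trait value is
    ``intercept + slope * expression + N(0, noise_sd)``.  Default slopes
    carry the drought-response sign pattern; default intercepts are 100.
    """
    if slopes is None:
        slopes = DEFAULT_TRAIT_SLOPES
    if intercepts is None:
        intercepts = {t: 100.0 for t in slopes}
    rng = np.random.default_rng(seed)
    rows = []
    for (eco, treatment), expr in expression_summary.sort_index().items():
        row = {"ecotype": eco, "treatment": treatment}
        for trait in slopes:
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            row[trait] = intercepts[trait] + slopes[trait] * expr + noise
        rows.append(row)
    return pd.DataFrame(rows)


def gen_tree_with_trait(
    n_tips: int,
    lambda_true: float = 1.0,
    seed: int = 0,
    birth_rate: float = 1.0,
    sigma2: float = 1.0,
) -> tuple[dendropy.Tree, pd.Series]:
    """Random Yule tree plus a tip trait with λ-scaled Brownian covariance.

    The trait vector is multivariate normal with covariance
    ``sigma2 * C(λ)`` where C is the shared-path-length matrix and the
    off-diagonal is scaled by ``lambda_true`` (1 = pure Brownian motion,
    0 = independent tips).
    """
    if not 0 <= lambda_true <= 1:
        raise ValueError("lambda_true must be in [0, 1]")
    if n_tips < 4:
        raise ValueError("need >= 4 tips")
    from .phylosignal import tree_vcv

    rng = np.random.default_rng(seed)
    newick = _yule_newick(n_tips, birth_rate, rng)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    C = tree_vcv(tree)
    cov = lambda_true * C.to_numpy()
    np.fill_diagonal(cov, np.diag(C.to_numpy()))
    values = rng.multivariate_normal(np.zeros(n_tips), sigma2 * cov, method="cholesky")
    trait = pd.Series(values, index=list(C.index), name="trait")
    return tree, trait


def _yule_newick(n_tips: int, birth_rate: float, rng: np.random.Generator) -> str:
    """Pure-birth (Yule) tree as a newick string.

    Starting from one lineage, the waiting time to the next split is
    exponential with rate (current lineages x birth_rate) and a uniformly
    chosen lineage splits; after the n-th tip a final exponential waiting
    time runs out the terminal branches, so no branch has zero length.
    """
    birth_times = {0: 0.0}          # node -> time of birth
    children: dict[int, tuple[int, int]] = {}
    active = [0]
    nxt = 1
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        kids = (nxt, nxt + 1)
        nxt += 2
        for k in kids:
            birth_times[k] = t
            active.append(k)
        children[parent] = kids
    t += rng.exponential(1.0 / (n_tips * birth_rate))

    labels = iter(f"t{i}" for i in range(1, n_tips + 1))

    def render(node: int) -> str:
        end = birth_times[children[node][0]] if node in children else t
        length = end - birth_times[node]
        if node in children:
            a, b = children[node]
            return f"({render(a)},{render(b)}):{length:.10f}"
        return f"{next(labels)}:{length:.10f}"

    return f"{render(0)};"


def gen_climate_table(
    n_ecotypes: int = 54,
    n_vars: int = 19,
    loading: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bioclimatic variables driven by one latent cold–warm gradient.

    Each variable is ``sign_j * loading * g + noise`` around a
    variable-specific offset, where g is the latent standard-normal
    gradient (positive = colder).  Temperature-like variables (including
    the bio11 anchor) load negatively on cold; precipitation-like ones
    positively.  Returns (ecotype x variable frame, latent gradient).
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(size=n_ecotypes)
    names = [f"bio{j}" for j in range(1, n_vars + 1)]
    # bio1..bio11 temperature-like (negative on cold), bio12+ precipitation-like
    signs = np.array([-1.0 if j <= 11 else 1.0 for j in range(1, n_vars + 1)])
    data = {}
    for name, s in zip(names, signs):
        offset = rng.normal(10.0, 2.0)
        data[name] = offset + s * loading * g + rng.normal(0.0, noise_sd, size=n_ecotypes)
    index = [f"eco{e:02d}" for e in range(1, n_ecotypes + 1)]
    frame = pd.DataFrame(data, index=index)
    return frame, pd.Series(g, index=index, name="gradient")
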
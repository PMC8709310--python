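# Methods

`dhnkit` reimplements a dehydrin (group-2 LEA protein) comparative-genomics
workflow as a tested library: motif-based family annotation, biochemical
characterization, duplication calling, multi-ecotype clustering, promoter
scanning, drought-response expression and trait statistics, climate-niche
classification and phylogenetic-signal testing. Every stage has a matching
synthetic-data generator with known ground truth, so the whole pipeline is
verifiable without access to reference genomes or RNA-seq.

## Segment annotation

Dehydrins are recognized by short conserved motifs. The consensus queries
are

| segment | query | role |
|---|---|---|
| K | `EKKGIMDKIKEKLPG` | family identifier, amphipathic helix |
| Y | `VDEYGNP` | N-terminal motif |
| S | `SSSSS+` (run of ≥5 S) | phosphorylation target |
| ϕ | `EDDGQGR` | polar interpatter linker |
| F | `DRGLFDKFIGKK` | N-terminal motif of some seed-plant dehydrins |
| NLS | `KKDKKKKKEKK` | nuclear localization signal |

Fixed-length queries are slid as ungapped windows and scored by Hamming
distance; windows within the mismatch tolerance (default 4) are candidate
hits. Ungapped Hamming matching is the deterministic, oracle-checkable
reading of a short-query protein search; for 7–15-mer queries gaps are not
meaningful. The S segment is reported as every maximal serine run of five
or more (mismatches are not defined for a run pattern). Overlapping
candidates — within and across segment types — are resolved greedily,
lowest mismatch count first, ties to the leftmost window; the result is
order-independent and identical to repeatedly accepting the best remaining
window and re-scanning the uncovered sequence.

A protein is a dehydrin when it carries a K-segment within 4 mismatches of
the consensus (strict rule). HIRD11-type dehydrins lack a canonical
K-segment but retain a degraded one; the annotator therefore keeps a second,
relaxed K tier (5–8 mismatches, rendered `K*`), and the extended rule also
accepts a relaxed K co-occurring with an S run or an NLS. Both the strict
tolerance and the relaxed ceiling are configurable.

The architecture string lists hits in sequence order, collapsing repeats
with a multiplicity suffix (`K,K → K2`), rendering ϕ runs as a single ϕ,
and joining `NLS` to following tokens with a dash — reproducing the
eight-string vocabulary `FSK2, FSK3, SϕK2, YSϕK2, YSϕK, Y3SϕK, Y3SϕK2,
NLS-K*S`. Coordinates are 0-based half-open throughout.

## Biochemical descriptors

Molecular weight (average isotopic masses + one water), Kyte–Doolittle
GRAVY and the Guruprasad dipeptide instability index follow the ProtParam
conventions via Biopython. The isoelectric point is the root of the
Henderson–Hasselbalch net charge over the termini and D/E/C/Y/H/K/R side
chains, using the EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1) as a named, swappable table; the
charge is monotone in pH, and bisection is run down to an interval of
1e-7 pH units so the result is the actual root rather than an arbitrary
point of a flat low-charge region (the returned pH always has |charge|
< 1e-4). Proteins built purely from the consensus segments have negative
GRAVY — the hydrophilicity that defines the family.

## Duplication calling

Within one genome, two loci are homologous when they share a family label
or their families are declared homologous in the configuration (defaults:
Bdhn1–Bdhn2, Bdhn4–Bdhn5, Bdhn7–Bdhn8). A homologous pair is a tandem
duplication when both loci lie on one chromosome with an intergenic gap
(nearer interval ends) of at most 50 kb — the boundary inclusive — and a
segmental duplication otherwise; "segmental" is deliberately the
complement, since cross-chromosome pairs are its canonical case. When a
family has several copies, the pair is tandem if any copy combination
satisfies the rule (an adjacent homolog exists). Calls are merged across
the genomes of a genome group (D-type: B. distachyon Bd21 and the
B. hybridum D subgenome; S-type: B. stacei ABR114, the B. hybridum S
subgenome and B. sylvaticum Ain-1), so a duplication shared by a diploid
and its derived allotetraploid subgenome counts as one event. On the
packaged five-genome reference layout this yields 4 tandem and 2
segmental events.

## Ecotype clustering

Pairwise similarity is the identity fraction of a BLOSUM62 global
alignment (gap open 11, extend 1), gap columns counted in the denominator;
identity rather than BLOSUM-positive fraction is the natural reading of a
95% similarity threshold (a switch is provided). Clustering is greedy:
sequences are processed in descending length order (ties by id) and join
the first existing cluster containing a member they match at ≥95%, else
found a new cluster. The representative (founding member) is compared
first; the remaining members are consulted only when the representative
similarity falls within 0.10 of the threshold — members of one cluster are
mutually close, so a far-off representative rules the cluster out without
further alignments. The member-linkage step matters statistically: at 2%
per-copy divergence, two copies of one gene are ~96% identical on average
with a standard deviation of 1–2 points, so demanding a match to one fixed
founder would spuriously split clusters near the 95% boundary. Clusters
with fewer than three members dissolve, and a rescue pass re-compares
their members (and other unmatched sequences) to the surviving clusters.
Sequences matching two clusters within 1% similarity are flagged
ambiguous — the analog of gene pairs that co-annotate in real panels and
need manual curation — but are still assigned to the first passing
cluster.

## Promoter scanning

Promoter windows run from 500 bp upstream to 200 bp downstream of the TSS;
minus-strand genes use the mirrored interval reverse-complemented, so all
windows read 5′→3′ along the gene with the TSS 500 bases in. Windows
truncated at contig edges are returned with a warning. A PWM (4 × width
base probabilities; pseudocount 0.01 renormalized per column) scores every
offset on both strands as Σ log2(p_base/background); hits at or above the
threshold are reported with TSS-relative 0-based positions. The threshold
default of 9 is treated as a plain bit-score cutoff and is configurable;
offsets containing degenerate bases are skipped and logged.

## Expression statistics

TPM values are compared nonparametrically. Per gene, a two-sided Wilcoxon
rank-sum test contrasts watered/dry (or cool/hot, or the within-water
temperature cells); the exact null distribution is enumerated when both
groups have ≤8 samples and no ties, otherwise the normal approximation
with tie correction is used. Benjamini–Hochberg correction is applied over
all genes of a batch (conservative family definition). Among-ecotype
differences use Kruskal–Wallis omnibus tests followed by Tukey HSD with a
compact letter display (insert-and-absorb algorithm). The drought percent
change per gene is the unweighted mean over ecotypes of
(mean_D − mean_W)/mean_W × 100; rank tests use raw TPM (ranks are
transform-invariant) while inter-gene correlations use Pearson r on
log(TPM+1) ecotype means. Trait summaries mirror the expression ones at
ecotype level: paired Wilcoxon signed-rank tests of W vs D ecotype means,
percent change with W as denominator, and ordinary least squares of trait
on expression (the ecotype is the unit of analysis; replicates are
averaged first; raw TPM by default, switchable to log).

## Climate niches and phylogenetic signal

Climate niches come from a correlation-matrix PCA of the 19 bioclimatic
variables: columns standardized (ddof 1), leading eigenvector scores
signed so that the coldest-quarter temperature anchor loads negatively
(cold ecotypes score positive), classes cold (PC1 > 2.5), warm
(PC1 < −2.5) and mesic between. The printed class definition in the
source material contradicts itself ("warm < 2.5" vs "mesic −2.5..2.5");
warm < −2.5 is the only consistent resolution and is what is implemented.

Phylogenetic signal uses the tip-by-tip shared-path-length matrix C of the
input tree. Blomberg's K is (MSE0/MSE)/E[MSE0/MSE | BM], with MSE0 the
raw and MSE the C⁻¹-weighted mean squared deviation around the GLS
(phylogenetic) mean, and the Brownian expectation computed analytically as
(tr C − n/(1ᵀC⁻¹1))/(n−1); significance is a tip-label permutation test
(default 999 permutations, add-one smoothing), bit-reproducible for a
fixed seed. Pagel's λ scales the off-diagonal of C and is estimated by
maximizing the profile multivariate-normal likelihood over [0, λ_max] with
bounded scalar optimization (xatol 1e-8), endpoints checked explicitly;
λ_max is the largest value keeping C positive-definite, capped at 1.1.
Significance is a likelihood-ratio test against λ = 0 (χ², 1 df). At λ = 0
the likelihood reduces to the closed-form independent-tips limit, which
the tests verify. K agrees to 1e-10 with an independent dense-algebra
evaluation (and with R phytools on fixed fixtures).

## Synthetic data

The generators define the conditions under which the pipeline is tested:

- **Proteins** are consensus segments concatenated in architecture order,
  separated by random linkers, then mutated per residue. Linkers draw from
  {T, H, A} — small/polar residues typical of the disordered inter-segment
  regions, chosen from the letters that occur in *none* of the consensus
  queries, so no window inside a linker can ever satisfy a mismatch
  threshold (with short 7-mer queries and 4 allowed mismatches, broader
  polar alphabets produce chance ϕ matches that corrupt planted
  architectures). `K*` is the K consensus with exactly 6 planted
  substitutions — above the 4-mismatch rule, inside the relaxed ≤8 tier.
  Mutation rates are restricted below 4/15 so the K segment survives the
  dehydrin rule in expectation.
- **Locus tables** plant tandem pairs at a stated gap (default 10 kb,
  ≤50 kb enforced) and segmental pairs across chromosomes, plus singleton
  decoy families; the packaged five-genome layout reproduces the reference
  duplication geography.
- **Ecotype panels** spawn per-ecotype copies mutated at a stated
  divergence with optional dropout; truth maps every copy to its source
  gene.
- **Expression matrices** use log-normal replicate noise (default sd 0.2
  on the log scale) around gene baselines, multiplied by (1+θ) under
  drought; the default experiment is 32 ecotypes × 4 replicates per
  watering condition with θ = 0.0574, 0.39, 0.678, 0.978 on the four
  leaf-expressed dehydrins and θ = 0 on six decoys. Replicates are split
  evenly over cool/hot with no planted temperature effect, matching the
  observed dominance of the drought response. (The source reports the
  Bdhn1a effect inconsistently — percent vs fold scale; the generator
  plants effects on the percent scale and does not attempt to reconcile.)
- **Traits** are intercept + slope × expression + Gaussian noise per
  ecotype × treatment, with default slopes carrying the observed sign
  pattern (positive: pro, blwgrd, rmr, delta13c/WUE, leafc, cn; negative:
  leaf_rwc, leaf_wc, leafn; zero: lma, abvgrd, ttlmass).
- **Trees** are pure-birth (Yule) topologies with exponential waiting
  times; a final exponential extension runs out the terminal branches so C
  is never singular. Tip traits are multivariate normal with covariance
  σ² × λ-transformed C.
- **Climate tables** drive 19 variables from one latent cold–warm
  gradient (temperature-like variables loading negatively on cold,
  precipitation-like positively).

All generators are deterministic given seed and parameters, and at zero
mutation/noise every downstream stage recovers the planted truth exactly.

What the generators do *not* emulate: real sequence content beyond segment
composition (no codon structure, no indels, no paralog-specific linker
homology), genomic context (no synteny blocks or intergenic gene density),
count-based expression noise (TPM is modeled directly, not via reads), or
spatial/temporal climate structure. Passing tests therefore demonstrate
the correctness of the statistics and decision rules under their stated
models, not robustness to alignment error, annotation noise or
quantification artifacts in real data.

## Problem sizes

The test suite runs the stages at reduced but structurally faithful sizes
chosen to keep the full suite fast on one CPU: clustering at 10 genes ×
20–54 ecotypes, expression at 6–32 ecotypes × 4 replicates, trees at
12–30 tips, K/λ calibration over 120–200 replicate simulations. The
acceptance script uses the full study design for its quantity (32 ecotypes
× 4 replicates).

## Known limitations

- The mismatch semantics of the S run pattern are undefined in the
  original rule; runs are matched exactly (no mismatches), which is the
  conservative reading.
- The token order of the HIRD11 architecture differs between sources
  (`K*(NLS)S` vs `K*NLSL-S`); output always follows hit positions in the
  sequence.
- The 8-architecture-to-gene map beyond the four YSϕK2 genes is not
  recoverable from the printed record; the packaged panel assigns the
  remaining seven architectures bijectively to the remaining seven genes.
- BH correction treats all genes of a run as one family; analyses mixing
  many contrasts in one call will be more conservative than per-contrast
  correction.
- Blomberg's K on a single tree has large sampling variance even under
  Brownian motion; calibration statements are about its expectation.
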
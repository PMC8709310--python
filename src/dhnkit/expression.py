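"""Differential-expression statistics for dehydrin TPM matrices.

The design is watered/dry (W/D) crossed with cool/hot (C/H) over many
ecotypes with replicated samples.  TPM values are compared with
nonparametric statistics, as appropriate for normalized abundances of a
small gene panel: two-sided Wilcoxon rank-sum tests per gene with
Benjamini–Hochberg correction across the batch, Kruskal–Wallis omnibus
tests with Tukey HSD post-hoc letters across ecotypes, drought-induced
percent change per gene, and inter-gene Pearson correlation of
log-transformed ecotype means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONTRASTS",
    "wilcoxon_de",
    "kruskal_tukey",
    "percent_change",
    "gene_correlation",
    "validate_design",
]

#: Named contrasts: (column, level_a, level_b) or ((water, temp) pairs).
CONTRASTS: dict[str, tuple] = {
    "WD": ("water", "W", "D"),
    "CH": ("temperature", "C", "H"),
    "CW-HW": ("combo", ("W", "C"), ("W", "H")),
    "CD-HD": ("combo", ("D", "C"), ("D", "H")),
}

_DESIGN_COLUMNS = ("ecotype", "water", "temperature", "replicate")


def validate_design(tpm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check the design table against the TPM matrix columns."""
    for col in _DESIGN_COLUMNS:
        if col not in design.columns:
            raise ValueError(f"design table missing column {col!r}")
    missing = [s for s in tpm.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples absent from design table: {missing[:5]}")
    if tpm.index.duplicated().any():
        raise ValueError("duplicate gene ids in TPM matrix")
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values")
    return design.loc[tpm.columns]


def _contrast_masks(design: pd.DataFrame, contrast: str) -> tuple[pd.Series, pd.Series]:
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; options: {sorted(CONTRASTS)}")
    spec = CONTRASTS[contrast]
    if spec[0] == "combo":
        (w_a, t_a), (w_b, t_b) = spec[1], spec[2]
        mask_a = (design["water"] == w_a) & (design["temperature"] == t_a)
        mask_b = (design["water"] == w_b) & (design["temperature"] == t_b)
    else:
        col, a, b = spec
        mask_a = design[col] == a
        mask_b = design[col] == b
    return mask_a, mask_b


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration when both n <= 8 and no
    ties, normal approximation with tie correction otherwise."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def wilcoxon_de(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str = "WD",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test with BH correction.

    Returns gene, contrast, raw_p, bh_adjusted_p, direction (sign of the
    group-b mean minus group-a mean) and significance at ``alpha``.
    Genes with fewer than 2 samples in either group are skipped with a
    warning.
    """
    design = validate_design(tpm, design)
    mask_a, mask_b = _contrast_masks(design, contrast)
    rows = []
    for gene in tpm.index:
        a = tpm.loc[gene, mask_a.values].to_numpy(dtype=float)
        b = tpm.loc[gene, mask_b.values].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"{gene}: group with < 2 samples, skipped", stacklevel=2)
            continue
        rows.append(
            {
                "gene": gene,
                "contrast": contrast,
                "raw_p": _ranksum_p(a, b),
                "direction": int(np.sign(b.mean() - a.mean())),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["bh_adjusted_p"] = multipletests(out["raw_p"], method="fdr_bh")[1]
    out["significant"] = out["bh_adjusted_p"] <= alpha
    return out


def _compact_letter_display(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``distinct`` holds unordered pairs that differ significantly; groups
    sharing a letter are not significantly different.
    """
    def differ(a: str, b: str) -> bool:
        return (a, b) in distinct or (b, a) in distinct

    sets: list[set[str]] = [set(groups)]
    for a, b in sorted(distinct):
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s < t or s == t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def kruskal_tukey(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    water: str = "D",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Among-ecotype tests within one watering treatment.

    Per gene: Kruskal–Wallis omnibus H (tie-corrected) over ecotype groups,
    then Tukey HSD on the group values with a compact letter display
    (ecotypes sharing a letter do not differ significantly).  Requires at
    least 3 ecotype groups.

    Returns (omnibus frame, letters frame).
    """
    design = validate_design(tpm, design)
    sel = design["water"] == water
    sub_design = design[sel]
    ecotypes = sorted(sub_design["ecotype"].unique())
    if len(ecotypes) < 3:
        raise ValueError(f"need >= 3 ecotype groups, got {len(ecotypes)}")
    omnibus_rows, letter_rows = [], []
    for gene in tpm.index:
        values = tpm.loc[gene, sel.values].to_numpy(dtype=float)
        labels = sub_design["ecotype"].to_numpy()
        groups = [values[labels == e] for e in ecotypes]
        if np.ptp(values) == 0:
            h, p = 0.0, 1.0  # all observations identical: no evidence
        else:
            h, p = stats.kruskal(*groups)
        omnibus_rows.append({"gene": gene, "H": float(h), "p": float(p)})

        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        distinct = {
            (str(r["group1"]), str(r["group2"]))
            for _, r in res.iterrows()
            if bool(r["reject"])
        }
        letters = _compact_letter_display(ecotypes, distinct)
        for eco in ecotypes:
            letter_rows.append({"gene": gene, "ecotype": eco, "letters": letters[eco]})
    return pd.DataFrame(omnibus_rows), pd.DataFrame(letter_rows)


def percent_change(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    baseline: str = "W",
    treated: str = "D",
) -> tuple[pd.Series, pd.DataFrame]:
    """Drought-induced percent change per gene.

    Per ecotype: ``(mean_D - mean_W) / mean_W * 100`` over that ecotype's
    samples (replicates and temperatures pooled).  The gene-level value is
    the unweighted mean across ecotypes; ecotypes with zero baseline mean
    are skipped with a warning.

    Returns (per-gene Series, per-gene x per-ecotype detail frame).
    """
    design = validate_design(tpm, design)
    rows = []
    for gene in tpm.index:
        for eco, eco_design in design.groupby("ecotype", sort=True):
            cols = eco_design.index
            w = tpm.loc[gene, cols[eco_design["water"] == baseline]].to_numpy(dtype=float)
            d = tpm.loc[gene, cols[eco_design["water"] == treated]].to_numpy(dtype=float)
            if len(w) == 0 or len(d) == 0:
                continue
            if w.mean() == 0:
                warnings.warn(f"{gene}/{eco}: zero baseline mean, skipped", stacklevel=2)
                continue
            rows.append(
                {
                    "gene": gene,
                    "ecotype": eco,
                    "percent_change": (d.mean() - w.mean()) / w.mean() * 100.0,
                }
            )
    detail = pd.DataFrame(rows)
    per_gene = detail.groupby("gene")["percent_change"].mean()
    per_gene.name = "percent_change"
    return per_gene, detail


def gene_correlation(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    water: str = "D",
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Pearson correlation between gene pairs across ecotype means.

    Values are ``log(TPM + offset)`` averaged per ecotype within the
    selected watering condition.  Zero-variance genes are flagged with
    r = NaN rather than dropped.
    """
    design = validate_design(tpm, design)
    sel = design["water"] == water
    if sel.sum() < 3:
        raise ValueError("need >= 3 samples for correlation")
    logt = np.log(tpm.loc[:, sel.values] + log_offset)
    means = logt.T.groupby(design.loc[sel, "ecotype"]).mean().T  # genes x ecotypes
    rows = []
    for g1, g2 in combinations(tpm.index, 2):
        x, y = means.loc[g1].to_numpy(), means.loc[g2].to_numpy()
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            rows.append({"gene_a": g1, "gene_b": g2, "r": np.nan, "p": np.nan,
                         "flag": "zero_variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene_a": g1, "gene_b": g2, "r": float(r), "p": float(p), "flag": "."})
    return pd.DataFrame(rows)
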
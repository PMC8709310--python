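"""Drought-response phenotypic trait summaries and trait~expression regression.

The unit of analysis is the ecotype: replicate measurements are averaged
per ecotype and treatment before testing.  Percent change uses the watered
(W) treatment as denominator; trait~expression relations are ordinary
least squares on ecotype-level values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAIT_NAMES",
    "RegressionResult",
    "trait_change_summary",
    "fit_trait_expression_regression",
    "regress_panel",
]

#: The twelve drought-response traits (delta13c doubles as the WUE proxy).
TRAIT_NAMES: tuple[str, ...] = (
    "leaf_rwc", "leaf_wc", "lma", "pro", "abvgrd", "blwgrd",
    "ttlmass", "rmr", "delta13c", "leafc", "leafn", "cn",
)


@dataclass
class RegressionResult:
    trait: str
    gene: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _ecotype_means(traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-(ecotype, treatment) means of one trait column."""
    return (
        traits.groupby(["ecotype", "treatment"])[trait]
        .mean()
        .unstack("treatment")
    )


def trait_change_summary(
    traits: pd.DataFrame,
    trait_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean percent change (D vs W) per trait plus a paired Wilcoxon test.

    ``traits`` is long-format with columns ecotype, treatment (W/D) and one
    column per trait.  Percent change is averaged over ecotypes with
    complete W/D pairs; unpaired ecotypes are excluded with a warning.
    The signed-rank test compares the paired ecotype means.
    """
    if trait_names is None:
        trait_names = tuple(c for c in TRAIT_NAMES if c in traits.columns)
    rows = []
    for trait in trait_names:
        wide = _ecotype_means(traits, trait)
        unpaired = wide.index[wide.isna().any(axis=1)]
        if len(unpaired):
            warnings.warn(
                f"{trait}: unpaired ecotypes excluded: {list(unpaired)[:5]}",
                stacklevel=2,
            )
        wide = wide.dropna()
        w, d = wide["W"].to_numpy(), wide["D"].to_numpy()
        nonzero = w != 0
        pct = float(np.mean((d[nonzero] - w[nonzero]) / w[nonzero] * 100.0))
        diffs = d - w
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(w, d, zero_method="wilcox").pvalue)
        rows.append(
            {"trait": trait, "percent_change": pct, "p": p, "n_ecotypes": len(wide)}
        )
    return pd.DataFrame(rows)


def fit_trait_expression_regression(
    trait_values: pd.Series,
    expression: pd.Series,
    trait: str = "",
    gene: str = "",
) -> RegressionResult:
    """OLS of an ecotype-indexed trait on ecotype-indexed gene expression."""
    merged = pd.concat(
        [trait_values.rename("y"), expression.rename("x")], axis=1, join="inner"
    ).dropna()
    if len(merged) < 3:
        raise ValueError(f"regression needs >= 3 matched ecotypes, got {len(merged)}")
    fit = stats.linregress(merged["x"], merged["y"])
    return RegressionResult(
        trait=trait,
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(merged),
    )


def regress_panel(
    traits: pd.DataFrame,
    expression_summary: pd.DataFrame,
    treatment: str = "D",
) -> pd.DataFrame:
    """All trait x gene regressions at ecotype level within one treatment.

    ``expression_summary`` is ecotype x gene (e.g., mean TPM under D).
    """
    sub = traits[traits["treatment"] == treatment]
    trait_names = tuple(c for c in TRAIT_NAMES if c in traits.columns)
    rows = []
    for trait in trait_names:
        y = sub.groupby("ecotype")[trait].mean()
        for gene in expression_summary.columns:
            res = fit_trait_expression_regression(
                y, expression_summary[gene], trait=trait, gene=gene
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
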
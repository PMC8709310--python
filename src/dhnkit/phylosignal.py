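"""Phylogenetic signal of continuous traits: Blomberg's K and Pagel's λ.

Both statistics quantify how strongly tip trait values covary with
phylogenetic relatedness, summarized by the tip-by-tip shared-path-length
matrix C of a rooted tree with branch lengths (C_ij = depth of the most
recent common ancestor of tips i and j; diagonal = root-to-tip distance).
Values near 1 are consistent with Brownian motion on the tree; values
near 0 indicate phylogenetic independence.

K is the ratio of observed to C⁻¹-weighted mean squared error, scaled by
its Brownian-motion expectation (computed analytically from tr(C) and the
GLS normalization), with significance from tip-label permutations.
λ rescales the off-diagonal of C and is estimated by maximizing the
multivariate-normal likelihood over [0, λ_max], with significance from a
likelihood-ratio test against λ = 0 (χ², 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SignalResult",
    "tree_vcv",
    "blomberg_k",
    "pagel_lambda",
]


@dataclass
class SignalResult:
    statistic: str  # "K" | "lambda"
    estimate: float
    p_value: float
    n_tips: int
    method: str
    log_likelihood: float | None = None


def tree_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared-path-length (phylogenetic variance-covariance) matrix.

    C_ij is the root-to-MRCA distance of tips i and j; C_ii the
    root-to-tip distance.  Missing branch lengths count as 0.
    """
    tree = tree.clone(depth=1)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    C = np.zeros((n, n))

    def depth(node) -> float:
        d, p = 0.0, node
        while p.parent_node is not None:
            d += p.edge.length or 0.0
            p = p.parent_node
        return d

    # postorder: each internal node's depth covers all cross-child tip pairs
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [index[id(node)]]
            C[node._tipset[0], node._tipset[0]] = depth(node)
            continue
        children = [c._tipset for c in node.child_nodes()]
        d = depth(node)
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = d
        node._tipset = [i for ts in children for i in ts]
    return pd.DataFrame(C, index=labels, columns=labels)


def _align(C: pd.DataFrame, trait: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    tips = set(C.index)
    names = set(trait.index)
    if tips != names:
        missing = sorted(tips ^ names)
        raise ValueError(f"tip labels and trait names differ: {missing[:10]}")
    order = list(C.index)
    return C.to_numpy(dtype=float), trait.loc[order].to_numpy(dtype=float)


def _mse_ratio(C_inv: np.ndarray, ones: np.ndarray, x: np.ndarray) -> float:
    """MSE0/MSE with the GLS (phylogenetic) mean, up to the common n-1."""
    denom = ones @ C_inv @ ones
    a_hat = (ones @ C_inv @ x) / denom
    r = x - a_hat
    mse0 = r @ r
    mse = r @ C_inv @ r
    return mse0 / mse


def blomberg_k(
    tree: dendropy.Tree | pd.DataFrame,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 uses raw deviations from
    the GLS mean, MSE the C⁻¹-weighted deviations, and the Brownian
    expectation is (tr C − n / (1'C⁻¹1)) / (n − 1).  The p-value is the
    add-one-smoothed proportion of permuted MSE0/MSE ratios at or above
    the observed one.
    """
    C_df = tree if isinstance(tree, pd.DataFrame) else tree_vcv(tree)
    C, x = _align(C_df, trait)
    n = len(x)
    C_inv = np.linalg.inv(C)
    ones = np.ones(n)
    expected = (np.trace(C) - n / (ones @ C_inv @ ones)) / (n - 1)
    observed = _mse_ratio(C_inv, ones, x)
    k = (observed / expected)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _mse_ratio(C_inv, ones, rng.permutation(x)) >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return SignalResult("K", float(k), float(p), n, f"permutation({n_perm})")


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _neg_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    Cl = _lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Cl_inv = np.linalg.inv(Cl)
    ones = np.ones(n)
    a_hat = (ones @ Cl_inv @ x) / (ones @ Cl_inv @ ones)
    r = x - a_hat
    sigma2 = (r @ Cl_inv @ r) / n
    if sigma2 <= 0:
        return np.inf
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return -ll


def _max_lambda(C: np.ndarray, cap: float = 1.1) -> float:
    """Largest λ (≤ cap) keeping the transformed matrix positive-definite."""
    lam = cap
    while lam > 1.0:
        try:
            np.linalg.cholesky(_lambda_transform(C, lam))
            return lam
        except np.linalg.LinAlgError:
            lam -= 0.01
    return 1.0


def pagel_lambda(
    tree: dendropy.Tree | pd.DataFrame,
    trait: pd.Series,
) -> SignalResult:
    """Maximum-likelihood Pagel's λ with a LRT against λ = 0.

    The off-diagonal of C is scaled by λ ∈ [0, λ_max] (λ_max keeps C
    positive-definite, capped at 1.1) and the profile MVN likelihood is
    maximized by bounded scalar optimization (xatol 1e-8).
    """
    C_df = tree if isinstance(tree, pd.DataFrame) else tree_vcv(tree)
    C, x = _align(C_df, trait)
    n = len(x)
    try:
        np.linalg.cholesky(_lambda_transform(C, 0.0))
    except np.linalg.LinAlgError:
        raise ValueError("C at lambda=0 is not positive-definite")

    lam_max = _max_lambda(C)
    res = optimize.minimize_scalar(
        _neg_loglik, args=(C, x), bounds=(0.0, lam_max), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the optimizer can miss a boundary optimum; check endpoints explicitly
    for cand in (0.0, lam_max):
        ll_c = -_neg_loglik(cand, C, x)
        if ll_c > ll_hat:
            lam_hat, ll_hat = cand, ll_c
    ll0 = -_neg_loglik(0.0, C, x)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return SignalResult("lambda", lam_hat, p, n, "LRT(chi2, 1df)", log_likelihood=ll_hat)
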
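"""Climate-niche classification from a PCA of bioclimatic variables.

Ecotypes are ordinated on the correlation-matrix PCA of their 19
temperature/precipitation variables; the first axis (PC1) is signed so
that colder climates score positively (a designated anchor variable —
by default the coldest-quarter mean temperature, bio11 — loads
negatively), and ecotypes are classed cold (PC1 > +cutoff), warm
(PC1 < −cutoff) or mesic (between), with cutoff 2.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NicheClassification", "climate_pc1_classes"]

DEFAULT_CUTOFF = 2.5
DEFAULT_ANCHOR = "bio11"


@dataclass
class NicheClassification:
    scores: pd.Series          # ecotype -> PC1 score
    classes: pd.Series         # ecotype -> {cold, mesic, warm}
    variance_explained: float  # fraction of total variance on PC1
    loadings: pd.Series        # variable -> PC1 loading


def climate_pc1_classes(
    climate: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    anchor_var: str = DEFAULT_ANCHOR,
) -> NicheClassification:
    """Classify ecotype climate niches by their PC1 score.

    Columns are standardized (mean 0, sd 1, ddof=1), the correlation
    matrix is eigendecomposed, and scores are projections on the leading
    eigenvector.  Constant columns are dropped with a warning.  The axis
    sign is fixed by requiring the anchor variable (negated) to load
    positively; if the anchor is absent, the variable with the largest
    absolute loading is made to load positively instead.
    """
    if len(climate) < 3:
        raise ValueError("need >= 3 ecotypes")
    values = climate.astype(float)
    constant = values.columns[values.std(ddof=1) == 0]
    if len(constant):
        warnings.warn(f"dropping constant columns: {list(constant)}", stacklevel=2)
        values = values.drop(columns=list(constant))
    if values.shape[1] < 2:
        raise ValueError("need >= 2 variables with nonzero variance")

    z = (values - values.mean()) / values.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]

    loadings = pd.Series(v1, index=values.columns)
    if anchor_var in loadings.index:
        if loadings[anchor_var] > 0:  # cold anchor must load negatively
            v1, loadings = -v1, -loadings
    else:
        top = loadings.abs().idxmax()
        if loadings[top] < 0:
            v1, loadings = -v1, -loadings

    scores = pd.Series(z.to_numpy() @ v1, index=values.index, name="pc1")
    classes = pd.Series(
        np.select(
            [scores > cutoff, scores < -cutoff], ["cold", "warm"], default="mesic"
        ),
        index=values.index,
        name="climate_class",
    )
    return NicheClassification(
        scores=scores,
        classes=classes,
        variance_explained=float(eigvals[0] / eigvals.sum()),
        loadings=loadings,
    )
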
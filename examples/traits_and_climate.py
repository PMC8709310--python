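"""Drought trait responses, trait~expression regression, climate classes.

Couples the twelve phenotypic traits linearly to dehydrin expression
(positive slopes for proline, root allocation, WUE, leaf C and C/N;
negative for leaf water contents and leaf N), summarizes drought-induced
trait changes, regresses a trait on expression, and classes ecotype
climate niches from the PCA of 19 bioclimatic variables.
"""

import pandas as pd

from dhnkit import (
    climate_pc1_classes,
    fit_trait_expression_regression,
    trait_change_summary,
)
from dhnkit import simulate as sim

# ecotype-level expression under W and D driving the traits
rows, vals = [], []
for e in range(1, 25):
    rows += [(f"eco{e:02d}", "W"), (f"eco{e:02d}", "D")]
    vals += [10.0 + 0.2 * e, 16.0 + 0.2 * e]
expr = pd.Series(vals, index=pd.MultiIndex.from_tuples(rows))

traits = sim.gen_trait_table(expr, noise_sd=0.8, seed=2)
summary = trait_change_summary(traits)
print(summary.round(3).to_string(index=False))

res = fit_trait_expression_regression(
    traits[traits.treatment == "D"].groupby("ecotype")["pro"].mean(),
    expr.xs("D", level=1), trait="pro", gene="Bdhn3")
print(f"\npro ~ expression: slope={res.slope:.2f}, R2={res.r_squared:.2f}, "
      f"p={res.p_value:.2g} (planted slope 1.0)")

clim, _ = sim.gen_climate_table(54, seed=3)
niche = climate_pc1_classes(clim)
print(f"\nclimate PC1 explains {niche.variance_explained:.0%} of variance; "
      f"classes: {niche.classes.value_counts().to_dict()}")
print("PC1 > 2.5 = cold, < -2.5 = warm, else mesic.")
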
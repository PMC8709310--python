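"""Phylogenetic signal of a continuous trait: Blomberg's K and Pagel's λ.

Simulates a 30-tip Yule tree with a trait evolved under Brownian motion
(λ = 1) and an independent trait (λ = 0), and tests both statistics.
Values near 1 mean trait variation tracks the tree; near 0 means
phylogenetic independence.
"""

from dhnkit import blomberg_k, pagel_lambda, tree_vcv
from dhnkit import simulate as sim

for lam_true in (1.0, 0.0):
    tree, trait = sim.gen_tree_with_trait(n_tips=30, lambda_true=lam_true, seed=8)
    C = tree_vcv(tree)
    k = blomberg_k(C, trait, n_perm=999, seed=8)
    lam = pagel_lambda(C, trait)
    print(f"simulated lambda={lam_true:.0f}:  "
          f"K={k.estimate:.3f} (perm p={k.p_value:.3f})   "
          f"lambda_hat={lam.estimate:.3f} (LRT p={lam.p_value:.3g})")

print("\nUnder Brownian motion lambda_hat sits at 1 and both tests are")
print("significant (K is unbiased around 1 but varies widely on any single")
print("tree); for the independent trait both estimates collapse toward 0 and")
print("stay non-significant.")
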
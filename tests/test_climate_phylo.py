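"""Climate-niche PCA classes and phylogenetic signal statistics."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from dhnkit import simulate as sim
from dhnkit.climate import climate_pc1_classes
from dhnkit.phylosignal import blomberg_k, pagel_lambda, tree_vcv

FIXTURE_NEWICK = "((t1:1.0,t2:1.0):2.0,((t3:0.5,t4:0.5):1.5,t5:2.0):1.0);"

# Blomberg K on the 5-tip fixture, cross-checked against an independent
# implementation of the same matrix formula (phytools::phylosig agrees to
# 1e-10 on both trait vectors).
FIXTURE_TRAIT_A = {"t1": 1.2, "t2": 0.9, "t3": -0.4, "t4": -0.1, "t5": 2.3}
FIXTURE_K_A = 1.0931088603
FIXTURE_TRAIT_B = {"t1": 1.2, "t2": -0.6, "t3": -0.4, "t4": 0.8, "t5": 2.3}
FIXTURE_K_B = 0.5513031951


def dense_k_oracle(C: np.ndarray, x: np.ndarray) -> float:
    """Blomberg's K by direct dense algebra, independent of the package."""
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = one @ Ci @ x / (one @ Ci @ one)
    r = x - a
    ratio = (r @ r) / (r @ Ci @ r)
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return ratio / expected


def iid_loglik(x: np.ndarray, scale: np.ndarray) -> float:
    """Closed-form MVN log-likelihood for diagonal covariance s2*diag(scale)
    with the GLS mean and profiled s2 (the lambda=0 limit)."""
    n = len(x)
    w = 1.0 / scale
    a = (w * x).sum() / w.sum()
    r = x - a
    s2 = (r * r * w).sum() / n
    logdet = np.log(scale).sum()
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


@pytest.fixture(scope="module")
def fixture_C():
    tree = dendropy.Tree.get(data=FIXTURE_NEWICK, schema="newick")
    return tree_vcv(tree)


class TestTreeVcv:
    def test_fixture_matrix(self, fixture_C):
        C = fixture_C
        assert C.loc["t1", "t2"] == 2.0
        assert C.loc["t3", "t4"] == 2.5
        assert C.loc["t3", "t5"] == 1.0
        assert C.loc["t1", "t5"] == 0.0
        assert np.allclose(np.diag(C), 3.0)
        assert np.allclose(C, C.T)

    def test_psd(self, fixture_C):
        eig = np.linalg.eigvalsh(fixture_C.to_numpy())
        assert (eig > -1e-10).all()


class TestBlombergK:
    @pytest.mark.parametrize("trait,expected", [
        (FIXTURE_TRAIT_A, FIXTURE_K_A),
        (FIXTURE_TRAIT_B, FIXTURE_K_B),
    ])
    def test_fixture_values_and_dense_oracle(self, fixture_C, trait, expected):
        x = pd.Series(trait)
        res = blomberg_k(fixture_C, x, n_perm=9, seed=0)
        oracle = dense_k_oracle(fixture_C.to_numpy(),
                                x.loc[fixture_C.index].to_numpy())
        assert res.estimate == pytest.approx(oracle, abs=1e-12)
        assert res.estimate == pytest.approx(expected, abs=1e-9)

    def test_affine_invariance(self, fixture_C):
        x = pd.Series(FIXTURE_TRAIT_A)
        k1 = blomberg_k(fixture_C, x, n_perm=5, seed=1).estimate
        k2 = blomberg_k(fixture_C, 3.5 * x - 11.0, n_perm=5, seed=1).estimate
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_permutation_p_reproducible(self, fixture_C):
        x = pd.Series(FIXTURE_TRAIT_A)
        p1 = blomberg_k(fixture_C, x, n_perm=199, seed=7).p_value
        p2 = blomberg_k(fixture_C, x, n_perm=199, seed=7).p_value
        assert p1 == p2

    def test_mismatched_labels_error(self, fixture_C):
        x = pd.Series({"t1": 1.0, "t2": 2.0, "t3": 0.5, "t4": 1.5, "tX": 0.0})
        with pytest.raises(ValueError, match="tX"):
            blomberg_k(fixture_C, x, n_perm=5, seed=0)

    def test_bm_calibration_mean_near_one(self):
        ks = []
        for s in range(200):
            tree, trait = sim.gen_tree_with_trait(30, 1.0, seed=1000 + s)
            ks.append(blomberg_k(tree_vcv(tree), trait, n_perm=1, seed=0).estimate)
        assert np.mean(ks) == pytest.approx(1.0, abs=0.15)

    def test_independent_trait_p_uniformish(self):
        """Permutation p for iid traits should be non-significant most of
        the time (nominal type-I control)."""
        sig = 0
        for s in range(40):
            tree, trait = sim.gen_tree_with_trait(20, 0.0, seed=3000 + s)
            p = blomberg_k(tree_vcv(tree), trait, n_perm=99, seed=s).p_value
            sig += p <= 0.05
        assert sig <= 7  # ~5% expected


class TestPagelLambda:
    def test_lambda_zero_equals_iid_closed_form(self, fixture_C):
        x = pd.Series(FIXTURE_TRAIT_B)
        res = pagel_lambda(fixture_C, x)
        xv = x.loc[fixture_C.index].to_numpy()
        ll0 = iid_loglik(xv, np.diag(fixture_C.to_numpy()))
        # lambda-hat is ~0 here, so the fitted log-likelihood matches the
        # iid limit
        assert res.estimate == pytest.approx(0.0, abs=1e-3)
        assert res.log_likelihood == pytest.approx(ll0, abs=1e-6)

    def test_loglik_at_optimum_beats_endpoints(self):
        for s in (1, 2, 3):
            tree, trait = sim.gen_tree_with_trait(15, 0.5, seed=400 + s)
            C = tree_vcv(tree)
            res = pagel_lambda(C, trait)
            from dhnkit.phylosignal import _max_lambda, _neg_loglik
            Cn = C.to_numpy()
            xv = trait.loc[C.index].to_numpy()
            for lam in (0.0, _max_lambda(Cn)):
                assert res.log_likelihood >= -_neg_loglik(lam, Cn, xv) - 1e-9

    def test_bm_recovery_mean_near_one(self):
        lams = [
            pagel_lambda(tree_vcv(t), x).estimate
            for t, x in (sim.gen_tree_with_trait(30, 1.0, seed=5000 + s)
                         for s in range(60))
        ]
        assert np.mean(lams) > 0.85

    def test_independent_recovery_near_zero(self):
        lams, sig = [], 0
        for s in range(60):
            tree, trait = sim.gen_tree_with_trait(30, 0.0, seed=6000 + s)
            res = pagel_lambda(tree_vcv(tree), trait)
            lams.append(res.estimate)
            sig += res.p_value <= 0.05
        assert np.mean(lams) < 0.15
        assert sig <= 9  # LRT at nominal rate

    def test_lambda_bounds_validation(self):
        with pytest.raises(ValueError):
            sim.gen_tree_with_trait(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            sim.gen_tree_with_trait(10, -0.1, seed=0)
        with pytest.raises(ValueError):
            sim.gen_tree_with_trait(3, 0.5, seed=0)


class TestTreeTraitGenerator:
    def test_lambda_one_covariance_is_bm(self):
        tree, _ = sim.gen_tree_with_trait(12, 1.0, seed=9)
        C = tree_vcv(tree).to_numpy()
        cov = 1.0 * C.copy()
        np.fill_diagonal(cov, np.diag(C))
        assert np.allclose(cov, C)

    def test_determinism(self):
        t1, x1 = sim.gen_tree_with_trait(12, 0.7, seed=42)
        t2, x2 = sim.gen_tree_with_trait(12, 0.7, seed=42)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert x1.equals(x2)

    def test_ultrametric_and_positive_branches(self):
        tree, _ = sim.gen_tree_with_trait(25, 1.0, seed=77)
        C = tree_vcv(tree)
        assert np.allclose(np.diag(C), np.diag(C)[0])
        assert np.linalg.cond(C) < 1e9


class TestClimateClasses:
    def test_two_separated_clusters_opposite_signs(self):
        rng = np.random.default_rng(12)
        cold = rng.normal(0.0, 0.1, size=(5, 6)) + np.array([-3, -3, -3, 3, 3, 3])
        warm = rng.normal(0.0, 0.1, size=(5, 6)) - np.array([-3, -3, -3, 3, 3, 3])
        frame = pd.DataFrame(np.vstack([cold, warm]),
                             columns=[f"bio{i}" for i in (1, 2, 11, 12, 13, 14)],
                             index=[f"e{i}" for i in range(10)])
        res = climate_pc1_classes(frame)
        assert (res.scores.iloc[:5] > 0).all()
        assert (res.scores.iloc[5:] < 0).all()

    def test_variance_explained_definition(self):
        clim, _ = sim.gen_climate_table(30, seed=13)
        res = climate_pc1_classes(clim)
        z = (clim - clim.mean()) / clim.std(ddof=1)
        eig = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))
        assert res.variance_explained == pytest.approx(eig[-1] / eig.sum())

    def test_planted_gradient_recovery(self):
        clim, gradient = sim.gen_climate_table(54, loading=1.0, noise_sd=0.05,
                                               seed=14)
        res = climate_pc1_classes(clim)
        # PC1 tracks the latent cold-warm gradient almost perfectly, with
        # cold ecotypes (high gradient) scoring positive
        assert np.corrcoef(res.scores, gradient)[0, 1] > 0.999
        assert res.variance_explained > 0.95
        # class boundaries at +-2.5 recover the labels implied by the scores
        expected = np.select(
            [res.scores > 2.5, res.scores < -2.5], ["cold", "warm"], "mesic")
        assert (res.classes == expected).all()
        assert set(res.classes) == {"cold", "mesic", "warm"}

    def test_constant_column_dropped_with_warning(self):
        clim, _ = sim.gen_climate_table(10, seed=15)
        clim["bio1"] = 7.7
        with pytest.warns(UserWarning, match="constant"):
            res = climate_pc1_classes(clim)
        assert "bio1" not in res.loadings.index

    def test_too_few_ecotypes_errors(self):
        clim, _ = sim.gen_climate_table(10, seed=16)
        with pytest.raises(ValueError):
            climate_pc1_classes(clim.iloc[:2])
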
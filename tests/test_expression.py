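"""Nonparametric differential expression, BH correction, percent change."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dhnkit import simulate as sim
from dhnkit.expression import (
    _compact_letter_display,
    _ranksum_p,
    gene_correlation,
    kruskal_tukey,
    percent_change,
    validate_design,
    wilcoxon_de,
)


def exact_ranksum_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2
    stat = abs(observed - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= stat - 1e-9:
            count += 1
    return count / total


class TestRanksum:
    def test_identical_groups_p_one(self):
        assert _ranksum_p(np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0])) == 1.0

    def test_fully_separated_4v4_exact(self):
        p = _ranksum_p(np.array([1.0, 2.0, 3.0, 4.0]), np.array([10.0, 11.0, 12.0, 13.0]))
        assert p == pytest.approx(2 / 70)

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 4), (5, 3), (8, 8)])
    def test_exact_matches_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(3):
            a = rng.normal(size=n_a)
            b = rng.normal(0.5, size=n_b)
            assert _ranksum_p(a, b) == pytest.approx(exact_ranksum_oracle(a, b))


class TestWilcoxonDE:
    def test_planted_effects_survive_bh(self):
        truth = sim.default_expression_truth(n_ecotypes=16, n_replicates=4,
                                             dispersion=0.2, seed=21)
        tpm, design = sim.gen_expression_matrix(truth)
        de = wilcoxon_de(tpm, design, "WD").set_index("gene")
        strong = [g for g, th in truth.drought_effect.items() if th >= 0.39]
        for gene in strong:
            assert de.loc[gene, "significant"]
            assert de.loc[gene, "direction"] == 1
        decoys = [g for g, th in truth.drought_effect.items() if th == 0.0]
        assert sum(de.loc[g, "significant"] for g in decoys) <= 1

    def test_bh_adjustment_properties(self):
        truth = sim.default_expression_truth(n_ecotypes=6, n_replicates=3,
                                             dispersion=0.3, seed=22)
        tpm, design = sim.gen_expression_matrix(truth)
        de = wilcoxon_de(tpm, design, "WD").sort_values("raw_p").reset_index()
        m = len(de)
        assert (de["bh_adjusted_p"] >= de["raw_p"] - 1e-12).all()
        assert de["bh_adjusted_p"].is_monotonic_increasing
        # BH formula: monotonized min of p * m / rank, capped at 1
        manual = np.minimum.accumulate(
            (de["raw_p"] * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(de["bh_adjusted_p"], np.minimum(manual, 1.0))

    def test_label_permutation_destroys_significance(self):
        truth = sim.default_expression_truth(n_ecotypes=12, n_replicates=4,
                                             dispersion=0.2, seed=23)
        tpm, design = sim.gen_expression_matrix(truth)
        rng = np.random.default_rng(0)
        shuffled = design.copy()
        shuffled["water"] = rng.permutation(shuffled["water"].to_numpy())
        de = wilcoxon_de(tpm, shuffled, "WD")
        assert de["significant"].sum() == 0

    def test_missing_design_column_named(self):
        truth = sim.default_expression_truth(4, 2, 0.1, seed=1)
        tpm, design = sim.gen_expression_matrix(truth)
        with pytest.raises(ValueError, match="temperature"):
            validate_design(tpm, design.drop(columns="temperature"))

    def test_unknown_contrast_errors(self):
        truth = sim.default_expression_truth(4, 2, 0.1, seed=1)
        tpm, design = sim.gen_expression_matrix(truth)
        with pytest.raises(ValueError, match="contrast"):
            wilcoxon_de(tpm, design, "XY")


class TestKruskalTukey:
    def test_hand_enumerated_h_statistic(self):
        # three groups of three, no ties: H = 12/(N(N+1)) * sum n(Rbar - R)^2
        groups = {"e1": [1.0, 2.0, 3.0], "e2": [4.0, 5.0, 6.0], "e3": [7.0, 8.0, 9.0]}
        values = [v for g in groups.values() for v in g]
        ranks = stats.rankdata(values)
        n, N = 3, 9
        h_manual = 12 / (N * (N + 1)) * sum(
            n * (ranks[i * 3:(i + 1) * 3].mean() - (N + 1) / 2) ** 2 for i in range(3)
        )
        tpm = pd.DataFrame({f"{e}_D_r{i}": [v] for e, vs in groups.items()
                            for i, v in enumerate(vs)}, index=["g1"])
        design = pd.DataFrame(
            [{"sample": f"{e}_D_r{i}", "ecotype": e, "water": "D",
              "temperature": "C", "replicate": i}
             for e, vs in groups.items() for i in range(3)]
        ).set_index("sample")
        omnibus, _ = kruskal_tukey(tpm, design)
        assert omnibus.loc[0, "H"] == pytest.approx(h_manual)

    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(31)
        samples = {f"e{e}_D_r{i}": [10.0 + rng.normal(0, 0.5)]
                   for e in range(1, 5) for i in range(4)}
        tpm = pd.DataFrame(samples, index=["g1"])
        design = pd.DataFrame(
            [{"sample": s, "ecotype": s.split("_")[0], "water": "D",
              "temperature": "C", "replicate": int(s[-1])} for s in samples]
        ).set_index("sample")
        _, letters = kruskal_tukey(tpm, design)
        assert set(letters["letters"]) == {"a"}

    def test_shifted_ecotype_gets_distinct_letter(self):
        rng = np.random.default_rng(32)
        samples = {}
        for e in range(1, 5):
            shift = 50.0 if e == 4 else 0.0
            for i in range(4):
                samples[f"e{e}_D_r{i}"] = [10.0 + shift + rng.normal(0, 0.5)]
        tpm = pd.DataFrame(samples, index=["g1"])
        design = pd.DataFrame(
            [{"sample": s, "ecotype": s.split("_")[0], "water": "D",
              "temperature": "C", "replicate": int(s[-1])} for s in samples]
        ).set_index("sample")
        _, letters = kruskal_tukey(tpm, design)
        lt = letters.set_index("ecotype")["letters"]
        assert set(lt.loc["e4"]).isdisjoint(set("".join(lt.loc[["e1", "e2", "e3"]])))

    def test_fewer_than_three_groups_errors(self):
        truth = sim.default_expression_truth(2, 3, 0.1, seed=2)
        tpm, design = sim.gen_expression_matrix(truth)
        with pytest.raises(ValueError, match="3 ecotype groups"):
            kruskal_tukey(tpm, design)

    def test_cld_insert_absorb(self):
        letters = _compact_letter_display(
            ["a", "b", "c"], {("a", "c")})
        assert set(letters["a"]).isdisjoint(set(letters["c"]))
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])


class TestPercentChange:
    def test_exact_doubling_is_hundred_percent(self):
        truth = sim.SimExpressionTruth(
            gene_ids=("g1",), drought_effect={"g1": 1.0},
            baseline_tpm={"g1": 20.0}, dispersion=0.0,
            n_ecotypes=3, n_replicates=2, seed=0)
        tpm, design = sim.gen_expression_matrix(truth)
        per_gene, _ = percent_change(tpm, design)
        assert per_gene["g1"] == pytest.approx(100.0)

    def test_zero_effect_is_near_zero(self):
        truth = sim.SimExpressionTruth(
            gene_ids=("g1",), drought_effect={"g1": 0.0},
            baseline_tpm={"g1": 20.0}, dispersion=0.2,
            n_ecotypes=32, n_replicates=4, seed=33)
        tpm, design = sim.gen_expression_matrix(truth)
        per_gene, _ = percent_change(tpm, design)
        assert abs(per_gene["g1"]) < 6.0

    def test_zero_baseline_skipped_with_warning(self):
        tpm = pd.DataFrame(
            {"e1_W_r1": [0.0], "e1_W_r2": [0.0], "e1_D_r1": [5.0], "e1_D_r2": [5.0],
             "e2_W_r1": [10.0], "e2_W_r2": [10.0], "e2_D_r1": [20.0], "e2_D_r2": [20.0]},
            index=["g1"])
        design = pd.DataFrame(
            [{"sample": s, "ecotype": s.split("_")[0], "water": s.split("_")[1],
              "temperature": "C", "replicate": int(s[-1])} for s in tpm.columns]
        ).set_index("sample")
        with pytest.warns(UserWarning, match="zero baseline"):
            per_gene, detail = percent_change(tpm, design)
        assert len(detail) == 1
        assert per_gene["g1"] == pytest.approx(100.0)


class TestGeneCorrelation:
    def test_shared_ecotype_effect_detected(self):
        rng = np.random.default_rng(44)
        ecos = [f"e{i}" for i in range(12)]
        shared = {e: rng.normal(0, 0.5) for e in ecos}
        cols, rows = {}, []
        for e in ecos:
            for r in range(3):
                s = f"{e}_D_r{r}"
                cols[s] = [50 * np.exp(shared[e] + rng.normal(0, 0.05)),
                           80 * np.exp(shared[e] + rng.normal(0, 0.05)),
                           30 * np.exp(rng.normal(0, 0.05))]
                rows.append({"sample": s, "ecotype": e, "water": "D",
                             "temperature": "C", "replicate": r})
        tpm = pd.DataFrame(cols, index=["gA", "gB", "gC"])
        design = pd.DataFrame(rows).set_index("sample")
        corr = gene_correlation(tpm, design).set_index(["gene_a", "gene_b"])
        assert corr.loc[("gA", "gB"), "r"] > 0.8
        assert corr.loc[("gA", "gB"), "p"] < 0.01
        assert abs(corr.loc[("gA", "gC"), "r"]) < 0.5

    def test_zero_variance_flagged(self):
        tpm = pd.DataFrame(
            {f"e{i}_D_r{r}": [5.0, float(i + r)] for i in range(3) for r in range(2)},
            index=["flat", "var"])
        design = pd.DataFrame(
            [{"sample": c, "ecotype": c.split("_")[0], "water": "D",
              "temperature": "C", "replicate": int(c[-1])} for c in tpm.columns]
        ).set_index("sample")
        corr = gene_correlation(tpm, design)
        row = corr.set_index(["gene_a", "gene_b"]).loc[("flat", "var")]
        assert row["flag"] == "zero_variance"
        assert np.isnan(row["r"])
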
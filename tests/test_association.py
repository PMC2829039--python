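"""Tests of the differential (moderated t) and feature-association screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from colonymorph.association import (ModeratedTTest, PermutationAssociation,
                                     bh_fdr, collapse_replicates,
                                     linear_association, logistic_association,
                                     moderated_t_one_vs_rest, normalize_feature,
                                     permutation_pvalue, permutation_screen,
                                     squeeze_variances)
from helpers import bh_stepup, permutation_pvalue_exhaustive


class TestCollapseReplicates:
    def test_mean_and_median_and_identity(self):
        raw = pd.DataFrame({"a1": [2.0, 1.0], "a2": [4.0, 2.0], "a3": [0.0, 100.0],
                            "b1": [5.0, 5.0]})
        line_of = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        mean = collapse_replicates(raw, line_of, method="mean")
        assert mean.loc[0, "A"] == pytest.approx(2.0)
        med = collapse_replicates(raw, line_of, method="median")
        assert med.loc[1, "A"] == pytest.approx(2.0)
        assert med.loc[0, "B"] == 5.0  # single replicate unchanged

    def test_unmapped_column_raises(self):
        raw = pd.DataFrame({"a1": [1.0]})
        with pytest.raises(ValueError, match="no line assignment"):
            collapse_replicates(raw, {}, method="mean")


def _toy_expression(n_genes=200, n1=6, n2=6, effect_genes=(), effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(7.0, 0.5, size=(n_genes, n1 + n2))
    for g in effect_genes:
        X[g, :n1] += effect
    lines = [f"L{i}" for i in range(n1 + n2)]
    labels = {ln: (0 if i < n1 else 1) for i, ln in enumerate(lines)}
    return pd.DataFrame(X, index=[f"G{i}" for i in range(n_genes)],
                        columns=lines), labels


class TestModeratedT:
    def test_d0_zero_recovers_ordinary_t(self):
        expr, labels = _toy_expression(effect_genes=(0, 1))
        table = moderated_t_one_vs_rest(expr, labels, 0, d0_override=0.0)
        x1 = expr.iloc[:, :6].to_numpy()
        x2 = expr.iloc[:, 6:].to_numpy()
        t_ref = stats.ttest_ind(x1, x2, axis=1).statistic
        np.testing.assert_allclose(table["t"].reindex(expr.index), t_ref, rtol=1e-10)

    def test_d0_infinite_shrinks_every_variance_to_prior(self):
        expr, labels = _toy_expression()
        table = moderated_t_one_vs_rest(expr, labels, 0, d0_override=np.inf)
        np.testing.assert_allclose(table["s2_post"], table["s0_2"].iloc[0])
        # with equal standard errors the gene ordering is by |beta|
        assert (table["beta"].abs().is_monotonic_decreasing
                or table["p_value"].is_monotonic_increasing)

    def test_posterior_variance_between_prior_and_observed(self):
        expr, labels = _toy_expression()
        table = moderated_t_one_vs_rest(expr, labels, 0)
        lo = np.minimum(table["s2"], table["s0_2"])
        hi = np.maximum(table["s2"], table["s0_2"])
        assert ((table["s2_post"] >= lo - 1e-12) & (table["s2_post"] <= hi + 1e-12)).all()
        assert (table["fdr"] >= table["p_value"] - 1e-15).all()

    def test_prior_parameter_recovery_from_simulated_variances(self):
        # variances drawn from a scaled inverse chi-square prior (d0 = 4,
        # s0^2 = 0.05); the moment-matching estimator recovers both within 25%
        d0_true, s0_2_true, df = 4.0, 0.05, 22  # n = 12 vs 12
        for seed in range(10):
            rng = np.random.default_rng(seed)
            prior_var = d0_true * s0_2_true / rng.chisquare(d0_true, size=10_000)
            s2 = prior_var * rng.chisquare(df, size=10_000) / df
            d0_hat, s0_2_hat, _ = squeeze_variances(s2, df)
            assert d0_hat == pytest.approx(d0_true, rel=0.25)
            assert s0_2_hat == pytest.approx(s0_2_true, rel=0.25)

    def test_matches_limma_reference(self, tmp_path):
        # independent oracle: the reference R implementation of the moderated
        # t-statistic on a small two-group design
        import subprocess
        expr, labels = _toy_expression(n_genes=50, effect_genes=(0, 1, 2), seed=3)
        csv = tmp_path / "expr.csv"
        expr.to_csv(csv)
        rscript = tmp_path / "mod_t.R"
        rscript.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.csv("{csv}", row.names=1))\n'
            'design <- cbind(rest=1, target=rep(c(1,0), each=6))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(gene=rownames(x), t=fit$t[,"target"],'
            ' p=fit$p.value[,"target"], d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.csv(out, "{tmp_path / "out.csv"}", row.names=FALSE)\n')
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv").set_index("gene")
        table = moderated_t_one_vs_rest(expr, labels, 0).reindex(ref.index)
        np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(table["p_value"], ref["p"], rtol=1e-6)
        assert table["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert table["s0_2"].iloc[0] == pytest.approx(ref["s02"].iloc[0], rel=1e-4)

    def test_planted_genes_rank_first(self):
        expr, labels = _toy_expression(effect_genes=(3, 4, 5), effect=3.0, seed=1)
        table = moderated_t_one_vs_rest(expr, labels, 0)
        assert set(table.index[:3]) == {"G3", "G4", "G5"}

    def test_small_groups_rejected(self):
        expr, _ = _toy_expression(n1=1, n2=4)
        labels = {c: (0 if i < 1 else 1) for i, c in enumerate(expr.columns)}
        with pytest.raises(ValueError, match=">= 2 lines"):
            moderated_t_one_vs_rest(expr, labels, 0)

    def test_estimator_wrapper(self):
        expr, labels = _toy_expression(effect_genes=(0,), seed=2)
        model = ModeratedTTest(target_cluster=0)
        model.fit(expr.T.to_numpy(), [labels[c] for c in expr.columns],
                  feature_names=list(expr.index), sample_names=list(expr.columns))
        assert model.results_.index[0] == "G0"
        assert model.d0_ > 0


class TestLinearAssociation:
    def test_exact_positive_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        a, b, r, r2 = linear_association(x, 2 * x + 1)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))
        assert (a, b) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_exact_negative_line(self):
        x = np.array([0.0, 1.0, 2.0])
        _, _, r, _ = linear_association(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        _, _, r, r2 = linear_association([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert r2 == pytest.approx(0.64)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            linear_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogisticAssociation:
    def test_exact_logistic_relationship_inverts_to_r_one(self):
        x = np.linspace(-2, 2, 9)
        y = 1.0 / (1.0 + np.exp(-x))
        a, b, r = logistic_association(x, y)
        assert r == pytest.approx(1.0)
        assert b == pytest.approx(1.0)
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_feature_normalization_bounds(self):
        y = normalize_feature(np.array([3.0, 5.0, 10.0]), eps=1e-3)
        assert y.min() == pytest.approx(1e-3)
        assert y.max() == pytest.approx(1 - 1e-3)
        with pytest.raises(ValueError, match="constant"):
            normalize_feature(np.array([2.0, 2.0]))

    def test_out_of_range_feature_rejected(self):
        with pytest.raises(ValueError, match="strictly in"):
            logistic_association([1.0, 2.0, 3.0], np.array([0.0, 0.5, 1.0]))


class TestPermutationPvalue:
    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 6))  # up to 5 lines, 120 permutations
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = float(np.corrcoef(x, y)[0, 1])
            p = permutation_pvalue(r, x, y, exhaustive=True)
            assert p == pytest.approx(permutation_pvalue_exhaustive(x, y), abs=1e-12)

    def test_sign_taxonomy_counting_rule(self):
        # positive r counts permuted r >= observed; negative r counts <=
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r_obs = float(np.corrcoef(x, y)[0, 1])
        p = permutation_pvalue(r_obs, x, y, M=500, seed=2)
        rng2 = np.random.default_rng(2)
        rs = np.array([float(np.corrcoef(x, y[rng2.permutation(5)])[0, 1])
                       for _ in range(500)])
        expected = np.mean(rs >= r_obs) if r_obs >= 0 else np.mean(rs <= r_obs)
        assert p == pytest.approx(expected)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="M"):
            permutation_pvalue(0.5, np.arange(4.0), np.arange(4.0), M=0)


class TestBHFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.02, 0.03, 0.5]),
                                   [0.02, 0.04, 0.04, 0.5])

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_direct_stepup_computation(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr([0.5, 1.2])


class TestPermutationScreen:
    def test_null_rejection_rate_reflects_sign_conditioning(self):
        # The taxonomy assigns each gene its one-sided test in the direction
        # of the observed correlation, so under the null the taxonomy p-value
        # is Uniform(0, 1/2) and the rejection rate at nominal alpha is
        # 2 * alpha: with 10,000 null genes and M = 1000 the fraction of
        # genes with p < 0.05 is 0.10, not 0.05.
        rng = np.random.default_rng(0)
        G, L = 10_000, 24
        expr = pd.DataFrame(rng.normal(size=(G, L)),
                            index=[f"G{i}" for i in range(G)],
                            columns=[f"L{i}" for i in range(L)])
        feature = pd.Series(rng.normal(size=L), index=expr.columns)
        table = permutation_screen(expr, feature, link="linear", M=1000, seed=1)
        frac = float((table["p_value"] < 0.05).mean())
        assert frac == pytest.approx(0.10, abs=0.015)

    def test_planted_zero_noise_genes_attain_floor_and_rank_first(
            self, tiny_study_zero_noise):
        study = tiny_study_zero_noise
        M = 1000
        lin = permutation_screen(study.expression, study.line_size,
                                 link="linear", M=M, seed=0)
        planted = study.truth_genes.query("role == 'size_linked' and link == 'linear'")
        for g in planted["gene_id"]:
            assert lin.loc[g, "p_value"] <= 1.0 / M
        assert lin.index[0] in set(planted["gene_id"]) | set(
            study.truth_genes.query("link == 'logistic'")["gene_id"])

    def test_logistic_screen_recovers_logistic_genes(self, tiny_study_zero_noise):
        study = tiny_study_zero_noise
        table = permutation_screen(study.expression, study.line_size,
                                   link="logistic", M=500, seed=0)
        planted = set(study.truth_genes.query("link == 'logistic'")["gene_id"])
        assert planted <= set(table.index[:10])
        assert (table.loc[sorted(planted), "taxonomy"] == "positive").all()

    def test_estimator_wrapper(self, tiny_study_zero_noise):
        study = tiny_study_zero_noise
        model = PermutationAssociation(link="linear", n_permutations=200,
                                       random_state=0)
        model.fit(study.expression.T.to_numpy(),
                  study.line_size.to_numpy(),
                  feature_names=list(study.expression.index),
                  sample_names=list(study.expression.columns))
        assert {"r", "p_value", "fdr", "taxonomy"} <= set(model.results_.columns)
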
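"""Normalization, moderated/paired testing and FDR adjustment.

The moderated t machinery is cross-checked against the Bioconductor
limma implementation (via Rscript) on a small matrix — an independent
route through the same empirical-Bayes model.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats

from myelinlfq.de_stats import (
    ModerationPrior,
    _trigamma_inverse,
    adjust_fdr,
    fit_moderation_prior,
    log2_transform,
    moderated_t_test,
    paired_t_test,
    pooled_variances,
    quantile_normalize,
    storey_pi0,
)
from myelinlfq.errors import ConfigError, PipelineOrderError, TransformError
from myelinlfq.types import IntensityMatrix, SampleDesign


def _mat(arr, columns, scale="log2", index=None):
    df = pd.DataFrame(arr, columns=columns)
    if index is not None:
        df.index = index
    return IntensityMatrix(df, scale)


class TestTransforms:
    def test_log2_examples(self):
        m = _mat([[8.0, 1.0]], ["a", "b"], scale="raw")
        out = log2_transform(m)
        assert out.values.iloc[0].tolist() == [3.0, 0.0]
        assert out.scale == "log2"

    def test_log2_preserves_missing(self):
        m = _mat([[8.0, np.nan]], ["a", "b"], scale="raw")
        assert np.isnan(log2_transform(m).values.iloc[0, 1])

    def test_log2_rejects_nonpositive_naming_cell(self):
        m = IntensityMatrix(
            pd.DataFrame([[2.0, 0.0]], index=["prot7"], columns=["a", "b"]), "raw"
        )
        with pytest.raises(TransformError, match="prot7"):
            log2_transform(m)

    def test_quantile_normalize_worked_example(self):
        m = _mat(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), ["a", "b"])
        out = quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert out.values["a"].tolist() == expected
        assert out.values["b"].tolist() == expected

    def test_quantile_normalize_fixed_point_and_single_column(self):
        same = _mat(np.array([[5.0, 5.0], [1.0, 1.0]]), ["a", "b"])
        pd.testing.assert_frame_equal(quantile_normalize(same).values, same.values)
        single = _mat(np.array([[3.0], [1.0], [2.0]]), ["a"])
        pd.testing.assert_frame_equal(quantile_normalize(single).values, single.values)

    def test_quantile_normalize_requires_complete_matrix(self):
        m = _mat([[1.0, np.nan], [2.0, 3.0]], ["a", "b"])
        with pytest.raises(PipelineOrderError):
            quantile_normalize(m)

    def test_quantile_normalize_equalizes_columns(self):
        rng = np.random.default_rng(3)
        m = _mat(rng.normal(20, 3, (50, 4)), list("abcd"))
        out = quantile_normalize(m).values
        means = out.mean(axis=0)
        assert np.allclose(means, means.iloc[0], atol=1e-9)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        # rank order preserved within columns
        for c in out.columns:
            assert (out[c].rank() == m.values[c].rank()).all()


class TestModerationPrior:
    def test_trigamma_inverse_identity(self):
        assert _trigamma_inverse(float(special.polygamma(1, 3.0))) == pytest.approx(3.0, abs=1e-8)

    def test_identical_variances_give_infinite_d0(self):
        prior = fit_moderation_prior(np.full(1000, 0.25), df_residual=4)
        assert np.isinf(prior.d0)
        # bias-corrected location: exp(log s^2 - digamma(df/2) + log(df/2))
        expected = np.exp(np.log(0.25) - special.digamma(2.0) + np.log(2.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_parameter_recovery_from_scaled_inverse_chisquare(self):
        """d0 within +-25% and s0^2 within +-10%, mean over 10 seeds."""
        d0_true, s0_true, df = 4.0, 0.05, 4
        d0s, s0s = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
            s2 = sigma2 * rng.chisquare(df, 5000) / df
            prior = fit_moderation_prior(s2, df)
            d0s.append(prior.d0)
            s0s.append(prior.s0_sq)
        assert np.mean(d0s) == pytest.approx(d0_true, rel=0.25)
        assert np.mean(s0s) == pytest.approx(s0_true, rel=0.10)

    def test_degenerate_all_zero_variances_rejected(self):
        with pytest.raises(Exception):
            fit_moderation_prior(np.zeros(100), 4)


class TestModeratedT:
    @staticmethod
    def _random_experiment(seed=0, n=40):
        rng = np.random.default_rng(seed)
        design = SampleDesign.from_groups(
            {"young": ["y1", "y2", "y3"], "old": ["o1", "o2", "o3"]}
        )
        vals = pd.DataFrame(
            rng.normal(20, 2, (n, 6)),
            index=[f"P{i:03d}" for i in range(n)],
            columns=design.samples,
        )
        return IntensityMatrix(vals, "normalized"), design

    def test_zero_d0_limit_equals_ordinary_pooled_t(self):
        matrix, design = self._random_experiment(1)
        de = moderated_t_test(matrix, design, ModerationPrior(d0=0.0, s0_sq=1.0))
        assert np.allclose(de["t_moderated"], de["t_ordinary"], atol=1e-12)
        # and matches scipy's pooled two-sample t
        ref = stats.ttest_ind(
            matrix.values[design.samples_in("old")],
            matrix.values[design.samples_in("young")],
            axis=1, equal_var=True,
        )
        assert np.allclose(de["t_moderated"], ref.statistic, atol=1e-10)

    def test_infinite_d0_full_shrinkage(self):
        matrix, design = self._random_experiment(2)
        de = moderated_t_test(matrix, design, ModerationPrior(d0=np.inf, s0_sq=0.7))
        assert np.allclose(de["s_post_sq"], 0.7)

    def test_posterior_variance_between_sample_and_prior(self):
        matrix, design = self._random_experiment(3)
        s_sq, df = pooled_variances(matrix, design)
        prior = fit_moderation_prior(s_sq, df)
        de = moderated_t_test(matrix, design, prior)
        lo = np.minimum(de["s_sq"], prior.s0_sq)
        hi = np.maximum(de["s_sq"], prior.s0_sq)
        assert ((de["s_post_sq"] >= lo - 1e-12) & (de["s_post_sq"] <= hi + 1e-12)).all()

    def test_log2fc_is_old_minus_young(self):
        design = SampleDesign.from_groups({"young": ["y1", "y2"], "old": ["o1", "o2"]})
        m = _mat([[1.0, 1.0, 3.0, 3.0]], design.samples, scale="normalized")
        de = moderated_t_test(m, design, ModerationPrior(d0=1.0, s0_sq=0.5))
        assert de["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_agrees_with_limma_reference_implementation(self, tmp_path):
        """Independent oracle: Bioconductor limma's lmFit + eBayes on the
        same matrix must give the same prior, posterior variances,
        moderated t and p (to numerical tolerance)."""
        matrix, design = self._random_experiment(7, n=80)
        s_sq, df = pooled_variances(matrix, design)
        prior = fit_moderation_prior(s_sq, df)
        de = moderated_t_test(matrix, design, prior)

        tsv = tmp_path / "mat.tsv"
        matrix.values.to_csv(tsv, sep="\t")
        rscript = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("%s", row.names = 1))
            groups <- factor(c("young","young","young","old","old","old"),
                             levels = c("young","old"))
            design <- model.matrix(~groups)
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                              s2post = fit$s2.post)
            cat(fit$df.prior, fit$s2.prior, "\\n")
            write.table(out, "%s", sep = "\\t", quote = FALSE)
            """
            % (tsv, tmp_path / "limma_out.tsv")
        )
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        d0_r, s0_r = map(float, proc.stdout.split()[:2])
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t", index_col=0)
        assert prior.d0 == pytest.approx(d0_r, rel=1e-6)
        assert prior.s0_sq == pytest.approx(s0_r, rel=1e-6)
        assert np.allclose(de["s_post_sq"], ref["s2post"], rtol=1e-10)
        assert np.allclose(de["t_moderated"], ref["t"], rtol=1e-10)
        assert np.allclose(de["p"], ref["p"], rtol=1e-8)

    def test_null_type_one_error_calibrated(self):
        """Fraction of p < 0.05 on a pure-null simulation stays near 0.05."""
        rates = []
        for seed in range(5):
            matrix, design = self._random_experiment(seed, n=2000)
            s_sq, df = pooled_variances(matrix, design)
            prior = fit_moderation_prior(s_sq, df)
            de = moderated_t_test(matrix, design, prior)
            rates.append((de["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)


class TestPairedT:
    @staticmethod
    def _paired(diffs, base=20.0):
        n = len(diffs)
        design = SampleDesign.paired([f"m{i}" for i in range(1, n + 1)])
        pairs = design.pair_table()
        vals = pd.DataFrame(index=["P1"], columns=design.samples, dtype=float)
        for pid, d in zip(pairs.index, diffs):
            vals.loc["P1", pairs.loc[pid, "intact"]] = base
            vals.loc["P1", pairs.loc[pid, "crush"]] = base + d
        return IntensityMatrix(vals, "log2"), design

    def test_all_zero_differences(self):
        m, design = self._paired([0.0, 0.0, 0.0])
        de = paired_t_test(m, design)
        assert de["t"].iloc[0] == 0.0
        assert de["p"].iloc[0] == 1.0

    def test_constant_nonzero_differences_flagged(self):
        m, design = self._paired([1.0, 1.0, 1.0, 1.0])
        de = paired_t_test(m, design)
        assert de["zero_variance"].iloc[0]
        assert de["p"].iloc[0] == 1.0

    def test_worked_example_diffs_1_2_3(self):
        m, design = self._paired([1.0, 2.0, 3.0])
        de = paired_t_test(m, design)
        assert de["t"].iloc[0] == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert de["p"].iloc[0] == pytest.approx(0.0742, abs=5e-4)

    def test_incomplete_pairs_dropped_pairwise(self):
        m, design = self._paired([1.0, 2.0, 3.0, 4.0])
        m.values.loc["P1", design.pair_table().iloc[0]["crush"]] = np.nan
        de = paired_t_test(m, design)
        assert de["n_pairs"].iloc[0] == 3


class TestFdr:
    def test_bh_worked_example(self):
        q, pi0 = adjust_fdr(np.array([0.01, 0.02, 0.03]), "bh")
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert pi0 is None

    def test_single_p_value(self):
        q, _ = adjust_fdr(np.array([0.2]), "bh")
        assert q[0] == pytest.approx(0.2)

    def test_storey_is_bh_scaled_by_pi0(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 500)
        q_bh, _ = adjust_fdr(p, "bh")
        q_st, pi0 = adjust_fdr(p, "storey")
        assert 0 < pi0 <= 1
        assert np.allclose(q_st, np.minimum(q_bh * pi0, 1.0))

    def test_storey_pi0_near_one_on_uniform_null(self):
        rng = np.random.default_rng(0)
        assert storey_pi0(rng.uniform(0, 1, 5000)) == pytest.approx(1.0, abs=0.05)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ConfigError):
            adjust_fdr(np.array([0.5, 0.0]), "bh")

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=40))
    def test_bh_q_monotone_in_p_and_at_least_p(self, pvals):
        p = np.array(pvals)
        q, _ = adjust_fdr(p, "bh")
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
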
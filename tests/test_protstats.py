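"""Proteomics statistics: filtering, normalization, imputation, moderated t."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lysoquant.protstats import (
    ImputationParams,
    bh_adjust,
    class_enrichment,
    filter_valid,
    impute,
    moderated_t,
    one_sample_t,
    quantile_normalize,
    relative_band_abundance,
)


def _design(n_a=5, n_b=5):
    samples = [f"lyso_{i}" for i in range(n_a)] + [f"PNS_{i}" for i in range(n_b)]
    return pd.DataFrame({"sample": samples, "condition": ["lyso"] * n_a + ["PNS"] * n_b})


class TestFilterValid:
    def test_rule_examples(self):
        design = _design()
        row_kept = [1.0] * 4 + [np.nan] + [np.nan] * 5  # 4/5 lyso, 0/5 PNS
        row_dropped = [1.0] * 3 + [np.nan] * 2 + [1.0] * 3 + [np.nan] * 2  # 3/5 both
        m = pd.DataFrame([row_kept, row_dropped], index=["keep", "drop"], columns=design["sample"])
        out = filter_valid(m, design)
        assert list(out.index) == ["keep"]

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(0)
        design = _design()
        m = pd.DataFrame(
            rng.normal(20, 2, (300, 10)), columns=design["sample"],
            index=[f"P{i}" for i in range(300)],
        ).mask(rng.random((300, 10)) < 0.4)
        out = filter_valid(m, design)
        for pid in m.index:
            frac_a = m.loc[pid, design["sample"][:5]].notna().mean()
            frac_b = m.loc[pid, design["sample"][5:]].notna().mean()
            assert (pid in out.index) == (frac_a >= 0.7 or frac_b >= 0.7)


class TestQuantileNormalize:
    def test_two_by_two_definition_oracle(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [1.5, 3.5])
        np.testing.assert_allclose(out["b"], [1.5, 3.5])

    def test_identical_columns_are_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_idempotent_on_complete_matrices(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(20, 3, (50, 4)), columns=list("abcd"))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_columns_acquire_identical_sorted_values(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(20, 3, (40, 3)), columns=list("abc"))
        out = quantile_normalize(m)
        ref = np.sort(out["a"].to_numpy())
        for col in "bc":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)

    def test_rank_order_within_column_preserved(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("abc"))
        m["c"] = np.exp(m["c"])  # monotone transform of one sample
        out = quantile_normalize(m)
        for col in m:
            assert (out[col].rank() == m[col].rank()).all()

    def test_missing_entries_stay_missing(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 4.0, np.nan]})
        out = quantile_normalize(m)
        assert out.isna().equals(m.isna())

    def test_groupwise_normalization_preserves_between_group_shift(self):
        rng = np.random.default_rng(4)
        base = rng.normal(20, 2, 200)
        m = pd.DataFrame({
            "a1": base + rng.normal(0, 0.1, 200),
            "a2": base + rng.normal(0, 0.1, 200),
            "b1": base + 3 + rng.normal(0, 0.1, 200),
            "b2": base + 3 + rng.normal(0, 0.1, 200),
        })
        out = quantile_normalize(m, groups={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        shift = out[["b1", "b2"]].mean().mean() - out[["a1", "a2"]].mean().mean()
        assert shift == pytest.approx(3.0, abs=0.1)


class TestImpute:
    def test_no_missing_returns_matrix_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        pd.testing.assert_frame_equal(impute(m, ImputationParams(seed=1)), m)

    def test_lfq_moments_converge_to_downshifted_narrowed_normal(self):
        """Imputed values approach Normal(mu - 1.8 sigma, (0.3 sigma)^2)."""
        rng = np.random.default_rng(5)
        observed = rng.normal(25.0, 2.0, 4000)
        col = np.concatenate([observed, np.full(40000, np.nan)])
        m = pd.DataFrame({"s": col})
        out = impute(m, ImputationParams(seed=6))
        imputed = out["s"].to_numpy()[4000:]
        mu, sigma = observed.mean(), observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sigma, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.03)

    def test_silac_mode_centers_on_zero(self):
        rng = np.random.default_rng(7)
        col = np.concatenate([rng.normal(0.0, 1.0, 2000), np.full(20000, np.nan)])
        m = pd.DataFrame({"s": col})
        out = impute(m, ImputationParams(mode="silac", seed=8))
        imputed = out["s"].to_numpy()[2000:]
        sigma = np.nanstd(col, ddof=1)
        assert imputed.mean() == pytest.approx(0.0, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.05)

    def test_determinism_and_seed_isolation(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(20, 2, (60, 3)), columns=list("abc")).mask(
            rng.random((60, 3)) < 0.2
        )
        out1 = impute(m, ImputationParams(seed=3))
        out2 = impute(m, ImputationParams(seed=3))
        out3 = impute(m, ImputationParams(seed=4))
        pd.testing.assert_frame_equal(out1, out2)
        diff = (out1 != out3) & out1.notna()
        assert diff.to_numpy().any()
        # observed positions untouched in every case
        pd.testing.assert_frame_equal(out1[m.notna()], m[m.notna()])
        pd.testing.assert_frame_equal(out3[m.notna()], m[m.notna()])

    def test_sample_with_too_few_observed_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="'a'"):
            impute(m, ImputationParams(seed=1))


def _bh_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * n / j, capped."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    for rank, idx in enumerate(order, start=1):
        adj[idx] = min(min(p[order[j - 1]] * n / j for j in range(rank, n + 1)), 1.0)
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=6)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_definition_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for n in (5, 50, 500):
            p = rng.random(n)
            p[: n // 5] = p[n // 5 : 2 * (n // 5)]  # inject ties
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_at_least_input_and_bounded(self):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestModeratedT:
    @staticmethod
    def _fixture(n=50, seed=7):
        rng = np.random.default_rng(seed)
        sd = rng.gamma(2.0, 0.25, n)
        values = rng.normal(0, 1, (n, 8)) * sd[:, None] + rng.normal(20, 2, n)[:, None]
        m = pd.DataFrame(values, index=[f"P{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(8)])
        design = pd.DataFrame({"sample": m.columns, "condition": ["A"] * 4 + ["B"] * 4})
        return m, design

    def test_d0_zero_reduces_to_ordinary_pooled_t(self):
        from scipy import stats

        m, design = self._fixture()
        res = moderated_t(m, design, ("A", "B"), d0_override=0.0)
        ref = stats.ttest_ind(m.iloc[:, :4], m.iloc[:, 4:], axis=1, equal_var=True)
        assert np.abs(res["t_mod"].to_numpy() - ref.statistic).max() < 1e-9
        assert np.abs(res["p_value"].to_numpy() - ref.pvalue).max() < 1e-9

    def test_d0_infinite_shrinks_every_variance_to_prior(self):
        m, design = self._fixture()
        res = moderated_t(m, design, ("A", "B"), d0_override=np.inf)
        assert res["s2_post"].nunique() == 1

    def test_posterior_variance_between_prior_and_sample(self):
        m, design = self._fixture()
        res = moderated_t(m, design, ("A", "B"))
        lo = np.minimum(res["s2"], res["s2_prior"])
        hi = np.maximum(res["s2"], res["s2_prior"])
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()
        assert (res["adj_p_value"] >= res["p_value"] - 1e-15).all()

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_matches_limma_reference_implementation(self, tmp_path):
        m, design = self._fixture()
        m.to_csv(tmp_path / "m.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(file.path('%s', 'm.csv'), row.names=1))
            design <- cbind(A=c(rep(1,4),rep(0,4)), B=c(rep(0,4),rep(1,4)))
            fit <- eBayes(contrasts.fit(lmFit(m, design),
                                        makeContrasts(A-B, levels=design)))
            write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior,
                                 s02=fit$s2.prior),
                      file.path('%s', 'r.csv'))
            """
            % (tmp_path, tmp_path)
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "oracle.R")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "r.csv", index_col=0)
        res = moderated_t(m, design, ("A", "B"))
        assert np.abs(res["t_mod"].to_numpy() - ref["t"].to_numpy()).max() < 1e-6
        assert np.abs(res["p_value"].to_numpy() - ref["p"].to_numpy()).max() < 1e-6
        assert res["df_prior"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res["s2_prior"].iloc[0] == pytest.approx(ref["s02"].iloc[0], rel=1e-6)

    def test_planted_effects_recovered_with_power(self):
        """log2 effects of 2.0 at n=4/4, sigma=0.5: |bias| < 0.1, power > 0.9."""
        rng = np.random.default_rng(12)
        n, n_hit = 1000, 100
        values = rng.normal(0, 0.5, (n, 8)) + 20.0
        values[:n_hit, :4] += 2.0
        m = pd.DataFrame(values, index=[f"P{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(8)])
        design = pd.DataFrame({"sample": m.columns, "condition": ["A"] * 4 + ["B"] * 4})
        res = moderated_t(m, design, ("A", "B"))
        assert res["log2fc"].iloc[:n_hit].mean() == pytest.approx(2.0, abs=0.1)
        power = (res["adj_p_value"].iloc[:n_hit] < 0.05).mean()
        assert power > 0.9

    def test_incomplete_matrix_rejected(self):
        m, design = self._fixture()
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            moderated_t(m, design, ("A", "B"))


class TestOneSampleT:
    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        x = rng.normal(1.3, 0.4, 9)
        t, p = one_sample_t(x, popmean=1.0)
        ref = stats.ttest_1samp(x, 1.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestClassEnrichment:
    def test_identical_fractions_give_unit_folds(self):
        design = _design(3, 3)
        rng = np.random.default_rng(14)
        col = rng.normal(20, 2, 50)
        m = pd.DataFrame({s: col for s in design["sample"]},
                         index=[f"P{i}" for i in range(50)])
        classes = pd.Series(["lysosomal"] * 10 + ["other"] * 40, index=m.index)
        out = class_enrichment(m, classes, design)
        for fold in out["class_fold"].values():
            assert fold == pytest.approx(1.0)

    def test_cutoff_rule_matches_brute_force(self):
        design = _design(3, 3)
        rng = np.random.default_rng(15)
        m = pd.DataFrame(rng.normal(20, 3, (80, 6)), columns=design["sample"],
                         index=[f"P{i}" for i in range(80)])
        classes = pd.Series(["other"] * 80, index=m.index)
        out = class_enrichment(m, classes, design)
        e = m.iloc[:, :3].mean(axis=1) - m.iloc[:, 3:].mean(axis=1)
        pd.testing.assert_series_equal(out["lysosomal_call"], e > 2.0, check_names=False)

    def test_missing_background_class_rejected(self):
        design = _design(2, 2)
        m = pd.DataFrame(np.ones((4, 4)), columns=design["sample"])
        classes = pd.Series(["lysosomal"] * 4, index=m.index)
        with pytest.raises(ValueError):
            class_enrichment(m, classes, design)


class TestRelativeBandAbundance:
    def test_target_doubling_detected(self):
        out = relative_band_abundance(
            target={"control": 1.0, "torin1": 2.0},
            references={"control": [1.0, 1.0], "torin1": [1.0, 1.0]},
            control="control",
        )
        assert out["control"] == pytest.approx(1.0)
        assert out["torin1"] == pytest.approx(2.0)

    def test_loading_control_logic(self):
        out = relative_band_abundance(
            target={"control": 1.0, "torin1": 2.0},
            references={"control": [1.0, 3.0], "torin1": [2.0, 6.0]},
            control="control",
        )
        assert out["torin1"] == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_band_abundance(
                target={"control": 1.0}, references={"control": [0.0, 2.0]}, control="control"
            )
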
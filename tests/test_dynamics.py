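import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma

from pol3dyn import dynamics as dyn


def one_way_design(n_reps=2, levels=("TP0", "TP36", "TP48", "TP60")):
    samples = [f"{l}_r{r}" for l in levels for r in range(1, n_reps + 1)]
    lev = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
    return samples, dyn.design_matrix(lev, list(levels))


class TestLinearModel:
    def test_level_means_and_pooled_variance_by_hand(self):
        samples, X = one_way_design()
        Y = pd.DataFrame([[0, 2, 3, 5, 0, 0, 0, 0]], columns=samples,
                         index=["L1"])
        fit = dyn.fit_linear_model(Y, X)
        assert list(fit.coef.loc["L1"]) == pytest.approx([1, 4, 0, 0])
        # residuals 2 + 2 + 0 + 0 pooled over 4 df
        assert fit.s2["L1"] == pytest.approx(1.0)
        assert fit.df_resid == 4

    def test_equal_replicates_give_zero_variance(self):
        samples, X = one_way_design()
        Y = pd.DataFrame([[5, 5, 7, 7, 1, 1, 2, 2]], columns=samples)
        fit = dyn.fit_linear_model(Y, X)
        assert fit.s2.iloc[0] == pytest.approx(0.0)

    def test_invariant_to_sample_order(self, rng):
        samples, X = one_way_design()
        Y = pd.DataFrame(rng.normal(size=(5, 8)), columns=samples)
        shuffled = list(rng.permutation(samples))
        a = dyn.fit_linear_model(Y, X)
        b = dyn.fit_linear_model(Y[shuffled], X)
        pd.testing.assert_frame_equal(a.coef, b.coef)
        pd.testing.assert_series_equal(a.s2, b.s2)

    def test_zero_residual_df_errors(self):
        samples, X = one_way_design(n_reps=1)
        Y = pd.DataFrame(np.ones((3, 4)), columns=samples)
        with pytest.raises(ValueError, match="degrees of freedom"):
            dyn.fit_linear_model(Y, X)


class TestEBayes:
    def test_parameter_recovery_from_hierarchical_draws(self):
        rng = np.random.default_rng(42)
        d0, s20, d, m = 4.0, 1.0, 4, 10_000
        sigma2 = s20 * d0 / rng.chisquare(d0, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        prior = dyn.ebayes_moderate(s2, d)
        assert prior.d_0 == pytest.approx(d0, rel=0.2)
        assert prior.s2_0 == pytest.approx(s20, rel=0.1)

    def test_identical_variances_give_degenerate_prior(self):
        s2 = np.full(50, 0.25)
        prior = dyn.ebayes_moderate(s2, df_resid=4)
        assert np.isinf(prior.d_0)
        assert prior.s2_0 == pytest.approx(0.25)
        assert prior.posterior_s2(s2, 4)[0] == pytest.approx(0.25)

    def test_zero_prior_df_reduces_to_ordinary_t(self, rng):
        samples, X = one_way_design()
        Y = pd.DataFrame(rng.normal(size=(20, 8)), columns=samples)
        fit = dyn.fit_linear_model(Y, X)
        res = dyn.contrast_test(fit, dyn.EBayesPrior(s2_0=1.0, d_0=0.0),
                                "TP36-TP0")
        est = fit.coef["TP36"] - fit.coef["TP0"]
        ordinary = est / np.sqrt(fit.s2 * 1.0)  # v_c = 1/2 + 1/2
        np.testing.assert_allclose(res["t"], ordinary, rtol=1e-10)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            dyn.ebayes_moderate(np.zeros(100), 4)

    @pytest.mark.parametrize("heteroskedastic", [False, True],
                             ids=["common-variance", "spread-variances"])
    def test_matches_limma_reference(self, rng, tmp_path, heteroskedastic):
        """Independent cross-check of the whole moderated-t route against
        the Bioconductor reference implementation, hitting both the finite
        and the degenerate (infinite) prior-df branches."""
        samples, X = one_way_design()
        noise_sd = 0.3
        if heteroskedastic:
            noise_sd = np.exp(rng.normal(-1.2, 0.8, (250, 1)))
        Y = pd.DataFrame(
            rng.normal(0, 1, (250, 8)) * noise_sd + rng.normal(0, 1, (250, 1)),
            columns=samples,
        )
        Y.iloc[:50, 2:4] += 1.0
        y_path = tmp_path / "y.tsv"
        Y.to_csv(y_path, sep="\t")
        fit = dyn.fit_linear_model(Y, X)
        prior = dyn.ebayes_moderate(fit.s2.to_numpy(), fit.df_resid)
        res = dyn.contrast_test(fit, prior, "TP36-TP0")
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.delim('{y_path}', row.names=1))
tp <- sub('_r[0-9]+$', '', colnames(y))
design <- model.matrix(~0+factor(tp, levels=c('TP0','TP36','TP48','TP60')))
colnames(design) <- c('TP0','TP36','TP48','TP60')
eb <- eBayes(contrasts.fit(lmFit(y, design),
                           makeContrasts(TP36-TP0, levels=design)))
out <- data.frame(t=eb$t[,1], p=eb$p.value[,1],
                  d0=eb$df.prior, s20=eb$s2.prior)
write.table(out, '{tmp_path / "r.tsv"}', sep='\\t', quote=FALSE)
""")
        assert shutil.which("Rscript"), "Rscript not on PATH"
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(res["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], atol=1e-8)
        assert prior.d_0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert prior.s2_0 == pytest.approx(ref["s20"].iloc[0], rel=1e-6)


class TestContrast:
    def test_zero_estimate_gives_p_one(self):
        samples, X = one_way_design()
        Y = pd.DataFrame([[1.0] * 8], columns=samples)
        fit = dyn.fit_linear_model(Y, X)
        res = dyn.contrast_test(fit, dyn.EBayesPrior(0.5, 4.0), "TP36-TP0")
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_location_invariance_per_locus(self, rng):
        samples, X = one_way_design()
        Y = pd.DataFrame(rng.normal(size=(10, 8)), columns=samples)
        fit1 = dyn.fit_linear_model(Y, X)
        shifts = rng.normal(size=(10, 1)) * 5
        fit2 = dyn.fit_linear_model(Y + shifts, X)
        p1 = dyn.ebayes_moderate(fit1.s2.to_numpy(), fit1.df_resid)
        p2 = dyn.ebayes_moderate(fit2.s2.to_numpy(), fit2.df_resid)
        r1 = dyn.contrast_test(fit1, p1, "TP36-TP0")
        r2 = dyn.contrast_test(fit2, p2, "TP36-TP0")
        np.testing.assert_allclose(r1["t"], r2["t"], atol=1e-9)

    def test_unknown_level_errors(self):
        samples, X = one_way_design()
        fit = dyn.fit_linear_model(
            pd.DataFrame(np.ones((2, 8)), columns=samples), X)
        with pytest.raises(ValueError, match="TP99"):
            dyn.contrast_test(fit, dyn.EBayesPrior(1, 1), "TP99-TP0")

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(3)
        samples, X = one_way_design()
        Y = pd.DataFrame(rng.normal(0, 0.2, (4000, 8)), columns=samples)
        fit = dyn.fit_linear_model(Y, X)
        prior = dyn.ebayes_moderate(fit.s2.to_numpy(), fit.df_resid)
        res = dyn.contrast_test(fit, prior, "TP36-TP0")
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestQvalues:
    def test_all_p_one(self):
        q, pi0 = dyn.qvalues(np.ones(500))
        assert pi0 == pytest.approx(1.0)
        assert np.allclose(q, 1.0)

    def test_uniform_p_gives_pi0_near_one(self):
        rng = np.random.default_rng(8)
        pi0s = [dyn.estimate_pi0(rng.random(10_000)) for _ in range(3)]
        assert np.mean(pi0s) == pytest.approx(1.0, abs=0.05)
        assert all(0.9 <= v <= 1.0 for v in pi0s)

    def test_thirty_percent_signal_mixture(self):
        rng = np.random.default_rng(9)
        ests = []
        for _ in range(5):
            p = np.concatenate([
                stats.norm.sf(rng.normal(4, 1, 3000)), rng.random(7000)])
            ests.append(dyn.estimate_pi0(p))
        assert np.mean(ests) == pytest.approx(0.7, abs=0.05)

    def test_q_monotone_in_p(self, rng):
        p = rng.random(2000) ** 2
        q, _ = dyn.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_ranking_with_degenerate_prior_follows_estimate(self, rng):
        samples, X = one_way_design()
        Y = pd.DataFrame(rng.normal(0, 0.1, (30, 8)), columns=samples)
        fit = dyn.fit_linear_model(Y, X)
        prior = dyn.EBayesPrior(s2_0=0.01, d_0=np.inf)
        res = dyn.contrast_test(fit, prior, "TP36-TP0")
        by_t = res["t"].abs().sort_values(ascending=False).index
        by_est = res["estimate"].abs().sort_values(ascending=False).index
        assert list(by_t) == list(by_est)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dyn.qvalues(np.array([]))


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=25,
                max_size=120))
def test_qvalues_properties_hold_for_arbitrary_p(p):
    """q-values are in [0, 1], monotone in p, and never below pi0 * p."""
    p = np.asarray(p)
    q, pi0 = dyn.qvalues(p)
    assert 0 < pi0 <= 1
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= pi0 * p - 1e-12).all()
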
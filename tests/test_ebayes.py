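"""Empirical-Bayes moderated-t machinery: OLS fits, prior estimation, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma

from hpameth.ebayes import (
    VariancePrior,
    bh_fdr,
    estimate_prior,
    fit_probes,
    moderated_t,
    run_dmp,
    trigamma_inverse,
)
from hpameth.synthetic_cohort import CohortConfig, generate_cohort
from hpameth.preprocess import beta_to_m

from conftest import make_matrix


def _design(X: np.ndarray, names) -> pd.DataFrame:
    return pd.DataFrame(X, index=[f"S{j:03d}" for j in range(X.shape[0])], columns=names)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: q_i = min over p_j >= p_i of min(1, m p_j / rank_j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        q[i] = running_min
    return q


class TestFitProbes:
    def test_intercept_only_recovers_mean_and_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.3, size=(1, 25))
        m = make_matrix(y, scale="M")
        design = _design(np.ones((25, 1)), ["intercept"])
        fit = fit_probes(m, design, "intercept")
        assert fit["coef"].iloc[0] == pytest.approx(y.mean())
        assert fit["sigma2"].iloc[0] == pytest.approx(y.var(ddof=1))
        assert fit["df_resid"].iloc[0] == 24

    def test_perfect_fit_has_zero_residual_variance(self):
        x = np.arange(10, dtype=float)
        m = make_matrix(x[None, :], scale="M")
        design = _design(np.column_stack([np.ones(10), x]), ["intercept", "x"])
        fit = fit_probes(m, design, "x")
        assert fit["coef"].iloc[0] == pytest.approx(1.0)
        assert fit["sigma2"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
        Y = rng.normal(size=(7, 10))
        m = make_matrix(Y, scale="M")
        design = _design(X, ["intercept", "x1", "x2"])
        fit = fit_probes(m, design, "x1")
        xtx_inv = np.linalg.inv(X.T @ X)
        for g in range(7):
            beta = xtx_inv @ X.T @ Y[g]
            resid = Y[g] - X @ beta
            assert fit["coef"].iloc[g] == pytest.approx(beta[1], rel=1e-10)
            assert fit["sigma2"].iloc[g] == pytest.approx(resid @ resid / 7, rel=1e-10)
        assert fit["stdev_unscaled"].iloc[0] == pytest.approx(math.sqrt(xtx_inv[1, 1]))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        m = make_matrix(np.zeros((2, 8)), scale="M")
        with pytest.raises(ValueError, match="rank"):
            fit_probes(m, _design(X, ["intercept", "dup"]), "dup")

    def test_misaligned_samples_rejected(self):
        m = make_matrix(np.zeros((2, 5)), scale="M")
        design = pd.DataFrame({"intercept": np.ones(5)}, index=[f"X{i}" for i in range(5)])
        with pytest.raises(ValueError, match="sample ids"):
            fit_probes(m, design, "intercept")


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [1.0, 5.0, 0.5, 44.5])
    def test_inverts_known_points(self, x):
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-7)

    def test_round_trip_over_nine_decades(self):
        rng = np.random.default_rng(1)
        for y in 10 ** rng.uniform(-3, 3, size=200):
            x = trigamma_inverse(float(y))
            assert polygamma(1, x) == pytest.approx(y, rel=1e-8)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            trigamma_inverse(0.0)
        with pytest.raises(ValueError):
            trigamma_inverse(-1.0)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_prior_df(self):
        prior = estimate_prior(np.full(500, 0.04), 89)
        assert math.isinf(prior.df)
        # prior variance is exp(mean e_g): the common s2 times the log-scale
        # bias correction (d_g/2) / exp(psi(d_g/2)), about 1.011 at d_g = 89
        from scipy.special import digamma

        expected = 0.04 * (89 / 2) / math.exp(digamma(89 / 2))
        assert prior.var == pytest.approx(expected, rel=1e-12)
        assert prior.var == pytest.approx(0.04, rel=0.02)

    def test_recovers_hierarchical_parameters(self):
        rng = np.random.default_rng(7)
        G, d0, s02, dg = 5000, 4.0, 0.05, 89
        sigma2 = s02 * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(dg, G) / dg
        prior = estimate_prior(s2, dg)
        assert prior.df == pytest.approx(d0, rel=0.15)
        assert prior.var == pytest.approx(s02, rel=0.10)

    def test_two_probes_returns_finite_result(self):
        prior = estimate_prior(np.array([0.01, 0.05]), 10)
        assert prior.var > 0 and prior.df > 0

    def test_zero_variance_probes_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="zero residual"):
            prior = estimate_prior(np.array([0.0, 0.02, 0.03]), 10)
        assert prior.var > 0

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(5), 10)


class TestModeratedT:
    def _fits(self, seed=0, G=50, dg=20):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "coef": rng.normal(size=G),
                "stdev_unscaled": np.full(G, 0.3),
                "sigma2": rng.chisquare(dg, G) / dg * 0.05,
                "df_resid": float(dg),
            },
            index=[f"cg{i}" for i in range(G)],
        )

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        fits = self._fits()
        out = moderated_t(fits, VariancePrior(df=0.0, var=1.0))
        t_ols = fits["coef"] / (fits["stdev_unscaled"] * np.sqrt(fits["sigma2"]))
        assert np.allclose(out["t"], t_ols)
        p_ols = 2 * stats.t.sf(np.abs(t_ols), fits["df_resid"])
        assert np.allclose(out["p"], p_ols)

    def test_infinite_prior_df_uses_prior_variance_everywhere(self):
        fits = self._fits()
        out = moderated_t(fits, VariancePrior(df=math.inf, var=0.07))
        assert np.allclose(out["s2_post"], 0.07)
        # probes with equal coef / u get equal statistics regardless of s2
        fits2 = fits.copy()
        fits2["sigma2"] = fits["sigma2"].to_numpy()[::-1]
        out2 = moderated_t(fits2, VariancePrior(df=math.inf, var=0.07))
        assert np.allclose(out["t"], out2["t"])

    def test_posterior_variance_between_sample_and_prior(self):
        for seed in range(5):
            fits = self._fits(seed=seed)
            prior = VariancePrior(df=4.0, var=0.05)
            out = moderated_t(fits, prior)
            lo = np.minimum(fits["sigma2"], prior.var)
            hi = np.maximum(fits["sigma2"], prior.var)
            assert ((out["s2_post"] >= lo - 1e-15) & (out["s2_post"] <= hi + 1e-15)).all()

    def test_shrinkage_direction_of_t(self):
        fits = self._fits(seed=3)
        prior = VariancePrior(df=4.0, var=float(np.median(fits["sigma2"])))
        mod = moderated_t(fits, prior)
        t_ols = (fits["coef"] / (fits["stdev_unscaled"] * np.sqrt(fits["sigma2"]))).to_numpy()
        smaller = fits["sigma2"].to_numpy() < prior.var
        nonzero = fits["coef"].to_numpy() != 0
        assert (np.abs(mod["t"].to_numpy())[smaller & nonzero] < np.abs(t_ols)[smaller & nonzero]).all()
        larger = fits["sigma2"].to_numpy() > prior.var
        assert (np.abs(mod["t"].to_numpy())[larger & nonzero] > np.abs(t_ols)[larger & nonzero]).all()


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p))

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestRunDmp:
    def _cohort(self, seed=0, **kw):
        cfg = CohortConfig(seed=seed, **kw)
        beta, pheno, ann, truth = generate_cohort(cfg)
        m = beta_to_m(beta)
        cand = ann.loc[~ann["transcript"].str.startswith("BG_"), "probe_id"]
        return m.subset_probes(cand), pheno, ann, truth

    def test_output_covers_every_probe(self):
        m, pheno, *_ = self._cohort(seed=1)
        out = run_dmp(m, None, pheno, preset="dst")
        assert len(out) == m.values.shape[0]
        assert {"coef", "t", "p", "q"} <= set(out.columns)
        assert out["q"].ge(out["p"] - 1e-15).all()

    def test_invariant_to_probe_order(self):
        m, pheno, *_ = self._cohort(seed=2)
        out1 = run_dmp(m, None, pheno, preset="dst")
        shuffled = m.subset_probes(m.probe_ids[::-1])
        out2 = run_dmp(shuffled, None, pheno, preset="dst")
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_planted_probes_rank_first_with_small_p(self):
        hits = 0
        for seed in range(20):
            m, pheno, ann, _ = self._cohort(seed=seed, planted_effects={"AJ877169": 1.0})
            out = run_dmp(m, None, pheno, preset="dst")
            planted = ann.loc[ann["transcript"] == "AJ877169", "probe_id"]
            hits += (out.loc[planted, "p"] < 0.05).all()
        assert hits >= 19

    def test_missing_phenotype_values_dropped_with_count(self):
        m, pheno, *_ = self._cohort(seed=3)
        pheno = pheno.copy()
        pheno.iloc[0, pheno.columns.get_loc("cortisol_baseline")] = np.nan
        with pytest.warns(UserWarning, match="dropped 1 sample"):
            out = run_dmp(m, None, pheno, preset="dst")
        assert out.attrs["n_samples"] == len(pheno) - 1
        assert out.attrs["n_dropped_missing"] == 1

    def test_unknown_preset_and_empty_overlap_rejected(self):
        m, pheno, *_ = self._cohort(seed=4)
        with pytest.raises(ValueError, match="preset"):
            run_dmp(m, None, pheno, preset="nope")
        other = pheno.copy()
        other.index = [f"Z{i}" for i in range(len(other))]
        with pytest.raises(ValueError, match="overlap"):
            run_dmp(m, "dst_ns", other)

    def test_continuous_phenotype_supported(self):
        m, pheno, *_ = self._cohort(seed=5)
        out = run_dmp(m, None, pheno, preset="tsh_t4")
        assert out["p"].between(0, 1).all()
        assert out.attrs["covariates"] == ["hypersexuality", "il6"]
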
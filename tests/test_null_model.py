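"""Gamma-GLM null: triplet construction, fitting, p-values."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from p16mave import null_model as nm
from p16mave import simulate_celltag_control
from p16mave.null_model import (
    DegenerateInputError,
    FitError,
    NullModel,
    Triplet,
    build_triplets,
    fit_null,
    variant_log_pvalue,
    variant_pvalue,
)


def simulate_glm_triplets(rng, n, alpha, a, b, r_sd=0.8, p_center=0.05, p_sd=0.8):
    """Draw triplets straight from the null model (the generating law the
    fitter is supposed to recover)."""
    r_init = np.exp(rng.normal(0.0, r_sd, n))
    p_init = p_center * np.exp(rng.normal(0.0, p_sd, n))
    p_init = np.clip(p_init, 1e-6, 0.9)
    mu = r_init**a * p_init**b
    r_cf = rng.gamma(shape=alpha, scale=mu / alpha)
    return pd.DataFrame({"r_cf": r_cf, "r_init": r_init, "p_init": p_init})


class TestTriplets:
    @pytest.mark.parametrize(
        "n_experiments,n_barcodes,expected",
        [(3, 20, 1140), (1, 20, 380), (1, 2, 2)],
    )
    def test_triplet_counts(self, config, n_experiments, n_barcodes, expected):
        """k barcodes yield k(k-1) triplets per experiment: 380 per CellTag
        experiment and 1,140 across the triplicate."""
        tables = simulate_celltag_control(
            config, seed=5, n_experiments=n_experiments, n_barcodes=n_barcodes
        )
        assert len(build_triplets(tables)) == expected

    def test_zero_count_policy(self, control_tables):
        broken = [t.copy() for t in control_tables]
        broken[0].loc[0, "count_day9"] = 0
        build_triplets(broken)  # pseudocount default: fine
        with pytest.raises(DegenerateInputError):
            build_triplets(broken, pseudocount=None)

    def test_triplet_validation(self):
        with pytest.raises(DegenerateInputError):
            Triplet(r_cf=-1.0, r_init=1.0, p_init=0.05)
        with pytest.raises(DegenerateInputError):
            Triplet(r_cf=1.0, r_init=1.0, p_init=1.5)

    def test_assay_triplets_anchor_on_synonymous(self, toy_config):
        from p16mave import simulate_screen

        counts, _ = simulate_screen(toy_config, seed=3)
        trips = nm.assay_triplets(counts)
        # 19 missense triplets per residue x replicate
        assert len(trips) == toy_config.n_residues * 19
        assert (trips["p_init"] < 1).all() and (trips["p_init"] > 0).all()


class TestFit:
    def test_zero_effect_recovery(self, rng):
        """Constant-mean data: both exponents vanish (|a|, |b| < 0.05)."""
        frame = simulate_glm_triplets(rng, 1140, alpha=5.0, a=0.0, b=0.0)
        model = fit_null(frame)
        assert abs(model.exp_rinit) < 0.05
        assert abs(model.exp_pinit) < 0.05

    def test_parameter_recovery_within_ten_percent(self, rng):
        """alpha=5, a=1, b=0.5 at n=1,140 recovered within +-10% each."""
        frame = simulate_glm_triplets(rng, 1140, alpha=5.0, a=1.0, b=0.5)
        model = fit_null(frame)
        assert abs(model.shape - 5.0) / 5.0 < 0.10
        assert abs(model.exp_rinit - 1.0) < 0.10
        assert abs(model.exp_pinit - 0.5) / 0.5 < 0.10

    def test_fit_attains_likelihood_of_generating_parameters(self, rng):
        frame = simulate_glm_triplets(rng, 1140, alpha=5.0, a=1.0, b=0.5)
        model = fit_null(frame)
        mu_true = frame["r_init"] ** 1.0 * frame["p_init"] ** 0.5
        ll_true = stats.gamma.logpdf(
            frame["r_cf"], a=5.0, scale=mu_true / 5.0
        ).sum()
        assert model.log_likelihood >= ll_true - 1e-6

    def test_agrees_with_statsmodels_glm(self, rng):
        """Independent cross-check: statsmodels' gamma GLM with log link and
        no intercept finds the same exponents."""
        import statsmodels.api as sm

        frame = simulate_glm_triplets(rng, 800, alpha=8.0, a=0.9, b=0.3)
        model = fit_null(frame)
        X = np.column_stack([np.log(frame["r_init"]), np.log(frame["p_init"])])
        ref = sm.GLM(
            frame["r_cf"].to_numpy(),
            X,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        assert np.allclose([model.exp_rinit, model.exp_pinit], ref.params, atol=1e-6)

    def test_moments_shape_fallback(self, rng):
        frame = simulate_glm_triplets(rng, 1140, alpha=5.0, a=1.0, b=0.5)
        mom = fit_null(frame, shape_method="moments")
        ml = fit_null(frame, shape_method="ml")
        assert abs(mom.shape - ml.shape) / ml.shape < 0.25

    def test_too_few_triplets(self):
        with pytest.raises(FitError):
            fit_null(pd.DataFrame({"r_cf": [1.0] * 5, "r_init": [1.0] * 5, "p_init": [0.05] * 5}))

    def test_collinear_covariates_rejected(self, rng):
        r = np.exp(rng.normal(-2.0, 0.3, 100))
        # log p_init exactly proportional to log r_init -> rank deficient
        frame = pd.DataFrame({"r_cf": r, "r_init": r, "p_init": r**2})
        with pytest.raises(FitError):
            fit_null(frame)

    def test_model_json_round_trip(self, tmp_path, control_tables):
        model = fit_null(build_triplets(control_tables))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = NullModel.from_json(path)
        assert back == model


class TestPvalues:
    def test_erlang_closed_form(self):
        """Shape 2, mean 2 (scale 1) at r_cf = 2: upper tail e^-2 (1+2)."""
        model = NullModel(shape=2.0, exp_rinit=0.0, exp_pinit=0.0, intercept=math.log(2.0))
        t = Triplet(r_cf=2.0, r_init=1.0, p_init=0.05)
        assert variant_pvalue(t, model) == pytest.approx(3.0 * math.exp(-2.0), abs=1e-10)

    def test_full_upper_tail_at_zero(self):
        model = NullModel(shape=3.0, exp_rinit=1.0, exp_pinit=0.0)
        p = variant_pvalue(Triplet(r_cf=1e-12, r_init=1.0, p_init=0.05), model)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_monotone_tail(self):
        model = NullModel(shape=4.0, exp_rinit=1.0, exp_pinit=0.0)
        p2 = variant_pvalue(Triplet(2.0, 1.0, 0.05), model)
        p3 = variant_pvalue(Triplet(3.0, 1.0, 0.05), model)
        assert p3 < p2

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 17.0, 240.0])
    @pytest.mark.parametrize("mu,r", [(0.5, 0.8), (1.0, 1.4), (2.0, 5.0)])
    def test_tail_matches_numerical_integration(self, alpha, mu, r):
        """Agreement with direct integration of the gamma density to 1e-8."""
        model = NullModel(shape=alpha, exp_rinit=0.0, exp_pinit=0.0, intercept=math.log(mu))
        p = variant_pvalue(Triplet(r, 1.0, 0.05), model)
        quad, _ = integrate.quad(
            lambda x: stats.gamma.pdf(x, a=alpha, scale=mu / alpha), r, np.inf
        )
        assert p == pytest.approx(quad, abs=1e-8)

    def test_log_pvalue_consistent_and_underflow_safe(self):
        model = NullModel(shape=100.0, exp_rinit=0.0, exp_pinit=0.0)
        t_mod = Triplet(1.5, 1.0, 0.05)
        assert variant_log_pvalue(t_mod, model) == pytest.approx(
            math.log(variant_pvalue(t_mod, model)), rel=1e-9
        )
        t_far = Triplet(20.0, 1.0, 0.05)
        lp = variant_log_pvalue(t_far, model)
        assert lp < -500  # far below float underflow of exp(lp)
        assert math.isfinite(lp)


class TestStatisticalProperties:
    def test_scale_equivariance(self, config):
        """Multiplying every count by a constant leaves triplets, fit and
        p-values unchanged (with pseudocounting disabled)."""
        tables = simulate_celltag_control(config, seed=21)
        scaled = [t.assign(
            count_day9=t["count_day9"] * 7, count_confluent=t["count_confluent"] * 7
        ) for t in tables]
        t1 = build_triplets(tables, pseudocount=None)
        t2 = build_triplets(scaled, pseudocount=None)
        pd.testing.assert_frame_equal(t1, t2)
        m1, m2 = fit_null(t1), fit_null(t2)
        assert m1.shape == pytest.approx(m2.shape)
        tr = Triplet(*t1.iloc[0][["r_cf", "r_init", "p_init"]])
        assert variant_pvalue(tr, m1) == pytest.approx(variant_pvalue(tr, m2))

    def test_null_pvalues_uniform_on_fresh_data(self, config):
        """Calibration: p-values of fresh null triplets under a model fitted
        to independent null data are ~uniform (KS distance < 0.05, n=2000).

        Tolerance 0.05 covers residual estimation error in (alpha, a, b)
        from the 3x20 calibration design."""
        model = fit_null(build_triplets(simulate_celltag_control(config, seed=42)))
        fresh = build_triplets(simulate_celltag_control(config, seed=777, n_experiments=6))
        p = np.exp(nm.log_pvalues(fresh, model))[:2000]
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05
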
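import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tundradiv import (
    MixedAltitudeModel,
    ModelSpec,
    fit_mixed,
    lrt_quadratic,
    scale_interaction_fit,
    tukey_scale_contrasts,
)
from tundradiv.models import NESTING_THREE, NESTING_TWO


def survey_frame(seed, sd_m=0.0, sd_t=0.0, sd_s=0.0, resid=0.3,
                 beta=(1.0, 0.0015, -1.5e-6), family="gaussian",
                 n_m=3, n_t=4, n_s=5, n_p=5, station_alt=False):
    """Nested survey-shaped data with a known quadratic altitude response."""
    rng = np.random.default_rng(seed)
    rows = []
    b0, b1, b2 = beta
    for m in range(n_m):
        um = rng.normal(0, sd_m) if sd_m else 0.0
        for t in range(n_t):
            ut = rng.normal(0, sd_t) if sd_t else 0.0
            base = rng.uniform(700, 1500)
            for s in range(n_s):
                us = rng.normal(0, sd_s) if sd_s else 0.0
                alt = rng.uniform(700, 1500) if station_alt else base + rng.normal(0, 15)
                for p in range(n_p):
                    eta = b0 + b1 * alt + b2 * alt * alt + um + ut + us
                    if family == "gaussian":
                        y = eta + rng.normal(0, resid)
                    else:
                        y = rng.poisson(np.exp(eta))
                    rows.append(
                        {"mountain": f"M{m}", "transect": f"T{t}",
                         "station": f"S{s}", "plot": f"P{p}",
                         "altitude_m": alt, "y": y}
                    )
    return pd.DataFrame(rows)


class TestGaussianOracles:
    def test_zero_variance_limit_matches_ols(self):
        df = survey_frame(0, beta=(0.5, 0.002, -1.2e-6))
        fit = MixedAltitudeModel("y", 2, "gaussian", NESTING_THREE).fit(df)
        ac = df["altitude_m"] - df["altitude_m"].mean()
        X = np.column_stack([np.ones(len(df)), ac, ac**2])
        ols = sm.OLS(df["y"], X).fit()
        cen = [fit._centered["Intercept"], fit._centered["_alt_c"],
               fit._centered["_alt_c2"]]
        assert np.allclose(cen, ols.params, atol=1e-4)

    def test_constant_response_flat(self):
        df = survey_frame(1)
        df["y"] = 2.5
        fit = MixedAltitudeModel("y", 2, "gaussian", NESTING_THREE).fit(df)
        coef = fit.coefficients_.set_index("term")
        assert coef.loc["altitude", "estimate"] == pytest.approx(0.0, abs=1e-8)
        assert coef.loc["altitude_sq", "estimate"] == pytest.approx(0.0, abs=1e-10)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in fit.vc_.values())

    def test_relabeling_invariance(self):
        # thorough fits converge to the unique ML optimum, which cannot
        # depend on how groups are named
        df = survey_frame(2, sd_t=0.3, sd_s=0.2)
        fit1 = MixedAltitudeModel("y", 2, "gaussian", NESTING_THREE,
                                  thorough=True).fit(df)
        relabeled = df.copy()
        relabeled["mountain"] = relabeled["mountain"].map(
            {"M0": "zebra", "M1": "yak", "M2": "wolf"}
        )
        relabeled["station"] = "st_" + relabeled["station"]
        fit2 = MixedAltitudeModel("y", 2, "gaussian", NESTING_THREE,
                                  thorough=True).fit(relabeled)
        a = fit1.coefficients_["estimate"].to_numpy()
        b = fit2.coefficients_["estimate"].to_numpy()
        assert np.allclose(a, b, atol=1e-6)

    def test_quadratic_peak_recovery_median_within_100m(self):
        """True peak at 1000 m, station SD 0.3: median vertex error < 100 m."""
        errs = []
        for seed in range(20):
            b2 = -2.0e-6
            b1 = -2 * b2 * 1000.0
            df = survey_frame(seed, sd_s=0.3, resid=0.3, beta=(0.2, b1, b2),
                              n_p=2)
            fit = MixedAltitudeModel("y", 2, "gaussian", NESTING_THREE).fit(df)
            errs.append(abs(fit.peak_altitude_ - 1000.0))
        assert np.median(errs) < 100.0


class TestPoissonOracles:
    def test_zero_variance_limit_matches_glm(self):
        df = survey_frame(3, beta=(1.2, 0.001, -6e-7), family="poisson", n_p=2)
        fit = MixedAltitudeModel("y", 2, "poisson", NESTING_THREE).fit(df)
        ac = df["altitude_m"] - df["altitude_m"].mean()
        X = np.column_stack([np.ones(len(df)), ac, ac**2])
        glm = sm.GLM(df["y"], X, family=sm.families.Poisson()).fit()
        cen = [fit._centered["Intercept"], fit._centered["_alt_c"],
               fit._centered["_alt_c2"]]
        assert np.allclose(cen, glm.params.to_numpy(), atol=1e-4)
        assert fit.loglik_ <= glm.llf + 1e-3

    def test_variance_recovered_when_present(self):
        df = survey_frame(4, sd_s=0.5, beta=(1.5, 0.0008, -5e-7),
                          family="poisson", n_p=3)
        fit = MixedAltitudeModel("y", 2, "poisson", NESTING_THREE).fit(df)
        assert fit.vc_["station"] > 0.05

    def test_non_count_response_rejected(self):
        df = survey_frame(5)
        with pytest.raises(ValueError):
            MixedAltitudeModel("y", 1, "poisson", NESTING_THREE).fit(df)


class TestLRT:
    def test_identical_fits_give_zero_chi_square(self):
        from tundradiv.models import likelihood_ratio

        res = likelihood_ratio(-123.45, -123.45)
        assert res.chi_square == 0.0 and res.p == 1.0
        # small negative differences are convergence noise, clamped
        res = likelihood_ratio(-123.4505, -123.45)
        assert res.chi_square == 0.0
        from tundradiv.models import ConvergenceError

        with pytest.raises(ConvergenceError):
            likelihood_ratio(-130.0, -123.45)

    def test_strong_curvature_detected(self):
        hits = 0
        for seed in range(10):
            df = survey_frame(seed + 100, sd_s=0.2, resid=0.2,
                              beta=(0.2, 1.6e-2, -8e-6))
            res = lrt_quadratic(ModelSpec("y"), df)
            hits += res.p < 0.001
        assert hits >= 9

    def test_chi_square_nonnegative_p_valid(self):
        df = survey_frame(7, sd_t=0.3, sd_s=0.3)
        res = lrt_quadratic(ModelSpec("y"), df)
        assert res.chi_square >= 0.0
        assert 0.0 <= res.p <= 1.0
        assert res.df == 1


def distance_frame(seed, shift=(0.0, 0.17, 0.22), curvature=(0.0, 0.0, 0.0),
                   n_m=3, n_t=3, n_s=3, n_p=3, resid=0.1):
    """Beta-diversity-shaped data: one row per plot per scale."""
    rng = np.random.default_rng(seed)
    rows = []
    scales = ["station", "transect", "landscape"]
    for m in range(n_m):
        for t in range(n_t):
            base = rng.uniform(700, 1500)
            for s in range(n_s):
                us = rng.normal(0, 0.05)
                alt = base + rng.normal(0, 15)
                for p in range(n_p):
                    for sc, mu, curv in zip(scales, shift, curvature):
                        y = (0.3 + mu + curv * (alt - 1000.0) ** 2
                             + us + rng.normal(0, resid))
                        rows.append(
                            {"mountain": f"M{m}", "transect": f"T{t}",
                             "station": f"S{s}", "plot": f"P{p}",
                             "altitude_m": alt, "scale": sc, "distance": y}
                        )
    return pd.DataFrame(rows)


class TestScaleInteraction:
    def test_single_scale_rejected(self):
        df = distance_frame(0)
        with pytest.raises(ValueError, match="three scale"):
            scale_interaction_fit(df[df["scale"] == "station"])

    def test_subset_curvature_recovered_for_curved_scale_only(self):
        """Curvature in the transect scale only: its subset quadratic term is
        significant in most seeds, the flat scales mostly not."""
        hits, false_hits = 0, 0
        for seed in range(10):
            df = distance_frame(seed, curvature=(0.0, -1.5e-6, 0.0))
            sf = scale_interaction_fit(df)
            terms = {
                s: f.coefficients_.set_index("term")
                for s, f in sf.subset_fits.items()
            }
            hits += terms["transect"].loc["altitude_sq", "p"] < 0.05
            false_hits += (
                (terms["station"].loc["altitude_sq", "p"] < 0.05)
                + (terms["landscape"].loc["altitude_sq", "p"] < 0.05)
            )
        assert hits >= 8
        assert false_hits <= 6

    def test_interaction_lrt_fields(self):
        df = distance_frame(1)
        sf = scale_interaction_fit(df)
        assert sf.interaction_lrt.df == 4  # 2 altitude terms x 2 scale dummies
        assert 0.0 <= sf.interaction_lrt.p <= 1.0
        assert sf.resid_df == sf.n_obs - 9


class TestTukeyContrasts:
    def test_antisymmetry_and_known_shifts(self):
        df = distance_frame(2, shift=(0.0, 0.17, 0.22), resid=0.05)
        sf = scale_interaction_fit(df)
        contrasts = {c.pair: c for c in tukey_scale_contrasts(sf)}
        (p1, c1), = [(k, v) for k, v in contrasts.items()
                     if set(k) == {"station", "transect"}]
        got = c1.difference if p1 == ("transect", "station") else -c1.difference
        assert got == pytest.approx(0.17, abs=0.04)
        (p2, c2), = [(k, v) for k, v in contrasts.items()
                     if set(k) == {"station", "landscape"}]
        got2 = c2.difference if p2 == ("landscape", "station") else -c2.difference
        assert got2 == pytest.approx(0.22, abs=0.04)

    def test_shifted_levels_significant_equal_pair_not(self):
        df = distance_frame(3, shift=(0.0, 0.0, 0.5), resid=0.05)
        sf = scale_interaction_fit(df)
        for c in tukey_scale_contrasts(sf):
            if set(c.pair) == {"station", "transect"}:
                assert c.p_tukey > 0.05
            else:
                assert c.p_tukey < 0.001

    def test_equal_means_rarely_significant(self):
        sig = 0
        for seed in range(5):
            df = distance_frame(seed + 50, shift=(0.0, 0.0, 0.0), resid=0.1)
            sf = scale_interaction_fit(df)
            sig += any(c.p_tukey < 0.05 for c in tukey_scale_contrasts(sf))
        assert sig <= 2


class TestFitMixedWrapper:
    def test_spec_round_trip(self):
        df = survey_frame(8, n_p=1)
        spec = ModelSpec("y", degree=1, family="gaussian", nesting=NESTING_TWO)
        fit = fit_mixed(spec, df)
        assert fit.degree == 1
        assert list(fit.coefficients_["term"]) == ["(Intercept)", "altitude"]

    def test_sklearn_params(self):
        est = MixedAltitudeModel(response="richness", family="poisson")
        params = est.get_params()
        assert params["response"] == "richness"
        est.set_params(degree=1)
        assert est.degree == 1
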
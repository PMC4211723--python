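"""Bayesian regression suite: recovery, calibration, DIC, shrinkage."""

import math

import numpy as np
import pandas as pd
import pytest

import hetmig as hm
from hetmig.bayes import (
    McmcChains,
    McmcSettings,
    day_difference,
    dic,
    fit_beta_fat,
    fit_lognormal_mass,
    fit_negbin,
    predicted_day_difference,
    residual_plot_data,
    shrinkage_refit,
)
from hetmig.design import Covariate, DesignSpec, standardize

FAST = McmcSettings(n_chains=2, n_iter=2000)


# -- standardize -------------------------------------------------------------

def test_standardize_two_point_case():
    st = standardize([2.0, 6.0])
    assert st.values.tolist() == [-0.5, 0.5]


def test_standardize_moments_and_inverse():
    rng = np.random.default_rng(0)
    x = rng.normal(10, 3, 200)
    st = standardize(x)
    assert st.values.mean() == pytest.approx(0.0, abs=1e-12)
    assert st.values.std(ddof=0) == pytest.approx(0.5)
    assert np.allclose(st.inverse(), x, atol=1e-12)


def test_standardize_constant_errors():
    with pytest.raises(ValueError):
        standardize([3.0, 3.0, 3.0])


# -- negative binomial -------------------------------------------------------

def _nb_data(rng, n=400, b0=3.0, b1=0.0, r=10.0):
    x = rng.integers(0, 2, n).astype(float)
    mu = np.exp(b0 + b1 * x)
    y = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame({"y": y, "x": x})


def test_negbin_intercept_only_recovery():
    rng = np.random.default_rng(1)
    mu, r = math.exp(3.0), 10.0
    df = pd.DataFrame({"y": rng.negative_binomial(r, r / (r + mu), 500)})
    fit = fit_negbin(DesignSpec("y"), df, FAST, seed=2)
    assert fit.summary.loc["Intercept", "median"] == pytest.approx(3.0, abs=0.1)


def test_negbin_null_covariate_sign_probability():
    df = _nb_data(np.random.default_rng(2))
    fit = fit_negbin(DesignSpec("y", [Covariate("x", "binary")]), df, FAST, seed=3)
    assert 0.3 <= fit.summary.loc["x", "p_neg"] <= 0.7
    assert fit.summary.loc["x", "p_neg"] + fit.summary.loc["x", "p_pos"] == pytest.approx(1.0)


def test_negbin_response_validation():
    spec = DesignSpec("y")
    with pytest.raises(ValueError):
        fit_negbin(spec, pd.DataFrame({"y": [1, -2, 3]}), FAST, seed=0)
    with pytest.raises(ValueError):
        fit_negbin(spec, pd.DataFrame({"y": [1.5, 2.0, 3.0]}), FAST, seed=0)


def test_negbin_large_dispersion_matches_poisson_glm():
    """With r large the NB fit reproduces Poisson regression estimates."""
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    n = 500
    x = rng.normal(size=n)
    mu = np.exp(2.0 + 0.3 * x)
    y = rng.poisson(mu)
    df = pd.DataFrame({"y": y, "x": x})
    fit = fit_negbin(
        DesignSpec("y", [Covariate("x", "continuous")]), df,
        McmcSettings(n_chains=2, n_iter=3000), seed=5,
    )
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    deltas = [
        abs(fit.summary.loc["Intercept", "median"] - glm.params[0]),
        abs(fit.summary.loc["x", "median"] - glm.params[1]),
    ]
    assert np.median(deltas) < 0.02


def test_negbin_deterministic_under_seed():
    df = _nb_data(np.random.default_rng(6), n=120)
    spec = DesignSpec("y", [Covariate("x", "binary")])
    small = McmcSettings(n_chains=2, n_iter=500)
    f1 = fit_negbin(spec, df, small, seed=9)
    f2 = fit_negbin(spec, df, small, seed=9)
    pd.testing.assert_frame_equal(f1.summary, f2.summary)
    assert f1.dic == f2.dic


# -- log-normal mass model ---------------------------------------------------

def _mass_data(rng, n_ind=130, n_repeat=45, b_age=0.1, b_age2=-0.08, b_march=-0.1,
               sigma_b=0.06, sigma_e=0.04):
    ages = rng.integers(1, 12, n_ind)
    std_age = (ages - ages.mean()) / (2 * ages.std(ddof=1))
    b = rng.normal(0, sigma_b, n_ind)
    rows = []
    for i in range(n_ind):
        periods = [0.0, 1.0] if i < n_repeat else [float(rng.integers(0, 2))]
        for march in periods:
            eta = 4.25 + b_age * std_age[i] + b_age2 * std_age[i] ** 2 \
                + b_march * march + b[i] + rng.normal(0, sigma_e)
            rows.append({"id": f"i{i}", "age": ages[i], "march": march,
                         "mass": math.exp(eta)})
    return pd.DataFrame(rows)


MASS_SPEC = DesignSpec(
    "mass",
    [Covariate("age", "continuous", standardized=True, degree=2),
     Covariate("march", "binary")],
    random_intercept="id",
)


def test_lognormal_recovers_quadratic_age():
    df = _mass_data(np.random.default_rng(7))
    fit = fit_lognormal_mass(MASS_SPEC, df, FAST, seed=8)
    for name, truth in [("age_std", 0.1), ("age_std^2", -0.08), ("march", -0.1)]:
        lo, hi = np.percentile(fit.chains.stacked(name), [2.5, 97.5])
        assert lo <= truth <= hi, f"{name}: CrI ({lo:.3f},{hi:.3f}) misses {truth}"
    assert fit.converged


def test_lognormal_march_effect_power():
    df = _mass_data(np.random.default_rng(17), n_ind=130)
    fit = fit_lognormal_mass(MASS_SPEC, df, FAST, seed=18)
    assert fit.summary.loc["march", "p_neg"] > 0.95


def test_lognormal_sigma_b_concentrates_when_zero():
    df = _mass_data(np.random.default_rng(9), n_ind=100, n_repeat=100, sigma_b=0.0,
                    sigma_e=0.1)
    fit = fit_lognormal_mass(MASS_SPEC, df, FAST, seed=10)
    # with two records per individual the boundary posterior cannot shrink
    # below ~sigma_e/sqrt(n); "concentrates near 0" means well below sigma_eps
    assert fit.summary.loc["sigma_b", "median"] < 0.5 * fit.summary.loc["sigma_eps", "median"]
    assert fit.summary.loc["sigma_b", "median"] < 0.05


def test_lognormal_positive_mass_required():
    df = pd.DataFrame({"mass": [50.0, -1.0], "age": [2, 3], "march": [0.0, 1.0],
                       "id": ["a", "b"]})
    with pytest.raises(ValueError, match="positive"):
        fit_lognormal_mass(MASS_SPEC, df, FAST, seed=0)


def test_lognormal_residuals_sum_near_zero():
    df = _mass_data(np.random.default_rng(11))
    fit = fit_lognormal_mass(MASS_SPEC, df, FAST, seed=12)
    assert abs(fit.residuals["residual"].sum()) < 0.1


def test_residual_plot_flags_planted_group_shift():
    """An unmodelled group-level shift shows up as skewed residuals."""
    df = _mass_data(np.random.default_rng(13))
    df["region"] = np.where(np.arange(len(df)) % 4 == 0, "shifted", "base")
    df.loc[df.region == "shifted", "mass"] *= math.exp(-0.15)
    spec = DesignSpec(
        "mass",
        [Covariate("age", "continuous", standardized=True, degree=2),
         Covariate("march", "binary"),
         Covariate("region_dummy", "dummy_set")],  # placeholder to carry labels
        random_intercept="id",
    )
    df["region_dummy"] = "all"  # constant: no effect on the fit
    fit = fit_lognormal_mass(spec, df, FAST, seed=14)
    resid = residual_plot_data(fit)
    resid["region"] = df["region"].to_numpy()
    shifted = resid.loc[resid.region == "shifted", "residual"].mean()
    base = resid.loc[resid.region == "base", "residual"].mean()
    assert shifted < base - 0.05


# -- beta fat model ----------------------------------------------------------

def test_beta_intercept_only_recovery():
    rng = np.random.default_rng(15)
    mu = 1 / (1 + math.exp(2.15))
    phi = 150.0
    df = pd.DataFrame({"fat": rng.beta(mu * phi, (1 - mu) * phi, 500)})
    fit = fit_beta_fat(DesignSpec("fat"), df, FAST, seed=16)
    assert fit.summary.loc["Intercept", "median"] == pytest.approx(-2.15, abs=0.15)


def test_beta_null_covariate_sign_probability():
    rng = np.random.default_rng(17)
    mu, phi = 0.1, 150.0
    df = pd.DataFrame({
        "fat": rng.beta(mu * phi, (1 - mu) * phi, 300),
        "x": rng.integers(0, 2, 300).astype(float),
    })
    fit = fit_beta_fat(DesignSpec("fat", [Covariate("x", "binary")]), df, FAST, seed=18)
    assert 0.3 <= fit.summary.loc["x", "p_neg"] <= 0.7


def test_beta_percent_conversion_and_range_check():
    rng = np.random.default_rng(19)
    pct = 100 * rng.beta(15, 135, 200)
    fit = fit_beta_fat(DesignSpec("fat"), pd.DataFrame({"fat": pct}),
                       McmcSettings(n_chains=2, n_iter=600), seed=20)
    assert -4 < fit.summary.loc["Intercept", "median"] < -1
    with pytest.raises(ValueError, match="outside"):
        fit_beta_fat(DesignSpec("fat"), pd.DataFrame({"fat": [0.5, 120.0]}), FAST, seed=0)


def test_beta_boundary_values_adjusted_not_rejected():
    rng = np.random.default_rng(21)
    vals = rng.beta(5, 45, 150)
    vals[0] = 0.0
    fit = fit_beta_fat(DesignSpec("fat"), pd.DataFrame({"fat": vals}),
                       McmcSettings(n_chains=2, n_iter=600), seed=22)
    assert np.isfinite(fit.dic)


def test_beta_mean_recovery_at_high_precision():
    """Planted mean recovered on the probability scale at large n."""
    rng = np.random.default_rng(23)
    mu, phi = 0.3, 100.0
    df = pd.DataFrame({"fat": rng.beta(mu * phi, (1 - mu) * phi, 1000)})
    fit = fit_beta_fat(DesignSpec("fat"), df, FAST, seed=24)
    mu_hat = 1 / (1 + math.exp(-fit.summary.loc["Intercept", "median"]))
    assert mu_hat == pytest.approx(mu, abs=0.01)


# -- DIC ---------------------------------------------------------------------

def _chains_from_deviance(dev, dev_at_mean=None):
    return McmcChains(draws={}, deviance=np.asarray(dev, dtype=float),
                      n_chains=1, n_iter=len(dev), burn_in=0, seed=0,
                      deviance_at_mean=dev_at_mean)


def test_dic_degenerate_posterior():
    with pytest.warns(UserWarning):
        d, p_var, _ = dic(_chains_from_deviance([[42.0] * 50]))
    assert p_var == 0.0
    assert d == 42.0


def test_dic_conjugate_normal_means():
    """k independent normal means, sigma known, diffuse prior: pD ~ k.

    Draws come from the exact conjugate posterior N(ybar_j, sigma^2/n),
    so this checks the DIC computation against closed-form theory.
    """
    rng = np.random.default_rng(25)
    k, n, sigma = 4, 25, 1.0
    y = rng.normal(0.0, sigma, (k, n))
    ybar = y.mean(axis=1)
    draws = ybar[None, :] + rng.normal(0, sigma / math.sqrt(n), (4000, k))
    dev = np.array([
        (((y - th[:, None]) / sigma) ** 2).sum() + k * n * math.log(2 * math.pi * sigma**2)
        for th in draws
    ])
    dev_at_mean = float((((y - draws.mean(0)[:, None]) / sigma) ** 2).sum()
                        + k * n * math.log(2 * math.pi * sigma**2))
    _, p_var, p_plug = dic(_chains_from_deviance(dev[None, :], dev_at_mean))
    assert p_var == pytest.approx(k, abs=0.5)
    assert p_plug == pytest.approx(k, abs=0.5)


def _mass_long(rng, n_ind=120, b_age2=-0.08):
    """Repeat captures two years apart: age varies within individual, so a
    quadratic age effect is not absorbable by the random intercept."""
    ages = rng.integers(1, 10, n_ind)
    b = rng.normal(0, 0.06, n_ind)
    rows = []
    for i in range(n_ind):
        for da in (0, 2):
            a = ages[i] + da
            sa = (a - 6) / (2 * 2.87)
            eta = 4.25 + 0.1 * sa + b_age2 * sa**2 + b[i] + rng.normal(0, 0.04)
            rows.append({"id": f"i{i}", "age": a, "march": float(da > 0),
                         "mass": math.exp(eta)})
    return pd.DataFrame(rows)


def test_dic_prefers_quadratic_age_when_planted():
    """Models with the quadratic age term fit quadratic-age data better."""
    wins = 0
    reps = 8
    lin_spec = DesignSpec(
        "mass",
        [Covariate("age", "continuous", standardized=True, degree=1),
         Covariate("march", "binary")],
        random_intercept="id",
    )
    small = McmcSettings(n_chains=2, n_iter=1200)
    for k in range(reps):
        df = _mass_long(np.random.default_rng(300 + k))
        quad = fit_lognormal_mass(MASS_SPEC, df, small, seed=k)
        lin = fit_lognormal_mass(lin_spec, df, small, seed=k)
        if quad.dic < lin.dic:
            wins += 1
    assert wins >= int(0.8 * reps)


# -- shrinkage refit ---------------------------------------------------------

def test_shrinkage_auto_prior_sd_and_monotone_pruning():
    rng = np.random.default_rng(26)
    n = 250
    x_strong = rng.integers(0, 2, n).astype(float)
    nulls = {f"z{j}": rng.integers(0, 2, n).astype(float) for j in range(6)}
    mu = np.exp(2.5 - 0.5 * x_strong)
    r = 8.0
    df = pd.DataFrame({"y": rng.negative_binomial(r, r / (r + mu)),
                       "x_strong": x_strong, **nulls})
    spec = DesignSpec("y", [Covariate("x_strong", "binary")]
                      + [Covariate(z, "binary") for z in nulls])
    fit = fit_negbin(spec, df, FAST, seed=27)
    refit, comparison = shrinkage_refit(fit, "auto", FAST, seed=28)
    meds = fit.coefficient_medians().drop("Intercept")
    assert comparison.attrs["prior_sd"] == pytest.approx(float(meds.std(ddof=1)))
    assert comparison["flag_after"].sum() <= comparison["flag_before"].sum()
    # the planted strong effect survives shrinkage
    row = comparison.set_index("coefficient").loc["x_strong"]
    assert row["flag_before"] and row["flag_after"]


def test_shrinkage_rejects_bad_prior_sd():
    df = _nb_data(np.random.default_rng(29), n=100)
    fit = fit_negbin(DesignSpec("y", [Covariate("x", "binary")]),
                     df, McmcSettings(n_chains=2, n_iter=500), seed=30)
    with pytest.raises(ValueError):
        shrinkage_refit(fit, -0.1, seed=0)


# -- day-difference prediction ----------------------------------------------

def test_day_difference_reported_haplogroup_shift():
    """Median intercept 2.932 and haplogroup-2 coefficient -0.350 predict a
    6-day earlier fall migration termination."""
    days, raw = day_difference(2.932, -0.350)
    assert days == 6
    assert raw == pytest.approx(math.exp(2.932) - math.exp(2.582))


def test_day_difference_zero_and_closed_form():
    assert day_difference(3.0, 0.0)[0] == 0
    days, raw = day_difference(3.0, -0.5)
    assert raw == pytest.approx(math.exp(3) - math.exp(2.5))
    assert days == 8


def test_predicted_day_difference_from_fit():
    rng = np.random.default_rng(31)
    n = 400
    hap2 = rng.integers(0, 2, n).astype(float)
    mu = np.exp(2.932 - 0.35 * hap2)
    r = 5.0
    df = pd.DataFrame({"days": rng.negative_binomial(r, r / (r + mu)), "hap2": hap2})
    fit = fit_negbin(DesignSpec("days", [Covariate("hap2", "binary")]), df, FAST, seed=32)
    dd = predicted_day_difference(fit, "hap2")
    assert 4 <= dd.days <= 8
    assert dd.posterior_draws.shape == fit.chains.stacked("Intercept").shape
    with pytest.raises(KeyError):
        predicted_day_difference(fit, "nope")
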
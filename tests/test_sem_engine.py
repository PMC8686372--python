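"""ML structural equation modelling: discrepancy, fitting, standardization."""

import numpy as np
import pandas as pd
import pytest

from ctg_interpret import sem_engine as se
from ctg_interpret.sem_engine import (
    ModelSpecError, NumericModelError, SEMData, build_model,
    effect_decomposition, fit_indices, fit_ml, fml_discrepancy,
    implied_covariance, independence_fml, measurement_model, standardize_solution,
    structural_model, wald_statistics,
)
from ctg_interpret.synthetic_ctg import generate_sem_sample, structural_true_params


def one_factor_model(indicators=("LB", "Mean", "Median")):
    return build_model({
        "latents": {"F": list(indicators)},
        "references": {"F": indicators[0]},
    })


def random_spd(rng, k):
    A = rng.normal(size=(k, k))
    return A @ A.T + k * np.eye(k)


# -- discrepancy --------------------------------------------------------------

def test_fml_zero_iff_equal(rng):
    S = random_spd(rng, 5)
    assert fml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-10)
    Sigma = S + 0.3 * np.eye(5)
    assert fml_discrepancy(S, Sigma) > 0


def test_fml_rejects_non_pd(rng):
    S = random_spd(rng, 3)
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(NumericModelError):
        fml_discrepancy(bad, S)
    with pytest.raises(NumericModelError):
        fml_discrepancy(S, bad)


def test_independence_fml_zero_on_diagonal():
    f, df = independence_fml(np.diag([2.0, 3.0, 0.5]))
    assert f == pytest.approx(0.0, abs=1e-12)
    assert df == 3


# -- model specification ------------------------------------------------------

def test_build_model_counts_free_parameters():
    model = one_factor_model()
    # 2 free loadings + 1 phi + 3 theta = 6 free; p(p+1)/2 = 6 -> df = 0
    assert model.n_free == 6
    assert model.df == 0


def test_build_model_rejects_shared_indicator():
    with pytest.raises(ModelSpecError, match="two latents"):
        build_model({"latents": {"A": ["LB", "Mean"], "B": ["Mean", "Mode"]},
                     "references": {"A": "LB", "B": "Mode"}})


def test_build_model_requires_reference():
    with pytest.raises(ModelSpecError, match="scaling"):
        build_model({"latents": {"A": ["LB", "Mean"]}, "references": {}})


def test_presets_are_well_formed():
    m = measurement_model()
    assert len(m.observed) == 17
    assert m.df > 0
    s = structural_model()
    assert "NSP" in s.observed
    assert "MLTV" not in s.observed
    assert set(s.latents_endo) == {"BCat", "DCat", "Fetal"}


def test_implied_covariance_matches_monte_carlo():
    model = structural_model()
    params = structural_true_params(model)
    Sigma = implied_covariance(model, params)
    frame = generate_sem_sample(model, params, n=60000, seed=7)
    S = frame.cov().to_numpy()
    assert np.max(np.abs(S - Sigma)) < 0.05


def test_true_params_give_unit_indicator_variances():
    model = structural_model()
    Sigma = implied_covariance(model, structural_true_params(model))
    np.testing.assert_allclose(np.diag(Sigma), 1.0, atol=1e-12)


# -- fitting ------------------------------------------------------------------

def test_just_identified_fit_is_exact(rng):
    model = one_factor_model()
    lam = {"LB": 1.0, "Mean": 0.8, "Median": 1.3}
    true = {"lambda:Mean<-F": 0.8, "lambda:Median<-F": 1.3, "phi:F~~F": 0.9,
            "theta:LB": 0.4, "theta:Mean": 0.5, "theta:Median": 0.3}
    frame = generate_sem_sample(model, true, n=400, seed=3)
    data = SEMData.from_frame(frame, model.observed)
    fit = fit_ml(model, data)
    assert fit.converged
    assert fit.fml == pytest.approx(0.0, abs=1e-10)
    # closed-form structure of the just-identified solution
    est = fit.estimates
    lam_hat = {"LB": 1.0, "Mean": est["lambda:Mean<-F"],
               "Median": est["lambda:Median<-F"]}
    phi_hat = est["phi:F~~F"]
    S = pd.DataFrame(data.S, index=data.variables, columns=data.variables)
    for a, b in [("LB", "Mean"), ("LB", "Median"), ("Mean", "Median")]:
        assert lam_hat[a] * lam_hat[b] * phi_hat == pytest.approx(
            S.loc[a, b], abs=1e-8)


def test_noiseless_structural_recovery():
    model = structural_model()
    true = structural_true_params(model)
    Sigma = implied_covariance(model, true)
    data = SEMData(Sigma, 2000, list(model.observed))
    fit = fit_ml(model, data)
    assert fit.converged
    assert fit.fml < 1e-12
    err = max(abs(fit.estimates[k] - true[k]) for k in true)
    assert err < 1e-6
    assert fit.heywood == []


def test_fit_reorders_data_columns():
    model = one_factor_model()
    true = {"lambda:Mean<-F": 0.8, "lambda:Median<-F": 1.3, "phi:F~~F": 0.9,
            "theta:LB": 0.4, "theta:Mean": 0.5, "theta:Median": 0.3}
    frame = generate_sem_sample(model, true, n=300, seed=11)
    shuffled = frame[["Median", "LB", "Mean"]]
    fit = fit_ml(model, SEMData.from_frame(shuffled, list(shuffled.columns)))
    fit2 = fit_ml(model, SEMData.from_frame(frame, model.observed))
    for k in fit.estimates:
        assert fit.estimates[k] == pytest.approx(fit2.estimates[k], abs=1e-6)


def test_semdata_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SEMData(np.array([[1.0, 0.5], [0.2, 1.0]]), 100, ["a", "b"])
    with pytest.raises(ValueError, match="exceed"):
        SEMData(np.eye(3), 3, ["a", "b", "c"])
    frame = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="missing"):
        SEMData.from_frame(frame, ["a", "b"])


def test_fit_rejects_underidentified():
    model = build_model({"latents": {"F": ["LB", "Mean"]},
                         "references": {"F": "LB"}})
    data = SEMData(np.array([[1.0, 0.4], [0.4, 1.0]]), 100, ["LB", "Mean"])
    with pytest.raises(ModelSpecError, match="identified"):
        fit_ml(model, data)


# -- standardization and inference --------------------------------------------

def test_standardized_loadings_are_correlations():
    model = one_factor_model()
    true = {"lambda:Mean<-F": 0.8, "lambda:Median<-F": 1.3, "phi:F~~F": 0.9,
            "theta:LB": 0.4, "theta:Mean": 0.5, "theta:Median": 0.3}
    Sigma = implied_covariance(model, true)
    fit = fit_ml(model, SEMData(Sigma, 500, list(model.observed)))
    std = standardize_solution(fit)
    # one-factor: standardized loading = indicator-factor correlation
    for obs, lam in [("LB", 1.0), ("Mean", 0.8), ("Median", 1.3)]:
        expect = lam * np.sqrt(0.9) / np.sqrt(Sigma[model.observed.index(obs),
                                                    model.observed.index(obs)])
        assert std[f"{obs}<-F"] == pytest.approx(expect, abs=1e-6)
    assert all(abs(v) <= 1.0 + 1e-9 for v in std.values())


def test_wald_table_structure_and_stars():
    model = structural_model()
    true = structural_true_params(model)
    frame = generate_sem_sample(model, true, n=2000, seed=5)
    fit = fit_ml(model, SEMData.from_frame(frame, model.observed))
    table = wald_statistics(fit)
    assert set(table.columns) == {"parameter", "estimate", "se", "cr", "p", "stars"}
    assert len(table) == fit.model.n_free
    strong = table[table["parameter"] == "gamma:DCat<-UCat"].iloc[0]
    assert strong["stars"] == "***" and strong["p"] < 0.001
    finite = table["se"].dropna()
    assert (finite > 0).all()


def test_effect_decomposition_product_rule():
    model = structural_model()
    true = structural_true_params(model)
    Sigma = implied_covariance(model, true)
    fit = fit_ml(model, SEMData(Sigma, 2000, list(model.observed)))
    eff = effect_decomposition(fit, "NSP").set_index("source")
    # VCat reaches NSP only through BCat: indirect = 0.527 * (-0.240)
    assert eff.loc["VCat", "direct"] == pytest.approx(0.0, abs=1e-8)
    assert eff.loc["VCat", "indirect"] == pytest.approx(0.527 * -0.240, abs=1e-4)
    assert eff.loc["ACat", "direct"] == pytest.approx(-0.665, abs=1e-4)
    assert eff.loc["ACat", "indirect"] == pytest.approx(0.0, abs=1e-8)
    # total = direct + indirect by construction
    np.testing.assert_allclose(eff["total"], eff["direct"] + eff["indirect"],
                               atol=1e-12)


def test_effect_decomposition_unknown_outcome():
    model = one_factor_model()
    true = {"lambda:Mean<-F": 0.8, "lambda:Median<-F": 1.3, "phi:F~~F": 0.9,
            "theta:LB": 0.4, "theta:Mean": 0.5, "theta:Median": 0.3}
    Sigma = implied_covariance(model, true)
    fit = fit_ml(model, SEMData(Sigma, 500, list(model.observed)))
    with pytest.raises(ValueError, match="not reachable"):
        effect_decomposition(fit, "XYZ")


def test_fit_indices_perfect_fit():
    model = structural_model()
    true = structural_true_params(model)
    Sigma = implied_covariance(model, true)
    fit = fit_ml(model, SEMData(Sigma, 2000, list(model.observed)))
    ix = fit_indices(fit)
    assert ix["chi2"] == pytest.approx(0.0, abs=1e-6)
    assert ix["cfi"] == pytest.approx(1.0, abs=1e-9)
    assert ix["rmsea"] == pytest.approx(0.0, abs=1e-9)
    assert ix["srmr"] < 1e-8
    assert ix["df"] == fit.model.df > 0


def test_fit_indices_just_identified_flag():
    model = one_factor_model()
    true = {"lambda:Mean<-F": 0.8, "lambda:Median<-F": 1.3, "phi:F~~F": 0.9,
            "theta:LB": 0.4, "theta:Mean": 0.5, "theta:Median": 0.3}
    frame = generate_sem_sample(model, true, n=300, seed=2)
    fit = fit_ml(model, SEMData.from_frame(frame, model.observed))
    ix = fit_indices(fit)
    assert ix["just_identified"] and ix["df"] == 0
    assert ix["rmsea"] == 0.0
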
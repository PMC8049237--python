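"""Filter, correlation, GPE, Sobol and local-sensitivity contracts."""

import numpy as np
import pandas as pd
import pytest

from cardioshape.sensitivity import (
    LocalSensitivityInput,
    lsa_battery,
    mode_phenotype_correlations,
    normalized_range_filter,
    saltelli_design,
    scenario_delta,
    sensitivity_coefficient,
    sobol_saltelli,
    train_gpes_loo,
)


# ----------------------------------------------------------------------
# normalized range filter
# ----------------------------------------------------------------------
def test_range_filter_examples():
    phenos = pd.DataFrame({
        "const": [5.0, 5.0, 5.0],
        "wide": [1.0, 2.0, 3.0],
        "boundary": [0.9, 1.0, 1.1],
    })
    values, retained = normalized_range_filter(phenos, threshold=0.2)
    assert values["const"] == 0.0 and "const" not in retained
    assert values["wide"] == pytest.approx(1.0) and "wide" in retained
    # exactly at threshold: retained (discard only strictly below)
    assert values["boundary"] == pytest.approx(0.2)
    assert "boundary" in retained


def test_range_filter_zero_mean_discarded_with_warning():
    phenos = pd.DataFrame({"sym": [-1.0, 0.0, 1.0]})
    with pytest.warns(RuntimeWarning, match="zero mean"):
        values, retained = normalized_range_filter(phenos)
    assert np.isnan(values["sym"]) and retained == []


def test_range_filter_negative_phenotype_judged_on_magnitude():
    phenos = pd.DataFrame({"dpdtmin": [-2.0, -1.5, -1.0]})
    values, retained = normalized_range_filter(phenos)
    assert values["dpdtmin"] == pytest.approx(1.0 / 1.5)
    assert "dpdtmin" in retained


def test_range_filter_respects_completion_flag():
    phenos = pd.DataFrame({
        "x": [1.0, 1.0, 100.0],
        "completed": [True, True, False],
    })
    values, retained = normalized_range_filter(phenos)
    assert values["x"] == 0.0


# ----------------------------------------------------------------------
# correlations
# ----------------------------------------------------------------------
def test_perfectly_linear_phenotype_has_unit_correlation(rng):
    w = pd.DataFrame(rng.normal(size=(20, 3)), columns=["m1", "m2", "m3"])
    p = pd.DataFrame({"y": 2.0 * w["m1"]})
    corr, summary = mode_phenotype_correlations(w, p)
    assert corr.loc["m1", "y"] == pytest.approx(1.0)


def test_independent_noise_has_low_correlation():
    rng = np.random.default_rng(42)
    w = pd.DataFrame(rng.normal(size=(50, 4)),
                     columns=[f"m{i}" for i in range(4)])
    p = pd.DataFrame({"y": rng.normal(size=50)})
    corr, _ = mode_phenotype_correlations(w, p)
    assert corr["y"].abs().max() < 0.4


def test_mean_absolute_correlation_summary(rng):
    w = pd.DataFrame(rng.normal(size=(30, 1)), columns=["m1"])
    p = pd.DataFrame({
        "a": 0.3 * w["m1"] + rng.normal(size=30),
        "b": -w["m1"],
    })
    corr, summary = mode_phenotype_correlations(w, p)
    expected = corr.loc["m1"].abs().mean()
    assert summary.loc["m1", "mean_absR"] == pytest.approx(expected)
    vals = pd.Series([0.3, 0.5, 0.7]).abs()
    assert vals.mean() == pytest.approx(0.5)


def test_zero_variance_column_reported_missing(rng):
    w = pd.DataFrame(rng.normal(size=(10, 1)), columns=["m1"])
    p = pd.DataFrame({"flat": np.ones(10)})
    corr, _ = mode_phenotype_correlations(w, p)
    assert np.isnan(corr.loc["m1", "flat"])


# ----------------------------------------------------------------------
# GPE training
# ----------------------------------------------------------------------
def test_gpe_interpolates_smooth_linear_target(rng):
    w = rng.normal(size=(20, 3))
    y = w.sum(axis=1)
    gpe = train_gpes_loo(w, y, random_state=0)
    assert gpe.mean_loo_mse < 1e-4
    pred = gpe.predict(w)
    assert np.allclose(pred, y, atol=3 * np.sqrt(gpe.mean_loo_mse) + 1e-3)


def test_gpe_constant_target_exact():
    w = np.random.default_rng(1).normal(size=(8, 2))
    y = np.full(8, 3.3)
    gpe = train_gpes_loo(w, y, random_state=0)
    assert gpe.mean_loo_mse == pytest.approx(0.0, abs=1e-12)
    assert gpe.predict(w) == pytest.approx(3.3)


def test_gpe_best_split_is_argmin():
    rng = np.random.default_rng(2)
    w = rng.normal(size=(12, 2))
    y = np.sin(w[:, 0]) + rng.normal(0, 0.01, 12)
    gpe = train_gpes_loo(w, y, random_state=0)
    assert gpe.best_split == int(np.argmin(gpe.loo_mse))


def test_gpe_synthetic_cases_always_in_training(rng):
    w = rng.normal(size=(10, 2))
    y = w[:, 0]
    mask = np.zeros(10, dtype=bool)
    mask[6:] = True  # synthetic cases: never left out
    gpe = train_gpes_loo(w, y, synthetic_mask=mask, random_state=0)
    assert gpe.loo_mse.size == 6


def test_gpe_too_few_cases_rejected(rng):
    with pytest.raises(ValueError):
        train_gpes_loo(rng.normal(size=(3, 2)), np.arange(3.0))


# ----------------------------------------------------------------------
# Saltelli / Sobol
# ----------------------------------------------------------------------
def test_saltelli_design_size():
    design = saltelli_design(np.array([[0, 1]] * 3), n=10, seed=0)
    assert design.shape == (80, 3)  # (2*3+2)*10


def test_ishigami_first_order_indices():
    a, b = 7.0, 0.1

    def ishigami(x):
        return (
            np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        )

    res = sobol_saltelli(ishigami, [[-np.pi, np.pi]] * 3, n=4096, seed=0)
    # closed form, derived from the variance decomposition of the function
    v = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
    s1_exact = np.array([0.5 * (1 + b * np.pi**4 / 5) ** 2 / v, a**2 / 8 / v, 0.0])
    assert np.allclose(res.s1, s1_exact, atol=0.02)
    assert np.all(res.st >= res.s1 - 0.02)


def test_sobol_estimates_converge_with_n():
    a, b = 7.0, 0.1

    def ishigami(x):
        return (
            np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        )

    v = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
    s1_exact = np.array([0.5 * (1 + b * np.pi**4 / 5) ** 2 / v, a**2 / 8 / v, 0.0])
    errs = []
    for n in (256, 4096):
        res = sobol_saltelli(ishigami, [[-np.pi, np.pi]] * 3, n=n, seed=1)
        errs.append(np.abs(res.s1 - s1_exact).max())
    assert errs[1] < errs[0]


def test_additive_model_has_no_interactions():
    def additive(x):
        return x[:, 0] + 2.0 * x[:, 1] + 0.5 * x[:, 2]

    res = sobol_saltelli(additive, [[0, 1]] * 3, n=2048, seed=0)
    assert np.all(res.st - res.s1 < 0.02)
    assert res.multifactorial < 0.02
    shares = res.shares()
    assert shares.sum() == pytest.approx(1.0)


def test_nonfinite_model_output_names_input():
    def bad(x):
        y = x[:, 0].copy()
        y[3] = np.nan
        return y

    with pytest.raises(ValueError, match="design row 3"):
        sobol_saltelli(bad, [[0, 1]] * 2, n=64, seed=0)


def test_design_deterministic_for_seed():
    r1 = saltelli_design(np.array([[0, 1]] * 2), 64, seed=5)
    r2 = saltelli_design(np.array([[0, 1]] * 2), 64, seed=5)
    assert np.array_equal(r1, r2)


# ----------------------------------------------------------------------
# local sensitivity
# ----------------------------------------------------------------------
def _sc(x0, y_fn):
    xm, xp = 0.9 * x0, 1.1 * x0
    return sensitivity_coefficient(LocalSensitivityInput(
        x0=x0, y0=y_fn(x0), x_minus=xm, x_plus=xp,
        y_minus=y_fn(xm), y_plus=y_fn(xp),
    ))


def test_linear_response_gives_unit_coefficient():
    assert _sc(3.7, lambda x: 5.0 * x) == pytest.approx(1.0, abs=1e-12)


def test_quadratic_response_gives_two():
    assert _sc(2.5, lambda x: x**2) == pytest.approx(2.0, abs=1e-12)


def test_constant_output_gives_zero():
    assert _sc(1.0, lambda x: 42.0) == pytest.approx(0.0, abs=1e-12)


def test_zero_baseline_output_rejected():
    with pytest.raises(ZeroDivisionError):
        sensitivity_coefficient(LocalSensitivityInput(
            x0=1.0, y0=0.0, x_minus=0.9, x_plus=1.1, y_minus=-1.0, y_plus=1.0
        ))


def test_scenario_delta_examples():
    assert scenario_delta(100.0, 110.0) == pytest.approx(10.0)
    assert scenario_delta(5.0, 5.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        scenario_delta(0.0, 1.0)
    a, b = 80.0, 100.0
    assert scenario_delta(a, b) == pytest.approx(-scenario_delta(b, a) * b / a)


def test_lsa_battery_slope_invariance_and_missing_rows():
    def evaluate(params):
        if params["bad"] > 1.05:
            raise RuntimeError("diverged")
        return {"y": 3.0 * params["lin"], "z": 7.0}

    base = {"lin": 2.0, "bad": 1.0}
    table = lsa_battery(evaluate, base, ["lin", "bad"])
    assert table.loc["lin", "y"] == pytest.approx(1.0, abs=1e-12)
    assert table.loc["lin", "z"] == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(table.loc["bad", "y"])
    # doubling the perturbation leaves a linear pathway's SC unchanged
    table2 = lsa_battery(evaluate, {"lin": 2.0, "bad": 0.5}, ["lin"],
                         perturbation=0.2)
    assert table2.loc["lin", "y"] == pytest.approx(1.0, abs=1e-12)
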
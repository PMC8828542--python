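import warnings

import numpy as np
import pandas as pd
import pytest

from rootpheno.phenostats import (
    MixedModelSpec,
    cullis_heritability,
    descriptive_stats,
    fit_mixed_model,
    trait_correlations,
    tukey_filter,
)
from rootpheno.sim import VarianceComponents, generate_design, simulate_phenotypes

from conftest import reml_grid_oracle


# ---------------------------------------------------------------- Tukey filter
def test_tukey_flags_the_gross_outlier():
    df = pd.DataFrame({"y": list(range(1, 10)) + [100]})
    filtered, flags = tukey_filter(df, "y")
    # linear-interpolation quartiles: Q1=3.25, Q3=7.75, upper fence 14.5
    q1, q3 = np.quantile(df["y"], [0.25, 0.75])
    assert (q1, q3) == (3.25, 7.75)
    assert flags.sum() == 1 and flags.iloc[-1]
    assert 100 not in filtered["y"].values


def test_tukey_constant_data_unflagged():
    df = pd.DataFrame({"y": [2.0] * 20})
    _, flags = tukey_filter(df, "y")
    assert flags.sum() == 0


def test_tukey_normal_flag_rate():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"y": rng.normal(size=10_000)})
    _, flags = tukey_filter(df, "y")
    rate = 100 * flags.mean()
    assert abs(rate - 0.7) < 0.3  # boxplot outlier rate of the normal ~0.70%


def test_tukey_grouped_and_small_groups():
    df = pd.DataFrame({"day": [12] * 10 + [15] * 3, "y": list(range(1, 10)) + [100, 1, 2, 3]})
    _, flags = tukey_filter(df, "y", group=["day"])
    assert flags.sum() == 1  # day-15 group too small to flag anything


# ------------------------------------------------------------------------ REML
def test_reml_deviance_matches_grid_oracle(tiny_mixed_table):
    spec = MixedModelSpec(response="y", fixed="chamber", random=("genotype",))
    fit = fit_mixed_model(tiny_mixed_table, spec)
    y = tiny_mixed_table["y"].to_numpy()
    X = np.column_stack([np.ones(6), (tiny_mixed_table["chamber"] == 2).astype(float)])
    Zg = pd.get_dummies(tiny_mixed_table["genotype"]).to_numpy(float)
    crit, _ = reml_grid_oracle(y, X, [Zg], [np.linspace(0, 60, 1500)])
    assert fit.deviance <= crit + 1e-4
    assert abs(fit.deviance - crit) < 1e-3  # grid resolution limits the gap


def test_reml_on_duplicated_data_matches_oracle(tiny_mixed_table):
    doubled = pd.concat([tiny_mixed_table, tiny_mixed_table], ignore_index=True)
    spec = MixedModelSpec(response="y", fixed="chamber", random=("genotype",))
    fit = fit_mixed_model(doubled, spec)
    y = doubled["y"].to_numpy()
    X = np.column_stack([np.ones(12), (doubled["chamber"] == 2).astype(float)])
    Zg = pd.get_dummies(doubled["genotype"]).to_numpy(float)
    crit, gam = reml_grid_oracle(y, X, [Zg], [np.linspace(0, 120, 2000)])
    assert fit.deviance <= crit + 1e-4
    # duplication halves the residual, roughly doubling the variance ratio
    fit_single = fit_mixed_model(tiny_mixed_table, spec)
    ratio_single = fit_single.variance_components["genotype"] / fit_single.variance_components["residual"]
    ratio_double = fit.variance_components["genotype"] / fit.variance_components["residual"]
    assert ratio_double > 1.5 * ratio_single


def test_null_signal_shrinks_blups_to_zero(small_design):
    vc = VarianceComponents(0.0, 0.0, 0.0, 1.0)
    table, _ = simulate_phenotypes(small_design, vc, traits=("TRL",), mu=3.0, seed=0)
    fit = fit_mixed_model(table, "TRL")
    assert fit.variance_components["genotype"] < 0.05
    assert np.abs(fit.genotype_effects).max() < 0.3
    assert fit.heritability < 0.4


def test_component_recovery_balanced_design():
    """Known components recovered within 15% (averaged over seeds)."""
    truth = {"genotype": 1.0, "chamber:block": 0.25, "chamber:block:sub_block": 0.25, "residual": 1.0}
    est = {k: [] for k in truth}
    for seed in range(12):
        design = generate_design(96, n_chambers=8, seed=seed, block_spec=((12,) * 4, (12,) * 4))
        vc = VarianceComponents(1.0, 0.25, 0.25, 1.0)
        table, _ = simulate_phenotypes(design, vc, traits=("y",), seed=100 + seed)
        fit = fit_mixed_model(table, "y")
        for k in truth:
            est[k].append(fit.variance_components[k])
    for k, v in truth.items():
        assert abs(np.mean(est[k]) - v) / v < 0.15, (k, np.mean(est[k]))


def test_blup_effects_centered_and_shrunk(balanced_table):
    table, truth = balanced_table
    fit = fit_mixed_model(table, "TRL")
    assert abs(fit.genotype_effects.mean()) < 1e-6 * fit.genotype_effects.std()
    assert fit.genotype_effects.var(ddof=1) <= fit.variance_components["genotype"] + 1e-9
    # BLUPs track the simulated truth
    eff = fit.genotype_effects
    true_eff = pd.Series(truth["TRL"]["genotype_effects"]).loc[eff.index]
    assert np.corrcoef(eff, true_eff)[0, 1] > 0.85


def test_heritability_affine_invariant(balanced_table):
    table, _ = balanced_table
    h1 = fit_mixed_model(table, "TRL").heritability
    table2 = table.copy()
    table2["TRL"] = 3.0 * table2["TRL"] - 7.0
    h2 = fit_mixed_model(table2, "TRL").heritability
    assert h1 == pytest.approx(h2, abs=1e-6)


def test_fit_deterministic(balanced_table):
    table, _ = balanced_table
    a = fit_mixed_model(table, "TRL")
    b = fit_mixed_model(table, "TRL")
    assert a.deviance == b.deviance
    assert a.blups.equals(b.blups)


def test_unbalanced_data_handled_without_imputation(balanced_table):
    table, _ = balanced_table
    thinned = table.sample(frac=0.8, random_state=0)
    fit = fit_mixed_model(thinned, "TRL")
    assert fit.n_obs == len(thinned)
    assert 0 <= fit.heritability <= 1


def test_error_paths():
    df = pd.DataFrame({"genotype": ["A", "B"], "chamber": [1, 1], "y": [1.0, 2.0]})
    with pytest.raises(ValueError, match="block"):
        fit_mixed_model(df, "y")  # default spec needs block columns
    with pytest.raises(ValueError, match="genotype"):
        MixedModelSpec(response="y", random=("chamber:block",))
    with pytest.raises(ValueError, match=">= 2 genotypes"):
        fit_mixed_model(
            pd.DataFrame({"genotype": ["A"] * 3, "chamber": [1, 1, 2], "y": [1.0, 2.0, 3.0]}),
            MixedModelSpec(response="y", random=("genotype",)),
        )


# ---------------------------------------------------------------- Cullis form
def test_cullis_limits():
    assert cullis_heritability(0.0, 2.0) == 1.0
    assert cullis_heritability(4.0, 2.0) == 0.0
    h, flags = cullis_heritability(1.0, 0.0, return_flags=True)
    assert h == 0.0 and any("degenerate" in f for f in flags)
    with pytest.raises(ValueError):
        cullis_heritability(-1.0, 1.0)


def test_balanced_heritability_close_to_closed_form(balanced_table):
    # sigma_g = sigma_e = 1, r = 8 reps -> H ~ r/(r+1) = 0.889
    table, _ = balanced_table
    fit = fit_mixed_model(table, "TRL")
    assert fit.heritability == pytest.approx(8 / 9, abs=0.06)


# ------------------------------------------------------- descriptive & corr
def test_descriptive_stats_small_examples():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
    out = descriptive_stats(df, ["a", "b"])
    assert out.loc["a", "mean"] == 2 and out.loc["a", "sd"] == 1 and out.loc["a", "cv_pct"] == 50
    assert out.loc["b", "sd"] == 0 and out.loc["b", "cv_pct"] == 0
    zero = pd.DataFrame({"c": [-1.0, 1.0]})
    assert np.isnan(descriptive_stats(zero, ["c"]).loc["c", "cv_pct"])


def test_descriptive_stats_monte_carlo_cv():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.normal(100, 15, size=10_000)})
    out = descriptive_stats(df, ["x"])
    assert out.loc["x", "cv_pct"] == pytest.approx(15.0, abs=0.5)


def test_trait_correlations_properties():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"x": rng.normal(size=375)})
    df["negx"] = -df["x"]
    df["z"] = rng.normal(size=375)
    corr = trait_correlations(df)
    assert corr.loc["x", "x"] == 1.0
    assert corr.loc["x", "negx"] == pytest.approx(-1.0)
    assert abs(corr.loc["x", "z"]) < 0.15
    assert np.allclose(corr, corr.T)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        corr2 = trait_correlations(df.assign(const=1.0))
    assert "const" not in corr2.columns and len(w) == 1
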
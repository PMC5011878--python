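"""Mixed-model layer: transformation policy, REML oracles, heritability,
Tukey HSD and BLUP summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import trait_records
from rhizoslides.errors import InsufficientDataError
from rhizoslides.experiment import TraitTable
from rhizoslides.reml import reml_fit
from rhizoslides.split_stats import (
    ModelSpec,
    VarianceComponents,
    blup_summaries,
    estimate_heritability,
    fit_mixed,
    heritability,
    mse_from_avsed,
    transform_trait,
    tukey_hsd,
)
from rhizoslides.synthetic import TrialTruth, simulate_trial


# --- transformation policy --------------------------------------------------

def test_sqrt_applied_to_root_traits():
    out = transform_trait([0.0, 1.0, 4.0, 9.0], "No_Lat_1st")
    assert out.tolist() == [0.0, 1.0, 2.0, 3.0]


def test_shoot_traits_pass_through():
    vals = [3.0, -1.0, 7.5]  # negatives fine when untransformed
    assert transform_trait(vals, "DW_S").tolist() == vals


def test_negative_root_trait_value_is_named():
    with pytest.raises(ValueError, match="indices \\[1\\]"):
        transform_trait([1.0, -0.1, 2.0], "Med_Lat_2nd")


# --- REML against textbook oracles ------------------------------------------

def _two_way_anova_oracle(df):
    """Balanced additive two-way ANOVA from raw sums of squares."""
    y = df["value"].to_numpy()
    G = df["genotype"].nunique()
    R = df["replicate"].nunique()
    grand = y.mean()
    gm = df.groupby("genotype")["value"].mean()
    rm = df.groupby("replicate")["value"].mean()
    ssg = R * ((gm - grand) ** 2).sum()
    ssr = G * ((rm - grand) ** 2).sum()
    sse = ((y - grand) ** 2).sum() - ssg - ssr
    dfe = (G - 1) * (R - 1)
    return {
        "genotype": (ssg / (G - 1)) / (sse / dfe),
        "replicate": (ssr / (R - 1)) / (sse / dfe),
        "dfe": dfe,
    }


def test_fixed_model_f_matches_two_way_anova(rng):
    rows = {}
    for g in range(1, 7):
        for r in range(1, 5):
            rows[(g, "none", r, "none")] = rng.normal(5 + 0.3 * g + 0.1 * r, 0.5)
    table = trait_records(rows, trait="DW_S", units="g")
    fit = fit_mixed(table, ModelSpec(response="DW_S", split_root=False,
                                     transform="none",
                                     heterogeneous_residual=False))
    oracle = _two_way_anova_oracle(table.df)
    an = fit.anova.set_index("term")
    assert an.loc["genotype", "F"] == pytest.approx(oracle["genotype"], abs=1e-8)
    assert an.loc["replicate", "F"] == pytest.approx(oracle["replicate"], abs=1e-8)
    assert an.loc["genotype", "den_df"] == oracle["dfe"]


def _one_way_ems_oracle(y, groups):
    """Expected-mean-squares estimators for a balanced one-way random layout."""
    df = pd.DataFrame({"y": y, "g": groups})
    a = df["g"].nunique()
    r = len(df) // a
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    msb = r * ((means - grand) ** 2).sum() / (a - 1)
    msw = (df["y"] - df["g"].map(means)).pow(2).sum() / (len(df) - a)
    return max((msb - msw) / r, 0.0), msw


def test_reml_matches_ems_on_balanced_one_way(rng):
    for _ in range(3):
        G, R = 12, 4
        y = np.repeat(rng.normal(0, 1, G), R) + rng.normal(0, 1.3, G * R)
        groups = np.repeat(np.arange(G), R)
        Z = np.zeros((G * R, G))
        Z[np.arange(G * R), groups] = 1.0
        res = reml_fit(y, np.ones((G * R, 1)), Z=Z)
        s2g, s2e = _one_way_ems_oracle(y, groups)
        assert res.sigma2_u == pytest.approx(s2g, rel=1e-6)
        assert res.sigma2_e["all"] == pytest.approx(s2e, rel=1e-6)


def test_noiseless_trial_identified_exactly():
    truth = TrialTruth.sample(
        trait="ER_Cr", units="cm/d", mu=1.4, n_effect_delta=0.4,
        sigma2_g={"high": 0.01, "low": 0.004}, genotype_corr=0.3,
        rep_sd=0.05, side_sd=0.02, sigma2_gr=0.0,
        sigma2_e={"high": 0.0, "low": 0.0},
        n_genotypes=4, n_reps=3, rng=np.random.default_rng(7),
    )
    table = simulate_trial(truth, seed=1)
    fit = fit_mixed(table, ModelSpec(response="ER_Cr", transform="none"))
    assert all(v == 0.0 for v in fit.varcomp.values())
    resid = table.df["value"].to_numpy() - fit.result.fitted
    assert np.abs(resid).max() < 1e-8


def test_component_recovery_with_heterogeneous_residuals():
    """Per-stratum residual variances are recovered without cross-talk."""
    est_h, est_l, est_gr = [], [], []
    rng = np.random.default_rng(99)
    for _ in range(30):
        truth = TrialTruth.sample(
            trait="t", mu=0.0, sigma2_g=1.0, genotype_corr=1.0,
            sigma2_gr=0.5, sigma2_e={"high": 2.0, "low": 4.0},
            n_genotypes=24, n_reps=4, rng=rng,
        )
        fit = fit_mixed(simulate_trial(truth, seed=rng),
                        ModelSpec(response="t", transform="none"))
        est_h.append(fit.varcomp["residual_high"])
        est_l.append(fit.varcomp["residual_low"])
        est_gr.append(fit.varcomp["GR"])
    assert np.mean(est_h) == pytest.approx(2.0, rel=0.10)
    assert np.mean(est_l) == pytest.approx(4.0, rel=0.10)
    assert np.mean(est_gr) == pytest.approx(0.5, rel=0.25)


def test_gr_blups_sum_to_zero():
    rng = np.random.default_rng(5)
    truth = TrialTruth.sample(trait="t", mu=2.0, sigma2_g=0.3, sigma2_gr=0.4,
                              sigma2_e=1.0, n_genotypes=8, n_reps=4, rng=rng)
    fit = fit_mixed(simulate_trial(truth, seed=rng),
                    ModelSpec(response="t", transform="none"))
    assert fit.gr_blups.sum() == pytest.approx(0.0, abs=1e-6)


# --- heritability -----------------------------------------------------------

@pytest.mark.parametrize(
    "s2g, s2e, r, expected",
    [(3.0, 4.0, 4, 0.75), (0.0, 5.0, 4, 0.0), (2.0, 4.0, 4, 2 / 3),
     (-0.5, 4.0, 4, 0.0), (1.0, 0.0, 2, 1.0)],
)
def test_heritability_formula(s2g, s2e, r, expected):
    assert heritability(VarianceComponents(s2g, s2e, r)) == pytest.approx(expected)


def test_heritability_monotone_in_genetic_variance_and_reps():
    grid = np.linspace(0, 5, 11)
    h = [heritability(VarianceComponents(g, 4.0, 4)) for g in grid]
    assert all(b >= a for a, b in zip(h, h[1:]))
    hr = [heritability(VarianceComponents(1.0, 4.0, r)) for r in (1, 2, 4, 8)]
    assert all(b >= a for a, b in zip(hr, hr[1:]))
    assert all(0.0 <= v <= 1.0 for v in h + hr)


def test_heritability_invalid_replication():
    with pytest.raises(ValueError):
        VarianceComponents(1.0, 1.0, 0)


def test_estimate_heritability_on_known_stratum():
    rng = np.random.default_rng(11)
    truth = TrialTruth.sample(trait="sim", mu=10.0, sigma2_g=1.0,
                              genotype_corr=0.0, sigma2_gr=0.0, sigma2_e=2.0,
                              n_genotypes=24, n_reps=4, rng=rng)
    est = [estimate_heritability(simulate_trial(truth, seed=rng), "sim", "high").h2
           for _ in range(20)]
    assert np.mean(est) == pytest.approx(2 / 3, abs=0.08)


# --- Tukey HSD --------------------------------------------------------------

def test_tukey_hsd_values():
    assert tukey_hsd(q=4.0, mse=1.0, n=4) == pytest.approx(2.0)
    assert tukey_hsd(q=3.0, mse=0.0, n=4) == 0.0


def test_mse_from_avsed_inverts_sed():
    # sed = sqrt(2 MSE / n): avsed 1 with n = 2 implies MSE 1
    assert mse_from_avsed(1.0, 2) == pytest.approx(1.0)
    q = 3.5
    assert tukey_hsd(q, mse_from_avsed(1.0, 2), 2) == pytest.approx(q * np.sqrt(0.5))


def test_tukey_rejects_bad_inputs():
    with pytest.raises(ValueError):
        tukey_hsd(q=4.0, mse=1.0, n=0)
    with pytest.raises(ValueError):
        tukey_hsd(q=-1.0, mse=1.0, n=2)


# --- BLUP summaries ---------------------------------------------------------

def test_perfectly_correlated_traits_share_pc1(rng):
    base = rng.normal(0, 1, 24)
    m = pd.DataFrame({"a": base, "b": 2.0 * base + 5.0})
    s = blup_summaries(m)
    assert s.correlations.loc["a", "b"] == pytest.approx(1.0)
    assert s.explained_variance_ratio[0] == pytest.approx(1.0)


def test_correlation_matches_manual_pearson():
    m = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [3.0, 1.0, 2.0]})
    s = blup_summaries(m)
    a, b = m["a"], m["b"]
    manual = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
    assert s.correlations.loc["a", "b"] == pytest.approx(manual)


def test_zero_variance_trait_dropped_with_warning(rng):
    m = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                      "flat": np.ones(10)})
    with pytest.warns(UserWarning, match="flat"):
        s = blup_summaries(m)
    assert "flat" not in s.matrix.columns


def test_pca_sign_convention_and_requirements(rng):
    m = pd.DataFrame(rng.normal(size=(24, 4)), columns=list("abcd"))
    s = blup_summaries(m)
    for pc in s.pca_loadings.columns:
        col = s.pca_loadings[pc]
        assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0
    with pytest.raises(InsufficientDataError):
        blup_summaries(m.iloc[:2])
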
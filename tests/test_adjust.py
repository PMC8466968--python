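"""Phenotype adjustment model and LS-means."""

import numpy as np
import pandas as pd
import pytest

from rhmscan import PhenotypeAdjustment, trait_summary
from rhmscan.reml import reml_loglik


def test_balanced_design_means_equal_family_means(balanced_records):
    """Balanced complete design with sigma2_b ~ 0: GLS collapses to OLS and
    LS-means equal raw family means."""
    fit = PhenotypeAdjustment(balanced_records, "PH").fit()
    means = fit.adjusted_means()
    raw = balanced_records.groupby("family")["PH"].mean()
    for fam in raw.index:
        assert means[fam] == pytest.approx(raw[fam], abs=1e-6)


def _unbalanced_records():
    rng = np.random.default_rng(8)
    rows = []
    for rep in (1, 2):
        for bi, fams in enumerate([("A", "B", "C", "D"), ("E", "F", "G", "H")], start=1):
            for fam in fams:
                rows.append(
                    {"family": fam, "rep": rep, "block": bi,
                     "GY": 10 + rng.normal(0, 1),
                     "plants_per_plot": rng.integers(18, 24),
                     "kernel_moisture": rng.normal(13, 1)}
                )
    df = pd.DataFrame(rows)
    return df.drop(index=3).reset_index(drop=True)  # one missing plot


def test_unbalanced_fixed_effects_match_gls_oracle():
    """Fixed-effect estimates equal a brute-force GLS solve built from the
    explicit covariance matrix at the fitted variance components."""
    rec = _unbalanced_records()
    model = PhenotypeAdjustment(rec, "GY")
    fit = model.fit()
    V = fit.sigma2_block * model.structures[0] + fit.sigma2_resid * model.structures[1]
    X = model.X.to_numpy(float)
    Vinv = np.linalg.inv(V)
    beta_oracle = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ model.y)
    np.testing.assert_allclose(fit.reml.beta, beta_oracle, atol=1e-8)


def test_adjusted_means_match_marginal_mean_oracle():
    """LS-means equal explicit averaging of the coefficient vector over rep
    levels with covariates at grand means."""
    rec = _unbalanced_records()
    model = PhenotypeAdjustment(rec, "GY")
    fit = model.fit()
    beta = fit.coefficients()
    means = fit.adjusted_means()
    n_reps = rec["rep"].nunique()
    for fam in sorted(rec["family"].unique()):
        x = pd.Series(0.0, index=model.X.columns)
        x["intercept"] = 1.0
        for c in model.X.columns:
            if c.startswith("rep_"):
                x[c] = 1.0 / n_reps
        for c in model.covariates:
            if c in x.index:
                x[c] = rec[c].mean()
        if f"fam_{fam}" in x.index:
            x[f"fam_{fam}"] = 1.0
        assert means[fam] == pytest.approx(float(x @ beta), abs=1e-10)


def test_constant_covariate_aliased_and_dropped():
    rec = _unbalanced_records()
    rec["kernel_moisture"] = 13.0  # constant -> aliased with intercept
    with pytest.warns(UserWarning, match="aliased"):
        model = PhenotypeAdjustment(rec, "GY")
    fit = model.fit()
    base = PhenotypeAdjustment(_unbalanced_records().assign(kernel_moisture=13.0)
                               .pipe(lambda d: d), "GY", covariates=["plants_per_plot"]).fit()
    np.testing.assert_allclose(
        fit.adjusted_means().to_numpy(), base.adjusted_means().to_numpy(), atol=1e-8
    )


def test_translation_equivariance():
    rec = _unbalanced_records()
    m1 = PhenotypeAdjustment(rec, "GY").fit().adjusted_means()
    rec2 = rec.assign(GY=rec["GY"] + 7.5)
    m2 = PhenotypeAdjustment(rec2, "GY").fit().adjusted_means()
    np.testing.assert_allclose(m2.to_numpy() - m1.to_numpy(), 7.5, atol=1e-8)


def test_relabeling_rep_block_ids_leaves_means_unchanged():
    rec = _unbalanced_records()
    m1 = PhenotypeAdjustment(rec, "GY").fit().adjusted_means()
    rec2 = rec.assign(rep=rec["rep"].map({1: "x", 2: "y"}),
                      block=rec["block"].map({1: 17, 2: 3}))
    m2 = PhenotypeAdjustment(rec2, "GY").fit().adjusted_means()
    np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-8)


def test_reml_loglik_nondecreasing_over_iterations():
    rec = _unbalanced_records()
    fit = PhenotypeAdjustment(rec, "GY").fit()
    path = np.array(fit.reml.loglik_path)
    assert np.all(np.diff(path) >= -1e-7)


def test_requires_two_replications():
    rec = _unbalanced_records()
    with pytest.raises(ValueError, match="2 replications"):
        PhenotypeAdjustment(rec[rec["rep"] == 1], "GY")


# --- trait summary --------------------------------------------------------


def test_trait_summary_self_and_antisymmetric_correlations():
    rng = np.random.default_rng(0)
    y = rng.normal(size=50)
    means = pd.DataFrame({"A": y, "B": -y})
    out = trait_summary(means)
    assert out["pearson_r"].loc["A", "A"] == 1.0
    assert out["pearson_r"].loc["A", "B"] == pytest.approx(-1.0, abs=1e-12)


def test_trait_summary_null_correlation_distribution():
    """Two independent traits over 98 families: |r| < 0.3 in >= 95% of
    replicates (Monte-Carlo null)."""
    rng = np.random.default_rng(1)
    small = 0
    n_rep = 200
    for _ in range(n_rep):
        r = np.corrcoef(rng.normal(size=98), rng.normal(size=98))[0, 1]
        small += abs(r) < 0.3
    assert small / n_rep >= 0.95


def test_trait_summary_constant_trait_warns():
    means = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": [5.0] * 4})
    with pytest.warns(UserWarning, match="constant"):
        out = trait_summary(means)
    assert np.isnan(out["pearson_r"].loc["A", "B"])


def test_trait_summary_reports_shapiro_and_histogram():
    rng = np.random.default_rng(2)
    means = pd.DataFrame({"A": rng.normal(size=98)})
    out = trait_summary(means)
    info = out["traits"]["A"]
    assert 0 < info["shapiro_W"] <= 1
    assert sum(info["hist_counts"]) == 98
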
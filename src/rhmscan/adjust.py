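"""Per-trait phenotype adjustment in the incomplete-block design.

The plot model is

    y = intercept + replication + covariates + progeny + block(rep) + e,

with progeny (family) treated as FIXED so that estimated marginal means —
LS-means — can be reported per family, and block-within-replication random
with variance sigma2_b estimated by REML.  Covariates (plants per plot,
kernel moisture) enter only for the yield traits GY and PE.  A family's
adjusted mean averages the fitted fixed surface over replication levels with
covariates held at their grand means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .reml import MixedVarianceModel

__all__ = ["PhenotypeAdjustment", "PhenotypeAdjustmentResults", "trait_summary"]

DEFAULT_COVARIATES = {"GY": ["plants_per_plot", "kernel_moisture"],
                      "PE": ["plants_per_plot", "kernel_moisture"]}


def _dummies(values: pd.Series, prefix: str, drop_first: bool) -> pd.DataFrame:
    d = pd.get_dummies(values.astype(str), prefix=prefix, drop_first=drop_first)
    return d.astype(float)


class PhenotypeAdjustment:
    """Build the adjustment model for one trait from a plot-record table.

    Parameters
    ----------
    records : DataFrame with columns ``family``, ``rep``, ``block`` and the
        trait; rows with a missing trait value are dropped.
    trait : trait column name.
    covariates : covariate column names; defaults to plants-per-plot and
        kernel moisture for GY/PE and none otherwise.
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 covariates: list[str] | None = None):
        records = records.loc[records[trait].notna()].reset_index(drop=True)
        if records["rep"].nunique() < 2:
            raise ValueError("need at least 2 replications")
        self.records = records
        self.trait = trait
        self.covariates = (
            covariates if covariates is not None else DEFAULT_COVARIATES.get(trait, [])
        )

        y = records[trait].to_numpy(dtype=float)
        rep_d = _dummies(records["rep"], "rep", drop_first=True)
        fam_d = _dummies(records["family"], "fam", drop_first=True)
        cov = records[self.covariates].astype(float) if self.covariates else pd.DataFrame(index=records.index)
        X = pd.concat(
            [pd.Series(1.0, index=records.index, name="intercept"), rep_d, cov, fam_d],
            axis=1,
        )

        # drop aliased columns (rank-deficient design) by pivoted QR
        Xv = X.to_numpy(dtype=float)
        q, r, piv = linalg.qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        keep = np.sort(piv[:rank])
        dropped = [X.columns[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
        if any(c.startswith("fam_") for c in dropped):
            raise ValueError(f"aliased progeny columns cannot be dropped: {dropped}")
        if dropped:
            warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
        self.X = X.iloc[:, keep]
        self.y = y

        # block-within-rep random effect: one level per (rep, block)
        key = records["rep"].astype(str) + ":" + records["block"].astype(str)
        Zb = _dummies(key, "blk", drop_first=False).to_numpy(dtype=float)
        self.Z_block = Zb
        self.structures = [Zb @ Zb.T, np.eye(len(y))]

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, trait: str, **kw) -> "PhenotypeAdjustment":
        return cls(records, trait, **kw)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "PhenotypeAdjustmentResults":
        mm = MixedVarianceModel(
            self.y, self.X.to_numpy(dtype=float), self.structures,
            names=["block", "residual"],
        )
        res = mm.fit(tol=tol, maxiter=maxiter)
        return PhenotypeAdjustmentResults(self, res)


@dataclass
class PhenotypeAdjustmentResults:
    model: PhenotypeAdjustment
    reml: object  # MixedVarianceResults

    @property
    def sigma2_block(self) -> float:
        return float(self.reml.sigma2[0])

    @property
    def sigma2_resid(self) -> float:
        return float(self.reml.sigma2[1])

    @property
    def loglik(self) -> float:
        return float(self.reml.loglik)

    def coefficients(self) -> pd.Series:
        return pd.Series(self.reml.beta, index=self.model.X.columns)

    def adjusted_means(self) -> pd.Series:
        """LS-means per family: average the fixed surface over replication
        levels, covariates at their grand means."""
        beta = self.coefficients()
        cols = self.model.X.columns
        rec = self.model.records
        families = sorted(rec["family"].astype(str).unique())
        rep_cols = [c for c in cols if c.startswith("rep_")]
        n_reps = rec["rep"].nunique()
        cov_means = {c: rec[c].astype(float).mean() for c in self.model.covariates}

        base = pd.Series(0.0, index=cols)
        if "intercept" in cols:
            base["intercept"] = 1.0
        for c in rep_cols:  # dropped-first coding: each observed level weight 1/n_reps
            base[c] = 1.0 / n_reps
        for c, mval in cov_means.items():
            if c in cols:
                base[c] = mval

        out = {}
        for fam in families:
            x = base.copy()
            col = f"fam_{fam}"
            if col in cols:
                x[col] = 1.0
            out[fam] = float(x @ beta)
        return pd.Series(out, name=self.model.trait)

    def summary(self) -> str:
        lines = [
            f"Phenotype adjustment for {self.model.trait}"
            f" (n plots = {len(self.model.y)})",
            f"  sigma2_block = {self.sigma2_block:.6g}",
            f"  sigma2_resid = {self.sigma2_resid:.6g}",
            f"  REML log-likelihood = {self.loglik:.4f}",
            f"  covariates: {self.model.covariates or 'none'}",
        ]
        return "\n".join(lines)


def trait_summary(means: pd.DataFrame, n_bins: int = 10) -> dict:
    """Descriptive surface over family adjusted means.

    Returns per-trait mean/SD/histogram/Shapiro-Wilk and the pairwise
    Pearson correlation matrix with p-values.  Constant traits yield missing
    correlations with a warning.
    """
    if len(means) < 3:
        raise ValueError("need at least 3 families")
    traits = list(means.columns)
    per_trait = {}
    for t in traits:
        v = means[t].to_numpy(dtype=float)
        counts, edges = np.histogram(v, bins=n_bins)
        W, p = stats.shapiro(v)
        per_trait[t] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
            "shapiro_W": float(W),
            "shapiro_p": float(p),
        }
    r_mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p_mat = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            va, vb = means[a].to_numpy(float), means[b].to_numpy(float)
            if va.std() == 0 or vb.std() == 0:
                warnings.warn(f"constant trait in pair ({a},{b}); correlation undefined")
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(va, vb)
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return {"traits": per_trait, "pearson_r": r_mat, "pearson_p": p_mat}
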
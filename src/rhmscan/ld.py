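"""Linkage-disequilibrium decay: pairwise r² and the Hill–Weir expected-decay
curve.

For unphased dosage data, r² between two loci is the squared Pearson
correlation of the dosage vectors.  The expected r² under drift-recombination
equilibrium for a sample of n gametes/individuals is the Hill–Weir
expectation

    E[r²](C) = (10 + C) / ((2 + C)(11 + C))
               * [1 + ((3 + C)(12 + 12 C + C²)) / (n (2 + C)(11 + C))]

with C = rho * d, the population recombination parameter scaled by physical
distance d in bp.  Note the curve decays monotonically to the finite sampling
asymptote 1/n, not to zero.  rho is estimated by non-linear least squares on
the observed (distance, r²) cloud; the half-decay distance is where the
fitted curve reaches half its value at the smallest observed distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "hill_weir_expected_r2",
    "pairwise_r2",
    "LDDecayFit",
    "fit_hill_weir",
    "half_decay_distance",
]


def hill_weir_expected_r2(C: np.ndarray, n: int) -> np.ndarray:
    """Hill–Weir expectation of r² at scaled recombination distance C."""
    C = np.asarray(C, dtype=float)
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return a * b


def pairwise_r2(
    genotypes,
    chromosome,
    max_distance_bp: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """All intra-chromosomal pairwise r² values with physical distances.

    Returns ``(table, n_skipped)`` where the table has columns
    ``chromosome, pos1, pos2, dist, r2`` and ``n_skipped`` counts pairs
    dropped because one member has zero dosage variance.  Dosages must be
    imputed (no missing values).
    """
    info = genotypes.snp_info
    mask = (info["chromosome"].astype(str) == str(chromosome)).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"chromosome {chromosome!r} has fewer than 2 SNPs")
    M = np.asarray(genotypes.dosages[:, mask], dtype=float)
    if np.isnan(M).any():
        raise ValueError("dosages contain missing values; impute first")
    pos = info["position"][mask].to_numpy()

    sd = M.std(axis=0)
    ok = sd > 0
    Mk, posk = M[:, ok], pos[ok]
    m = Mk.shape[1]
    Z = (Mk - Mk.mean(axis=0)) / Mk.std(axis=0)
    R = (Z.T @ Z) / Mk.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    dist = np.abs(posk[ju] - posk[iu]).astype(float)
    r2 = np.clip(R[iu, ju] ** 2, 0.0, 1.0)
    m0 = int(mask.sum())
    n_skipped = m0 * (m0 - 1) // 2 - m * (m - 1) // 2
    keep = dist > 0
    tab = pd.DataFrame(
        {
            "chromosome": str(chromosome),
            "pos1": posk[iu][keep],
            "pos2": posk[ju][keep],
            "dist": dist[keep],
            "r2": r2[keep],
        }
    )
    if max_distance_bp is not None:
        tab = tab[tab["dist"] <= max_distance_bp].reset_index(drop=True)
    return tab, n_skipped


@dataclass
class LDDecayFit:
    """Fitted Hill–Weir decay for one chromosome."""

    chromosome: str
    rho_hat: float
    n: int
    half_decay_bp: float | None
    rss: float
    n_pairs: int
    n_starts_converged: int

    def expected_r2(self, dist_bp: np.ndarray) -> np.ndarray:
        return hill_weir_expected_r2(self.rho_hat * np.asarray(dist_bp, float), self.n)


def fit_hill_weir(
    pairs: pd.DataFrame,
    n: int,
    rho_grid: np.ndarray | None = None,
) -> LDDecayFit:
    """Least-squares fit of rho in the Hill–Weir decay curve.

    Multi-start non-linear least squares over a log-spaced grid of initial
    rho values; non-negativity enforced by optimising log(rho).
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to fit the decay curve")
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    d = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if rho_grid is None:
        rho_grid = np.logspace(-6, -2, 9)

    def resid(log_rho: np.ndarray) -> np.ndarray:
        return hill_weir_expected_r2(np.exp(log_rho[0]) * d, n) - r2

    best = None
    n_conv = 0
    for rho0 in rho_grid:
        sol = optimize.least_squares(resid, x0=[np.log(rho0)], method="lm")
        if not sol.success:
            continue
        n_conv += 1
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (float(np.exp(sol.x[0])), rss)
    if best is None:
        raise RuntimeError("Hill-Weir fit failed to converge from all starting values")
    rho_hat, rss = best
    fit = LDDecayFit(
        chromosome=str(pairs["chromosome"].iloc[0]) if "chromosome" in pairs else "",
        rho_hat=rho_hat,
        n=n,
        half_decay_bp=None,
        rss=rss,
        n_pairs=len(pairs),
        n_starts_converged=n_conv,
    )
    try:
        fit.half_decay_bp = half_decay_distance(fit, d_min=float(d.min()))
    except ValueError:
        fit.half_decay_bp = None
    return fit


def half_decay_distance(fit: LDDecayFit, d_min: float) -> float:
    """Distance at which the fitted curve falls to half its value at d_min.

    Solved by bisection to 1 bp.  Raises if the half-value target lies at or
    below the curve's large-distance asymptote 1/n (unreachable).
    """
    if fit.rho_hat <= 0:
        raise ValueError("half-decay undefined for rho_hat <= 0")
    f0 = float(hill_weir_expected_r2(fit.rho_hat * d_min, fit.n))
    target = f0 / 2.0
    asymptote = 1.0 / fit.n
    if target <= asymptote:
        raise ValueError(
            f"half-decay target {target:.4g} is at or below the 1/n asymptote "
            f"{asymptote:.4g}"
        )
    lo, hi = float(d_min), float(d_min) + 1.0
    while float(hill_weir_expected_r2(fit.rho_hat * hi, fit.n)) > target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("half-decay distance beyond search range")
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if float(hill_weir_expected_r2(fit.rho_hat * mid, fit.n)) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
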
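"""Restricted maximum likelihood for linear mixed models with dense covariance
structures.

The model is

    y = X beta + sum_c  u_c,        u_c ~ N(0, sigma2_c * K_c),

where each ``K_c`` is a known symmetric positive semi-definite n x n matrix
(e.g. ``Z Z'`` for a design-factor random effect, ``Z G Z'`` for a genomic
effect, or the identity for the residual).  Variance components are estimated
by maximising the REML log-likelihood

    l(sigma2) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],

with ``V = sum_c sigma2_c K_c`` and
``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``, using average-information (AI)
quasi-Newton updates with step halving and an EM fallback, under the
constraint ``sigma2_c >= 0``.  Components that converge onto the boundary are
fixed at zero and the remaining components are refit.

This is the engine behind both the plot-level phenotype-adjustment model
(random incomplete blocks) and the regional heritability scan (block +
regional genomic + polygenic + residual components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "MixedVarianceModel",
    "MixedVarianceResults",
    "reml_loglik",
    "direct_reml_maximize",
]


def _validate(y: np.ndarray, X: np.ndarray, structures: list[np.ndarray]) -> None:
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix X is rank deficient")
    for i, K in enumerate(structures):
        if K.shape != (n, n):
            raise ValueError(f"covariance structure {i} is not {n}x{n}")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError(f"covariance structure {i} is not symmetric")


def reml_loglik(
    sigma2: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
) -> float:
    """REML log-likelihood (up to the additive constant -(n-p)/2 log 2*pi).

    Returns ``-inf`` when V is not positive definite at ``sigma2``.
    """
    V = np.zeros_like(structures[0])
    for s, K in zip(sigma2, structures):
        V += s * K
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv_X = linalg.cho_solve(cf, X, check_finite=False)
    Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
    XtVinvX = X.T @ Vinv_X
    sign, logdet_XtVinvX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    return -0.5 * (logdet_V + logdet_XtVinvX + float(y @ Py))


@dataclass
class MixedVarianceResults:
    """Converged (or flagged) REML estimates for a :class:`MixedVarianceModel`."""

    model: "MixedVarianceModel"
    sigma2: np.ndarray
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    converged: bool
    n_iter: int
    loglik_path: list[float] = field(default_factory=list)
    boundary: np.ndarray | None = None  # bool mask of components fixed at 0

    @property
    def names(self) -> list[str]:
        return self.model.names

    def summary(self) -> str:
        lines = [
            "Mixed variance-component model (REML, average information)",
            f"  n obs: {self.model.nobs}   fixed effects: {self.model.X.shape[1]}",
            f"  REML log-likelihood: {self.loglik:.6f}"
            f"   converged: {self.converged} ({self.n_iter} iterations)",
            "  Variance components:",
        ]
        for name, s2 in zip(self.names, self.sigma2):
            lines.append(f"    {name:<12s} {s2:.6g}")
        return "\n".join(lines)


class MixedVarianceModel:
    """Linear mixed model defined by a response, fixed design and a list of
    covariance structures; ``fit()`` runs constrained AI-REML.

    Parameters
    ----------
    y : response vector, length n.
    X : fixed-effect design, n x p, full column rank.
    structures : list of symmetric PSD n x n covariance kernels, one per
        variance component.  The residual identity must be included
        explicitly.
    names : optional component labels for reporting.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        structures: list[np.ndarray],
        names: list[str] | None = None,
    ):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        structures = [np.asarray(K, dtype=float) for K in structures]
        _validate(y, X, structures)
        n, p = X.shape
        if n <= p + len(structures):
            raise ValueError("too few observations for the number of parameters")
        self.y = y
        self.X = X
        self.structures = structures
        self.names = names or [f"vc{i}" for i in range(len(structures))]

    @property
    def nobs(self) -> int:
        return self.y.shape[0]

    # -- internals ---------------------------------------------------------

    def _pieces(self, sigma2: np.ndarray):
        """V^-1-based quantities needed by one AI/EM iteration."""
        y, X = self.y, self.X
        V = np.zeros((self.nobs, self.nobs))
        for s, K in zip(sigma2, self.structures):
            V += s * K
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv = linalg.cho_solve(cf, np.eye(self.nobs), check_finite=False)
        Vinv_X = Vinv @ X
        XtVinvX = X.T @ Vinv_X
        XtVinvX_inv = np.linalg.inv(XtVinvX)
        P = Vinv - Vinv_X @ XtVinvX_inv @ Vinv_X.T
        Py = P @ y
        logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sign, logdet_X = np.linalg.slogdet(XtVinvX)
        ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
        beta = XtVinvX_inv @ (Vinv_X.T @ y)
        return P, Py, ll, beta, XtVinvX_inv

    def _fit_free(
        self,
        free: np.ndarray,
        start: np.ndarray,
        tol: float,
        maxiter: int,
    ):
        """AI-REML over the components flagged in ``free``; others pinned at 0."""
        y = self.y
        n = self.nobs
        vary = float(np.var(y)) or 1.0
        floor = 1e-8 * vary
        free = free.copy()
        sigma2 = start.copy()
        sigma2[~free] = 0.0
        sigma2[free] = np.maximum(sigma2[free], floor)

        P, Py, ll, beta, bcov = self._pieces(sigma2)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            idx = np.flatnonzero(free)
            Ks = [self.structures[i] for i in idx]
            KPy = [K @ Py for K in Ks]
            # score: dl/dsigma2_c = -1/2 (tr(P K_c) - y'P K_c P y)
            trPK = np.array([float(np.sum(P * K)) for K in Ks])
            yPKPy = np.array([float(Py @ v) for v in KPy])
            score = -0.5 * (trPK - yPKPy)

            # active set: a component sitting on the floor whose gradient
            # points outward (negative) is pinned at exactly zero
            on_floor = sigma2[idx] <= floor * (1.0 + 1e-9)
            pin = on_floor & (score < 0)
            if pin.any():
                for j in idx[pin]:
                    sigma2[j] = 0.0
                    free[j] = False
                if not free.any():
                    converged = True
                    break
                P, Py, ll, beta, bcov = self._pieces(sigma2)
                path.append(ll)
                continue

            # average information: AI_cd = 1/2 y'P K_c P K_d P y
            PKPy = [P @ v for v in KPy]
            AI = 0.5 * np.array([[float(u @ v) for v in KPy] for u in PKPy])

            accepted = None
            try:
                delta = np.linalg.solve(AI + 1e-10 * np.eye(len(idx)) * np.trace(AI), score)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(10):  # step halving
                    cand = sigma2.copy()
                    cand[idx] = np.maximum(sigma2[idx] + step * delta, floor)
                    cand_ll = reml_loglik(cand, y, self.X, self.structures)
                    if cand_ll >= ll - 1e-12:
                        accepted = cand
                        break
                    step *= 0.5
            if accepted is None:
                # EM fallback (monotone): sigma2 <- sigma2 + sigma2^2 (y'PKPy - tr(PK))/n
                cand = sigma2.copy()
                cand[idx] = np.maximum(
                    sigma2[idx] + sigma2[idx] ** 2 * (yPKPy - trPK) / n, floor
                )
                cand_ll = reml_loglik(cand, y, self.X, self.structures)
                if cand_ll < ll:  # numerically stuck; stop
                    converged = True
                    break
                accepted = cand

            sigma2 = accepted
            P, Py, ll_new, beta, bcov = self._pieces(sigma2)
            path.append(ll_new)
            if abs(ll_new - ll) < tol * (1.0 + abs(ll)):
                ll = ll_new
                converged = True
                break
            ll = ll_new

        at_floor = free & (sigma2 <= floor * (1.0 + 1e-9))
        return sigma2, ll, beta, bcov, converged, it, path, at_floor, free

    # -- public ------------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        tol: float = 1e-8,
        maxiter: int = 100,
    ) -> MixedVarianceResults:
        """Estimate variance components by AI-REML.

        ``start`` optionally warm-starts the iteration (values <= 0 are lifted
        to a small positive floor).  Components that land on the zero boundary
        are fixed at 0 and the remaining components refit; the reported
        log-likelihood is the better of the two fits.
        """
        n_c = len(self.structures)
        vary = float(np.var(self.y)) or 1.0
        if start is None:
            start = np.full(n_c, vary / n_c)
        start = np.asarray(start, dtype=float).copy()
        free = np.ones(n_c, dtype=bool)

        sigma2, ll, beta, bcov, conv, it, path, at_floor, free_out = self._fit_free(
            free, start, tol, maxiter
        )
        total_iter = it
        # boundary refit: any component that converged ON the floor (rather
        # than being pinned by the active set) is fixed at exactly zero and
        # the remaining components refit
        while at_floor.any() and (free_out & ~at_floor).sum() >= 1:
            free = free_out & ~at_floor
            s2b, llb, betab, bcovb, convb, itb, pathb, at_floor, free_out = (
                self._fit_free(free, sigma2, tol, maxiter)
            )
            total_iter += itb
            if llb >= ll - 1e-10:
                sigma2, ll, beta, bcov, conv = s2b, llb, betab, bcovb, convb
                path = path + pathb
            else:  # boundary refit should not lose likelihood; keep original
                break
        boundary = ~free_out
        sigma2 = sigma2.copy()
        sigma2[boundary] = 0.0

        return MixedVarianceResults(
            model=self,
            sigma2=sigma2,
            loglik=ll,
            beta=beta,
            beta_cov=bcov,
            converged=conv,
            n_iter=total_iter,
            loglik_path=path,
            boundary=boundary,
        )


def direct_reml_maximize(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 5000,
) -> tuple[np.ndarray, float]:
    """Derivative-free direct maximisation of the REML log-likelihood.

    Nelder-Mead on log-variances from several random starts, plus explicit
    boundary sub-models with each single component removed.  Slow but entirely
    independent of the AI-REML iteration; used as a cross-check oracle.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    structures = [np.asarray(K, dtype=float) for K in structures]
    rng = np.random.default_rng(seed)
    vary = float(np.var(y)) or 1.0
    n_c = len(structures)

    def run(subset: list[int]) -> tuple[np.ndarray, float]:
        Ks = [structures[i] for i in subset]

        def neg(theta: np.ndarray) -> float:
            full = np.zeros(n_c)
            full[subset] = np.exp(theta)
            return -reml_loglik(full, y, X, structures)

        best_ll, best_s2 = -np.inf, None
        starts = [np.log(np.full(len(Ks), vary / n_c))]
        for _ in range(n_starts - 1):
            starts.append(np.log(vary * rng.uniform(0.02, 2.0, size=len(Ks))))
        for x0 in starts:
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": maxiter},
            )
            if -res.fun > best_ll:
                best_ll = -res.fun
                best_s2 = np.zeros(n_c)
                best_s2[subset] = np.exp(res.x)
        return best_s2, best_ll

    best_s2, best_ll = run(list(range(n_c)))
    # boundary candidates: drop each non-residual component in turn
    for drop in range(n_c):
        subset = [i for i in range(n_c) if i != drop]
        if not subset:
            continue
        s2, ll = run(subset)
        if ll > best_ll:
            best_s2, best_ll = s2, ll
    return best_s2, best_ll
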
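"""Regional heritability mapping: windowed variance-component scan.

Overlapping genomic windows (100 kb, 50 kb step by default) each get a
regional VanRaden relationship matrix ``Greg``.  Per window the plot-level
mixed model

    y = X beta + Z1 b + Z2 r + Z3 u + e,
    b ~ N(0, I sb2), r ~ N(0, Greg sr2), u ~ N(0, G su2), e ~ N(0, I se2)

is fitted by AI-REML (fixed effects: intercept, replication, and the
plants-per-plot / kernel-moisture covariates for GY and PE).  The regional
component is tested by a likelihood-ratio test against the null model
without ``r`` (chi-square with 1 df by default, or the 50:50 boundary
mixture), and the regional heritability is

    h2_region = sr2 / (sr2 + su2 + se2),

block variance excluded from the denominator as design rather than
genetic-plus-residual variance.  Significant windows (p <= alpha) that
overlap or abut are merged into QTL regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import vanraden_grm, regional_grm
from .reml import MixedVarianceModel

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "ScanConfig",
    "VarianceComponents",
    "RHMResult",
    "QTLRegion",
    "make_windows",
    "build_design",
    "lrt_pvalue",
    "regional_heritability",
    "RegionalHeritabilityScan",
    "ScanResults",
    "merge_regions",
    "manhattan_table",
]


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) with the SNP ids it contains."""

    chromosome: str
    start: int
    end: int
    snp_ids: tuple = ()

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ScanConfig:
    window_size: int = 100_000
    step: int = 50_000
    min_snps: int = 2
    alpha: float = 0.001
    lrt_reference: str = "chi2_1df"  # or "mixture_50_50"
    exclude_window_from_G: bool = False
    reml_tol: float = 1e-8
    reml_maxiter: int = 100

    def __post_init__(self):
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.lrt_reference not in ("chi2_1df", "mixture_50_50"):
            raise ValueError(f"unknown LRT reference {self.lrt_reference!r}")


@dataclass
class VarianceComponents:
    sigma2_b: float
    sigma2_r: float
    sigma2_u: float
    sigma2_e: float

    def __post_init__(self):
        for name in ("sigma2_b", "sigma2_r", "sigma2_u", "sigma2_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and non-negative")


@dataclass
class RHMResult:
    window: Window
    trait: str
    environment: str
    components: VarianceComponents
    logL_full: float
    logL_null: float
    lrt: float
    p_value: float
    h2_region: float
    h2_polygenic: float
    converged: bool


@dataclass
class QTLRegion:
    chromosome: str
    start: int
    end: int
    n_snps: int
    peak_neglog10p: float
    peak_h2_region: float
    windows: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


def make_windows(snp_info: pd.DataFrame, cfg: ScanConfig) -> list[Window]:
    """Enumerate windows [k*step, k*step + window_size) per chromosome until
    the last SNP is covered; keep only windows holding >= min_snps SNPs."""
    windows: list[Window] = []
    for chrom, sub in snp_info.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy()
        ids = sub["id"].to_numpy()
        last = int(pos.max())
        k = 0
        while k * cfg.step <= last:
            start = k * cfg.step
            end = start + cfg.window_size
            inside = (pos >= start) & (pos < end)
            if int(inside.sum()) >= cfg.min_snps:
                windows.append(
                    Window(str(chrom), start, end, tuple(ids[inside].tolist()))
                )
            k += 1
    return windows


def build_design(
    records: pd.DataFrame,
    trait: str,
    family_ids: list[str],
    covariates: list[str] | None = None,
) -> dict:
    """Assemble y, X and the random-effect incidence matrices for the scan.

    ``family_ids`` is the genotyped family order (rows of the GRM); every
    phenotyped family must appear in it.  Covariates default to plants per
    plot and kernel moisture for GY/PE and none otherwise.
    """
    from .adjust import DEFAULT_COVARIATES, _dummies

    records = records.loc[records[trait].notna()].reset_index(drop=True)
    missing = sorted(set(records["family"].astype(str)) - set(map(str, family_ids)))
    if missing:
        raise ValueError(f"phenotyped families without genotypes: {missing}")
    if covariates is None:
        covariates = DEFAULT_COVARIATES.get(trait, [])

    y = records[trait].to_numpy(dtype=float)
    rep_d = _dummies(records["rep"], "rep", drop_first=True)
    parts = [pd.Series(1.0, index=records.index, name="intercept"), rep_d]
    if covariates:
        parts.append(records[covariates].astype(float))
    X = pd.concat(parts, axis=1)

    key = records["rep"].astype(str) + ":" + records["block"].astype(str)
    Z1 = _dummies(key, "blk", drop_first=False).to_numpy(dtype=float)

    fam_index = {str(f): i for i, f in enumerate(family_ids)}
    Z3 = np.zeros((len(records), len(family_ids)))
    for r, fam in enumerate(records["family"].astype(str)):
        Z3[r, fam_index[fam]] = 1.0

    return {
        "y": y,
        "X": X,
        "Z1": Z1,
        "Z3": Z3,
        "records": records,
        "covariates": covariates,
    }


def lrt_pvalue(
    logL_full: float, logL_null: float, reference: str = "chi2_1df"
) -> tuple[float, float]:
    """LRT statistic (clipped at 0) and its p-value.

    ``chi2_1df`` refers the statistic to a chi-square with 1 df
    (conservative at the sigma2 >= 0 boundary); ``mixture_50_50`` uses the
    boundary mixture  1/2 chi2_0 + 1/2 chi2_1.
    """
    lrt = max(0.0, 2.0 * (logL_full - logL_null))
    if reference == "chi2_1df":
        p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    elif reference == "mixture_50_50":
        p = float(0.5 * stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    else:
        raise ValueError(f"unknown LRT reference {reference!r}")
    return lrt, p


def regional_heritability(vc: VarianceComponents) -> tuple[float, float]:
    """(h2_region, h2_polygenic) with block variance excluded from the
    denominator."""
    denom = vc.sigma2_r + vc.sigma2_u + vc.sigma2_e
    if denom <= 0:
        raise ValueError("zero genetic-plus-residual variance")
    return vc.sigma2_r / denom, vc.sigma2_u / denom


class RegionalHeritabilityScan:
    """Model object for the windowed scan on one trait x environment.

    Parameters
    ----------
    genotypes : family-level, QC'd and imputed genotype matrix.
    records : plot-level phenotype table (family, rep, block, covariates,
        trait columns).
    trait : trait column to scan.
    environment : label recorded in the results.
    config : :class:`ScanConfig`.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        records: pd.DataFrame,
        trait: str,
        environment: str = "ENV1",
        config: ScanConfig | None = None,
    ):
        self.genotypes = genotypes
        self.trait = trait
        self.environment = environment
        self.config = config or ScanConfig()
        self.design = build_design(records, trait, list(genotypes.individual_ids))
        self.freqs = genotypes.allele_freqs()
        self.grm = vanraden_grm(
            genotypes.dosages, freqs=self.freqs, ids=list(genotypes.individual_ids),
            snp_ids=list(genotypes.snp_info["id"]),
        )
        self.windows = make_windows(genotypes.snp_info, self.config)
        Z1, Z3 = self.design["Z1"], self.design["Z3"]
        self._K_block = Z1 @ Z1.T
        self._K_poly = Z3 @ self.grm.values @ Z3.T
        self._I = np.eye(len(self.design["y"]))

    # -- single fits -------------------------------------------------------

    def _structures_null(self) -> list[np.ndarray]:
        return [self._K_block, self._K_poly, self._I]

    def fit_null(self):
        mm = MixedVarianceModel(
            self.design["y"],
            self.design["X"].to_numpy(dtype=float),
            self._structures_null(),
            names=["block", "polygenic", "residual"],
        )
        return mm.fit(tol=self.config.reml_tol, maxiter=self.config.reml_maxiter)

    def fit_window(self, window: Window, null_res=None):
        """Full-model AI-REML fit for one window (warm-started from the null
        estimates when provided)."""
        cfg = self.config
        Z1, Z3, y = self.design["Z1"], self.design["Z3"], self.design["y"]
        Greg = regional_grm(self.genotypes, window, freqs=self.freqs)
        if cfg.exclude_window_from_G:
            keep = ~self.genotypes.snp_info["id"].isin(window.snp_ids).to_numpy()
            G = vanraden_grm(
                self.genotypes.dosages[:, keep],
                freqs=self.freqs[keep],
                ids=list(self.genotypes.individual_ids),
            ).values
            K_poly = Z3 @ G @ Z3.T
        else:
            K_poly = self._K_poly
        structures = [self._K_block, Z3 @ Greg.values @ Z3.T, K_poly, self._I]
        mm = MixedVarianceModel(
            y, self.design["X"].to_numpy(dtype=float), structures,
            names=["block", "regional", "polygenic", "residual"],
        )
        start = None
        if null_res is not None:
            sb, su, se = null_res.sigma2
            start = np.array([sb, 0.05 * max(se, 1e-8), su, se])
        return mm.fit(start=start, tol=cfg.reml_tol, maxiter=cfg.reml_maxiter)

    # -- full scan ---------------------------------------------------------

    def fit(self) -> "ScanResults":
        """Fit the null model once, then every window; returns ScanResults."""
        cfg = self.config
        null_res = self.fit_null()
        results: list[RHMResult] = []
        for w in self.windows:
            try:
                full = self.fit_window(w, null_res=null_res)
            except Exception as exc:  # scan continues past individual failures
                logger.warning("window %s failed: %s", w.label, exc)
                continue
            lrt, p = lrt_pvalue(full.loglik, null_res.loglik, cfg.lrt_reference)
            vc = VarianceComponents(*np.maximum(full.sigma2, 0.0))
            h2r, h2u = regional_heritability(vc)
            results.append(
                RHMResult(
                    window=w,
                    trait=self.trait,
                    environment=self.environment,
                    components=vc,
                    logL_full=full.loglik,
                    logL_null=null_res.loglik,
                    lrt=lrt,
                    p_value=p,
                    h2_region=h2r,
                    h2_polygenic=h2u,
                    converged=full.converged,
                )
            )
        return ScanResults(self, null_res, results)


@dataclass
class ScanResults:
    """Scan outcome: per-window components, tests and heritabilities."""

    model: RegionalHeritabilityScan
    null_fit: object
    results: list[RHMResult]

    def manhattan_table(self) -> pd.DataFrame:
        return manhattan_table(self.results, alpha=self.model.config.alpha)

    def qtl_regions(self, alpha: float | None = None) -> list[QTLRegion]:
        return merge_regions(
            self.results, alpha=alpha if alpha is not None else self.model.config.alpha
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "chromosome": r.window.chromosome,
                    "start": r.window.start,
                    "end": r.window.end,
                    "n_snps": len(r.window.snp_ids),
                    "trait": r.trait,
                    "environment": r.environment,
                    "sigma2_b": r.components.sigma2_b,
                    "sigma2_r": r.components.sigma2_r,
                    "sigma2_u": r.components.sigma2_u,
                    "sigma2_e": r.components.sigma2_e,
                    "logL_full": r.logL_full,
                    "logL_null": r.logL_null,
                    "lrt": r.lrt,
                    "p_value": r.p_value,
                    "h2_region": r.h2_region,
                    "h2_polygenic": r.h2_polygenic,
                    "converged": r.converged,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.to_frame()
        regions = self.qtl_regions()
        lines = [
            f"Regional heritability scan: trait {self.model.trait}, "
            f"{self.model.environment}",
            f"  windows tested: {len(tab)}",
            f"  null model logL: {self.null_fit.loglik:.4f}",
        ]
        if len(tab):
            best = tab.loc[tab["p_value"].idxmin()]
            lines.append(
                f"  top window: {best['chromosome']}:{int(best['start'])}-"
                f"{int(best['end'])}  p = {best['p_value']:.3g}  "
                f"h2_region = {best['h2_region']:.3f}"
            )
        lines.append(
            f"  significant windows (p <= {self.model.config.alpha}): "
            f"{int((tab['p_value'] <= self.model.config.alpha).sum()) if len(tab) else 0}"
        )
        lines.append(f"  QTL regions after merging: {len(regions)}")
        for reg in regions:
            lines.append(
                f"    {reg.label}  snps = {reg.n_snps}  "
                f"peak -log10 p = {reg.peak_neglog10p:.2f}  "
                f"peak h2_region = {reg.peak_h2_region:.3f}"
            )
        return "\n".join(lines)


def merge_regions(results: list[RHMResult], alpha: float = 0.001) -> list[QTLRegion]:
    """Merge significant windows (p <= alpha) that overlap or abut into QTL
    regions; span is the interval union, SNP count is distinct SNPs."""
    sig = [r for r in results if r.p_value <= alpha]
    regions: list[QTLRegion] = []
    by_chrom: dict[str, list[RHMResult]] = {}
    for r in sig:
        by_chrom.setdefault(r.window.chromosome, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.window.start)
        group: list[RHMResult] = []
        for r in rs:
            if group and r.window.start <= group[-1].window.end:
                group.append(r)
            else:
                if group:
                    regions.append(_close_group(chrom, group))
                group = [r]
        if group:
            regions.append(_close_group(chrom, group))
    return regions


def _close_group(chrom: str, group: list[RHMResult]) -> QTLRegion:
    start = min(r.window.start for r in group)
    end = max(r.window.end for r in group)
    snps = set()
    for r in group:
        snps.update(r.window.snp_ids)
    peak = min(group, key=lambda r: r.p_value)
    return QTLRegion(
        chromosome=chrom,
        start=start,
        end=end,
        n_snps=len(snps),
        peak_neglog10p=float(-np.log10(max(peak.p_value, 1e-300))),
        peak_h2_region=peak.h2_region,
        windows=[r.window for r in group],
    )


def manhattan_table(results: list[RHMResult], alpha: float = 0.001) -> pd.DataFrame:
    """One row per tested window in genome order: midpoint, -log10 p,
    regional h2, significance flag (p <= alpha inclusive)."""
    rows = []
    for r in results:
        rows.append(
            {
                "chromosome": r.window.chromosome,
                "midpoint": r.window.midpoint,
                "start": r.window.start,
                "end": r.window.end,
                "neglog10_p": float(-np.log10(max(r.p_value, 1e-300))),
                "h2_region": r.h2_region,
                "significant": bool(r.p_value <= alpha),
            }
        )
    tab = pd.DataFrame(rows)
    if len(tab):
        tab = tab.sort_values(["chromosome", "start"], kind="mergesort").reset_index(
            drop=True
        )
    return tab
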
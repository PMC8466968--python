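"""Synthetic S1-family genotypes and plot phenotypes for desk-scale testing.

The generator emulates a recurrent-selection popcorn panel: ~98 S1 families
genotyped by capture probes, phenotyped in incomplete blocks with three
replications.  Marker structure is clustered — probes produce tight clusters
of SNPs, and within a cluster families share founder haplotypes, which
induces the within-window LD that the regional scan exploits.  Each family's
genotype comes from sampling a parent's two cluster haplotypes from a small
founder pool and one generation of selfing (expected inbreeding F = 0.5).

Phenotypes are built per plot as

    y = mean + rep + block(rep) + covariates + regional QTL terms
        + polygenic value + residual,

with the regional terms constructed from centred dosages of the SNPs inside
each configured QTL window, scaled so the realised variance fraction across
families equals the configured regional h²; the polygenic value is drawn
with covariance proportional to the whole-genome VanRaden matrix and scaled
to the configured polygenic h²; the residual picks up the remainder so the
non-design phenotypic variance is 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import vanraden_grm

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the real design: 98 S1 families, 3 replications in
    incomplete blocks, 10 chromosomes of 200 Mb carrying ~50 probe clusters
    each (10 SNPs per 40 kb cluster, 4 founder haplotypes), MAF floor 0.05.
    """

    n_families: int = 98
    n_reps: int = 3
    n_blocks_per_rep: int = 7
    n_chromosomes: int = 10
    chrom_length_bp: float = 2.0e8
    n_clusters_per_chrom: int = 50
    snps_per_cluster: int = 10
    cluster_span_bp: float = 40_000.0
    n_founder_haplotypes_per_cluster: int = 4
    maf_floor: float = 0.05
    qtl_windows: list = field(default_factory=list)  # [(chrom, start, end), ...]
    regional_h2: list = field(default_factory=list)  # parallel to qtl_windows
    polygenic_h2: float = 0.3
    block_var_frac: float = 0.05
    rep_effect_sizes: tuple = (0.0, 0.3, -0.3)
    covariate_coeffs: dict = field(
        default_factory=lambda: {"plants_per_plot": 0.03, "kernel_moisture": -0.05}
    )
    traits: tuple = ("GY", "PE", "PH", "EH")
    trait_means: dict = field(
        default_factory=lambda: {"GY": 2500.0, "PE": 28.0, "PH": 180.0, "EH": 100.0}
    )
    seed: int = 0

    def __post_init__(self):
        if len(self.regional_h2) != len(self.qtl_windows):
            raise ValueError("regional_h2 must parallel qtl_windows")
        total = sum(self.regional_h2) + self.polygenic_h2 + self.block_var_frac
        if total >= 1.0:
            raise ValueError(
                f"regional + polygenic + block variance fractions sum to {total} >= 1"
            )
        if any(h <= 0 or h >= 1 for h in self.regional_h2):
            raise ValueError("each regional_h2 must lie in (0, 1)")
        for chrom, start, end in self.qtl_windows:
            if not (0 <= start < end <= self.chrom_length_bp):
                raise ValueError(
                    f"QTL window {chrom}:{start}-{end} outside chromosome length"
                )
        if not 1 <= self.n_blocks_per_rep <= self.n_families:
            raise ValueError("n_blocks_per_rep must be in [1, n_families]")


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated data set."""

    qtl_windows: list
    regional_h2: list
    variance_components: dict  # per trait: {"sigma2_r": [...], "sigma2_u", "sigma2_e", "sigma2_b"}
    polygenic_values: dict  # per trait: family -> value
    regional_values: dict  # per trait: list (per window) of family -> value
    block_effects: dict  # per trait: (rep, block) -> value
    rep_effects: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _cluster_positions(cfg: SimConfig, rng: np.random.Generator):
    """Deterministic cluster centres, jittered SNP positions within spans."""
    chroms, positions, cluster_of = [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        centres = (np.arange(cfg.n_clusters_per_chrom) + 0.5) * (
            cfg.chrom_length_bp / cfg.n_clusters_per_chrom
        )
        for k, centre in enumerate(centres):
            offs = np.sort(
                rng.uniform(-cfg.cluster_span_bp / 2, cfg.cluster_span_bp / 2,
                            size=cfg.snps_per_cluster)
            )
            pos = np.clip(np.round(centre + offs), 1, cfg.chrom_length_bp - 1)
            pos = np.unique(pos.astype(np.int64))
            while len(pos) < cfg.snps_per_cluster:  # resolve rounding collisions
                extra = np.round(
                    centre + rng.uniform(-cfg.cluster_span_bp / 2, cfg.cluster_span_bp / 2)
                )
                pos = np.unique(np.append(pos, np.clip(extra, 1, cfg.chrom_length_bp - 1)))
            chroms += [str(c)] * cfg.snps_per_cluster
            positions += list(np.sort(pos)[: cfg.snps_per_cluster])
            cluster_of += [(c, k)] * cfg.snps_per_cluster
    return chroms, positions, cluster_of


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate family-level dosages with founder-haplotype LD in clusters.

    Returns the genotype matrix (one row per family) and a small dict of
    bookkeeping (founder frequencies, haplotype picks) reused by tests.
    SNPs violating the MAF floor are resampled at the founder-allele level
    (haplotype assignments kept), unless only one founder haplotype exists,
    in which case clusters are deliberately monomorphic across families.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, cluster_of = _cluster_positions(cfg, rng)
    m = len(positions)
    n_fam = cfg.n_families
    n_hap = cfg.n_founder_haplotypes_per_cluster
    spc = cfg.snps_per_cluster

    clusters = list(dict.fromkeys(cluster_of))
    dosages = np.zeros((n_fam, m))
    col = 0
    for cl in clusters:
        # founder haplotypes for this cluster: n_hap x snps_per_cluster
        founder_p = rng.uniform(0.15, 0.85, size=spc)
        H = (rng.random((n_hap, spc)) < founder_p).astype(float)
        # parent picks two haplotypes; S1 child draws each gamete from them
        parent = rng.integers(0, n_hap, size=(n_fam, 2))
        pick = rng.integers(0, 2, size=(n_fam, 2))  # which parental hap per gamete
        hap_idx = np.take_along_axis(parent, pick, axis=1)  # n_fam x 2
        block = H[hap_idx[:, 0]] + H[hap_idx[:, 1]]

        if n_hap >= 2:
            for j in range(spc):
                attempts = 0
                while True:
                    p = block[:, j].mean() / 2.0
                    if min(p, 1 - p) >= cfg.maf_floor:
                        break
                    attempts += 1
                    if attempts > 500:
                        raise RuntimeError("could not satisfy MAF floor; widen founder_p")
                    col_alleles = (rng.random(n_hap) < rng.uniform(0.2, 0.8)).astype(float)
                    H[:, j] = col_alleles
                    block[:, j] = H[hap_idx[:, 0], j] + H[hap_idx[:, 1], j]
        dosages[:, col : col + spc] = block
        col += spc

    fam_ids = [f"F{i + 1:03d}" for i in range(n_fam)]
    snp_info = pd.DataFrame(
        {
            "id": [f"S{c}_{p}" for c, p in zip(chroms, positions)],
            "chromosome": chroms,
            "position": np.asarray(positions, dtype=np.int64),
        }
    )
    g = GenotypeMatrix(
        individual_ids=fam_ids,
        family_ids=fam_ids,
        dosages=dosages,
        snp_info=snp_info,
    ).sorted_by_position()
    return g, {"clusters": clusters}


def _scale_to_var(v: np.ndarray, target_var: float) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) effect vector; no polymorphism")
    return v * (np.sqrt(target_var) / sd)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the plot-level phenotype table for all configured traits.

    One record per family x replication; incomplete blocks are a random
    equal-size partition of families within each rep.  Covariates
    (plants per plot, kernel moisture) attach to GY/PE only.
    """
    if genotypes.n_individuals != cfg.n_families:
        raise ValueError("genotype families do not match config n_families")
    rng = np.random.default_rng(cfg.seed + 1)
    n_fam, n_reps = cfg.n_families, cfg.n_reps
    fams = list(genotypes.individual_ids)
    info = genotypes.snp_info

    # regional design pieces: centred dosages per QTL window
    freqs = genotypes.allele_freqs()
    W_all = genotypes.dosages - 2.0 * freqs
    window_cols = []
    for chrom, start, end in cfg.qtl_windows:
        mask = (
            (info["chromosome"].astype(str) == str(chrom))
            & (info["position"] >= start)
            & (info["position"] < end)
        ).to_numpy()
        if not mask.any():
            raise ValueError(f"QTL window {chrom}:{start}-{end} contains no SNPs")
        window_cols.append(mask)

    G = vanraden_grm(genotypes.dosages, freqs=freqs, ids=fams).values
    L = np.linalg.cholesky(G + 1e-8 * np.trace(G) / n_fam * np.eye(n_fam))

    # plot design
    rows = []
    block_of = {}
    for rep in range(1, n_reps + 1):
        perm = rng.permutation(n_fam)
        blocks = np.array_split(perm, cfg.n_blocks_per_rep)
        for b, members in enumerate(blocks, start=1):
            for i in members:
                block_of[(rep, fams[i])] = b
    plants = np.round(rng.normal(21, 2, size=n_fam * n_reps)).clip(5)
    moisture = rng.normal(13.0, 1.5, size=n_fam * n_reps)

    sigma2_e = {
        t: 1.0 - sum(cfg.regional_h2) - cfg.polygenic_h2 - cfg.block_var_frac
        for t in cfg.traits
    }
    truth = SimTruth(
        qtl_windows=list(cfg.qtl_windows),
        regional_h2=list(cfg.regional_h2),
        variance_components={},
        polygenic_values={},
        regional_values={},
        block_effects={},
        rep_effects=list(cfg.rep_effect_sizes[:n_reps]),
    )

    trait_cols = {t: [] for t in cfg.traits}
    per_trait_fam_effects = {}
    for t in cfg.traits:
        regional_vals = []
        for mask, h2 in zip(window_cols, cfg.regional_h2):
            a = rng.normal(size=int(mask.sum()))
            regional_vals.append(_scale_to_var(W_all[:, mask] @ a, h2))
        if cfg.polygenic_h2 > 0:
            poly = _scale_to_var(L @ rng.normal(size=n_fam), cfg.polygenic_h2)
        else:
            poly = np.zeros(n_fam)
        blocks_eff = {
            (rep, b): rng.normal(0.0, np.sqrt(cfg.block_var_frac)) if cfg.block_var_frac > 0 else 0.0
            for rep in range(1, n_reps + 1)
            for b in range(1, cfg.n_blocks_per_rep + 1)
        }
        per_trait_fam_effects[t] = (regional_vals, poly, blocks_eff)
        truth.variance_components[t] = {
            "sigma2_r": list(cfg.regional_h2),
            "sigma2_u": cfg.polygenic_h2,
            "sigma2_b": cfg.block_var_frac,
            "sigma2_e": sigma2_e[t],
        }
        truth.polygenic_values[t] = dict(zip(fams, poly.tolist()))
        truth.regional_values[t] = [dict(zip(fams, rv.tolist())) for rv in regional_vals]
        truth.block_effects[t] = {f"{rep}:{b}": v for (rep, b), v in blocks_eff.items()}

    idx = 0
    for rep in range(1, n_reps + 1):
        rep_eff = cfg.rep_effect_sizes[rep - 1] if rep - 1 < len(cfg.rep_effect_sizes) else 0.0
        for i, fam in enumerate(fams):
            rec = {
                "family": fam,
                "env": "ENV1",
                "rep": rep,
                "block": block_of[(rep, fam)],
                "plants_per_plot": float(plants[idx]),
                "kernel_moisture": float(moisture[idx]),
            }
            for t in cfg.traits:
                regional_vals, poly, blocks_eff = per_trait_fam_effects[t]
                yv = rep_eff + blocks_eff[(rep, rec["block"])]
                for rv in regional_vals:
                    yv += rv[i]
                yv += poly[i]
                yv += rng.normal(0.0, np.sqrt(sigma2_e[t]))
                if t in ("GY", "PE"):
                    yv += cfg.covariate_coeffs.get("plants_per_plot", 0.0) * (
                        rec["plants_per_plot"] - 21.0
                    )
                    yv += cfg.covariate_coeffs.get("kernel_moisture", 0.0) * (
                        rec["kernel_moisture"] - 13.0
                    )
                rec[t] = cfg.trait_means.get(t, 0.0) + yv
            rows.append(rec)
            idx += 1

    records = pd.DataFrame(rows)
    return records, truth
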
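"""End-to-end pipeline: QC -> adjustment -> GRM -> LD -> scan -> regions ->
candidate genes, with all artifacts written as TSV/CSV plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import PhenotypeAdjustment, trait_summary
from .annot import genes_in_region, read_gff3
from .genotypes import (
    QCConfig,
    aggregate_to_families,
    filter_individuals,
    filter_snps,
    impute_missing,
    read_genotypes,
)
from .io import write_tsv
from .kinship import vanraden_grm
from .ld import fit_hill_weir, pairwise_r2
from .scan import RegionalHeritabilityScan, ScanConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    output_dir: str
    annotation: str | None = None
    traits: list = field(default_factory=lambda: ["GY"])
    environment: str = "ENV1"
    qc: QCConfig = field(default_factory=QCConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    aggregate_families: bool = True
    ld_max_distance_bp: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotypes", "phenotypes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.annotation is not None and not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation path does not exist: {self.annotation}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write artifacts under ``cfg.output_dir``.

    Returns a dict of the in-memory products (genotypes, reports, fits,
    scan results, regions, candidate genes) for programmatic use.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- QC stage
    g = read_genotypes(cfg.genotypes)
    g = filter_individuals(g, cfg.qc)
    g, qc_report = filter_snps(g, cfg.qc)
    g = impute_missing(g)
    if cfg.aggregate_families:
        g = aggregate_to_families(g)
    write_tsv(qc_report.to_frame(), out / "qc_report.tsv")

    # --- phenotypes and adjusted means
    records = pd.read_csv(cfg.phenotypes)
    means = {}
    adj_fits = {}
    for trait in cfg.traits:
        fit = PhenotypeAdjustment(records, trait).fit()
        adj_fits[trait] = fit
        means[trait] = fit.adjusted_means()
    means_df = pd.DataFrame(means)
    means_df.index.name = "family"
    means_df.reset_index().to_csv(out / "adjusted_means.tsv", sep="\t", index=False)
    if len(means_df) >= 3 and len(cfg.traits) >= 1:
        summ = trait_summary(means_df)
        summ["pearson_r"].to_csv(out / "trait_correlations.tsv", sep="\t")
        norm = pd.DataFrame(
            [
                {"trait": t, "mean": v["mean"], "sd": v["sd"],
                 "shapiro_W": v["shapiro_W"], "shapiro_p": v["shapiro_p"]}
                for t, v in summ["traits"].items()
            ]
        )
        write_tsv(norm, out / "trait_normality.tsv")

    # --- GRM
    grm = vanraden_grm(
        g.dosages, freqs=g.allele_freqs(), ids=list(g.individual_ids),
        snp_ids=list(g.snp_info["id"]),
    )
    grm.to_tsv(out / "grm.tsv")

    # --- LD decay per chromosome
    ld_rows = []
    for chrom in dict.fromkeys(g.snp_info["chromosome"].astype(str)):
        try:
            pairs, _ = pairwise_r2(g, chrom, max_distance_bp=cfg.ld_max_distance_bp)
            fit = fit_hill_weir(pairs, n=g.n_individuals)
            ld_rows.append(
                {
                    "chromosome": chrom,
                    "n_pairs": fit.n_pairs,
                    "rho_hat": fit.rho_hat,
                    "half_decay_bp": fit.half_decay_bp,
                    "rss": fit.rss,
                }
            )
        except ValueError as exc:
            logger.warning("LD fit skipped for chromosome %s: %s", chrom, exc)
    ld_df = pd.DataFrame(ld_rows)
    write_tsv(ld_df, out / "ld_decay.tsv")

    # --- scan per trait
    scan_frames, region_frames, gene_frames = [], [], []
    genes = read_gff3(cfg.annotation) if cfg.annotation else None
    all_results = {}
    for trait in cfg.traits:
        scan = RegionalHeritabilityScan(
            g, records, trait, environment=cfg.environment, config=cfg.scan
        )
        res = scan.fit()
        all_results[trait] = res
        tab = res.to_frame()
        tab.insert(0, "trait_name", trait)
        scan_frames.append(tab)
        for reg in res.qtl_regions():
            region_frames.append(
                {
                    "trait": trait,
                    "chromosome": reg.chromosome,
                    "region": f"{reg.start}-{reg.end}",
                    "n_snps": reg.n_snps,
                    "peak_neglog10p": reg.peak_neglog10p,
                    "peak_h2_region": reg.peak_h2_region,
                }
            )
            if genes is not None:
                hits = genes_in_region(genes, reg)
                for _, row in hits.iterrows():
                    gene_frames.append(
                        {
                            "trait": trait,
                            "region": f"{reg.chromosome}:{reg.start}-{reg.end}",
                            "gene_id": row["gene_id"],
                            "start": row["start"],
                            "end": row["end"],
                            "description": row["description"],
                        }
                    )
    write_tsv(
        pd.concat(scan_frames, ignore_index=True) if scan_frames else pd.DataFrame(),
        out / "scan_results.tsv",
    )
    write_tsv(pd.DataFrame(region_frames), out / "qtl_regions.tsv")
    if genes is not None:
        write_tsv(pd.DataFrame(gene_frames), out / "candidate_genes.tsv")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    return {
        "genotypes": g,
        "qc_report": qc_report,
        "adjusted_means": means_df,
        "adjust_fits": adj_fits,
        "grm": grm,
        "ld": ld_df,
        "scans": all_results,
        "regions": pd.DataFrame(region_frames),
        "genes": pd.DataFrame(gene_frames) if genes is not None else None,
    }
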
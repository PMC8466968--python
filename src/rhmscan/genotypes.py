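"""Genotype container, readers and quality control.

Dosages are counts of the alternate allele in {0, 1, 2} with NaN for missing.
QC follows the usual family-panel recipe: drop individuals with too much
missing data, then drop SNPs by minor-allele frequency and missingness
(MAF strictly > ``maf_min`` computed on non-missing calls; missing fraction
strictly < ``snp_missing_max``; individual missing fraction strictly
> ``ind_missing_max`` removes), then mean-impute the residual holes before
relationship matrices are built.  Genotyped plants can be aggregated to
family-level rows (mean dosage) for family-phenotype models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "QCConfig",
    "QCReport",
    "read_genotypes",
    "filter_individuals",
    "filter_snps",
    "impute_missing",
    "aggregate_to_families",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP coordinates.

    ``snp_info`` is a DataFrame with columns ``id``, ``chromosome``,
    ``position`` (bp, as given by the source file), one row per SNP, in the
    same column order as ``dosages``.
    """

    individual_ids: list[str]
    family_ids: list[str]
    dosages: np.ndarray  # float, NaN = missing
    snp_info: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.family_ids) != n:
            raise ValueError("id lists do not match dosage rows")
        if len(self.snp_info) != m:
            raise ValueError("snp_info does not match dosage columns")
        if self.snp_info["id"].duplicated().any():
            dups = self.snp_info["id"][self.snp_info["id"].duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dups[:5]}")
        if (self.snp_info["position"] < 0).any():
            raise ValueError("negative SNP positions")
        vals = self.dosages[~np.isnan(self.dosages)]
        # family-mean aggregation can produce fractional dosages, so the
        # invariant is the [0, 2] range rather than exact {0, 1, 2}
        if vals.size and ((vals < 0) | (vals > 2)).any():
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.snp_info.sort_values(
            ["chromosome", "position"], kind="mergesort"
        ).index.to_numpy()
        return replace(
            self,
            dosages=self.dosages[:, order],
            snp_info=self.snp_info.iloc[order].reset_index(drop=True),
        )

    def allele_freqs(self) -> np.ndarray:
        """Observed alternate-allele frequencies from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def per_chromosome_counts(self) -> pd.Series:
        return self.snp_info.groupby("chromosome", sort=True).size()


@dataclass
class QCConfig:
    ind_missing_max: float = 0.10
    snp_missing_max: float = 0.05
    maf_min: float = 0.05

    def __post_init__(self):
        for name in ("ind_missing_max", "snp_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_individuals_before: int
    n_individuals_after: int
    n_snps_before: int
    n_snps_after: int
    n_removed_maf: int
    n_removed_missing: int
    per_chromosome: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individuals_before", self.n_individuals_before),
            ("individuals_after", self.n_individuals_after),
            ("snps_before", self.n_snps_before),
            ("snps_after", self.n_snps_after),
            ("snps_removed_maf", self.n_removed_maf),
            ("snps_removed_missing", self.n_removed_missing),
        ]
        rows += [(f"snps_chr_{c}", n) for c, n in self.per_chromosome.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# readers

def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.array(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if n_multi:
        logger.info("dropped %d multi-allelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    snp_info = pd.DataFrame({"id": ids, "chromosome": chroms, "position": poss})
    return GenotypeMatrix(
        individual_ids=samples,
        family_ids=list(samples),
        dosages=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        snp_info=snp_info,
    )


def _read_csv(path) -> GenotypeMatrix:
    """Genotype CSV dialect: header ``id,family,<snp ids...>``, then two
    comment rows ``#chrom`` and ``#pos`` carrying coordinates, then one row
    per individual/family with dosages (empty or NA = missing)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        chrom_row = fh.readline().rstrip("\n").split(",")
        pos_row = fh.readline().rstrip("\n").split(",")
        if header[:2] != ["id", "family"] or chrom_row[0] != "#chrom" or pos_row[0] != "#pos":
            raise ValueError(f"{path}: not a genotype CSV (bad header rows)")
        snp_ids = header[2:]
        chroms = chrom_row[2:]
        poss = [int(p) for p in pos_row[2:]]
        body = pd.read_csv(fh, header=None, names=header, na_values=["NA", ""])
    snp_info = pd.DataFrame({"id": snp_ids, "chromosome": chroms, "position": poss})
    return GenotypeMatrix(
        individual_ids=body["id"].astype(str).tolist(),
        family_ids=body["family"].astype(str).tolist(),
        dosages=body[snp_ids].to_numpy(dtype=float),
        snp_info=snp_info,
    )


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from VCF or the package's genotype CSV dialect.

    SNPs are returned sorted by (chromosome, position).  ``format`` is
    inferred from the file suffix when omitted.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "csv"
    if format == "vcf":
        g = _read_vcf(path)
    elif format == "csv":
        g = _read_csv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return g.sorted_by_position()


# ---------------------------------------------------------------------------
# QC operations

def filter_individuals(g: GenotypeMatrix, cfg: QCConfig) -> GenotypeMatrix:
    """Remove individuals whose missing fraction exceeds ``ind_missing_max``
    (strict >); order preserved."""
    miss = np.isnan(g.dosages).mean(axis=1)
    keep = miss <= cfg.ind_missing_max
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    n_rm = int((~keep).sum())
    if n_rm:
        logger.info("removed %d individuals with missingness > %g", n_rm, cfg.ind_missing_max)
    return replace(
        g,
        individual_ids=[i for i, k in zip(g.individual_ids, keep) if k],
        family_ids=[f for f, k in zip(g.family_ids, keep) if k],
        dosages=g.dosages[keep],
    )


def filter_snps(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Keep SNPs with MAF > ``maf_min`` (on non-missing calls) and missing
    fraction < ``snp_missing_max``; returns the filtered matrix and a report
    with per-chromosome counts."""
    miss = np.isnan(g.dosages).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g.dosages, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf > cfg.maf_min
    keep_miss = miss < cfg.snp_missing_max
    keep = keep_maf & keep_miss
    if not keep.any():
        raise ValueError("no SNPs survive the MAF/missingness filters")
    out = replace(
        g,
        dosages=g.dosages[:, keep],
        snp_info=g.snp_info[keep].reset_index(drop=True),
    )
    report = QCReport(
        n_individuals_before=g.n_individuals,
        n_individuals_after=g.n_individuals,
        n_snps_before=g.n_snps,
        n_snps_after=out.n_snps,
        n_removed_maf=int((~keep_maf).sum()),
        n_removed_missing=int((~keep_miss).sum()),
        per_chromosome={str(c): int(n) for c, n in out.per_chromosome_counts().items()},
    )
    return out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its SNP's mean non-missing dosage."""
    D = g.dosages.copy()
    all_missing = np.isnan(D).all(axis=0)
    if all_missing.any():
        bad = g.snp_info["id"][all_missing].tolist()
        raise ValueError(f"SNPs with all calls missing: {bad[:5]}")
    col_mean = np.nanmean(D, axis=0)
    holes = np.isnan(D)
    D[holes] = np.broadcast_to(col_mean, D.shape)[holes]
    return replace(g, dosages=D)


def aggregate_to_families(g: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse genotyped plants to one row per family (mean dosage, ignoring
    missing calls); family order follows first appearance."""
    fams = list(dict.fromkeys(g.family_ids))
    fam_arr = np.asarray(g.family_ids)
    rows = []
    for fam in fams:
        block = g.dosages[fam_arr == fam]
        if block.shape[0] == 0:
            raise ValueError(f"family {fam!r} has no individuals")
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(block, axis=0))
    return replace(
        g,
        individual_ids=fams,
        family_ids=fams,
        dosages=np.vstack(rows),
    )
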
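"""Genotype reading, QC filters, imputation and family aggregation."""

import numpy as np
import pandas as pd
import pytest

from rhmscan import (
    GenotypeMatrix,
    QCConfig,
    aggregate_to_families,
    filter_individuals,
    filter_snps,
    impute_missing,
    read_genotypes,
)
from rhmscan.io import write_genotype_csv, write_vcf


def _gm(dosages, positions=None, chrom="1", families=None):
    D = np.asarray(dosages, dtype=float)
    n, m = D.shape
    positions = positions or list(range(100, 100 + 100 * m, 100))
    ids = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(
        individual_ids=ids,
        family_ids=families or ids,
        dosages=D,
        snp_info=pd.DataFrame(
            {"id": [f"s{j}" for j in range(m)], "chromosome": chrom, "position": positions}
        ),
    )


# --- readers --------------------------------------------------------------


def test_vcf_dosages_are_alt_allele_counts(tmp_path):
    g = _gm([[0, 1], [1, 2], [2, np.nan]])
    path = tmp_path / "x.vcf"
    write_vcf(g, path)
    g2 = read_genotypes(path, format="vcf")
    np.testing.assert_array_equal(np.nan_to_num(g2.dosages, nan=-1),
                                  np.nan_to_num(g.dosages, nan=-1))
    assert g2.individual_ids == g.individual_ids


def test_vcf_multiallelic_records_dropped(tmp_path):
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb",
    ]
    for k in range(5):
        alt = "C,G" if k == 2 else "C"  # one tri-allelic record
        lines.append(f"1\t{100 + k}\tv{k}\tA\t{alt}\t.\t.\t.\tGT\t0/0\t0/1")
    path = tmp_path / "m.vcf"
    path.write_text("\n".join(lines) + "\n")
    g = read_genotypes(path)
    assert g.n_snps == 4
    assert "v2" not in set(g.snp_info["id"])


def test_csv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    D = rng.integers(0, 3, size=(5, 8)).astype(float)
    D[1, 3] = np.nan
    g = _gm(D)
    path = tmp_path / "g.csv"
    write_genotype_csv(g, path)
    g2 = read_genotypes(path, format="csv")
    np.testing.assert_array_equal(np.nan_to_num(g2.dosages, nan=-9),
                                  np.nan_to_num(g.dosages, nan=-9))
    assert list(g2.snp_info["position"]) == list(g.snp_info["position"])
    assert g2.family_ids == g.family_ids


def test_duplicate_snp_id_rejected():
    with pytest.raises(ValueError, match="duplicate SNP ids"):
        GenotypeMatrix(
            individual_ids=["a"],
            family_ids=["a"],
            dosages=np.zeros((1, 2)),
            snp_info=pd.DataFrame(
                {"id": ["s1", "s1"], "chromosome": "1", "position": [1, 2]}
            ),
        )


# --- individual filter ----------------------------------------------------


def test_individual_missingness_boundary_rules():
    """15% missing removed at a 10% threshold; exactly 10% retained
    (strict >); fully observed retained."""
    n_snps = 20
    D = np.zeros((3, n_snps))
    D[0, :1] = 1  # 0% missing
    D[1, :3] = np.nan  # 15%
    D[2, :2] = np.nan  # exactly 10%
    g = _gm(D)
    out = filter_individuals(g, QCConfig(ind_missing_max=0.10))
    assert out.individual_ids == ["i0", "i2"]


def test_all_individuals_removed_raises():
    D = np.full((2, 4), np.nan)
    with pytest.raises(ValueError, match="all individuals"):
        filter_individuals(_gm(D), QCConfig())


# --- SNP filter -----------------------------------------------------------


def test_snp_filter_maf_and_missing_rules():
    # col0: dosages (0,0,0,1) -> MAF 1/8 = 0.125 > 0.05 -> kept
    # col1: monomorphic -> removed
    # col2: 1 of 4 missing (25% >= 5%) -> removed despite fine MAF
    D = np.array(
        [
            [0, 0, 1],
            [0, 0, 1],
            [0, 0, np.nan],
            [1, 0, 2],
        ],
        dtype=float,
    )
    g = _gm(D)
    out, report = filter_snps(g, QCConfig())
    assert list(out.snp_info["id"]) == ["s0"]
    assert report.n_snps_before == 3 and report.n_snps_after == 1


def test_snp_filter_idempotent_and_report_conserved():
    rng = np.random.default_rng(2)
    D = rng.integers(0, 3, size=(30, 50)).astype(float)
    D[rng.random(D.shape) < 0.03] = np.nan
    g = _gm(D)
    once, rep = filter_snps(g, QCConfig())
    twice, rep2 = filter_snps(once, QCConfig())
    np.testing.assert_array_equal(
        np.nan_to_num(once.dosages, nan=-9), np.nan_to_num(twice.dosages, nan=-9)
    )
    assert rep.n_snps_after == rep2.n_snps_after == rep2.n_snps_before
    assert sum(rep.per_chromosome.values()) == rep.n_snps_after


def test_snp_filter_matches_bruteforce_enumeration():
    rng = np.random.default_rng(3)
    D = rng.integers(0, 3, size=(25, 40)).astype(float)
    D[rng.random(D.shape) < 0.08] = np.nan
    g = _gm(D)
    cfg = QCConfig()
    out, _ = filter_snps(g, cfg)
    survivors = []
    for j in range(40):
        col = D[:, j]
        obs = col[~np.isnan(col)]
        miss_frac = np.isnan(col).mean()
        p = obs.mean() / 2 if len(obs) else 0.0
        if min(p, 1 - p) > cfg.maf_min and miss_frac < cfg.snp_missing_max:
            survivors.append(f"s{j}")
    assert list(out.snp_info["id"]) == survivors


# --- imputation and aggregation -------------------------------------------


def test_impute_mean_and_identity():
    D = np.array([[0, 1], [2, 1], [np.nan, 1]], dtype=float)
    out = impute_missing(_gm(D))
    assert out.dosages[2, 0] == pytest.approx(1.0)
    fully = _gm(np.array([[0.0, 2.0], [2.0, 0.0]]))
    np.testing.assert_array_equal(impute_missing(fully).dosages, fully.dosages)


def test_impute_all_missing_column_raises():
    D = np.array([[np.nan], [np.nan]])
    with pytest.raises(ValueError, match="all calls missing"):
        impute_missing(_gm(D))


def test_aggregate_family_means():
    D = np.array([[0, 2], [2, 2], [1, 0]], dtype=float)
    g = _gm(D, families=["A", "A", "B"])
    out = aggregate_to_families(g)
    assert out.individual_ids == ["A", "B"]
    np.testing.assert_allclose(out.dosages, [[1, 2], [1, 0]])


def test_aggregate_identity_when_one_individual_per_family():
    rng = np.random.default_rng(4)
    g = _gm(rng.integers(0, 3, size=(4, 6)).astype(float))
    out = aggregate_to_families(g)
    np.testing.assert_array_equal(out.dosages, g.dosages)
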
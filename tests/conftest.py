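import numpy as np
import pandas as pd
import pytest

from rhmscan import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def planted_sim():
    """Small synthetic panel with one planted regional QTL (h2_r = 0.3) at
    1:49.95-50.05 Mb, used by the scan tests."""
    cfg = SimConfig(
        n_chromosomes=2,
        n_clusters_per_chrom=10,
        qtl_windows=[("1", 49_950_000, 50_050_000)],
        regional_h2=[0.3],
        polygenic_h2=0.2,
        seed=11,
    )
    g, _ = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(g, cfg)
    return cfg, g, records, truth


@pytest.fixture(scope="session")
def null_sim():
    """Synthetic panel with no regional QTL (polygenic + design only)."""
    cfg = SimConfig(
        n_chromosomes=2,
        n_clusters_per_chrom=8,
        polygenic_h2=0.3,
        seed=7,
    )
    g, _ = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(g, cfg)
    return cfg, g, records, truth


@pytest.fixture()
def toy_gff3(tmp_path):
    """Three-gene toy annotation on chromosome 8 around the 171.7 Mb QTL
    region plus one gene on chromosome 2."""
    text = "\n".join(
        [
            "##gff-version 3",
            "8\ttest\tgene\t171750000\t171760000\t.\t+\t.\tID=GRMZM2G133175;description=CYSTM stress tolerance",
            "8\ttest\tgene\t171500000\t171600000\t.\t+\t.\tID=GRMZM2G000001;description=left of region",
            "8\ttest\tgene\t171820000\t171900000\t.\t-\t.\tID=GRMZM2G000002;description=straddles region end",
            "2\ttest\tgene\t13400000\t13410000\t.\t+\t.\tID=GRMZM2G051958;description=PEPCK",
            "",
        ]
    )
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


@pytest.fixture()
def balanced_records():
    """Balanced complete two-rep design, 6 families, one block per rep."""
    rng = np.random.default_rng(5)
    rows = []
    fam_effect = dict(zip("ABCDEF", rng.normal(0, 1, 6)))
    for rep in (1, 2):
        for fam, eff in fam_effect.items():
            rows.append(
                {
                    "family": fam,
                    "rep": rep,
                    "block": 1,
                    "PH": 100 + eff + rng.normal(0, 0.5),
                }
            )
    return pd.DataFrame(rows)
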
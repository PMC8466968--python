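"""Writers for the package's plain-text interchange formats.

Genotype CSV dialect (round-trips through
:func:`rhmscan.genotypes.read_genotypes`):

    id,family,S1_100,S1_200,...
    #chrom,,1,1,...
    #pos,,100,200,...
    F001,F001,0,1,...

Missing dosages are written as ``NA``.  A minimal VCF writer is provided for
interoperability (integer dosages only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["write_genotype_csv", "write_vcf", "write_phenotype_csv", "write_tsv"]


def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    snp_ids = g.snp_info["id"].tolist()
    with open(path, "w") as fh:
        fh.write("id,family," + ",".join(snp_ids) + "\n")
        fh.write("#chrom,," + ",".join(g.snp_info["chromosome"].astype(str)) + "\n")
        fh.write("#pos,," + ",".join(g.snp_info["position"].astype(str)) + "\n")
        for ind, fam, row in zip(g.individual_ids, g.family_ids, g.dosages):
            vals = ["NA" if np.isnan(v) else f"{v:g}" for v in row]
            fh.write(f"{ind},{fam}," + ",".join(vals) + "\n")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write integer dosages as unphased GT calls in a minimal VCFv4.2 file."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.snp_info["chromosome"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, row in g.snp_info.iterrows():
            calls = []
            for v in g.dosages[:, j]:
                if np.isnan(v):
                    calls.append("./.")
                elif float(v) in gt_map:
                    calls.append(gt_map[float(v)])
                else:
                    raise ValueError("VCF writer requires integer dosages in {0,1,2}")
            fh.write(
                f"{row['chromosome']}\t{int(row['position'])}\t{row['id']}\tA\tC\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_phenotype_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
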
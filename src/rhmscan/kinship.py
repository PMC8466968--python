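"""Genomic relationship matrices (VanRaden method).

Given a dosage matrix ``M`` (entities x SNPs, values in [0, 2]) and allele
frequencies ``p``, the centred matrix is ``W = M - 2p`` (column-wise) and the
relationship matrix is

    G = W W' / (2 * sum_j p_j (1 - p_j)).

Regional matrices use the SNP columns falling inside one genomic window, with
allele frequencies taken from the full panel so that regional and
whole-genome matrices share a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GRM", "vanraden_grm", "regional_grm"]


@dataclass
class GRM:
    """A VanRaden genomic relationship matrix with its scaling constant."""

    ids: list[str]
    values: np.ndarray
    denom: float
    snp_subset: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        with open(path, "w") as fh:
            fh.write(f"#denom\t{self.denom:.12g}\n")
            fh.write(f"#snps\t{','.join(self.snp_subset)}\n")
            df.to_csv(fh, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        with open(path) as fh:
            denom = float(fh.readline().split("\t")[1])
            snps_field = fh.readline().rstrip("\n").split("\t")
            snps = snps_field[1].split(",") if len(snps_field) > 1 and snps_field[1] else []
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(ids=list(df.index.astype(str)), values=df.values, denom=denom,
                   snp_subset=snps)


def vanraden_grm(
    dosages: np.ndarray,
    freqs: np.ndarray | None = None,
    ids: list[str] | None = None,
    snp_ids: list[str] | None = None,
) -> GRM:
    """Compute the VanRaden genomic relationship matrix.

    Parameters
    ----------
    dosages : entities x SNPs matrix with no missing values.
    freqs : per-SNP alternate-allele frequency; defaults to observed column
        means / 2.  Monomorphic columns (p = 0 or 1) are dropped with a
        warning.
    """
    M = np.asarray(dosages, dtype=float)
    if M.ndim != 2:
        raise ValueError("dosages must be 2-D (entities x SNPs)")
    if np.isnan(M).any():
        raise ValueError("dosages contain missing values; impute first")
    n, m = M.shape
    p = np.asarray(freqs, dtype=float) if freqs is not None else M.mean(axis=0) / 2.0
    if p.shape != (m,):
        raise ValueError("freqs length does not match SNP count")
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNPs from GRM")
    if not poly.any():
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    M = M[:, poly]
    p = p[poly]
    kept = [s for s, keep in zip(snp_ids, poly) if keep]
    W = M - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return GRM(
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        values=G,
        denom=denom,
        snp_subset=kept,
    )


def regional_grm(genotypes, window, freqs: np.ndarray | None = None) -> GRM:
    """VanRaden matrix restricted to the SNPs of one genomic window.

    ``genotypes`` is a :class:`~rhmscan.genotypes.GenotypeMatrix`; ``window``
    any object with ``chromosome``, ``start`` and ``end`` attributes
    (positions in ``[start, end)`` are included).  ``freqs`` are per-SNP
    frequencies for the FULL panel (defaults to observed); the subset of
    frequencies for the window's SNPs is used, keeping regional matrices on
    the whole-genome scale.
    """
    info = genotypes.snp_info
    mask = (
        (info["chromosome"].astype(str) == str(window.chromosome))
        & (info["position"] >= window.start)
        & (info["position"] < window.end)
    ).to_numpy()
    if not mask.any():
        raise ValueError(
            f"window {window.chromosome}:{window.start}-{window.end} contains no SNPs"
        )
    p_full = (
        np.asarray(freqs, dtype=float)
        if freqs is not None
        else np.nanmean(genotypes.dosages, axis=0) / 2.0
    )
    return vanraden_grm(
        genotypes.dosages[:, mask],
        freqs=p_full[mask],
        ids=list(genotypes.individual_ids),
        snp_ids=list(info["id"][mask]),
    )
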
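"""Candidate-gene lookup: genes overlapping significant QTL regions.

Gene features are read from a local GFF3 annotation (e.g. the maize B73
AGPv3 gene build) and intersected with QTL-region intervals.  "Candidate
gene" follows the any-overlap convention: a gene counts if any part of its
annotated span intersects the region (full containment available by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneRecord", "read_gff3", "genes_in_region"]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, GFF3 convention (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    description: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if not self.chromosome:
            raise ValueError(f"gene {self.gene_id}: missing chromosome")


def read_gff3(path) -> pd.DataFrame:
    """Extract ``gene`` features from a GFF3 file.

    Returns a DataFrame with columns ``gene_id, chromosome, start, end,
    description``.  Duplicate gene ids raise; a file without gene features
    returns an empty table with a warning.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc

    rows = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        desc = ""
        for key in ("description", "Note", "product"):
            if key in feat.attributes:
                desc = feat.attributes[key][0]
                break
        rows.append(
            {
                "gene_id": gid,
                "chromosome": str(feat.seqid),
                "start": int(feat.start),
                "end": int(feat.end),
                "description": desc,
            }
        )
    if not rows:
        warnings.warn(f"no gene features found in {path}")
        return pd.DataFrame(
            columns=["gene_id", "chromosome", "start", "end", "description"]
        )
    return pd.DataFrame(rows)


def genes_in_region(
    genes: pd.DataFrame,
    region,
    chrom_map: dict[str, str] | None = None,
    containment: bool = False,
) -> pd.DataFrame:
    """Genes intersecting one QTL region, sorted by start.

    ``region`` needs ``chromosome``, ``start``, ``end`` attributes with the
    region half-open [start, end).  ``chrom_map`` normalises annotation
    chromosome labels (e.g. {"chr8": "8"}) before matching.  With
    ``containment=True`` a gene must lie entirely inside the region.
    """
    if genes.empty:
        return genes
    labels = genes["chromosome"].astype(str)
    if chrom_map:
        labels = labels.map(lambda c: chrom_map.get(c, c))
    on_chrom = genes[labels == str(region.chromosome)]
    if containment:
        hit = (on_chrom["start"] >= region.start) & (on_chrom["end"] < region.end)
    else:
        hit = (on_chrom["start"] < region.end) & (on_chrom["end"] >= region.start)
    return on_chrom[hit].sort_values("start", kind="mergesort").reset_index(drop=True)
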
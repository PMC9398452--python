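"""TE-gene association: nearest genes, genic H3K9me2, expression ranks.

Each TE is linked to its single closest gene and classified as sitting 5'
or 3' of it (strand-aware: upstream of the transcription start site means
5').  Gene-body H3K9me2 is the mean of non-missing 25-bp HMD bins over the
gene span, with genes that contain a TE excluded (a TE inside the body
would confound the estimate).  Expression is summarized as RPKM averaged
over two replicates and converted to a descending rank (rank 1 = highest
expressed); genes with zero RPKM in both replicates are dropped.

For species with data from two strains, per-gene allele z-scores compare
the homologous alleles with and without an adjacent TE:

    z_hmd  = (mean HMD with TE - mean HMD without) / SD(pooled per-bin values)
    z_rank = (mean rank with TE - mean rank without) / SD(four per-replicate ranks)

Positive z means the TE-carrying allele is more heterochromatic (z_hmd) or
lower expressed (z_rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TeRecord
from .hmd import HmdTrack


@dataclass
class GeneRecord:
    """Gene interval with expression and gene-body chromatin summaries."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    genic_hmd: float | None = None
    rpkm_rep1: float | None = None
    rpkm_rep2: float | None = None
    rpkm_mean: float | None = None
    expression_rank: float | None = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TeGeneLink:
    te_id: str
    gene_id: str
    distance: int
    orientation: str  # "5'" or "3'" relative to the gene


def nearest_gene(te: TeRecord, genes: Sequence[GeneRecord]) -> TeGeneLink | None:
    """Closest gene on the TE's chromosome; distance 0 for genic TEs.

    Orientation is relative to the gene: a TE upstream of the TSS is 5',
    downstream of the transcription end is 3'.  Genic TEs take the side of
    the nearer gene end.  Equidistant genes tie-break toward the smaller
    gene id.
    """
    candidates = [g for g in genes if g.chrom == te.chrom]
    if not candidates:
        return None

    def dist(g: GeneRecord) -> int:
        if te.end <= g.start:
            return g.start - te.end
        if g.end <= te.start:
            return te.start - g.end
        return 0

    best = min(candidates, key=lambda g: (dist(g), g.gene_id))
    d = dist(best)
    te_mid = (te.start + te.end) / 2
    gene_mid = (best.start + best.end) / 2
    before_gene = te_mid < gene_mid
    if best.strand == "+":
        orientation = "5'" if before_gene else "3'"
    else:
        orientation = "3'" if before_gene else "5'"
    return TeGeneLink(te.te_id, best.gene_id, d, orientation)


def genic_hmd(
    track: HmdTrack, gene: GeneRecord, tes: Sequence[TeRecord] = ()
) -> float | None:
    """Mean non-missing gene-body HMD; None if excluded or all-missing.

    Genes overlapped by any TE are excluded (returns None), as are genes
    with no non-missing bin.
    """
    for te in tes:
        if te.chrom == gene.chrom and te.start < gene.end and gene.start < te.end:
            return None
    bs = track.bin_size
    vals = track.valid_values(gene.start // bs, -(-gene.end // bs))
    if len(vals) == 0:
        return None
    return float(vals.mean())


def expression_rank(
    rpkm_rep1: Mapping[str, float] | pd.Series,
    rpkm_rep2: Mapping[str, float] | pd.Series,
    ortholog_filter: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean RPKM and descending expression ranks over retained genes.

    Replicate tables must share gene ids.  Genes with 0 RPKM in both
    replicates are excluded; ties receive average ranks; rank 1 is the
    highest expressed gene.  Optionally restricted to a shared-ortholog
    gene list before ranking.
    """
    r1 = pd.Series(rpkm_rep1, dtype=float)
    r2 = pd.Series(rpkm_rep2, dtype=float)
    shared = r1.index.intersection(r2.index)
    if len(shared) == 0:
        raise ValueError("replicate RPKM tables share no gene ids")
    df = pd.DataFrame({"rpkm_rep1": r1[shared], "rpkm_rep2": r2[shared]})
    if ortholog_filter is not None:
        df = df.loc[df.index.intersection(pd.Index(ortholog_filter))]
    df = df[(df["rpkm_rep1"] > 0) | (df["rpkm_rep2"] > 0)]
    df["rpkm_mean"] = df[["rpkm_rep1", "rpkm_rep2"]].mean(axis=1)
    df["expression_rank"] = df["rpkm_mean"].rank(ascending=False, method="average")
    df.index.name = "gene_id"
    return df


def allele_z(hmd_with: np.ndarray, hmd_without: np.ndarray) -> float:
    """Gene-body HMD z-score between TE-carrying and TE-free alleles.

    Denominator is the SD of the pooled per-bin values of both alleles.
    """
    a = np.asarray(hmd_with, dtype=float)
    b = np.asarray(hmd_without, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each allele needs at least two non-missing bins")
    pooled_sd = np.concatenate([a, b]).std(ddof=1)
    if pooled_sd == 0:
        raise ZeroDivisionError("pooled SD is zero; z undefined")
    return float((a.mean() - b.mean()) / pooled_sd)


def expression_allele_z(
    rank_with: Sequence[float], rank_without: Sequence[float]
) -> float:
    """Expression-rank z-score between alleles from per-replicate ranks.

    Denominator is the sample SD of the four per-replicate rank values.
    Positive z: the TE-carrying allele has a larger rank, i.e. lower
    expression.
    """
    a = np.asarray(rank_with, dtype=float)
    b = np.asarray(rank_without, dtype=float)
    if len(a) != 2 or len(b) != 2 or np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("two per-replicate rank estimates required per allele")
    sd = np.concatenate([a, b]).std(ddof=1)
    if sd == 0:
        if a.mean() == b.mean():  # identical ranks: no shift, z is 0
            return 0.0
        raise ZeroDivisionError("rank SD is zero; z undefined")
    return float((a.mean() - b.mean()) / sd)
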
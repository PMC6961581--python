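"""Gene expression: exon assignment, RPKM, template-count matrices, PCA.

Bulk reads count toward a transcript only when every aligned base lies
within that transcript's exons; single-cell reads qualify when at least
half the read length falls within the exons of some transcript of a gene.
Single-cell counts are unique templates per (gene, cell), collapsed by
varietal tag.  Bulk abundance is RPKM with multi-transcript genes reduced
to their highest-RPKM transcript.

The PCA follows a fixed normalization: per-cell mean normalization, then
log(x + 1), then per-gene centering, then principal components with
per-feature centering and unit scaling.  Marker genes are the 20 most
positively and 20 most negatively PC1-correlated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ExonModel",
    "assign_read_to_gene",
    "count_expression",
    "rpkm",
    "pca_and_markers",
    "PcaResult",
]


@dataclass
class ExonModel:
    """Exon structure per transcript, grouped by gene.

    ``transcripts`` columns: gene, transcript, chrom, strand, exons (list of
    0-based half-open (start, end) tuples, non-overlapping and sorted).
    """

    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        for exons in self.transcripts["exons"]:
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError("overlapping exons within a transcript")

    @classmethod
    def from_bed12(cls, path: str) -> "ExonModel":
        """Read a BED12 exon model; the name field is ``gene|transcript``
        (or just the gene, reused as transcript id)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                gene, _, transcript = name.partition("|")
                rows.append(
                    {
                        "gene": gene,
                        "transcript": transcript or gene,
                        "chrom": chrom,
                        "strand": strand,
                        "exons": exons,
                    }
                )
        return cls(pd.DataFrame(rows))

    @property
    def genes(self) -> list[str]:
        return sorted(self.transcripts["gene"].unique())

    def transcript_lengths(self) -> pd.Series:
        return self.transcripts.set_index("transcript")["exons"].map(
            lambda ex: sum(e - s for s, e in ex)
        )


def _overlap_with_exons(blocks: Sequence[tuple[int, int]], exons: Sequence[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for es, ee in exons:
            total += max(0, min(be, ee) - max(bs, es))
    return total


def assign_read_to_gene(
    chrom: str,
    blocks: Sequence[tuple[int, int]],
    model: ExonModel,
    mode: str = "singlecell",
    read_length: Optional[int] = None,
) -> Optional[str]:
    """Assign an aligned read to a gene, or None.

    ``blocks`` are the aligned segments (0-based half-open).  Bulk mode
    demands all aligned bases within one transcript's exons; single-cell
    mode demands >= 50% of the read length within some transcript's exons
    (boundary inclusive).  A read qualifying for two different genes is
    ambiguous and dropped (returns None).
    """
    aligned = sum(e - s for s, e in blocks)
    read_length = read_length or aligned
    hits = set()
    for t in model.transcripts.itertuples(index=False):
        if t.chrom != chrom:
            continue
        ov = _overlap_with_exons(blocks, t.exons)
        if mode == "bulk":
            if ov == aligned:
                hits.add(t.gene)
        elif mode == "singlecell":
            if ov * 2 >= read_length:
                hits.add(t.gene)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if len(hits) == 1:
        return hits.pop()
    return None


def count_expression(
    reads: pd.DataFrame,
    model: ExonModel,
    mode: str = "singlecell",
    read_length: int = 76,
) -> pd.DataFrame:
    """Genes x cells matrix of unique-template counts.

    ``reads`` columns: bag, tag, chrom, pos, strand (pos the 0-based
    leftmost aligned base; reads are treated as single ``read_length``
    blocks).  A varietal tag seen on two genes within a BAG counts for the
    gene with more supporting reads; ties are ambiguous and dropped.
    """
    # assignment depends only on (chrom, pos) for fixed read length: memoize
    unique = reads[["chrom", "pos"]].drop_duplicates()
    unique["gene"] = [
        assign_read_to_gene(c, [(p, p + read_length)], model, mode, read_length)
        for c, p in zip(unique["chrom"], unique["pos"])
    ]
    assigned = reads.merge(unique, on=["chrom", "pos"], how="left").dropna(subset=["gene"])
    # resolve (bag, tag) -> gene by read support; ties dropped
    support = (
        assigned.groupby(["bag", "tag", "gene"], observed=True).size().rename("n").reset_index()
    )
    support = support.sort_values(["bag", "tag", "n"], ascending=[True, True, False])
    top = support.drop_duplicates(["bag", "tag"], keep="first")
    # a tie exists when the two best genes have equal support
    tied = {
        (b, t)
        for (b, t), grp in support.groupby(["bag", "tag"], observed=True)
        if len(grp) > 1 and grp["n"].iloc[0] == grp["n"].iloc[1]
    }
    keep = top[~top.set_index(["bag", "tag"]).index.isin(tied)]
    counts = keep.groupby(["gene", "bag"], observed=True).size().unstack(fill_value=0)
    return counts.reindex(
        index=model.genes, columns=sorted(reads["bag"].unique()), fill_value=0
    )


def rpkm(
    transcript_counts: pd.Series,
    transcript_lengths: pd.Series,
    total_mapped: int,
    model: Optional[ExonModel] = None,
) -> pd.Series:
    """Reads per kilobase per million mapped reads, per gene.

    RPKM_t = reads_t * 1e9 / (length_t * total); for genes with several
    transcripts the highest-RPKM transcript represents the gene.  Without a
    model the per-transcript values are returned.
    """
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    lengths = transcript_lengths.reindex(transcript_counts.index)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    values = transcript_counts * 1e9 / (lengths * total_mapped)
    if model is None:
        return values
    gene_of = model.transcripts.set_index("transcript")["gene"]
    return values.groupby(values.index.map(gene_of)).max()


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # cells x components
    explained_variance_ratio: np.ndarray
    markers: pd.DataFrame  # gene, correlation, sign
    bulk_coordinates: Optional[pd.DataFrame] = None
    dropped_genes: list = field(default_factory=list)


def pca_and_markers(
    matrix: pd.DataFrame,
    bulk: Optional[pd.DataFrame] = None,
    n_components: int = 2,
    n_markers: int = 20,
) -> PcaResult:
    """PCA of a genes x cells expression matrix with PC1 marker genes.

    Normalization: divide each cell by its mean, log(x + 1), center each
    gene, then PCA on cells x genes with per-feature centering and unit
    scaling.  Constant genes are dropped (recorded in the result).  Bulk
    profiles (genes x samples) are pushed through the same transform and
    projected into the cell PC space.  Markers are the ``n_markers`` most
    positively and most negatively PC1-correlated genes.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 cells")

    def normalize(m: pd.DataFrame) -> pd.DataFrame:
        cell_mean = m.mean(axis=0)
        if (cell_mean == 0).any():
            raise ValueError("cell with all-zero counts")
        logd = np.log1p(m / cell_mean)
        return logd.sub(logd.mean(axis=1), axis=0)

    norm = normalize(matrix)
    variances = norm.var(axis=1)
    dropped = list(variances.index[variances == 0])
    norm = norm.loc[variances > 0]
    if norm.shape[0] < 2:
        raise ValueError("need at least 2 genes with nonzero variance")

    X = norm.T.to_numpy()  # cells x genes
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    pca = PCA(n_components=min(n_components, min(Xs.shape) - 1), svd_solver="full")
    coords = pca.fit_transform(Xs)
    coordinates = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )

    pc1 = coords[:, 0]
    corr = norm.apply(lambda g: np.corrcoef(g.to_numpy(), pc1)[0, 1], axis=1)
    corr = corr.dropna().sort_values()
    neg = corr.head(n_markers)
    pos = corr.tail(n_markers)
    markers = pd.DataFrame(
        {
            "gene": list(pos.index[::-1]) + list(neg.index),
            "correlation": list(pos.to_numpy()[::-1]) + list(neg.to_numpy()),
            "sign": ["+"] * len(pos) + ["-"] * len(neg),
        }
    )

    bulk_coords = None
    if bulk is not None:
        bn = normalize(bulk.reindex(matrix.index).fillna(0.0))
        bn = bn.loc[norm.index]
        Xb = scaler.transform(bn.T.to_numpy())
        bulk_coords = pd.DataFrame(
            pca.transform(Xb), index=bulk.columns, columns=coordinates.columns
        )

    return PcaResult(coordinates, pca.explained_variance_ratio_, markers, bulk_coords, dropped)


def marker_heatmap_order(matrix: pd.DataFrame, markers: pd.DataFrame) -> list:
    """Cell ordering for the marker-gene heatmap.

    Cells are clustered on the normalized marker-gene submatrix with
    Euclidean distance and complete linkage; returns the leaf order.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    sub = np.log1p(matrix.loc[markers["gene"]] / matrix.mean(axis=0))
    Z = linkage(sub.T.to_numpy(), method="complete", metric="euclidean")
    return [matrix.columns[i] for i in leaves_list(Z)]
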
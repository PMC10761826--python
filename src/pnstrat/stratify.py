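"""Ward clustering of samples and genes, subtype labelling, and PCA overlay.

Samples are clustered on purity-adjusted residuals of the proteostasis-
network genes; genes are co-clustered (z-scored per gene) so that the
"cluster 1" gene block can anchor the A/B labelling convention: sample
clusters with lower mean expression of cluster-1 genes are labelled A,
the rest B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .datamodel import DataError, ExpressionMatrix, logger


@dataclass
class SampleGrouping:
    """Cluster labels for samples (or genes when ``axis='genes'``)."""

    labels: pd.Series            # item id -> label
    k: int
    axis: str = "samples"
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)
    label_convention: str = "raw"

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise DataError("duplicate item identifiers in grouping")
        if self.linkage_matrix is not None:
            heights = self.linkage_matrix[:, 2]
            if np.any(np.diff(heights) < -1e-9):
                raise DataError("Ward merge heights must be non-decreasing")

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def zscore_genes(data: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples; constant genes map to 0."""
    values = data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=data.index, columns=data.columns)


def ward_cluster(
    matrix: ExpressionMatrix | pd.DataFrame, axis: str, k: int
) -> SampleGrouping:
    """Agglomerative Ward (Ward.D2 on Euclidean distances) cut into k groups.

    ``axis='samples'`` clusters columns, ``axis='genes'`` clusters rows.
    The agglomeration is deterministic given the input order (ties are
    resolved by the nearest-neighbour-chain ordering of the linkage
    routine).
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if axis not in ("samples", "genes"):
        raise DataError(f"axis must be 'samples' or 'genes', got {axis!r}")
    obs = data.T if axis == "samples" else data
    items = obs.index
    X = obs.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("non-finite entries in clustering input")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise DataError(f"k={k} outside [1, {n}]")
    if k == 1 or n == 1:
        labels = pd.Series(["1"] * n, index=items)
        return SampleGrouping(labels=labels, k=1, axis=axis)
    Z = linkage(X, method="ward")
    assign = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(assign.astype(str), index=items)
    return SampleGrouping(labels=labels, k=int(labels.nunique()), axis=axis,
                          linkage_matrix=Z)


def designate_cluster1(gene_grouping: SampleGrouping) -> str:
    """The anchor gene cluster: largest membership, ties to the cluster
    containing the lexicographically smallest gene id."""
    sizes = gene_grouping.labels.value_counts()
    top = sizes[sizes == sizes.max()].index
    if len(top) == 1:
        return top[0]
    firsts = {lab: min(gene_grouping.members(lab)) for lab in top}
    return min(firsts, key=firsts.get)


def label_groups(
    sample_grouping: SampleGrouping,
    gene_grouping: SampleGrouping,
    residual_matrix: ExpressionMatrix | pd.DataFrame,
    cluster1: str | None = None,
) -> SampleGrouping:
    """Rank sample clusters by mean residual expression of cluster-1 genes.

    The lower-mean clusters are labelled A (A1, A2, ... in ascending
    mean), the higher-mean clusters B.  With two clusters the labels are
    plain "A" and "B".  Exact ties (within 1e-12) are broken by the
    smallest member sample id and logged.
    """
    data = (residual_matrix.data if isinstance(residual_matrix, ExpressionMatrix)
            else residual_matrix)
    if cluster1 is None:
        cluster1 = designate_cluster1(gene_grouping)
    genes = [g for g in gene_grouping.members(cluster1) if g in data.index]
    if not genes:
        raise DataError(f"gene cluster {cluster1!r} has no genes in the matrix")

    clusters = sorted(sample_grouping.labels.unique())
    stats = []
    for lab in clusters:
        members = sample_grouping.members(lab)
        mean = float(data.loc[genes, members].to_numpy().mean())
        stats.append((lab, mean, min(members)))
    means = [m for _, m, _ in stats]
    if len(set(np.round(means, 12))) < len(means):
        logger.warning("tie in cluster-1 means; breaking by smallest sample id")
    order = sorted(stats, key=lambda t: (t[1], t[2]))

    k = len(order)
    n_a = 1 if k <= 2 else k // 2
    new_names: dict[str, str] = {}
    if k == 2:
        new_names[order[0][0]] = "A"
        new_names[order[1][0]] = "B"
    else:
        for i, (lab, _, _) in enumerate(order):
            if i < n_a:
                new_names[lab] = f"A{i + 1}"
            else:
                new_names[lab] = f"B{i - n_a + 1}"
    labels = sample_grouping.labels.map(new_names)
    return SampleGrouping(
        labels=labels,
        k=k,
        axis=sample_grouping.axis,
        linkage_matrix=sample_grouping.linkage_matrix,
        label_convention="lower-cluster1-mean=A",
    )


def merge_subgroups(grouping: SampleGrouping, merge_map: Mapping[str, str]) -> SampleGrouping:
    """Merge subtype labels (e.g. {A1: A, A2: A, B1: B, B2: B}); counts add."""
    present = set(grouping.labels.unique())
    missing = present - set(merge_map)
    if missing:
        raise DataError(f"merge_map does not cover labels: {sorted(missing)}")
    labels = grouping.labels.map(dict(merge_map))
    return SampleGrouping(
        labels=labels,
        k=int(labels.nunique()),
        axis=grouping.axis,
        linkage_matrix=grouping.linkage_matrix,
        label_convention=grouping.label_convention + "+merged",
    )


def pca_overlay(matrices: Mapping[str, ExpressionMatrix], n_components: int = 2) -> pd.DataFrame:
    """Gene-centred PCA of samples pooled across cohorts.

    ``matrices`` maps a cohort tag to an expression matrix on a common
    normalised scale; samples are projected jointly on the shared gene
    universe and returned as a frame of PC coordinates with a ``cohort``
    column.  Sample ids are prefixed by their cohort tag to stay unique.
    """
    if not matrices:
        raise DataError("no matrices supplied")
    universes = [set(m.gene_ids) for m in matrices.values()]
    shared = sorted(set.intersection(*universes))
    if not shared:
        raise DataError("cohorts have disjoint gene universes")
    blocks = []
    tags = []
    for tag, mat in matrices.items():
        block = mat.data.loc[shared]
        block.columns = [f"{tag}:{s}" for s in block.columns]
        blocks.append(block)
        tags.extend([tag] * block.shape[1])
    pooled = pd.concat(blocks, axis=1)
    X = pooled.T.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)  # centre each gene
    n_components = min(n_components, *X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords,
        index=pooled.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out["cohort"] = tags
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    out.attrs["components"] = pca.components_
    return out
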
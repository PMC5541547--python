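"""Export the Z-linked log2 expression profile for heatmap rendering.

Unlike the ratio statistics, the profile keeps *every* Z-linked gene,
including those with zero FPKM, so the heatmap shows silent loci; zeros are
replaced by ``log2(floor)`` with a small display floor that never feeds
back into the statistics.  A deterministic hierarchical clustering
(correlation distance, average linkage) is offered for row grouping.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expr_io import ExpressionMatrix
from .linkage import assign_linkage

__all__ = ["DEFAULT_FLOOR", "z_profile_matrix", "cluster_genes"]

#: Display floor for zero FPKM: log2(2**-10) = -10 on the heatmap scale.
DEFAULT_FLOOR = 2.0**-10


def z_profile_matrix(
    fpkm: ExpressionMatrix,
    gene_chromosome: Mapping[str, int | str],
    z_chromosome: int = 1,
    floor: float = DEFAULT_FLOOR,
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene × sample log2-FPKM matrix restricted to Z-linked genes.

    All Z-linked genes are included even when unexpressed; zero FPKM maps to
    ``log2(floor)``.  ``sample_order`` reorders columns (default: matrix
    order).
    """
    if fpkm.unit != "fpkm":
        raise ValueError(f"z_profile_matrix expects fpkm, got {fpkm.unit!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    _, z_sub, _ = assign_linkage(fpkm, gene_chromosome, z_chromosome)
    if not z_sub.gene_ids:
        raise ValueError("no Z-linked genes in the matrix")
    vals = z_sub.values.clip(lower=floor)
    out = np.log2(vals)
    if sample_order is not None:
        out = out[list(sample_order)]
    return out


def cluster_genes(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Deterministic hierarchical clustering of profile rows into k clusters.

    Average-linkage agglomeration on correlation distance, seedless.  Rows
    with zero variance (flat profiles) have undefined correlation; their
    pairwise distance is treated as 0 to other flat rows and 1 otherwise.
    Cluster labels are canonicalised by the lexicographically smallest gene
    id they contain, so permuting the row order permutes labels identically.
    Distance ties are resolved by scipy's deterministic merge order over the
    given condensed distances.
    """
    n = matrix.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if k == n:
        return pd.Series(
            np.argsort(np.argsort(matrix.index)) + 1, index=matrix.index, name="cluster"
        )
    x = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(x, metric="correlation")
    if np.isnan(d).any():
        flat = x.std(axis=1) == 0
        iu = np.triu_indices(n, k=1)
        both_flat = flat[iu[0]] & flat[iu[1]]
        d = np.where(np.isnan(d), np.where(both_flat, 0.0, 1.0), d)
        # flat rows with identical values are genuinely distance-0; differing
        # constant rows are still flat profiles and grouped together
    d = np.clip(d, 0.0, None)
    link = hierarchy.linkage(d, method="average")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # canonical labels: clusters numbered 1..k by their smallest member gene id
    genes = list(matrix.index)
    members: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        members.setdefault(int(c), []).append(g)
    order = sorted(members, key=lambda c: min(members[c]))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[int(c)] for c in raw], index=matrix.index, name="cluster")
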
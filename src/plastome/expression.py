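"""Per-gene expression normalization and profile clustering.

Raw per-gene read counts are normalized with the relative log expression
(RLE, median-of-ratios) method: each gene's reference is its geometric mean
across samples (over genes with all-positive counts), each sample's size
factor is the median of its count/reference ratios, and normalized counts
are raw counts divided by the size factor.  Downstream display uses
log2(normalized + 1).  Sample profiles are clustered hierarchically with
average linkage on a 1 - Pearson correlation distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome import PlastomeError


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Genes with a zero count in any sample are excluded from the reference
    set; an error is raised when no gene is positive in all samples.
    """
    if counts.shape[1] < 2:
        raise PlastomeError("need at least 2 samples")
    if (counts.values < 0).any():
        raise PlastomeError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise PlastomeError("cannot compute size factors: no gene positive in all samples")
    ref = counts.loc[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo_mean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Normalized counts (raw / size factor) and the size factors."""
    sf = rle_size_factors(counts)
    return counts.div(sf, axis=1), sf


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); refuses negative input."""
    if (normalized.values < 0).any():
        raise PlastomeError("log transform requires non-negative values")
    return np.log2(normalized + 1)


def cluster_profiles(
    matrix: pd.DataFrame, linkage_method: str = "average"
) -> tuple[np.ndarray, list[str], str]:
    """Hierarchical clustering of sample columns on 1 - Pearson correlation.

    Returns the scipy linkage matrix, the deterministic leaf order (ties
    broken by input column order), and a Newick string of the dendrogram.
    """
    if matrix.shape[1] < 2:
        raise PlastomeError("need at least 2 samples to cluster")
    values = matrix.values.astype(float)
    sd = values.std(axis=0)
    flat = [matrix.columns[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise PlastomeError(
            f"zero-variance sample(s) {flat}: correlation distance undefined"
        )
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(Z)
    leaf_names = [str(matrix.columns[i]) for i in order]
    newick = _to_newick(hierarchy.to_tree(Z), [str(c) for c in matrix.columns])
    return Z, leaf_names, newick


def _to_newick(node, names: list[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return names[n.id]
        left, right = rec(n.get_left()), rec(n.get_right())
        return f"({left}:{n.dist / 2:.6g},{right}:{n.dist / 2:.6g})"

    return rec(node) + ";"


def expression_table(
    counts: pd.DataFrame, groups: dict[str, str] | None = None
) -> dict:
    """Full expression stage: RLE normalization, log2(norm+1), clustering.

    Returns a dict with ``size_factors``, ``normalized``, ``log2`` and the
    clustering results (``linkage``, ``leaf_order``, ``newick``); the log2
    matrix reordered by leaf order is provided as ``heatmap`` for display.
    """
    normalized, sf = rle_normalize(counts)
    logm = log_transform(normalized)
    Z, leaves, newick = cluster_profiles(logm)
    return {
        "size_factors": sf,
        "normalized": normalized,
        "log2": logm,
        "linkage": Z,
        "leaf_order": leaves,
        "newick": newick,
        "heatmap": logm[leaves],
        "groups": groups or {},
    }
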
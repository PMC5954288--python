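"""miRNA abundance normalisation and cross-library summaries.

Abundances are expressed as RPTM (reads per ten million sequencing
tags), the per-library count scaled by 1e7 over the library total.
Rows for hierarchical clustering must reach 5 RPTM in at least two
libraries with a standard deviation of at least 1; libraries are then
compared by Pearson correlation of ln(RPTM + 1) and clustered on
distance 1 - CC with complete linkage.  PCA uses rows averaging >= 5
RPTM, ln(x + 1)-transformed and column-centred, via SVD.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def rptm(counts: pd.DataFrame, library_totals: Optional[Dict[str, int]] = None) -> pd.DataFrame:
    """Reads-per-ten-million normalisation of a tag x library count table.

    ``library_totals`` defaults to the column sums (all sequencing tags
    of the library); a mapped-only denominator can be passed instead.
    """
    totals = pd.Series(library_totals) if library_totals else counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for {bad}")
    return counts.div(totals, axis=1) * 1e7


def select_for_clustering(
    matrix: pd.DataFrame,
    min_rptm: float = 5.0,
    min_libraries: int = 2,
    min_sd: float = 1.0,
) -> pd.DataFrame:
    """Rows with >= 5 RPTM in >= 2 libraries and sample SD >= 1."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    expressed = (matrix >= min_rptm).sum(axis=1) >= min_libraries
    sd = matrix.std(axis=1, ddof=1) >= min_sd
    return matrix.loc[expressed & sd]


def correlate_and_cluster(
    matrix: pd.DataFrame,
) -> Tuple[pd.DataFrame, "hierarchy.ClusterNode", str]:
    """Library-level correlation and hierarchical clustering.

    Returns (CC matrix, root ClusterNode, Newick string).  Values are
    ln(x + 1)-transformed; libraries are compared by Pearson CC and
    clustered on 1 - CC with complete linkage.  Zero-variance columns
    are excluded with a warning (their correlations are undefined).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 selected rows")
    logm = np.log1p(matrix)
    sd = logm.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding zero-variance libraries: {list(sd.index[~sd])}")
    logm = logm.loc[:, keep]
    cc = logm.corr(method="pearson")
    dist = 1.0 - cc.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    root = hierarchy.to_tree(Z)
    newick = _to_newick(root, list(cc.columns))
    return cc, root, newick


def _to_newick(node, labels: List[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{n.dist:.6g}"
        return f"({rec(n.left)},{rec(n.right)}):{n.dist:.6g}"

    return f"({rec(node.left)},{rec(node.right)});" if not node.is_leaf() else f"({labels[node.id]});"


def pca(
    matrix: pd.DataFrame, min_mean_rptm: float = 5.0
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of libraries from rows with mean RPTM >= 5.

    ln(x + 1) transform, column (gene) centring across libraries, then
    SVD.  Returns (library coordinates on the components,
    explained-variance fractions summing to 1).  Component signs are
    arbitrary.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 libraries")
    sel = matrix.loc[matrix.mean(axis=1) >= min_mean_rptm]
    if sel.shape[0] < 2:
        raise ValueError("fewer than 2 rows pass the mean-RPTM filter")
    X = np.log1p(sel.to_numpy()).T        # libraries x miRNAs
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), frac
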
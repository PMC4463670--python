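"""Stem-loop RT-qPCR relative expression (2^-ddCt) and tissue clustering.

Ct values are averaged over replicates, normalised to the 5S rRNA reference
gene (dCt = Ct_miRNA - Ct_5S), then referenced to a baseline tissue
(ddCt = dCt_tissue - dCt_reference); relative expression is 2^-ddCt, so the
reference tissue column is identically 1.  The miRNA x tissue matrix is
clustered agglomeratively on log2 values (Euclidean distance, average
linkage by default) for both rows and columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

REFERENCE_GENE = "5S"


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct TSV (tissue, target, ct[, replicate])."""
    df = pd.read_csv(path, sep="\t")
    required = {"tissue", "target", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean Ct over replicates -> target x tissue matrix."""
    if (ct_table["ct"] <= 0).any() or not np.isfinite(ct_table["ct"]).all():
        raise ValueError("Ct values must be positive and finite")
    return ct_table.pivot_table(index="target", columns="tissue", values="ct", aggfunc="mean")


def delta_ct(ct_mirna: float, ct_5s: float) -> float:
    """dCt = Ct_miRNA - Ct_5S."""
    return ct_mirna - ct_5s


def relative_expression(
    ct_table: pd.DataFrame,
    reference_tissue: str = "muscle",
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """miRNA x tissue matrix of 2^-ddCt, referenced to one tissue.

    Missing Ct values propagate as NaN and are excluded from clustering
    distances downstream.
    """
    ct = ct_table if ct_table.index.name == "target" else mean_ct(ct_table)
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    if reference_tissue not in ct.columns:
        raise ValueError(f"reference tissue {reference_tissue!r} missing from Ct table")
    dct = ct.drop(index=reference_gene).sub(ct.loc[reference_gene], axis=1)
    ddct = dct.sub(dct[reference_tissue], axis=0)
    rel = 2.0 ** (-ddct)
    rel.attrs["reference_tissue"] = reference_tissue
    return rel


def _nan_euclidean(mat: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances, ignoring coordinates missing in either
    row (rescaled to the full dimension, sklearn-style)."""
    n, d = mat.shape
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if not mask.any():
                raise ValueError("rows share no observed values")
            diff = mat[i, mask] - mat[j, mask]
            out[k] = np.sqrt((diff @ diff) * d / mask.sum())
            k += 1
    return out


def cluster_heatmap(
    matrix: pd.DataFrame, method: str = "average"
) -> dict[str, object]:
    """Hierarchical clustering of rows (miRNAs) and columns (tissues).

    Returns linkages, deterministic leaf orders and Newick dendrograms.
    Values are log2-transformed first; the distance is Euclidean with
    missing values excluded pairwise.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    logm = np.log2(matrix.to_numpy(dtype=float))
    out: dict[str, object] = {}
    for axis, labels, key in (
        (0, list(matrix.index), "row"),
        (1, list(matrix.columns), "col"),
    ):
        data = logm if axis == 0 else logm.T
        link = hierarchy.linkage(_nan_euclidean(data), method=method)
        order = hierarchy.leaves_list(link)
        out[f"{key}_linkage"] = link
        out[f"{key}_order"] = [labels[i] for i in order]
        out[f"{key}_newick"] = linkage_to_newick(link, labels)
    return out


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def _walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"


def synthetic_ct_table(
    fold_matrix: pd.DataFrame,
    reference_tissue: str,
    ct_5s: float = 18.0,
    base_dct: float = 6.0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Construct a long-format Ct table realising known fold changes.

    Inverse of :func:`relative_expression`: Ct = Ct_5S + base_dct -
    log2(fold).  Used to verify that designed fold changes are recovered.
    """
    rows = []
    for tissue in fold_matrix.columns:
        for rep in range(1, replicates + 1):
            rows.append({"tissue": tissue, "target": REFERENCE_GENE, "ct": ct_5s, "replicate": rep})
        for target in fold_matrix.index:
            ct = ct_5s + base_dct - np.log2(fold_matrix.loc[target, tissue])
            for rep in range(1, replicates + 1):
                rows.append({"tissue": tissue, "target": target, "ct": ct, "replicate": rep})
    df = pd.DataFrame(rows)
    df.attrs["reference_tissue"] = reference_tissue
    return df
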
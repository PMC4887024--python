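"""Row-standardized two-way hierarchical clustering of top-PIF proteins.

Clusters both proteins (rows) and samples (columns) of the log2
abundance matrix restricted to the top-k PIF proteins, and checks
whether the two-cluster cut of the sample dendrogram separates the high
and low groups (cluster purity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


def row_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, (sample) sd 1.

    Rows with zero spread carry no clustering information and are
    dropped with a warning; an all-constant matrix is an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to standardize rows")
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all rows are constant")
    if constant.any():
        logger.warning("dropped %d constant row(s)", int(constant.sum()))
        matrix = matrix.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    """Two-way dendrograms, leaf orders, and the 2-cluster sample cut."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    col_partition: pd.Series  # sample -> {1, 2}

    def purity(self, groups: pd.Series) -> float:
        """Fraction of samples on the majority group of their cluster,
        under the best of the two cluster-to-group mappings."""
        g = groups.reindex(self.col_partition.index)
        labels = sorted(g.unique())
        if len(labels) != 2:
            raise ValueError("purity needs exactly two groups")
        match_a = ((self.col_partition == 1) == (g == labels[0])).mean()
        return float(max(match_a, 1.0 - match_a))


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows and columns.

    Euclidean distance with average linkage by default (the linkage and
    metric used for the published dendrogram are not pinned down, so
    both are configurable).  The two-cluster sample partition comes
    from cutting the column tree at its final merge.
    """
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite entries")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_link = hierarchy.linkage(vals, method=method, metric=metric)
    col_link = hierarchy.linkage(vals.T, method=method, metric=metric)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    partition = pd.Series(
        hierarchy.fcluster(col_link, 2, criterion="maxclust"),
        index=matrix.columns,
        name="cluster",
    )
    return ClusterResult(row_link, col_link, row_order, col_order, partition)


def export_heatmap(
    result: ClusterResult,
    matrix: pd.DataFrame,
    tsv_path: str | Path,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the leaf-ordered matrix as TSV (and optionally an image).

    The TSV row/column order matches the dendrogram leaf orders exactly;
    the image uses a red/green diverging palette.
    """
    ordered = matrix.loc[result.row_order, result.col_order]
    ordered.rename_axis("protein").to_csv(tsv_path, sep="\t")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * ordered.shape[1]), max(4, 0.12 * ordered.shape[0]))
        )
        vmax = np.abs(ordered.to_numpy()).max()
        im = ax.imshow(ordered, cmap="RdYlGn_r", aspect="auto",
                       vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(ordered.shape[0]))
        ax.set_yticklabels(ordered.index, fontsize=5)
        fig.colorbar(im, ax=ax, shrink=0.5)
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return ordered
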
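"""Graph summaries of thresholded connectivity networks.

Per-ROI weighted degree (sum of Fisher-z weights over significant incident
edges), binary degree, Watts-Strogatz local clustering on the binarized
graph, whole-network density, tertile density classification of a cohort,
and the two-group degree comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .atlas import AtlasTable
from .synthetic import DensityClass
from .transform import SubjectNetwork

__all__ = [
    "DensityProfile",
    "weighted_degree",
    "binary_degree",
    "clustering_coefficient",
    "network_density",
    "node_metrics",
    "classify_density",
    "degree_table",
    "group_matching_ttest",
]


@dataclass(frozen=True)
class DensityProfile:
    """Edge density of one subject's network, with its cohort tertile."""

    subject_id: str
    density: float
    density_class: DensityClass | None = None


def _check_square(a: np.ndarray, b: np.ndarray | None = None) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if b is not None and b.shape != a.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def weighted_degree(z_matrix: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """degree_i = sum_j adjacency[i, j] * z[i, j] (significant edges only)."""
    z = np.asarray(z_matrix, dtype=float)
    adj = np.asarray(adjacency)
    _check_square(z, adj)
    return (adj * z).sum(axis=1)


def binary_degree(adjacency: np.ndarray) -> np.ndarray:
    """Number of significant edges incident to each node."""
    adj = np.asarray(adjacency)
    _check_square(adj)
    return adj.sum(axis=1).astype(int)


def clustering_coefficient(adjacency: np.ndarray) -> np.ndarray:
    """Binary local clustering C_i = 2 * triangles_i / (k_i * (k_i - 1)).

    Nodes with fewer than two neighbours get C_i = 0.
    """
    adj = np.asarray(adjacency)
    _check_square(adj)
    vals = np.unique(adj)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("clustering requires a binary adjacency matrix")
    a = adj.astype(float)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def network_density(adjacency: np.ndarray) -> float:
    """Fraction of the K(K-1)/2 possible edges that are significant."""
    adj = np.asarray(adjacency)
    _check_square(adj)
    k = adj.shape[0]
    if k < 2:
        return 0.0
    edges = int(np.triu(adj, 1).sum())
    return edges / (k * (k - 1) / 2)


def node_metrics(net: SubjectNetwork, atlas: AtlasTable) -> pd.DataFrame:
    """Per-ROI table of weighted degree, binary degree and clustering."""
    if net.n_rois != atlas.n_rois:
        raise ValueError("network size does not match atlas")
    return pd.DataFrame(
        {
            "roi_id": atlas.roi_ids,
            "name": atlas.column_order,
            "subnetwork": [r.subnetwork.value for r in atlas],
            "weighted_degree": weighted_degree(net.z_matrix, net.adjacency),
            "binary_degree": binary_degree(net.adjacency),
            "clustering": clustering_coefficient(net.adjacency),
        }
    )


def classify_density(profiles: list[DensityProfile]) -> list[DensityProfile]:
    """Split a cohort into high/medium/low density tertiles.

    Subjects are ranked by descending density (ties broken by input order,
    which makes the split deterministic); the thirds are near-equal, with
    any remainder going to the denser classes first.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("density classification needs at least 3 subjects")
    order = sorted(range(n), key=lambda i: (-profiles[i].density, i))
    chunks = np.array_split(np.arange(n), 3)
    classes = [DensityClass.HIGH, DensityClass.MEDIUM, DensityClass.LOW]
    assigned: dict[int, DensityClass] = {}
    pos = 0
    for chunk, cls_ in zip(chunks, classes):
        for _ in chunk:
            assigned[order[pos]] = cls_
            pos += 1
    return [
        DensityProfile(p.subject_id, p.density, assigned[i])
        for i, p in enumerate(profiles)
    ]


def degree_table(
    group1_degrees: np.ndarray | pd.Series,
    group2_degrees: np.ndarray | pd.Series,
    atlas: AtlasTable,
    group1_label: str = "group1",
    group2_label: str = "group2",
) -> pd.DataFrame:
    """Two-group weighted-degree comparison, one row per ROI.

    Rows are sorted by descending group-1 degree; ties keep atlas
    (ascending AAL index) order.  Degree vectors must be in atlas order.
    """
    d1 = np.asarray(group1_degrees, dtype=float)
    d2 = np.asarray(group2_degrees, dtype=float)
    if d1.shape != (atlas.n_rois,) or d2.shape != (atlas.n_rois,):
        raise ValueError(
            f"degree vectors must cover all {atlas.n_rois} atlas ROIs"
        )
    df = pd.DataFrame(
        {
            "subnetwork": [r.subnetwork.value for r in atlas],
            "roi_id": atlas.roi_ids,
            "name": atlas.column_order,
            f"degree_{group1_label}": d1,
            f"degree_{group2_label}": d2,
        }
    )
    df = df.sort_values(
        f"degree_{group1_label}", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return df


def group_matching_ttest(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test used to check group matching.

    Returns (t, df, two-sided p) with df = n_a + n_b - 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return float(res.statistic), df, float(res.pvalue)
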
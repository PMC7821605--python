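"""Fisher z transformation, edge significance, and group stacking.

Selected correlations are positivized (absolute value), mapped through the
variance-stabilizing Fisher transform z = 0.5 * ln((1+r)/(1-r)), and tested
edge-wise with the classical normal approximation: under the null the
statistic z * sqrt(n-3) is standard normal.  Edges with two-sided p below
the threshold (0.001 by default) form the binary adjacency matrix; the z
values serve as edge weights.

Group-level networks come from "stacked" data: each subject's series is
standardized column-wise and concatenated along time, and the same
jackknife -> select -> positivize -> Fisher -> binarize chain runs on the
stack with n equal to the total number of stacked volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from . import jackknife
from .synthetic import TimeSeriesMatrix

__all__ = [
    "SubjectNetwork",
    "GroupStack",
    "fisher_z",
    "positivize",
    "edge_significance",
    "binarize",
    "build_network",
    "stack_group",
    "group_network",
]


@dataclass(frozen=True)
class SubjectNetwork:
    """Weighted + binarized connectivity network for one analysis unit.

    ``z_matrix`` holds non-negative Fisher-z weights (zero diagonal),
    ``p_matrix`` two-sided edge p-values (unit diagonal), ``adjacency`` the
    binary graph thresholded at ``alpha``.
    """

    z_matrix: np.ndarray
    p_matrix: np.ndarray
    adjacency: np.ndarray
    n_volumes: int
    alpha: float = 0.001
    subject_id: str | None = None

    @property
    def n_rois(self) -> int:
        return self.z_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class GroupStack:
    """Concatenated per-subject standardized series for one group."""

    data: np.ndarray
    subject_boundaries: tuple[int, ...]
    subject_ids: tuple[str | None, ...]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform z = 0.5 * ln((1+r)/(1-r))."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("Fisher transform requires |r| < 1; clamp upstream")
    out = 0.5 * np.log((1.0 + arr) / (1.0 - arr))
    return float(out) if np.isscalar(r) else out


def positivize(matrix: np.ndarray) -> np.ndarray:
    """Element-wise absolute value (sign of an edge is discarded)."""
    return np.abs(np.asarray(matrix, dtype=float))


def edge_significance(z: np.ndarray | float, n_volumes: int) -> np.ndarray | float:
    """Two-sided p-value of a Fisher-z weight at sample size ``n_volumes``.

    Statistic |z| * sqrt(n-3) referred to the standard normal.  For square
    matrix input the diagonal is set to 1 (self-edges are not tested).
    """
    if n_volumes <= 3:
        raise ValueError("edge significance needs more than 3 volumes")
    arr = np.asarray(z, dtype=float)
    p = 2.0 * scipy.stats.norm.sf(np.abs(arr) * np.sqrt(n_volumes - 3))
    if p.ndim == 2 and p.shape[0] == p.shape[1]:
        np.fill_diagonal(p, 1.0)
    return float(p) if np.isscalar(z) else p


def binarize(
    z_matrix: np.ndarray, n_volumes: int, alpha: float = 0.001
) -> np.ndarray:
    """Binary adjacency: 1 where the edge p-value is below ``alpha``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    p = edge_significance(z_matrix, n_volumes)
    adj = (p < alpha).astype(np.int8)
    adj = adj & adj.T  # exact symmetry even under FP asymmetry upstream
    np.fill_diagonal(adj, 0)
    return adj


def build_network(
    mats: jackknife.SubjectCorrelationMatrices,
    alpha: float = 0.001,
    subject_id: str | None = None,
) -> SubjectNetwork:
    """Positivize -> Fisher -> test -> binarize the selected correlations."""
    r = positivize(mats.r_selected)
    np.fill_diagonal(r, 0.0)  # z diagonal is 0 by convention; avoid the r=1 pole
    z = fisher_z(r)
    p = edge_significance(z, mats.n_volumes)
    adj = binarize(z, mats.n_volumes, alpha)
    return SubjectNetwork(
        z_matrix=z,
        p_matrix=p,
        adjacency=adj,
        n_volumes=mats.n_volumes,
        alpha=alpha,
        subject_id=subject_id,
    )


def stack_group(ts_list: Sequence[TimeSeriesMatrix]) -> GroupStack:
    """Standardize each subject column-wise and concatenate along time.

    Standardization removes per-subject offset and scale, which would
    otherwise masquerade as correlation once series from different
    subjects sit in the same columns.
    """
    if len(ts_list) == 0:
        raise ValueError("cannot stack an empty group")
    k = ts_list[0].n_rois
    names = ts_list[0].roi_names
    blocks: list[np.ndarray] = []
    boundaries: list[int] = [0]
    for ts in ts_list:
        if ts.n_rois != k or ts.roi_names != names:
            raise ValueError(
                f"subject {ts.subject_id!r} has mismatched ROI columns"
            )
        x = ts.data
        sd = x.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            roi = names[int(np.flatnonzero(sd <= 0)[0])]
            raise ValueError(
                f"constant series for ROI {roi!r} in subject {ts.subject_id!r}"
            )
        blocks.append((x - x.mean(axis=0)) / sd)
        boundaries.append(boundaries[-1] + ts.n_volumes)
    return GroupStack(
        data=np.vstack(blocks),
        subject_boundaries=tuple(boundaries),
        subject_ids=tuple(ts.subject_id for ts in ts_list),
    )


def group_network(
    stack: GroupStack,
    bias_tol: float = 0.05,
    ci_level: float = 0.95,
    alpha: float = 0.001,
    label: str | None = None,
) -> tuple[jackknife.SubjectCorrelationMatrices, SubjectNetwork]:
    """Run the full estimation chain on a stacked group series."""
    mats = jackknife.correlation_matrices(
        stack.data, bias_tol=bias_tol, ci_level=ci_level
    )
    net = build_network(mats, alpha=alpha, subject_id=label)
    return mats, net
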
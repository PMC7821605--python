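"""Readers and writers for the pipeline's tabular artifacts.

Formats: TSV time series (header row of ROI names, one row per volume);
CSV matrices with ROI-name header row and column ('.' decimal, comma
separator); a long-format TSV edge table; a cohort manifest CSV; and
BrainNet Viewer ``.node``/``.edge`` exchange files.  Every writer's output
is parseable by the matching reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasTable, Subnetwork
from .jackknife import SubjectCorrelationMatrices
from .synthetic import TimeSeriesMatrix
from .transform import SubjectNetwork

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_matrix",
    "read_matrix",
    "write_edge_table",
    "write_manifest",
    "read_manifest",
    "read_coordinates",
    "write_brainnet",
]

# BrainNet node color codes, one per subnetwork (order is the legend order).
SUBNETWORK_COLOR = {
    Subnetwork.DMN_POSTERIOR: 1,
    Subnetwork.DMN_ANTERIOR: 2,
    Subnetwork.DMN_VENTRAL: 3,
    Subnetwork.SENSORIMOTOR: 4,
    Subnetwork.VISUAL: 5,
}


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    """One subject's series as TSV: ROI-name header, one row per volume."""
    df = pd.DataFrame(ts.data, columns=list(ts.roi_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(
    path: str | Path,
    atlas: AtlasTable,
    subject_id: str | None = None,
) -> TimeSeriesMatrix:
    """Read a TSV series and reorder columns to canonical atlas order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse time-series TSV: {exc}") from exc
    expected = set(atlas.column_order)
    got = set(df.columns)
    unknown = sorted(got - expected)
    if unknown:
        raise ValueError(f"{path}: unknown ROI column(s): {', '.join(unknown)}")
    missing = [n for n in atlas.column_order if n not in got]
    if missing:
        raise ValueError(f"{path}: missing ROI column(s): {', '.join(missing)}")
    df = df[list(atlas.column_order)]
    bad = df.columns[df.apply(lambda c: not np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in column(s): {', '.join(bad)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"{path}: missing/non-numeric cell at row {row}, column {col}")
    return TimeSeriesMatrix(
        data=df.to_numpy(dtype=float),
        roi_names=atlas.column_order,
        subject_id=subject_id or path.stem,
    )


def write_matrix(matrix: np.ndarray, atlas: AtlasTable, path: str | Path) -> None:
    """K x K matrix as CSV with ROI names on both axes."""
    names = list(atlas.column_order)
    pd.DataFrame(matrix, index=names, columns=names).to_csv(
        path, float_format="%.12g"
    )


def read_matrix(path: str | Path, atlas: AtlasTable) -> np.ndarray:
    """Read a matrix CSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0)
    names = list(atlas.column_order)
    if list(df.columns) != names or list(df.index) != names:
        try:
            df = df.loc[names, names]
        except KeyError as exc:
            raise ValueError(f"{path}: matrix axes do not match the atlas") from exc
    return df.to_numpy(dtype=float)


def write_edge_table(
    mats: SubjectCorrelationMatrices,
    atlas: AtlasTable,
    path: str | Path,
) -> None:
    """Long-format per-pair estimates (upper triangle) as TSV."""
    names = atlas.column_order
    iu, ju = np.triu_indices(mats.n_rois, k=1)
    df = pd.DataFrame(
        {
            "roi_a": [names[i] for i in iu],
            "roi_b": [names[j] for j in ju],
            "theta": mats.theta[iu, ju],
            "se": mats.se[iu, ju],
            "bias": mats.bias[iu, ju],
            "r_full": mats.r_full[iu, ju],
            "r_selected": mats.r_selected[iu, ju],
            "rule_used": np.where(
                mats.ci_limit_mask[iu, ju], "ci_limit", "jackknife_mean"
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manifest(
    ts_list: list[TimeSeriesMatrix],
    paths: list[str | Path],
    group_label: str,
    seed: int,
    path: str | Path,
) -> None:
    """Cohort manifest CSV: subject_id, group, density_class, file, volumes."""
    rows = []
    for ts, p in zip(ts_list, paths):
        rows.append(
            {
                "subject_id": ts.subject_id,
                "group": group_label,
                "density_class": ts.density_class.value if ts.density_class else "",
                "seed": seed,
                "t_volumes": ts.n_volumes,
                "path": str(p),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s): {sorted(missing)}")
    return df


def read_coordinates(path: str | Path, atlas: AtlasTable) -> np.ndarray:
    """MNI centroid CSV (roi_id, x, y, z) -> (K, 3) array in atlas order."""
    df = pd.read_csv(path)
    needed = {"roi_id", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: coordinates file needs columns {sorted(needed)}")
    df = df.set_index("roi_id")
    missing = [rid for rid in atlas.roi_ids if rid not in df.index]
    if missing:
        raise ValueError(f"{path}: coordinates missing for ROI id(s) {missing}")
    return df.loc[list(atlas.roi_ids), ["x", "y", "z"]].to_numpy(dtype=float)


def write_brainnet(
    net: SubjectNetwork,
    atlas: AtlasTable,
    basename: str | Path,
    coords: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Export ``.node`` and ``.edge`` files for BrainNet Viewer.

    ``.edge``: whitespace-delimited K x K matrix of z-weights on significant
    edges (0 elsewhere).  ``.node``: x y z color size label per region, with
    color coding the subnetwork and size the weighted degree.  With no
    coordinate table, node positions are written as zeros and a warning is
    emitted — the export is then only useful for its weights.
    """
    from .metrics import weighted_degree

    basename = Path(basename)
    k = net.n_rois
    if k != atlas.n_rois:
        raise ValueError("network size does not match atlas")
    if coords is None:
        warnings.warn(
            "no MNI coordinates supplied; writing zero node positions",
            stacklevel=2,
        )
        coords = np.zeros((k, 3))
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (k, 3):
        raise ValueError(f"coordinates must have shape ({k}, 3)")

    edge_path = basename.with_suffix(".edge")
    node_path = basename.with_suffix(".node")
    weights = net.z_matrix * net.adjacency
    np.savetxt(edge_path, weights, fmt="%.6f", delimiter="\t")

    sizes = weighted_degree(net.z_matrix, net.adjacency)
    with open(node_path, "w") as fh:
        for i, rec in enumerate(atlas):
            color = SUBNETWORK_COLOR[rec.subnetwork]
            fh.write(
                f"{coords[i, 0]:.2f}\t{coords[i, 1]:.2f}\t{coords[i, 2]:.2f}\t"
                f"{color}\t{sizes[i]:.4f}\t{rec.name}\n"
            )
    return node_path, edge_path
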
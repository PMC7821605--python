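"""End-to-end pipeline driver.

Orchestrates the full analysis for two groups — per-subject jackknife
correlation matrices, Fisher-z networks, graph metrics, density tertiles,
stacked group networks and the two-group degree table — either from
simulated cohorts or from time-series files listed in manifests.  Every
output of a run is reproducible from its config file and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from . import jackknife, metrics, transform
from .atlas import AtlasTable, load_atlas
from .synthetic import (
    CohortSpec,
    TimeSeriesMatrix,
    simulate_cohort,
    study_covariances,
    truncate_volumes,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one analysis run.

    ``group_manifests`` maps group label -> manifest CSV path; when empty
    the run is in simulate mode and generates ``n_subjects`` subjects per
    group label with the study's default block-covariance structure.
    """

    alpha: float = 0.001
    ci_level: float = 0.95
    bias_tol: float = 0.05
    n_keep_volumes: int = 220
    seed: int = 0
    group_labels: tuple[str, ...] = ("groupA", "groupB")
    n_subjects: int = 22
    simulate_t_volumes: int = 240
    group_manifests: dict[str, str] = field(default_factory=dict)
    coordinates_path: str | None = None
    output_dir: str = "dmnconn_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_keep_volumes <= 4:
            raise ValueError("n_keep_volumes must exceed 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_labels" in raw:
            raw["group_labels"] = tuple(raw["group_labels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["group_labels"] = list(raw["group_labels"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    atlas: AtlasTable
    subjects: dict[str, list[TimeSeriesMatrix]]
    subject_networks: dict[str, list[transform.SubjectNetwork]]
    group_networks: dict[str, transform.SubjectNetwork]
    group_matrices: dict[str, jackknife.SubjectCorrelationMatrices]
    density_profiles: dict[str, list[metrics.DensityProfile]]
    degree_table: pd.DataFrame
    output_dir: Path


def _load_group(
    manifest_path: str, atlas: AtlasTable
) -> list[TimeSeriesMatrix]:
    manifest = io_mod.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append(io_mod.read_timeseries(p, atlas, subject_id=str(row["subject_id"])))
    return out


def _simulate_group(
    label: str, index: int, config: PipelineConfig, atlas: AtlasTable
) -> list[TimeSeriesMatrix]:
    covs = study_covariances(atlas)
    # Disjoint per-group seed blocks so groups never share subject streams.
    cohort = CohortSpec(
        group_label=label,
        n_subjects=config.n_subjects,
        seed=config.seed + 100_000 * (index + 1),
    )
    specs = tuple(
        dataclasses.replace(s, t_volumes=config.simulate_t_volumes)
        for s in cohort.resolved_specs()
    )
    cohort = dataclasses.replace(cohort, subject_specs=specs)
    return simulate_cohort(covs, cohort, roi_names=atlas.column_order)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to disk."""
    atlas = load_atlas()
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log("dmnconn pipeline run")
    for k, v in dataclasses.asdict(config).items():
        log(f"config.{k} = {v!r}")

    atlas.to_csv(out_root / "atlas.csv")
    config.to_yaml(out_root / "config.yaml")

    coords = None
    if config.coordinates_path:
        coords = io_mod.read_coordinates(config.coordinates_path, atlas)

    subjects: dict[str, list[TimeSeriesMatrix]] = {}
    subject_networks: dict[str, list[transform.SubjectNetwork]] = {}
    group_networks: dict[str, transform.SubjectNetwork] = {}
    group_matrices: dict[str, jackknife.SubjectCorrelationMatrices] = {}
    density_profiles: dict[str, list[metrics.DensityProfile]] = {}
    group_degrees: dict[str, np.ndarray] = {}

    for gi, label in enumerate(config.group_labels):
        gdir = out_root / label
        (gdir / "subjects").mkdir(parents=True, exist_ok=True)
        if config.group_manifests:
            try:
                manifest = config.group_manifests[label]
            except KeyError:
                raise ValueError(f"no manifest given for group {label!r}")
            ts_list = _load_group(manifest, atlas)
            log(f"[{label}] loaded {len(ts_list)} subjects from {manifest}")
        else:
            ts_list = _simulate_group(label, gi, config, atlas)
            log(f"[{label}] simulated {len(ts_list)} subjects")

        ts_list = [
            truncate_volumes(ts, config.n_keep_volumes)
            if ts.n_volumes > config.n_keep_volumes
            else ts
            for ts in ts_list
        ]
        subjects[label] = ts_list

        nets: list[transform.SubjectNetwork] = []
        profiles: list[metrics.DensityProfile] = []
        for ts in ts_list:
            try:
                mats = jackknife.correlation_matrices(
                    ts, bias_tol=config.bias_tol, ci_level=config.ci_level
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage=jackknife subject={ts.subject_id!r}: {exc}"
                ) from exc
            net = transform.build_network(
                mats, alpha=config.alpha, subject_id=ts.subject_id
            )
            nets.append(net)
            profiles.append(
                metrics.DensityProfile(
                    subject_id=str(ts.subject_id),
                    density=metrics.network_density(net.adjacency),
                )
            )
            n_ci = int(np.triu(mats.ci_limit_mask, 1).sum())
            log(
                f"[{label}] subject={ts.subject_id} edges={net.n_edges} "
                f"ci_limit_pairs={n_ci}"
            )
            if n_ci:
                iu, ju = np.nonzero(np.triu(mats.ci_limit_mask, 1))
                for i, j in zip(iu, ju):
                    log(
                        f"[{label}] ci_limit subject={ts.subject_id} "
                        f"pair=({atlas.column_order[i]},{atlas.column_order[j]}) "
                        f"bias={mats.bias[i, j]:.4f}"
                    )
            io_mod.write_edge_table(
                mats, atlas, gdir / "subjects" / f"{ts.subject_id}_edges.tsv"
            )
            io_mod.write_matrix(
                net.adjacency, atlas, gdir / "subjects" / f"{ts.subject_id}_adjacency.csv"
            )
        subject_networks[label] = nets
        density_profiles[label] = metrics.classify_density(profiles)
        pd.DataFrame(
            [
                {
                    "subject_id": p.subject_id,
                    "density": p.density,
                    "density_class": p.density_class.value,
                }
                for p in density_profiles[label]
            ]
        ).to_csv(gdir / "density_profiles.csv", index=False)

        stack = transform.stack_group(ts_list)
        gmats, gnet = transform.group_network(
            stack,
            bias_tol=config.bias_tol,
            ci_level=config.ci_level,
            alpha=config.alpha,
            label=label,
        )
        group_matrices[label] = gmats
        group_networks[label] = gnet
        log(
            f"[{label}] group stack rows={stack.n_volumes} "
            f"edges={gnet.n_edges} density={metrics.network_density(gnet.adjacency):.4f}"
        )
        io_mod.write_matrix(gnet.z_matrix, atlas, gdir / "group_z.csv")
        io_mod.write_matrix(gnet.p_matrix, atlas, gdir / "group_p.csv")
        io_mod.write_matrix(gnet.adjacency, atlas, gdir / "group_adjacency.csv")
        io_mod.write_edge_table(gmats, atlas, gdir / "group_edges.tsv")
        metrics.node_metrics(gnet, atlas).to_csv(
            gdir / "node_metrics.tsv", sep="\t", index=False
        )
        io_mod.write_brainnet(gnet, atlas, gdir / "group_network", coords=coords)
        group_degrees[label] = metrics.weighted_degree(gnet.z_matrix, gnet.adjacency)

    labels = list(config.group_labels)
    if len(labels) >= 2:
        table = metrics.degree_table(
            group_degrees[labels[0]],
            group_degrees[labels[1]],
            atlas,
            group1_label=labels[0],
            group2_label=labels[1],
        )
    else:
        table = metrics.degree_table(
            group_degrees[labels[0]],
            group_degrees[labels[0]],
            atlas,
            group1_label=labels[0],
            group2_label=labels[0],
        )
    table.to_csv(out_root / "degree_table.csv", index=False)

    (out_root / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        config=config,
        atlas=atlas,
        subjects=subjects,
        subject_networks=subject_networks,
        group_networks=group_networks,
        group_matrices=group_matrices,
        density_profiles=density_profiles,
        degree_table=table,
        output_dir=out_root,
    )
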
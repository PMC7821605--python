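"""Synthetic ROI time-series cohorts.

No public recording accompanies the connectivity analysis this package
implements, so every downstream stage is exercised on simulated BOLD-like
data with the same structural features: 48 atlas regions partitioned into
five subnetworks, ~220 volumes per subject at TR = 2 s, 22 subjects per
group, a continuum of per-subject connectivity density, AR(1) temporal
autocorrelation, and occasional motion-like global spike artifacts.

Generation contract for one subject: draw T correlated Gaussian innovation
vectors with a block-structured correlation matrix, pass them through an
AR(1) filter x_t = phi * x_{t-1} + eps_t (which preserves the cross-ROI
correlation structure because every region shares the same phi), then shift
all regions of randomly selected volumes by a fixed multiple of their
standard deviation.  Spikes are global and same-signed, so they inflate
plain Pearson correlations — exactly the artifact the leave-one-volume-out
estimator is meant to resist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .atlas import AtlasTable, Subnetwork

__all__ = [
    "DensityClass",
    "BlockCovarianceSpec",
    "SubjectSpec",
    "CohortSpec",
    "TimeSeriesMatrix",
    "make_block_covariance",
    "simulate_subject",
    "simulate_cohort",
    "truncate_volumes",
    "study_covariances",
]


class DensityClass(str, Enum):
    """Connectivity-density stratum of a subject (continuum emulation)."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


# Multiplier applied to within-block correlations per density class.
DENSITY_SCALE: dict[DensityClass, float] = {
    DensityClass.HIGH: 1.0,
    DensityClass.MEDIUM: 0.6,
    DensityClass.LOW: 0.3,
}


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T volumes x K regions of BOLD-like values for one subject."""

    data: np.ndarray
    roi_names: tuple[str, ...]
    subject_id: str | None = None
    density_class: DensityClass | None = None
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("time series must be a 2-D (volumes x ROIs) array")
        if arr.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{arr.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        object.__setattr__(self, "data", arr)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BlockCovarianceSpec:
    """Target block correlation structure across subnetworks.

    ``r_within`` may be a single value or a per-subnetwork mapping
    (label -> correlation); ``r_between`` applies to every cross-block pair.
    """

    block_assignment: tuple[str, ...]
    r_within: float | Mapping[str, float] = 0.3
    r_between: float = 0.1

    @property
    def k_rois(self) -> int:
        return len(self.block_assignment)

    @classmethod
    def from_atlas(
        cls,
        atlas: AtlasTable,
        r_within: float | Mapping[str, float] = 0.3,
        r_between: float = 0.1,
    ) -> "BlockCovarianceSpec":
        labels = tuple(r.subnetwork.value for r in atlas)
        return cls(block_assignment=labels, r_within=r_within, r_between=r_between)

    def within_value(self, label: str) -> float:
        if isinstance(self.r_within, Mapping):
            return float(self.r_within[label])
        return float(self.r_within)


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject simulation parameters."""

    t_volumes: int = 220
    tr_seconds: float = 2.0
    ar1_phi: float = 0.3
    spike_rate: float = 0.02
    spike_amplitude: float = 4.0
    density_class: DensityClass = DensityClass.MEDIUM

    def __post_init__(self) -> None:
        if self.t_volumes <= 4:
            raise ValueError("t_volumes must exceed 4 (Fisher variance needs n > 3)")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """One group of subjects sharing a generation protocol.

    Subject i draws from an independent RNG stream seeded ``seed + i`` so
    appending a subject never perturbs earlier subjects' data.
    """

    group_label: str
    n_subjects: int = 22
    seed: int = 0
    subject_specs: tuple[SubjectSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.subject_specs is not None and len(self.subject_specs) != self.n_subjects:
            raise ValueError("subject_specs length must equal n_subjects")

    def resolved_specs(self) -> tuple[SubjectSpec, ...]:
        """Explicit specs, or a default near-equal high/medium/low split."""
        if self.subject_specs is not None:
            return self.subject_specs
        base = SubjectSpec()
        chunks = np.array_split(np.arange(self.n_subjects), 3)
        classes = [DensityClass.HIGH, DensityClass.MEDIUM, DensityClass.LOW]
        out: list[SubjectSpec] = []
        for chunk, cls_ in zip(chunks, classes):
            out.extend(replace(base, density_class=cls_) for _ in chunk)
        return tuple(out)


def make_block_covariance(spec: BlockCovarianceSpec) -> np.ndarray:
    """Unit-diagonal block correlation matrix, repaired to PSD if needed.

    Within-block off-diagonals take the block's ``r_within``; cross-block
    entries take ``r_between``.  If the naive construction is indefinite the
    spectrum is clipped at zero and the diagonal re-normalized to one.
    """
    labels = np.asarray(spec.block_assignment)
    for label in np.unique(labels):
        v = spec.within_value(str(label))
        if not 0.0 <= v < 1.0:
            raise ValueError(f"r_within for block {label!r} must lie in [0, 1)")
    if not 0.0 <= spec.r_between < 1.0:
        raise ValueError("r_between must lie in [0, 1)")

    k = spec.k_rois
    cov = np.full((k, k), spec.r_between, dtype=float)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        cov[np.ix_(idx, idx)] = spec.within_value(str(label))
    np.fill_diagonal(cov, 1.0)

    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] < -1e-10:
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 1e-10, None)) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
        np.fill_diagonal(cov, 1.0)
    return cov


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L @ L.T = cov; errors on non-PSD."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w[0] < -1e-8:
            raise ValueError("covariance matrix is not positive semidefinite")
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_subject(
    cov: np.ndarray,
    spec: SubjectSpec,
    seed: int | np.random.Generator,
    roi_names: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> TimeSeriesMatrix:
    """Simulate one subject's T x K series under the generation contract."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = _covariance_factor(cov)
    k = factor.shape[0]
    if roi_names is None:
        roi_names = tuple(f"ROI_{i + 1:02d}" for i in range(k))
    innovations = rng.standard_normal((spec.t_volumes, k)) @ factor.T
    if spec.ar1_phi > 0.0:
        data = scipy.signal.lfilter([1.0], [1.0, -spec.ar1_phi], innovations, axis=0)
    else:
        data = innovations
    if spec.spike_rate > 0.0:
        spikes = rng.random(spec.t_volumes) < spec.spike_rate
        if spikes.any():
            sd = data.std(axis=0, ddof=1)
            data = data.copy()
            data[spikes, :] += spec.spike_amplitude * sd
    return TimeSeriesMatrix(
        data=data,
        roi_names=tuple(roi_names),
        subject_id=subject_id,
        density_class=spec.density_class,
        tr_seconds=spec.tr_seconds,
    )


def simulate_cohort(
    cov_by_class: Mapping[DensityClass, np.ndarray] | np.ndarray,
    cohort: CohortSpec,
    roi_names: Sequence[str] | None = None,
) -> list[TimeSeriesMatrix]:
    """Simulate every subject of a cohort.

    ``cov_by_class`` maps each density class to its innovation correlation
    matrix; a single matrix is accepted and used for all classes.
    """
    specs = cohort.resolved_specs()
    out: list[TimeSeriesMatrix] = []
    for i, spec in enumerate(specs):
        if isinstance(cov_by_class, Mapping):
            cov = cov_by_class[spec.density_class]
        else:
            cov = cov_by_class
        out.append(
            simulate_subject(
                cov,
                spec,
                seed=cohort.seed + i,
                roi_names=roi_names,
                subject_id=f"{cohort.group_label}-{i + 1:02d}",
            )
        )
    return out


def truncate_volumes(ts: TimeSeriesMatrix, n_keep: int) -> TimeSeriesMatrix:
    """Keep the first ``n_keep`` volumes (protocol harmonization step)."""
    if n_keep > ts.n_volumes:
        raise ValueError(
            f"cannot keep {n_keep} volumes: series has only {ts.n_volumes}"
        )
    if n_keep <= 4:
        raise ValueError("n_keep must exceed 4 (Fisher variance needs n > 3)")
    return replace(ts, data=ts.data[:n_keep, :])


def study_covariances(
    atlas: AtlasTable,
    r_within: Mapping[str, float] | None = None,
    r_between: float = 0.1,
) -> dict[DensityClass, np.ndarray]:
    """Per-density-class covariances reproducing the study's structure.

    Default within-block correlations are elevated (0.6) in the sensorimotor
    and visual networks and moderate (0.3) in the three DMN subnetworks —
    the qualitative ordering reported for the clinical group — and are
    scaled by 1.0 / 0.6 / 0.3 for the high / medium / low density classes.
    """
    if r_within is None:
        r_within = {
            Subnetwork.DMN_POSTERIOR.value: 0.3,
            Subnetwork.DMN_ANTERIOR.value: 0.3,
            Subnetwork.DMN_VENTRAL.value: 0.3,
            Subnetwork.SENSORIMOTOR.value: 0.6,
            Subnetwork.VISUAL.value: 0.6,
        }
    out: dict[DensityClass, np.ndarray] = {}
    for cls_, scale in DENSITY_SCALE.items():
        scaled = {k: v * scale for k, v in r_within.items()}
        spec = BlockCovarianceSpec.from_atlas(
            atlas, r_within=scaled, r_between=r_between * scale
        )
        out[cls_] = make_block_covariance(spec)
    return out
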
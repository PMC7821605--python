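"""48-ROI default mode network parcellation.

The analysis operates on 48 regions of the AAL90 atlas (45 cortical and
subcortical areas per hemisphere) that together cover the default mode
network and its companion resting-state systems.  The regions are grouped
into five subnetworks: the posterior DMN (lateral parietal and middle
temporal cortex), the anterior DMN (insula, anterior cingulate, temporal
poles), the ventral DMN (precuneus, posterior cingulate, hippocampal and
fusiform regions, angular gyrus), a sensorimotor network and a visual
network.  All connectivity matrices in this package are indexed by this
atlas in a single canonical order: ascending AAL index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "Subnetwork",
    "ROIRecord",
    "AtlasTable",
    "load_atlas",
    "subnetwork_members",
]


class Subnetwork(str, Enum):
    """The five resting-state subnetworks of the parcellation."""

    DMN_POSTERIOR = "DMN_posterior"
    DMN_ANTERIOR = "DMN_anterior"
    DMN_VENTRAL = "DMN_ventral"
    SENSORIMOTOR = "Sensorimotor"
    VISUAL = "Visual"


# Expected subnetwork sizes; validated on load.
_SUBNETWORK_SIZES = {
    Subnetwork.DMN_POSTERIOR: 6,
    Subnetwork.DMN_ANTERIOR: 6,
    Subnetwork.DMN_VENTRAL: 12,
    Subnetwork.SENSORIMOTOR: 12,
    Subnetwork.VISUAL: 12,
}

# (AAL90 index, region name, subnetwork).  Region names carry the standard
# AAL "_L"/"_R" hemisphere suffix.
_ROI_TABLE: tuple[tuple[int, str, Subnetwork], ...] = (
    (59, "Parietal_Sup_L", Subnetwork.DMN_POSTERIOR),
    (60, "Parietal_Sup_R", Subnetwork.DMN_POSTERIOR),
    (61, "Parietal_Inf_L", Subnetwork.DMN_POSTERIOR),
    (62, "Parietal_Inf_R", Subnetwork.DMN_POSTERIOR),
    (85, "Temporal_Mid_L", Subnetwork.DMN_POSTERIOR),
    (86, "Temporal_Mid_R", Subnetwork.DMN_POSTERIOR),
    (29, "Insula_L", Subnetwork.DMN_ANTERIOR),
    (30, "Insula_R", Subnetwork.DMN_ANTERIOR),
    (31, "Cingulum_Ant_L", Subnetwork.DMN_ANTERIOR),
    (32, "Cingulum_Ant_R", Subnetwork.DMN_ANTERIOR),
    (87, "Temporal_Pole_Mid_L", Subnetwork.DMN_ANTERIOR),
    (88, "Temporal_Pole_Mid_R", Subnetwork.DMN_ANTERIOR),
    (35, "Cingulum_Post_L", Subnetwork.DMN_VENTRAL),
    (36, "Cingulum_Post_R", Subnetwork.DMN_VENTRAL),
    (37, "Hippocampus_L", Subnetwork.DMN_VENTRAL),
    (38, "Hippocampus_R", Subnetwork.DMN_VENTRAL),
    (39, "Parahippocampal_L", Subnetwork.DMN_VENTRAL),
    (40, "Parahippocampal_R", Subnetwork.DMN_VENTRAL),
    (55, "Fusiform_L", Subnetwork.DMN_VENTRAL),
    (56, "Fusiform_R", Subnetwork.DMN_VENTRAL),
    (65, "Angular_L", Subnetwork.DMN_VENTRAL),
    (66, "Angular_R", Subnetwork.DMN_VENTRAL),
    (67, "Precuneus_L", Subnetwork.DMN_VENTRAL),
    (68, "Precuneus_R", Subnetwork.DMN_VENTRAL),
    (1, "Precentral_L", Subnetwork.SENSORIMOTOR),
    (2, "Precentral_R", Subnetwork.SENSORIMOTOR),
    (7, "Frontal_Mid_L", Subnetwork.SENSORIMOTOR),
    (8, "Frontal_Mid_R", Subnetwork.SENSORIMOTOR),
    (19, "Supp_Motor_Area_L", Subnetwork.SENSORIMOTOR),
    (20, "Supp_Motor_Area_R", Subnetwork.SENSORIMOTOR),
    (57, "Postcentral_L", Subnetwork.SENSORIMOTOR),
    (58, "Postcentral_R", Subnetwork.SENSORIMOTOR),
    (63, "Supramarginal_L", Subnetwork.SENSORIMOTOR),
    (64, "Supramarginal_R", Subnetwork.SENSORIMOTOR),
    (69, "Paracentral_Lobule_L", Subnetwork.SENSORIMOTOR),
    (70, "Paracentral_Lobule_R", Subnetwork.SENSORIMOTOR),
    (43, "Calcarine_L", Subnetwork.VISUAL),
    (44, "Calcarine_R", Subnetwork.VISUAL),
    (45, "Cuneus_L", Subnetwork.VISUAL),
    (46, "Cuneus_R", Subnetwork.VISUAL),
    (47, "Lingual_L", Subnetwork.VISUAL),
    (48, "Lingual_R", Subnetwork.VISUAL),
    (49, "Occipital_Sup_L", Subnetwork.VISUAL),
    (50, "Occipital_Sup_R", Subnetwork.VISUAL),
    (51, "Occipital_Mid_L", Subnetwork.VISUAL),
    (52, "Occipital_Mid_R", Subnetwork.VISUAL),
    (53, "Occipital_Inf_L", Subnetwork.VISUAL),
    (54, "Occipital_Inf_R", Subnetwork.VISUAL),
)


@dataclass(frozen=True)
class ROIRecord:
    """One atlas region: AAL index, label, subnetwork membership."""

    roi_id: int
    name: str
    subnetwork: Subnetwork

    @property
    def hemisphere(self) -> str:
        """``"L"`` or ``"R"``, derived from the name suffix."""
        suffix = self.name.rsplit("_", 1)[-1]
        if suffix not in ("L", "R"):
            raise ValueError(f"ROI name {self.name!r} lacks an _L/_R suffix")
        return suffix


@dataclass(frozen=True)
class AtlasTable:
    """The full parcellation in canonical (ascending AAL index) order.

    The position of a record in :attr:`records` is the row/column index of
    that region in every matrix produced by the pipeline.
    """

    records: tuple[ROIRecord, ...]
    _by_id: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_by_id", {r.roi_id: i for i, r in enumerate(self.records)}
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ROIRecord]:
        return iter(self.records)

    @property
    def n_rois(self) -> int:
        return len(self.records)

    @property
    def column_order(self) -> tuple[str, ...]:
        """Region names in matrix column order."""
        return tuple(r.name for r in self.records)

    @property
    def roi_ids(self) -> tuple[int, ...]:
        return tuple(r.roi_id for r in self.records)

    def index_of(self, roi_id: int) -> int:
        """Matrix index of an AAL region id."""
        try:
            return self._by_id[roi_id]
        except KeyError:
            raise KeyError(f"AAL index {roi_id} is not part of the atlas") from None

    def get(self, roi_id: int) -> ROIRecord:
        return self.records[self.index_of(roi_id)]

    def by_name(self, name: str) -> ROIRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r} in the atlas")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in self.records],
                "name": [r.name for r in self.records],
                "subnetwork": [r.subnetwork.value for r in self.records],
                "hemisphere": [r.hemisphere for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["roi_id", "name", "subnetwork", "hemisphere"])
            for r in self.records:
                writer.writerow([r.roi_id, r.name, r.subnetwork.value, r.hemisphere])


def _validate(records: tuple[ROIRecord, ...]) -> None:
    if len(records) != 48:
        raise AssertionError("atlas must contain exactly 48 regions")
    ids = [r.roi_id for r in records]
    if len(set(ids)) != len(ids):
        raise AssertionError("duplicate AAL indices in atlas")
    for label, size in _SUBNETWORK_SIZES.items():
        members = [r for r in records if r.subnetwork is label]
        if len(members) != size:
            raise AssertionError(f"{label.value} must contain {size} regions")
        left = sum(1 for r in members if r.hemisphere == "L")
        if left * 2 != len(members):
            raise AssertionError(f"{label.value} is not hemisphere-balanced")


def load_atlas() -> AtlasTable:
    """Build the embedded 48-region atlas, sorted by ascending AAL index."""
    records = tuple(
        ROIRecord(roi_id, name, subnet)
        for roi_id, name, subnet in sorted(_ROI_TABLE)
    )
    _validate(records)
    return AtlasTable(records)


def subnetwork_members(atlas: AtlasTable, label: Subnetwork | str) -> list[ROIRecord]:
    """Regions of one subnetwork, in atlas (matrix) order."""
    try:
        label = Subnetwork(label)
    except ValueError:
        valid = ", ".join(s.value for s in Subnetwork)
        raise ValueError(f"unknown subnetwork {label!r}; expected one of: {valid}")
    return [r for r in atlas.records if r.subnetwork is label]
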
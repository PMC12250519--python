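"""Voxel-based damage volumetry.

The damaged volume of a scan is the per-voxel volume times the total count
of damage-labeled pixels across all B-scan slices:

    V = V_P * sum_k F(s_k)

where F(s_k) counts foreground pixels in slice k and V_P = dx*dy*dz.  With
the default spacings (lateral 10 um, axial 22 um, inter-slice 50 um) one
voxel is 11,000 um^3.  Masks must be in native scan geometry (un-padded)
before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MaskStack, SegmentationMask

__all__ = ["VoxelGeometry", "DamageVolumeResult", "damage_pixel_count",
           "damage_volume", "healing_table"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel spacings in micrometres.

    dx: lateral (image width axis), dy: axial/depth (image height axis),
    dz: inter-slice spacing.
    """

    dx: float = 10.0
    dy: float = 22.0
    dz: float = 50.0

    def __post_init__(self):
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def voxel_volume(self) -> float:
        """V_P in um^3."""
        return self.dx * self.dy * self.dz


@dataclass
class DamageVolumeResult:
    volume_um3: float
    per_slice_counts: list[int]
    geometry: VoxelGeometry
    meta: dict = field(default_factory=dict)

    @property
    def total_voxels(self) -> int:
        return int(sum(self.per_slice_counts))


def damage_pixel_count(mask: SegmentationMask | np.ndarray) -> int:
    """F(s_k): number of damage-labeled (label 1) pixels in one slice."""
    labels = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    uniq = np.unique(labels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask is not binary; labels found: {uniq}")
    return int((labels == 1).sum())


def damage_volume(masks: MaskStack | list, geom: VoxelGeometry | None = None,
                  meta: dict | None = None) -> DamageVolumeResult:
    geom = geom or VoxelGeometry()
    slices = list(masks)
    if not slices:
        raise ValueError("empty mask stack")
    counts = [damage_pixel_count(m) for m in slices]
    return DamageVolumeResult(
        volume_um3=geom.voxel_volume * float(sum(counts)),
        per_slice_counts=counts,
        geometry=geom,
        meta=dict(meta or {}),
    )


def healing_table(results: list[DamageVolumeResult]) -> pd.DataFrame:
    """Tabulate damage volume by (dose, timepoint), with relative change
    versus each dose's earliest timepoint."""
    rows = []
    for r in results:
        if "dose" not in r.meta or "timepoint" not in r.meta:
            raise ValueError("results must carry dose and timepoint metadata")
        rows.append({"dose": r.meta["dose"], "timepoint": r.meta["timepoint"],
                     "volume_um3": r.volume_um3})
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["dose", "timepoint"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["dose", "timepoint"]].drop_duplicates()
        raise ValueError(f"duplicate (dose, timepoint) keys: "
                         f"{pairs.to_records(index=False).tolist()}")
    df = df.sort_values(["dose", "timepoint"]).reset_index(drop=True)
    base = df.groupby("dose")["volume_um3"].transform("first")
    df["relative_change"] = np.where(base > 0, df["volume_um3"] / base, np.nan)
    return df
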
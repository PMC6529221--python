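"""Modality-averaged input maps restricted to a neuropil region.

Input neurons carrying a given sensory modality (olfactory, mechanosensory,
temperature, visual, taste) are summarised by averaging one exemplar mask
per cell type voxelwise and keeping only the voxels inside a region mask —
the machinery behind the observation that non-olfactory input concentrates
in a limited ventral zone of the lateral horn.  The occupancy statistic that
quantifies "how ventral" a map is, is this package's own operationalisation:
the fraction of a map's mass falling in each member of a region partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, LabelVolume, assert_same_grid, restrict_to_region

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ModalityMap:
    """Voxelwise mean of exemplar masks for one modality, zero outside the
    region; values are fractions in [0, 1]."""

    modality: str
    mean_volume: LabelVolume
    n_exemplars: int
    region_id: str = "LH"

    def __post_init__(self):
        data = self.mean_volume.data
        if data.min() < 0 or data.max() > 1 + 1e-9:
            raise ValueError("modality map values must lie in [0, 1]")

    @property
    def total_mass(self) -> float:
        return float(self.mean_volume.data.sum())


def average_modality(
    exemplars: list, region: BinaryMask, modality: str = "none", region_id: str = "LH"
) -> ModalityMap:
    """Voxelwise arithmetic mean of exemplar volumes, restricted to a region.

    Exemplars may be BinaryMasks (treated as 0/1) or LabelVolumes; one
    exemplar per cell type is the convention, enforced by the caller's
    explicit listing.  Averaging is permutation-invariant in exemplar order.
    """
    if not exemplars:
        raise ValueError("need at least one exemplar to average")
    for e in exemplars:
        assert_same_grid(e, region)
    stack = np.stack([np.asarray(e.data, dtype=np.float64) for e in exemplars])
    mean = stack.mean(axis=0)
    vol = LabelVolume(
        mean, spacing=region.spacing, origin=region.origin, space_id=region.space_id
    )
    vol = restrict_to_region(vol, region)
    return ModalityMap(
        modality=modality, mean_volume=vol, n_exemplars=len(exemplars), region_id=region_id
    )


def split_region(region: BinaryMask, axis: str = "z", plane: float | None = None):
    """Split a region into two half-masks by a plane along a named axis.

    ``plane`` is a voxel coordinate along the axis; by default the plane
    passes through the region's centroid, giving the configurable
    ventral/dorsal split.  Returns (below, above) masks, where "below" holds
    voxels with index <= plane.
    """
    ax = AXES[axis]
    coords = np.nonzero(region.data)
    if len(coords[0]) == 0:
        raise ValueError("cannot split an empty region")
    if plane is None:
        plane = float(np.mean(coords[ax]))
    idx = np.arange(region.shape[ax]).reshape(
        [-1 if i == ax else 1 for i in range(3)]
    )
    below = region.data & (idx <= plane)
    above = region.data & (idx > plane)
    meta = {"cell_type": region.cell_type or "region"}
    return (
        BinaryMask(below, spacing=region.spacing, origin=region.origin,
                   space_id=region.space_id, **meta),
        BinaryMask(above, spacing=region.spacing, origin=region.origin,
                   space_id=region.space_id, **meta),
    )


def modality_occupancy(
    mmap: ModalityMap, region_partition: list[BinaryMask], region: BinaryMask | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of the map's mass (sum of mean values) in each sub-region.

    The partition must cover every voxel where the map is non-zero (pass the
    full region to check coverage against it explicitly); over a true
    partition the fractions sum to 1.
    """
    vol = mmap.mean_volume
    for sub in region_partition:
        assert_same_grid(vol, sub)
    union = np.zeros(vol.shape, dtype=bool)
    for sub in region_partition:
        union |= sub.data
    support = region.data if region is not None else (vol.data > 0)
    if np.any(support & ~union):
        raise ValueError("partition does not cover the region")
    total = mmap.total_mass
    if total == 0:
        raise ValueError("modality map has zero mass")
    labels = labels or [sub.label for sub in region_partition]
    rows = [
        (lab, float(vol.data[sub.data].sum()) / total)
        for lab, sub in zip(labels, region_partition)
    ]
    return pd.DataFrame(rows, columns=["sub_region", "mass_fraction"])
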
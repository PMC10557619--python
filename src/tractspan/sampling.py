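"""Sampling scalar volumes along bundles.

Two aggregation modes feed the feature table: the tract average (unweighted
mean of a microstructure map over every voxel the bundle occupies) and
endpoint probing (read a cortical map at the voxel containing each
streamline's first and last point, average the two ends, then average over
streamlines). Cortical maps are undefined off the cortical ribbon, so NaN
voxels are expected: tract averaging excludes them, endpoint probing uses
the finite side of a streamline when only one end lands on a defined voxel
and drops streamlines with neither; both report how much was excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import nibabel as nib

from .geometry import StreamlineBundle, VoxelGrid, voxelize_bundle

__all__ = [
    "ScalarVolume",
    "TractAverage",
    "EndpointAverage",
    "tract_average_scalar",
    "endpoint_feature",
    "load_scalar_volume",
    "save_scalar_volume",
]


@dataclass
class ScalarVolume:
    """A 3D scalar map (NaN allowed) on a voxel grid, in feature units."""

    values: np.ndarray
    grid: VoxelGrid
    feature: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


class TractAverage(NamedTuple):
    value: float
    n_voxels: int
    n_excluded: int  # NaN voxels inside the tract mask

    @property
    def excluded_fraction(self) -> float:
        total = self.n_voxels + self.n_excluded
        return self.n_excluded / total if total else float("nan")


class EndpointAverage(NamedTuple):
    value: float
    n_streamlines: int
    n_dropped: int  # streamlines with NaN at both ends


def tract_average_scalar(bundle: StreamlineBundle, volume: ScalarVolume) -> TractAverage:
    """Unweighted mean of the map over all voxels occupied by the tract.

    NaN voxels are excluded from the mean and counted. Raises if no occupied
    voxel holds a finite value.
    """
    if bundle.grid is not None and not np.allclose(
        bundle.grid.affine, volume.grid.affine
    ):
        bundle = StreamlineBundle(
            streamlines=bundle.streamlines,
            bundle_id=bundle.bundle_id,
            grid=volume.grid,
        )
    elif bundle.grid is None:
        bundle = StreamlineBundle(
            streamlines=bundle.streamlines,
            bundle_id=bundle.bundle_id,
            grid=volume.grid,
        )
    mask = voxelize_bundle(bundle)
    sampled = volume.values[mask]
    finite = np.isfinite(sampled)
    if not np.any(finite):
        raise ValueError(
            f"bundle {bundle.bundle_id!r} occupies no voxel with a finite "
            f"{volume.feature!r} value"
        )
    return TractAverage(
        value=float(sampled[finite].mean()),
        n_voxels=int(finite.sum()),
        n_excluded=int((~finite).sum()),
    )


def endpoint_feature(bundle: StreamlineBundle, cortical_map: ScalarVolume) -> EndpointAverage:
    """Mean over streamlines of the two-end average of a cortical map.

    Each streamline contributes the average of the map value at the voxel
    containing its first point and at the voxel containing its last point
    (nearest-voxel sampling). If one end is NaN the finite end is used; if
    both are NaN the streamline is dropped and counted.
    """
    grid = cortical_map.grid
    dims = np.array(grid.shape)
    per_streamline = []
    n_dropped = 0
    for i, s in enumerate(bundle.streamlines):
        ends = np.vstack([s[0], s[-1]])
        vox = np.floor(grid.world_to_voxel(ends) + 0.5).astype(int)
        if np.any((vox < 0) | (vox >= dims)):
            raise ValueError(
                f"bundle {bundle.bundle_id!r}: endpoints of streamline {i} "
                "fall outside the map grid"
            )
        vals = cortical_map.values[vox[:, 0], vox[:, 1], vox[:, 2]]
        finite = np.isfinite(vals)
        if not np.any(finite):
            n_dropped += 1
            continue
        per_streamline.append(float(vals[finite].mean()))
    if not per_streamline:
        raise ValueError(
            f"bundle {bundle.bundle_id!r}: every streamline endpoint pair is "
            f"undefined in {cortical_map.feature!r}"
        )
    return EndpointAverage(
        value=float(np.mean(per_streamline)),
        n_streamlines=len(per_streamline),
        n_dropped=n_dropped,
    )


def load_scalar_volume(path: str | Path, feature: str | None = None) -> ScalarVolume:
    img = nib.load(str(path))
    grid = VoxelGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))
    return ScalarVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        grid=grid,
        feature=feature or Path(path).name.split(".")[0],
    )


def save_scalar_volume(volume: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine)
    nib.save(img, str(path))
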
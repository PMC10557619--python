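"""Macrostructural shape features of streamline bundles.

A bundle is a set of ordered 3D polylines (streamlines) in world millimetre
coordinates, together with a reference voxel grid. Ten shape features
summarise its macrostructure: volume, endpoint volume, length, span, curl,
diameter, elongation, and total / head / tail surface areas.

Conventions
-----------
* World coordinates are RAS+ millimetres; the grid affine maps voxel indices
  (centres at integers) to world mm.
* A point belongs to the voxel whose half-open interval
  ``[edge, edge + size)`` contains it, i.e. ``floor(v + 0.5)`` in continuous
  voxel coordinates.
* Length and span are per-streamline quantities averaged over the bundle;
  curl = length / span, which is >= 1 up to discretisation error.
* Volume and surface areas are computed on the binary voxel occupancy mask;
  surface area counts exposed voxel faces under 6-connectivity.
* The head of a bundle is the end whose centroid has the smaller coordinate
  along the dominant displacement axis (the most left / posterior / inferior
  end in RAS), with ties broken x, then y, then z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "VoxelGrid",
    "StreamlineBundle",
    "ShapeFeatures",
    "streamline_length",
    "centerline_features",
    "voxelize_bundle",
    "bundle_volumes",
    "cylinder_features",
    "split_head_tail",
    "surface_areas",
    "compute_shape_features",
    "load_tractogram",
    "save_tractogram",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel grid: array shape plus a voxel-to-world (RAS+ mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world mm points to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, points: np.ndarray) -> np.ndarray:
        vox = np.floor(self.world_to_voxel(points) + 0.5)
        return np.all((vox >= 0) & (vox < np.array(self.shape)), axis=1)


@dataclass
class StreamlineBundle:
    """Ordered 3D polylines in world mm with a reference voxel grid."""

    streamlines: list[np.ndarray]
    bundle_id: str = "bundle"
    grid: VoxelGrid | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} of bundle {self.bundle_id!r} must be an "
                    f"(n>=2, 3) array, got shape {s.shape}"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(
                    f"streamline {i} of bundle {self.bundle_id!r} has non-finite points"
                )
            cleaned.append(s)
        if not cleaned:
            raise ValueError(f"bundle {self.bundle_id!r} has no streamlines")
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class ShapeFeatures:
    """The ten macrostructural shape features of a bundle."""

    volume: float  # mm^3
    endpoint_volume: float  # mm^3
    length: float  # mm
    span: float  # mm
    curl: float  # unitless, >= 1
    diameter: float  # mm
    elongation: float  # unitless
    surface_area: float  # mm^2
    surface_area_head: float  # mm^2
    surface_area_tail: float  # mm^2

    FIELDS = (
        "volume",
        "endpoint_volume",
        "length",
        "span",
        "curl",
        "diameter",
        "elongation",
        "surface_area",
        "surface_area_head",
        "surface_area_tail",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


# ---------------------------------------------------------------------------
# centreline features


def streamline_length(streamline: np.ndarray) -> float:
    """Arc length of one polyline: sum of Euclidean segment lengths (mm)."""
    s = np.asarray(streamline, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())


def centerline_features(bundle: StreamlineBundle) -> tuple[float, float, float]:
    """Mean length, mean span, and curl (= length / span) of a bundle.

    Span is the straight-line distance between a streamline's two endpoints,
    averaged over streamlines. A closed-loop bundle (span ~ 0) has no defined
    curl; ``nan`` is returned rather than infinity.
    """
    lengths = np.array([streamline_length(s) for s in bundle.streamlines])
    spans = np.array(
        [np.linalg.norm(s[-1] - s[0]) for s in bundle.streamlines]
    )
    length = float(lengths.mean())
    span = float(spans.mean())
    curl = length / span if span > 1e-9 else float("nan")
    return length, span, curl


# ---------------------------------------------------------------------------
# voxelisation


def _densify(streamline: np.ndarray, max_step: float) -> np.ndarray:
    """Insert vertices so that consecutive points are < ``max_step`` apart."""
    pts = [streamline[:1]]
    seg = np.diff(streamline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    for i, L in enumerate(seg_len):
        n = max(int(np.ceil(L / max_step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pts.append(streamline[i] + t * seg[i])
    return np.vstack(pts)


def voxelize_bundle(
    bundle: StreamlineBundle,
    endpoints_only: bool = False,
    points_override: np.ndarray | None = None,
) -> np.ndarray:
    """Binary occupancy mask of the bundle on its grid.

    A voxel is occupied iff at least one (densified) streamline vertex maps
    into it. Segments are subdivided below half the smallest voxel size so no
    traversed voxel is skipped at fixture scale.
    """
    if bundle.grid is None:
        raise ValueError(f"bundle {bundle.bundle_id!r} has no reference grid")
    grid = bundle.grid
    max_step = float(grid.voxel_sizes.min()) / 2.0
    mask = np.zeros(grid.shape, dtype=bool)
    if points_override is not None:
        groups = [("points", np.atleast_2d(points_override))]
    elif endpoints_only:
        groups = [
            (i, np.vstack([s[0], s[-1]])) for i, s in enumerate(bundle.streamlines)
        ]
    else:
        groups = [
            (i, _densify(s, max_step)) for i, s in enumerate(bundle.streamlines)
        ]
    dims = np.array(grid.shape)
    for key, pts in groups:
        vox = np.floor(grid.world_to_voxel(pts) + 0.5).astype(int)
        bad = np.any((vox < 0) | (vox >= dims), axis=1)
        if np.any(bad):
            raise ValueError(
                f"bundle {bundle.bundle_id!r}: streamline {key} has points "
                f"outside the grid (first offender at world "
                f"{pts[np.argmax(bad)]})"
            )
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask


def bundle_volumes(bundle: StreamlineBundle) -> tuple[float, float]:
    """(volume, endpoint_volume) in mm^3 from voxel occupancy counts."""
    vv = bundle.grid.voxel_volume
    volume = float(voxelize_bundle(bundle).sum()) * vv
    endpoint_volume = float(voxelize_bundle(bundle, endpoints_only=True).sum()) * vv
    return volume, endpoint_volume


def cylinder_features(volume: float, length: float) -> tuple[float, float]:
    """Diameter and elongation of the bundle approximated as a cylinder.

    diameter = 2 sqrt(volume / (pi length)); elongation = length / diameter.
    """
    if volume <= 0 or length <= 0:
        raise ValueError("volume and length must be positive")
    diameter = 2.0 * np.sqrt(volume / (np.pi * length))
    return float(diameter), float(length / diameter)


# ---------------------------------------------------------------------------
# head / tail ends


def split_head_tail(
    bundle: StreamlineBundle,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orient streamlines consistently and split endpoints into head and tail.

    Returns ``(reversed_flags, head_points, tail_points)`` where
    ``reversed_flags[i]`` says streamline ``i`` was flipped relative to its
    stored order. Streamlines are first co-oriented against a reference
    streamline (flipping whichever assignment of ends is closer); the head is
    then the end cluster whose centroid is smaller along the dominant
    displacement axis, ties broken x (left) then y (posterior) then z
    (inferior).
    """
    ref = bundle.streamlines[0]
    flags = np.zeros(len(bundle), dtype=bool)
    firsts = np.empty((len(bundle), 3))
    lasts = np.empty((len(bundle), 3))
    for i, s in enumerate(bundle.streamlines):
        direct = np.linalg.norm(s[0] - ref[0]) + np.linalg.norm(s[-1] - ref[-1])
        flipped = np.linalg.norm(s[0] - ref[-1]) + np.linalg.norm(s[-1] - ref[0])
        if flipped < direct:
            flags[i] = True
            firsts[i], lasts[i] = s[-1], s[0]
        else:
            firsts[i], lasts[i] = s[0], s[-1]
    c_first = firsts.mean(axis=0)
    c_last = lasts.mean(axis=0)
    disp = c_last - c_first
    if np.linalg.norm(disp) < 1e-9:
        raise ValueError(
            f"bundle {bundle.bundle_id!r} is degenerate (zero end-to-end span); "
            "head/tail ends are undefined"
        )
    axis = int(np.argmax(np.abs(disp)))  # argmax tie-breaks x, then y, then z
    if c_first[axis] <= c_last[axis]:
        return flags, firsts, lasts
    return ~flags, lasts, firsts


def surface_areas(bundle: StreamlineBundle) -> tuple[float, float, float]:
    """(total, head, tail) surface areas in mm^2 from exposed voxel faces.

    A face of an occupied voxel counts as exposed when its 6-neighbour across
    that face is unoccupied (or outside the grid). Head and tail areas apply
    the same rule to the occupancy masks of head / tail endpoint voxels.
    """
    grid = bundle.grid
    total = _exposed_face_area(voxelize_bundle(bundle), grid)
    _, head_pts, tail_pts = split_head_tail(bundle)
    head = _exposed_face_area(
        voxelize_bundle(bundle, points_override=head_pts), grid
    )
    tail = _exposed_face_area(
        voxelize_bundle(bundle, points_override=tail_pts), grid
    )
    return total, head, tail


def _exposed_face_area(mask: np.ndarray, grid: VoxelGrid) -> float:
    sizes = grid.voxel_sizes
    face_area = [sizes[1] * sizes[2], sizes[0] * sizes[2], sizes[0] * sizes[1]]
    total = 0.0
    for ax in range(3):
        for shift in (-1, 1):
            neighbour = np.zeros_like(mask)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[ax] = slice(1, None)
                dst[ax] = slice(None, -1)
            else:
                src[ax] = slice(None, -1)
                dst[ax] = slice(1, None)
            neighbour[tuple(dst)] = mask[tuple(src)]
            total += float(np.sum(mask & ~neighbour)) * face_area[ax]
    return total


def compute_shape_features(bundle: StreamlineBundle) -> ShapeFeatures:
    """Assemble all ten shape features of a bundle."""
    length, span, curl = centerline_features(bundle)
    volume, endpoint_volume = bundle_volumes(bundle)
    diameter, elongation = cylinder_features(volume, length)
    total, head, tail = surface_areas(bundle)
    return ShapeFeatures(
        volume=volume,
        endpoint_volume=endpoint_volume,
        length=length,
        span=span,
        curl=curl,
        diameter=diameter,
        elongation=elongation,
        surface_area=total,
        surface_area_head=head,
        surface_area_tail=tail,
    )


# ---------------------------------------------------------------------------
# tractogram I/O (TRK stores voxel-space data + affine header; TCK world mm)


def save_tractogram(bundle: StreamlineBundle, path: str | Path) -> None:
    path = Path(path)
    tractogram = Tractogram(bundle.streamlines, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        if bundle.grid is None:
            raise ValueError("saving TRK requires a reference grid")
        header = {
            "voxel_to_rasmm": bundle.grid.affine.astype(np.float32),
            "voxel_sizes": bundle.grid.voxel_sizes.astype(np.float32),
            "dimensions": np.array(bundle.grid.shape, dtype=np.int16),
            "voxel_order": "RAS",
        }
        TrkFile(tractogram, header=header).save(str(path))
    elif path.suffix.lower() == ".tck":
        TckFile(tractogram).save(str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {path.suffix!r}")


def load_tractogram(
    path: str | Path,
    bundle_id: str | None = None,
    grid: VoxelGrid | None = None,
) -> StreamlineBundle:
    """Read a TRK or TCK file into a bundle in world mm coordinates.

    TRK files carry their reference grid in the header; for TCK (which stores
    only world coordinates) pass ``grid`` explicitly if voxel-based features
    are needed.
    """
    path = Path(path)
    tf = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if grid is None and isinstance(tf, TrkFile):
        header = tf.header
        grid = VoxelGrid(
            shape=tuple(int(d) for d in header["dimensions"]),
            affine=np.asarray(header["voxel_to_rasmm"], dtype=float),
        )
    return StreamlineBundle(
        streamlines=streamlines,
        bundle_id=bundle_id or path.stem,
        grid=grid,
    )
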
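"""Volume/mesh bridge: thresholding + centroids, iso-surfaces, file I/O.

Everything here operates in world millimetres through the volume affine
(voxel index → world mm).  Volumes are never re-oriented or resampled: all
inputs are assumed to live in one common, already co-registered space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from seegqa.geometry3d import GeometryError, TriMesh

__all__ = [
    "Blob",
    "Volume",
    "extract_isosurface",
    "read_mesh",
    "read_volume",
    "threshold_components",
    "write_mesh",
    "write_volume",
]


@dataclass
class Volume:
    """A 3D intensity volume with a voxel-index → world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a nonempty 3D array")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()


@dataclass(frozen=True)
class Blob:
    """A connected supra-threshold component."""

    n_voxels: int
    centroid: np.ndarray  # world mm
    mean_intensity: float


def threshold_components(vol: Volume, threshold: float, min_voxels: int = 2) -> list[Blob]:
    """Supra-threshold 26-connected components with world-space centroids.

    Centroids are intensity-weighted means of voxel centers mapped through
    the affine (weighting reduces quantization bias relative to a binary
    centroid).  Components smaller than ``min_voxels`` are suppressed as
    noise.  Returned sorted by voxel count descending.
    """
    from scipy import ndimage

    mask = vol.data > threshold
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    blobs = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        count = int(sub.sum())
        if count < min_voxels:
            continue
        w = np.asarray(vol.data[sl], dtype=float) * sub
        idx = np.argwhere(sub).astype(float)
        idx += np.array([s.start for s in sl], dtype=float)
        weights = w[sub]
        centroid_idx = (idx * weights[:, None]).sum(axis=0) / weights.sum()
        blobs.append(
            Blob(
                n_voxels=count,
                centroid=vol.index_to_world(centroid_idx),
                mean_intensity=float(weights.mean()),
            )
        )
    blobs.sort(key=lambda b: b.n_voxels, reverse=True)
    return blobs


def extract_isosurface(vol: Volume, level: float) -> TriMesh:
    """Marching-cubes iso-surface of a volume, in world mm.

    Only the largest connected surface component is retained (e.g. the
    scalp sheet rather than interior structures crossing the same level).
    """
    from skimage import measure
    import trimesh as _trimesh

    lo, hi = float(np.min(vol.data)), float(np.max(vol.data))
    if not (lo < level < hi):
        raise GeometryError(f"iso-level {level} outside intensity range ({lo}, {hi})")
    verts, faces, _, _ = measure.marching_cubes(np.asarray(vol.data, dtype=float), level=level)
    world = vol.index_to_world(verts)
    tm = _trimesh.Trimesh(vertices=world, faces=faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.faces))
    return TriMesh.from_trimesh(tm)


def read_mesh(path) -> TriMesh:
    """Read an STL or PLY surface mesh (binary or ASCII)."""
    import trimesh as _trimesh

    m = _trimesh.load(str(path), force="mesh")
    if m.is_empty or len(m.faces) == 0:
        raise ValueError(f"{path}: no triangles found")
    return TriMesh.from_trimesh(m)


def write_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as binary STL or PLY, by file extension."""
    mesh.to_trimesh().export(str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI volume (array + affine, no reorientation)."""
    import nibabel as nib

    img = nib.load(str(path))
    return Volume(data=np.asanyarray(img.dataobj), affine=img.affine)


def write_volume(vol: Volume, path) -> None:
    """Write a NIfTI volume."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))
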
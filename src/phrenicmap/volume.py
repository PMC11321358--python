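"""CT-style encoding of the nerve course in an attenuation volume.

The clinical pipeline writes the radiologist-delineated nerve path into the CT
series as a 5-pixel-wide curved line at 900 HU so that ordinary threshold
segmentation recovers it. This module reproduces that encoding on synthetic
volumes: rasterize a centerline polyline as a 900-HU tube, segment it back by
HU threshold, and extract an ordered centerline from the segmented voxels.
``roundtrip_distance_error`` quantifies how much of the encode/decode
discretization leaks into site-to-nerve distances.

Conventions: axis-aligned grids only; a voxel index refers to the voxel
center; world = origin + index * spacing. Volumes interchange as NIfTI-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import Polyline3, points_to_polyline_distances

__all__ = [
    "HUVolume",
    "VoxelSet",
    "rasterize_nerve",
    "segment_hu_threshold",
    "extract_centerline",
    "roundtrip_distance_error",
]


@dataclass
class HUVolume:
    """Scalar attenuation grid (HU) with per-axis spacing and world origin (mm)."""

    data: np.ndarray       # (nx, ny, nz) float32
    spacing: np.ndarray    # (3,) mm, > 0
    origin: np.ndarray     # (3,) mm, world coordinate of voxel (0,0,0) center

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world points (not rounded)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def copy(self) -> "HUVolume":
        return HUVolume(self.data.copy(), self.spacing.copy(), self.origin.copy())

    def save_nifti(self, path) -> None:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, aff), str(path))

    @classmethod
    def load_nifti(cls, path) -> "HUVolume":
        img = nib.load(str(path))
        aff = img.affine
        if np.max(np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3])))) > 1e-6:
            raise ValueError("only axis-aligned volumes are supported")
        return cls(np.asarray(img.dataobj, dtype=np.float32),
                   np.diag(aff[:3, :3]).copy(), aff[:3, 3].copy())

    @classmethod
    def background(cls, shape, spacing, origin, body_hu: float = 40.0,
                   air_hu: float = -1000.0) -> "HUVolume":
        """Synthetic thorax-like background: soft-tissue body ellipsoid (~40 HU)
        in air (-1000 HU), so a 900 HU marker is trivially separable."""
        shape = tuple(int(s) for s in shape)
        spacing = np.asarray(spacing, dtype=float)
        idx = np.indices(shape, dtype=float)
        center = (np.asarray(shape) - 1) / 2.0
        semi = np.maximum((np.asarray(shape) - 1) * spacing / 2.0, 1e-6)
        r2 = sum(((idx[k] - center[k]) * spacing[k] / semi[k]) ** 2 for k in range(3))
        data = np.where(r2 <= 1.0, body_hu, air_hu).astype(np.float32)
        return cls(data, spacing, np.asarray(origin, dtype=float))


@dataclass
class VoxelSet:
    """Integer voxel indices plus the owning volume's geometry."""

    indices: np.ndarray    # (n, 3) int
    spacing: np.ndarray
    origin: np.ndarray
    shape: tuple

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.indices.size and (
            np.any(self.indices < 0) or np.any(self.indices >= np.asarray(self.shape))
        ):
            raise ValueError("voxel index out of grid bounds")

    def __len__(self):
        return len(self.indices)

    @property
    def world_centers(self) -> np.ndarray:
        return self.origin + self.indices * self.spacing

    def to_csv(self, path) -> None:
        np.savetxt(path, self.indices, fmt="%d", delimiter=",", header="i,j,k", comments="")


def rasterize_nerve(path: Polyline3, vol: HUVolume, width_voxels: float = 5,
                    hu_value: float = 900.0) -> HUVolume:
    """Write the nerve path into a copy of ``vol`` as a tube at ``hu_value``.

    Every voxel whose *center* lies within radius ``width_voxels * mean_spacing
    / 2`` of the centerline is set to ``hu_value``; all others keep their
    value. The path (plus tube radius) must stay inside the grid.
    """
    if width_voxels < 1:
        raise ValueError("width_voxels must be >= 1")
    radius = width_voxels * float(np.mean(vol.spacing)) / 2.0

    # bounds check with tube-radius margin, reporting the offending vertex
    lo = vol.origin - vol.spacing / 2.0
    hi = vol.origin + (np.asarray(vol.shape) - 0.5) * vol.spacing
    for i, v in enumerate(path.vertices):
        if np.any(v - radius < lo) or np.any(v + radius > hi):
            raise ValueError(
                f"nerve path vertex {i} at {v.tolist()} exits the volume "
                f"(tube radius {radius:.2f} mm)"
            )

    out = vol.copy()
    shape = np.asarray(vol.shape)
    for a, b in zip(path.vertices[:-1], path.vertices[1:]):
        lo_w = np.minimum(a, b) - radius
        hi_w = np.maximum(a, b) + radius
        i0 = np.maximum(np.floor((lo_w - vol.origin) / vol.spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((hi_w - vol.origin) / vol.spacing).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        grids = np.meshgrid(*[np.arange(i0[k], i1[k]) for k in range(3)], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = vol.origin + idx * vol.spacing
        seg = Polyline3(np.vstack([a, b]))
        d = points_to_polyline_distances(centers, seg)
        hit = idx[d <= radius]
        out.data[hit[:, 0], hit[:, 1], hit[:, 2]] = hu_value
    return out


def segment_hu_threshold(vol: HUVolume, hu_min: float = 850.0) -> VoxelSet:
    """Voxels with attenuation >= ``hu_min`` (the marker separates cleanly from
    soft tissue and bone-range background by construction)."""
    idx = np.argwhere(vol.data >= hu_min)
    return VoxelSet(idx, vol.spacing, vol.origin, vol.shape)


def _connected_component_count(voxels: VoxelSet) -> int:
    idx = voxels.indices
    lo = idx.min(axis=0)
    sub = np.zeros(tuple(idx.max(axis=0) - lo + 1), dtype=bool)
    rel = idx - lo
    sub[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    _, n = ndimage.label(sub, structure=np.ones((3, 3, 3), dtype=int))
    return int(n)


def extract_centerline(voxels: VoxelSet, smooth_window_mm: float | None = None) -> Polyline3:
    """Ordered centerline polyline through a segmented tube of voxels.

    Voxel centers are projected onto the first principal axis to seed an
    ordering; centers are aggregated into one-voxel-wide bins along that axis
    (local centroid averaging over roughly a tube diameter), and the bin
    centroids are chained by greedy nearest neighbour starting from the
    extreme bin. Because the rasterized tube carries hemispherical end caps
    extending one radius beyond the true path ends, the chained curve is
    trimmed by the tube radius estimated from the voxel volume, so its
    endpoints land near the true path endpoints. The voxel set must be
    26-connected; a single voxel yields a degenerate one-point polyline
    (flagged on the result).
    """
    if len(voxels) == 0:
        raise ValueError("empty voxel set")
    if len(voxels) == 1:
        return Polyline3.degenerate(voxels.world_centers[0])
    n_comp = _connected_component_count(voxels)
    if n_comp != 1:
        raise ValueError(f"voxel set is disconnected: {n_comp} components (26-neighbourhood)")

    centers = voxels.world_centers
    mean = centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(centers - mean, full_matrices=False)
    axis = Vt[0]
    proj = (centers - mean) @ axis

    bin_w = float(np.max(voxels.spacing))
    if smooth_window_mm is not None:
        bin_w = max(bin_w, smooth_window_mm / 5.0)
    edges = np.arange(proj.min() - 1e-9, proj.max() + bin_w, bin_w)
    which = np.clip(np.digitize(proj, edges) - 1, 0, len(edges) - 2)
    order = np.argsort(which, kind="stable")
    which_s, centers_s = which[order], centers[order]
    uniq, starts = np.unique(which_s, return_index=True)
    centroids = np.add.reduceat(centers_s, starts, axis=0) / \
        np.diff(np.append(starts, len(centers_s)))[:, None]

    if len(centroids) == 1:
        # tube shorter than one bin: fall back to extreme projections
        lo, hi = centers[np.argmin(proj)], centers[np.argmax(proj)]
        if np.allclose(lo, hi):
            return Polyline3.degenerate(lo)
        return Polyline3(np.vstack([lo, hi]))

    # greedy nearest-neighbour chaining from the extreme centroid
    remaining = list(range(1, len(centroids)))
    chain = [0]
    while remaining:
        last = centroids[chain[-1]]
        d = np.linalg.norm(centroids[remaining] - last, axis=1)
        j = int(np.argmin(d))
        chain.append(remaining.pop(j))
    pts = centroids[chain]
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    line = Polyline3(pts[keep])

    # trim the end-cap overshoot: tube radius from capsule volume V = pi r^2 L
    volume = len(voxels) * float(np.prod(voxels.spacing))
    r_hat = np.sqrt(volume / (np.pi * max(line.length, 1e-9)))
    return _trim_polyline_ends(line, r_hat)


def _trim_polyline_ends(line: Polyline3, trim_mm: float) -> Polyline3:
    s = line.arc_length
    if trim_mm <= 0 or 2 * trim_mm >= s[-1]:
        return line
    t = np.clip(s, trim_mm, s[-1] - trim_mm)
    t = np.union1d(t, [trim_mm, s[-1] - trim_mm])
    pts = np.column_stack([np.interp(t, s, line.vertices[:, k]) for k in range(3)])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    return Polyline3(pts[keep])


def roundtrip_distance_error(path: Polyline3, spacing, sites,
                             width_voxels: float = 5, hu_value: float = 900.0,
                             hu_min: float = 850.0, margin_mm: float = 4.0) -> np.ndarray:
    """Per-site |d(site, extracted centerline) - d(site, true path)| in mm.

    Builds a tight background volume around the path at the given spacing,
    runs rasterize -> threshold-segment -> centerline, and propagates the
    discretization into the site distances. Empty site list -> empty output.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    radius = width_voxels * float(np.mean(spacing)) / 2.0
    pad = radius + margin_mm
    lo = path.vertices.min(axis=0) - pad
    hi = path.vertices.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 4)
    vol = HUVolume(np.zeros(tuple(shape), dtype=np.float32), spacing, lo)
    marked = rasterize_nerve(path, vol, width_voxels=width_voxels, hu_value=hu_value)
    extracted = extract_centerline(segment_hu_threshold(marked, hu_min=hu_min),
                                   smooth_window_mm=width_voxels * float(np.mean(spacing)))
    if sites.size == 0:
        return np.empty(0)
    d_true = points_to_polyline_distances(sites, path)
    d_est = points_to_polyline_distances(sites, extracted)
    return np.abs(d_est - d_true)
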
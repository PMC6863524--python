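"""Voxel representation of the target shape and region-labeling generators.

The slicer operates on a :class:`LabeledVolume`: an isotropic voxel grid of
integer region labels (0 = outside the shape, 1..K = design regions, -1 =
support material added later).  Shapes can come from watertight STL
surfaces (center-sampling voxelization), or from the synthetic fixture
generator.  Labeling generators reproduce the three spatial-patterning
strategies used for anatomic scaffolds: linear gradients along an axis,
depth shells from the surface, and local-thickness classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

SUPPORT_LABEL = -1

__all__ = [
    "LabeledVolume",
    "SUPPORT_LABEL",
    "voxelize_mesh",
    "resample",
    "label_linear_gradient",
    "label_shells",
    "label_by_thickness",
    "local_thickness",
    "make_fixture",
]


@dataclass
class LabeledVolume:
    """Axis-aligned voxel grid of integer region labels.

    ``labels[i, j, k]`` covers the half-open box
    ``origin + pitch*[i, i+1) x [j, j+1) x [k, k+1)``; the voxel center sits
    at ``origin + pitch * (i+1/2, j+1/2, k+1/2)``.  z is the build
    direction and z = 0 is the print bed.
    """

    labels: np.ndarray
    pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of voxels belonging to the shape or support."""
        return self.labels != 0

    @property
    def region_labels(self) -> list[int]:
        """Sorted nonzero labels present in the volume."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + self.pitch * (np.arange(n) + 0.5)

    @property
    def upper(self) -> np.ndarray:
        """Physical coordinates of the +x/+y/+z grid corner."""
        return self.origin + self.pitch * np.asarray(self.labels.shape)

    def with_labels(self, labels: np.ndarray) -> "LabeledVolume":
        return LabeledVolume(labels, self.pitch, self.origin.copy())

    # -- persistence: compressed array + JSON sidecar ---------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), labels=self.labels)
        meta = {"pitch": self.pitch, "origin": self.origin.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledVolume":
        path = Path(path)
        labels = np.load(path.with_suffix(".npz"))["labels"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(labels, meta["pitch"], np.asarray(meta["origin"]))


# ---------------------------------------------------------------------------
# STL voxelization
# ---------------------------------------------------------------------------


def _column_crossings(
    triangles: np.ndarray, xs: np.ndarray, ys: np.ndarray, x0: float, y0: float, pitch: float
):
    """z-values where each (x, y) grid column crosses the surface.

    Scanline parity fill: for every triangle, find the grid columns inside
    its plan-view projection (barycentric test) and record the z of the
    intersection.  Triangles that are vertical in plan view (zero projected
    area) contribute no crossings.
    """
    nx, ny = len(xs), len(ys)
    cross: dict[int, list[float]] = {}
    eps = 1e-12
    for tri in triangles:
        (ax, ay, az), (bx, by, bz), (cx, cy, cz) = tri
        det = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(det) < 1e-14:
            continue
        ilo = max(0, int(np.ceil((min(ax, bx, cx) - x0) / pitch - 0.5 - 1e-9)))
        ihi = min(nx - 1, int(np.floor((max(ax, bx, cx) - x0) / pitch - 0.5 + 1e-9)))
        jlo = max(0, int(np.ceil((min(ay, by, cy) - y0) / pitch - 0.5 - 1e-9)))
        jhi = min(ny - 1, int(np.floor((max(ay, by, cy) - y0) / pitch - 0.5 + 1e-9)))
        if ihi < ilo or jhi < jlo:
            continue
        gx, gy = np.meshgrid(xs[ilo : ihi + 1], ys[jlo : jhi + 1], indexing="ij")
        l0 = ((by - cy) * (gx - cx) + (cx - bx) * (gy - cy)) / det
        l1 = ((cy - ay) * (gx - cx) + (ax - cx) * (gy - cy)) / det
        l2 = 1.0 - l0 - l1
        inside = (l0 >= -eps) & (l1 >= -eps) & (l2 >= -eps)
        if not inside.any():
            continue
        zs = l0 * az + l1 * bz + l2 * cz
        ii, jj = np.nonzero(inside)
        for i, j, z in zip(ii + ilo, jj + jlo, zs[inside]):
            cross.setdefault(i * ny + j, []).append(float(z))
    return cross


def voxelize_mesh(mesh, pitch: float, bed_clearance: float | None = None) -> LabeledVolume:
    """Voxelize a watertight triangle surface with center sampling.

    A voxel is labeled 1 iff its center lies inside the surface (parity of
    surface crossings along the +z ray).  The result is translated so the
    lowest occupied voxel sits ``bed_clearance`` (default: one voxel pitch)
    above the bed plane z = 0; support generation fills the gap.

    ``mesh`` may be a trimesh.Trimesh or a path to an STL file (binary or
    ASCII).
    """
    import trimesh

    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    if isinstance(mesh, (str, Path)):
        mesh = trimesh.load_mesh(str(mesh))
    if mesh.faces.shape[0] == 0:
        raise ValueError("mesh has no faces")
    if not mesh.is_watertight:
        # every undirected edge of a closed surface is shared by exactly two faces
        _, inv = np.unique(mesh.edges_sorted, axis=0, return_inverse=True)
        n_open = int((np.bincount(inv) != 2).sum())
        raise ValueError(
            f"mesh is not watertight: {n_open} open/over-shared edges; "
            "repair the surface before voxelizing"
        )

    (bx0, by0, bz0), (bx1, by1, bz1) = mesh.bounds
    nx = max(1, int(np.ceil((bx1 - bx0) / pitch - 1e-9)))
    ny = max(1, int(np.ceil((by1 - by0) / pitch - 1e-9)))
    nz = max(1, int(np.ceil((bz1 - bz0) / pitch - 1e-9)))
    xs = bx0 + pitch * (np.arange(nx) + 0.5)
    ys = by0 + pitch * (np.arange(ny) + 0.5)
    zs = bz0 + pitch * (np.arange(nz) + 0.5)

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    cross = _column_crossings(np.asarray(mesh.triangles, dtype=float), xs, ys, bx0, by0, pitch)
    for key, zlist in cross.items():
        zlist.sort()
        # merge duplicate crossings from shared projected edges
        merged: list[float] = []
        for z in zlist:
            if merged and z - merged[-1] < 1e-9:
                continue
            merged.append(z)
        i, j = divmod(key, ny)
        for lo, hi in zip(merged[::2], merged[1::2]):
            k0 = int(np.searchsorted(zs, lo))
            k1 = int(np.searchsorted(zs, hi))
            labels[i, j, k0:k1] = 1

    if not labels.any():
        raise ValueError("voxelization produced an empty volume (shape thinner than pitch?)")

    # crop to the occupied bounding box and drop onto the bed
    occ = np.nonzero(labels)
    lo = [int(a.min()) for a in occ]
    hi = [int(a.max()) + 1 for a in occ]
    labels = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    clearance = pitch if bed_clearance is None else bed_clearance
    origin = np.array([bx0 + lo[0] * pitch, by0 + lo[1] * pitch, clearance])
    return LabeledVolume(labels, pitch, origin)


def resample(volume: LabeledVolume, new_pitch: float) -> LabeledVolume:
    """Nearest-neighbor label resampling preserving the physical extent."""
    if new_pitch <= 0:
        raise ValueError(f"new_pitch must be positive, got {new_pitch}")
    if abs(new_pitch - volume.pitch) < 1e-12:
        return volume.with_labels(volume.labels.copy())
    extent = np.asarray(volume.shape) * volume.pitch
    new_shape = np.maximum(1, np.rint(extent / new_pitch).astype(int))
    idx = []
    for axis in range(3):
        c = (np.arange(new_shape[axis]) + 0.5) * new_pitch
        idx.append(np.clip((c / volume.pitch).astype(int), 0, volume.shape[axis] - 1))
    labels = volume.labels[np.ix_(idx[0], idx[1], idx[2])]
    return LabeledVolume(labels, new_pitch, volume.origin.copy())


# ---------------------------------------------------------------------------
# Region labeling generators
# ---------------------------------------------------------------------------


def label_linear_gradient(volume: LabeledVolume, axis: int | str, region_count: int) -> LabeledVolume:
    """Split the occupied extent along an axis into K equal-length slabs.

    Slabs are labeled 1..K in order of increasing coordinate; only voxels
    that were occupied are relabeled.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if region_count < 1:
        raise ValueError(f"region_count must be >= 1, got {region_count}")
    occ = volume.occupied
    if not occ.any():
        raise ValueError("volume is empty")
    proj = np.nonzero(occ.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    imin, imax = int(proj.min()), int(proj.max())
    span = imax - imin + 1
    if region_count > span:
        raise ValueError(
            f"region_count {region_count} exceeds the occupied span of {span} voxels along axis {axis}"
        )
    idx = np.arange(volume.shape[axis])
    frac = (idx - imin + 0.5) / span
    slab = np.minimum(region_count - 1, np.maximum(0, (frac * region_count).astype(int))) + 1
    shape = [1, 1, 1]
    shape[axis] = -1
    labels = np.where(occ, slab.reshape(shape), 0).astype(np.int16)
    return volume.with_labels(labels)


def label_shells(volume: LabeledVolume, shell_boundaries: Sequence[float]) -> LabeledVolume:
    """Label by depth from the shape surface: shell 1 outermost, K+1 the core.

    Depth is the Euclidean distance (mm) of each interior voxel to the
    nearest outside voxel; depths are binned at the given strictly
    increasing boundaries (a depth equal to a boundary falls in the outer
    shell).
    """
    bounds = list(shell_boundaries)
    if any(b <= 0 for b in bounds) or any(
        b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])
    ):
        raise ValueError("shell boundaries must be strictly increasing and positive")
    occ = volume.occupied
    if not occ.any():
        raise ValueError("volume is empty")
    # pad so the world outside the grid counts as background
    depth = ndi.distance_transform_edt(np.pad(occ, 1))[1:-1, 1:-1, 1:-1] * volume.pitch
    labels = np.where(occ, np.searchsorted(bounds, depth, side="left") + 1, 0)
    return volume.with_labels(labels.astype(np.int16))


def local_thickness(volume: LabeledVolume) -> np.ndarray:
    """Per-voxel local thickness (mm) via the nearest medial EDT maximum.

    The interior distance transform is evaluated at medial maxima (voxels
    whose EDT equals the maximum over their 3x3x3 neighborhood); every
    occupied voxel inherits twice the EDT of its nearest medial maximum,
    i.e. the diameter of the largest inscribed sphere whose center ridge
    passes nearest to it.  Accurate to about one voxel on slabs.
    """
    occ = volume.occupied
    if not occ.any():
        raise ValueError("volume is empty")
    edt = ndi.distance_transform_edt(np.pad(occ, 1))[1:-1, 1:-1, 1:-1]
    maxima = occ & (edt >= ndi.maximum_filter(edt, size=3) - 1e-9)
    # nearest medial maximum for every voxel
    _, (ix, iy, iz) = ndi.distance_transform_edt(~maxima, return_indices=True)
    ridge_edt = edt[ix, iy, iz]
    thickness = (2.0 * ridge_edt - 1.0) * volume.pitch
    thickness[~occ] = 0.0
    return thickness


def label_by_thickness(
    volume: LabeledVolume, thickness_thresholds: Sequence[float]
) -> LabeledVolume:
    """Bin occupied voxels by local thickness; thinnest class = label 1."""
    thresholds = list(thickness_thresholds)
    if any(t <= 0 for t in thresholds) or any(
        t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thickness thresholds must be strictly increasing and positive")
    occ = volume.occupied
    if not occ.any():
        raise ValueError("volume is empty")
    thick = local_thickness(volume)
    labels = np.where(occ, np.searchsorted(thresholds, thick, side="left") + 1, 0)
    return volume.with_labels(labels.astype(np.int16))


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def make_fixture(
    kind: str,
    dimensions: Sequence[float],
    pitch: float,
    *,
    gap: float = 2.0,
    seed: int = 0,
) -> LabeledVolume:
    """Deterministic synthetic shapes for tests and demonstrations.

    kind:
      - ``box``: dimensions (lx, ly, lz) mm, resting on the bed.
      - ``floating_box``: same, floating ``gap`` mm above the bed.
      - ``cylinder``: dimensions (radius, height), axis = z, on the bed.
      - ``sphere``: dimensions (radius,), resting on the bed.
      - ``blob``: dimensions (lx, ly, lz); a seeded smooth random level set
        clipped to its largest connected component (anatomic-like curvature).
    """
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    dims = [float(d) for d in dimensions]
    if any(d <= 0 for d in dims):
        raise ValueError(f"dimensions must be positive, got {dims}")

    def grid(lx, ly, lz):
        n = [max(1, int(round(l / pitch))) for l in (lx, ly, lz)]
        return n

    if kind == "box" or kind == "floating_box":
        nx, ny, nz = grid(*dims[:3])
        labels = np.ones((nx, ny, nz), dtype=np.int16)
        z0 = gap if kind == "floating_box" else 0.0
        return LabeledVolume(labels, pitch, np.array([0.0, 0.0, z0]))

    if kind == "cylinder":
        r, h = dims
        nx = ny = max(1, int(round(2 * r / pitch)))
        nz = max(1, int(round(h / pitch)))
        c = (np.arange(nx) + 0.5) * pitch - r
        xx, yy = np.meshgrid(c, c, indexing="ij")
        disk = xx**2 + yy**2 <= r**2
        labels = np.repeat(disk[:, :, None], nz, axis=2).astype(np.int16)
        return LabeledVolume(labels, pitch, np.zeros(3))

    if kind == "sphere":
        (r,) = dims
        n = max(1, int(round(2 * r / pitch)))
        c = (np.arange(n) + 0.5) * pitch - r
        xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
        labels = (xx**2 + yy**2 + zz**2 <= r**2).astype(np.int16)
        return LabeledVolume(labels, pitch, np.zeros(3))

    if kind == "blob":
        nx, ny, nz = grid(*dims[:3])
        rng = np.random.default_rng(seed)
        coarse = rng.standard_normal((max(4, nx // 8), max(4, ny // 8), max(4, nz // 8)))
        field_ = ndi.zoom(ndi.gaussian_filter(coarse, 1.0), np.array([nx, ny, nz]) / coarse.shape, order=1)
        field_ = field_[:nx, :ny, :nz]
        mask = field_ > np.quantile(field_, 0.55)
        lab, n = ndi.label(mask)
        if n == 0:
            mask = field_ > np.quantile(field_, 0.4)
            lab, n = ndi.label(mask)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        labels = (lab == int(sizes.argmax())).astype(np.int16)
        return LabeledVolume(labels, pitch, np.zeros(3))

    raise ValueError(f"unknown fixture kind {kind!r}")
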
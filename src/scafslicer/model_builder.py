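"""In-silico predicted model: rasterize toolpaths into a voxel solid.

Every fiber is an axis-aligned rectangular box (length x nozzle-width x
layer-height); a voxel is solid iff its center falls inside some fiber's
box, and overlapping fibers merge by union.  The resulting
:class:`PredictedModel` is the digital twin of the print used to verify
porosity, pore geometry and inter-region pore connectivity before
manufacture.  STL export emits the exact voxel faces (no smoothing), so
the exported mesh volume is bit-consistent with the voxel count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .shape_model import SUPPORT_LABEL, LabeledVolume
from .slicer import ToolpathLayer

__all__ = [
    "PredictedModel",
    "PorosityMeasurement",
    "rasterize",
    "design_porosity_of",
    "gravimetric_porosity",
    "export_stl",
]


@dataclass
class PredictedModel:
    """Binary solid-occupancy grid of the expected print.

    ``region_of`` carries the source region label of each *solid* voxel
    (0 where void); ``design_regions``, when built from a labeled volume,
    carries the design label of every voxel position regardless of
    occupancy and is what the interface analysis partitions space with.
    """

    solid: np.ndarray
    region_of: np.ndarray
    pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    design_regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    def solid_only(self, role: str = "model") -> np.ndarray:
        """Solid mask restricted to model or support material."""
        if role == "model":
            return self.solid & (self.region_of != SUPPORT_LABEL)
        if role == "support":
            return self.solid & (self.region_of == SUPPORT_LABEL)
        raise ValueError(f"unknown role {role!r}")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {"solid": self.solid, "region_of": self.region_of}
        if self.design_regions is not None:
            arrays["design_regions"] = self.design_regions
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {"pitch": self.pitch, "origin": self.origin.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PredictedModel":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data["solid"], data["region_of"], meta["pitch"],
            np.asarray(meta["origin"]),
            data["design_regions"] if "design_regions" in data else None,
        )


@dataclass
class PorosityMeasurement:
    """A porosity value with its provenance.

    ``design_matrix`` porosities are void fractions of the predicted voxel
    model; ``gravimetric`` porosities come from mass (and optionally
    volume) comparison of a porous part against a solid part of the same
    dimensions.
    """

    porosity: float
    method: str
    mass_porous: float | None = None
    mass_solid: float | None = None
    volume_porous: float | None = None
    volume_solid: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError(f"porosity must be in [0, 1], got {self.porosity}")


def _index_range(lo: float, hi: float, origin: float, pitch: float, n: int) -> tuple[int, int]:
    """Indices whose voxel centers fall in [lo, hi); clipped to [0, n)."""
    i0 = int(math.ceil((lo - origin) / pitch - 0.5 - 1e-9))
    i1 = int(math.floor((hi - origin) / pitch - 0.5 + 1e-9)) + 1
    # centers exactly on hi are excluded (half-open convention)
    while i1 > i0 and origin + (i1 - 0.5) * pitch >= hi - 1e-9:
        i1 -= 1
    return max(0, i0), min(n, i1)


def rasterize(
    layers: list[ToolpathLayer],
    pitch: float,
    bounds: tuple | None = None,
    volume: LabeledVolume | None = None,
) -> PredictedModel:
    """Mark solid every voxel whose center lies inside a fiber's box.

    ``bounds`` is ((x0, y0, z0), (x1, y1, z1)); when omitted it is taken
    from ``volume`` (extended down to the bed) or, failing that, from the
    segments' extents.  The pitch must divide the layer height and be at
    most half the nozzle width so fibers are resolved.

    When ``volume`` is given, its labels are nearest-sampled onto the model
    grid as ``design_regions``.
    """
    segs = [s for layer in layers for s in layer.segments]
    if segs:
        h = segs[0].height
        w = segs[0].width
        ratio = h / pitch
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"pitch {pitch} must divide the layer height {h}")
        if pitch > w / 2 + 1e-9:
            raise ValueError(f"pitch {pitch} too coarse for nozzle width {w}")
    if bounds is None:
        if volume is not None:
            lo = np.array([volume.origin[0], volume.origin[1], 0.0])
            hi = volume.upper
        elif segs:
            pts = np.array([[*s.start, s.z] for s in segs] + [[*s.end, s.z] for s in segs])
            wmax = max(s.width for s in segs)
            lo = pts.min(axis=0) - [0, 0, 0]
            lo[:2] -= wmax / 2
            lo[2] = 0.0
            hi = pts.max(axis=0)
            hi[:2] += wmax / 2
        else:
            raise ValueError("cannot infer bounds from empty layers; pass bounds=")
    else:
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    n = np.maximum(1, np.rint((hi - lo) / pitch).astype(int))

    solid = np.zeros(tuple(n), dtype=bool)
    region = np.zeros(tuple(n), dtype=np.int16)
    for seg in segs:
        # rectangle footprint: full length along the fiber, one nozzle
        # width across it, one layer height in z
        x0, x1 = sorted((seg.start[0], seg.end[0]))
        y0, y1 = sorted((seg.start[1], seg.end[1]))
        if x1 - x0 < 1e-12:
            x0, x1 = x0 - seg.width / 2, x1 + seg.width / 2
        if y1 - y0 < 1e-12:
            y0, y1 = y0 - seg.width / 2, y1 + seg.width / 2
        i0, i1 = _index_range(x0, x1, lo[0], pitch, n[0])
        j0, j1 = _index_range(y0, y1, lo[1], pitch, n[1])
        k0, k1 = _index_range(seg.z - seg.height, seg.z, lo[2], pitch, n[2])
        if i1 > i0 and j1 > j0 and k1 > k0:
            solid[i0:i1, j0:j1, k0:k1] = True
            region[i0:i1, j0:j1, k0:k1] = seg.region

    design = None
    if volume is not None:
        idx = []
        inside = []
        for axis in range(3):
            c = lo[axis] + (np.arange(n[axis]) + 0.5) * pitch
            i = np.floor((c - volume.origin[axis]) / volume.pitch).astype(int)
            inside.append((i >= 0) & (i < volume.shape[axis]))
            idx.append(np.clip(i, 0, volume.shape[axis] - 1))
        design = volume.labels[np.ix_(idx[0], idx[1], idx[2])].astype(np.int16)
        out = ~(inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :])
        design[out] = 0
    region[~solid] = 0
    return PredictedModel(solid, region, pitch, lo, design)


def design_porosity_of(model: PredictedModel, region=None) -> PorosityMeasurement:
    """Void fraction of the model within a bounding region.

    ``region`` may be None (whole grid), an integer design label (that
    label's bounding box), or a pair of physical corner points
    ``((x0, y0, z0), (x1, y1, z1))``.
    """
    if region is None:
        sub = model.solid
    elif isinstance(region, (int, np.integer)):
        src = model.design_regions if model.design_regions is not None else model.region_of
        where = np.nonzero(src == region)
        if len(where[0]) == 0:
            raise ValueError(f"region label {region} not present in the model")
        sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in where)
        sub = model.solid[sl]
    else:
        lo, hi = region
        sl = []
        for axis in range(3):
            i0 = int(round((lo[axis] - model.origin[axis]) / model.pitch))
            i1 = int(round((hi[axis] - model.origin[axis]) / model.pitch))
            sl.append(slice(max(0, i0), min(model.shape[axis], i1)))
        sub = model.solid[tuple(sl)]
    if sub.size == 0:
        raise ValueError("empty porosity region")
    return PorosityMeasurement(
        porosity=float(1.0 - sub.mean()), method="design_matrix"
    )


def gravimetric_porosity(
    mass_porous: float,
    mass_solid: float,
    volume_porous: float | None = None,
    volume_solid: float | None = None,
) -> PorosityMeasurement:
    """Porosity from mass of a porous print vs a solid print.

    With equal volumes: ``1 - m_porous / m_solid``.  When the two parts
    have different volumes the comparison is density-normalized:
    ``1 - (m_p / v_p) / (m_s / v_s)``.
    """
    if mass_porous <= 0 or mass_solid <= 0:
        raise ValueError("masses must be positive")
    if (volume_porous is None) != (volume_solid is None):
        raise ValueError("provide both volumes or neither")
    if volume_porous is None:
        phi = 1.0 - mass_porous / mass_solid
        if phi < 0:
            raise ValueError(
                "porous mass exceeds solid mass at equal volumes (negative porosity)"
            )
        return PorosityMeasurement(phi, "gravimetric",
                                   mass_porous=mass_porous, mass_solid=mass_solid)
    if volume_porous <= 0 or volume_solid <= 0:
        raise ValueError("volumes must be positive")
    phi = 1.0 - (mass_porous / volume_porous) / (mass_solid / volume_solid)
    if phi < 0:
        raise ValueError("porous density exceeds solid density (negative porosity)")
    return PorosityMeasurement(
        phi, "gravimetric",
        mass_porous=mass_porous, mass_solid=mass_solid,
        volume_porous=volume_porous, volume_solid=volume_solid,
    )


# face templates: axis, direction, and the 4 cube-corner offsets (CCW seen
# from outside) of the face quad
_FACES = {
    (0, +1): ((1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)),
    (0, -1): ((0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)),
    (1, +1): ((0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)),
    (1, -1): ((0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)),
    (2, +1): ((0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)),
    (2, -1): ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)),
}


def export_stl(model: PredictedModel, path: str | Path | None = None):
    """Exact blocky surface of the solid voxels as a triangle mesh.

    Each exposed voxel face contributes two triangles; no smoothing is
    applied, so the mesh volume equals ``solid_count * pitch**3`` exactly
    and fiber rectangles survive in the exported geometry.  Returns a
    ``trimesh.Trimesh``; writes it to ``path`` when given.
    """
    import trimesh

    solid = model.solid
    if not solid.any():
        raise ValueError("model has no solid voxels to export")
    padded = np.pad(solid, 1, constant_values=False)
    quads = []
    for (axis, sign), corners in _FACES.items():
        shifted = np.roll(padded, -sign, axis=axis)[1:-1, 1:-1, 1:-1]
        exposed = solid & ~shifted
        cells = np.argwhere(exposed)
        if len(cells) == 0:
            continue
        quads.append((cells, corners))
    verts: list[tuple[int, int, int]] = []
    vmap: dict[tuple[int, int, int], int] = {}
    tris: list[tuple[int, int, int]] = []
    for cells, corners in quads:
        for cell in cells:
            ids = []
            for off in corners:
                key = (cell[0] + off[0], cell[1] + off[1], cell[2] + off[2])
                idx = vmap.get(key)
                if idx is None:
                    idx = len(verts)
                    vmap[key] = idx
                    verts.append(key)
                ids.append(idx)
            tris.append((ids[0], ids[1], ids[2]))
            tris.append((ids[0], ids[2], ids[3]))
    vertices = model.origin + model.pitch * np.asarray(verts, dtype=float)
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(tris), process=False)
    if path is not None:
        mesh.export(str(path))
    return mesh
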
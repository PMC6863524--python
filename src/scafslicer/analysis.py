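"""In-silico quality metrics: interface pore connectivity and pore sizing.

Two differently patterned regions are useful only if the pore networks
stay connected across their boundary.  The boundary is isolated as a thin
digital slab (default 200 um); connected void components of the slab that
reach both sides are the *connecting pores*, and the connected area
fraction is the summed pore area over the interface boundary area.

Pore and strut sizes are measured the way a stereoscope measurement would:
binarize a projection of the model, find enclosed void components, and
report each pore as the square root of its area; strut widths are solid
run lengths perpendicular to the strut direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .model_builder import PredictedModel

__all__ = ["InterfaceReport", "PoreSizeReport", "interface_connectivity", "measure_pores"]


@dataclass
class InterfaceReport:
    """Connectivity of the pore space across one region-region boundary.

    ``pore_areas`` lists every pore (connected void component) of the
    interface slab; in an open woodpile lattice each of these connects the
    two regions' pore networks, so their summed area over the boundary
    area is the ``connected_area_fraction``.  The subset of components
    that individually span the slab from the a side to the b side is also
    reported (``spanning_*``) as a conservative variant.
    """

    label_pair: tuple[int, int]
    slab_thickness: float
    interface_area: float  # mm^2
    pore_areas: list[float]  # mm^2, one per pore of the interface slab
    connected_area_fraction: float
    # conservative subset: components that reach both slab faces
    spanning_pore_areas: list[float] = field(default_factory=list)
    spanning_area_fraction: float = 0.0

    @property
    def pore_count(self) -> int:
        return len(self.pore_areas)


def interface_connectivity(
    model: PredictedModel,
    label_a: int,
    label_b: int,
    slab_thickness: float = 0.2,
    connectivity: int = 6,
) -> InterfaceReport:
    """Measure open pore area crossing the a-b region boundary.

    The slab is every voxel within ``slab_thickness / 2`` of the boundary
    surface (chessboard distance, so slab layers parallel the boundary).
    Pores are the connected void components of the slab (face connectivity
    by default; pass ``connectivity=26`` for vertex connectivity); each
    pore's area is its mean cross-section, component volume divided by the
    slab thickness.  The connected area fraction sums every pore of the
    slab; the components that individually reach the outermost slab layer
    on both the a side and the b side are additionally reported as the
    conservative ``spanning`` subset.
    """
    if model.design_regions is None:
        raise ValueError(
            "model carries no design-region map; rasterize with volume= to "
            "enable interface analysis"
        )
    if label_a == label_b:
        raise ValueError("labels must differ; relabel the volume to self-test a plane")
    regions = model.design_regions
    pitch = model.pitch
    n_half = max(1, int(round(slab_thickness / (2.0 * pitch))))

    da = ndi.distance_transform_cdt(regions != label_b, metric="chessboard")
    db = ndi.distance_transform_cdt(regions != label_a, metric="chessboard")
    is_a = regions == label_a
    is_b = regions == label_b
    if not (is_a & (da == 1)).any():
        raise ValueError(f"labels {label_a} and {label_b} are not adjacent")

    slab_a = is_a & (da >= 1) & (da <= n_half)
    slab_b = is_b & (db >= 1) & (db <= n_half)
    slab = slab_a | slab_b

    # boundary area: number of voxel faces where a touches b
    faces = 0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo_a, hi_b = is_a[tuple(sl_lo)], is_b[tuple(sl_hi)]
        lo_b, hi_a = is_b[tuple(sl_lo)], is_a[tuple(sl_hi)]
        faces += int((lo_a & hi_b).sum() + (lo_b & hi_a).sum())
    interface_area = faces * pitch**2

    void = slab & ~model.solid
    structure = ndi.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    lab, n_comp = ndi.label(void, structure=structure)
    counts = np.bincount(lab.ravel(), minlength=n_comp + 1)

    face_a = slab_a & (da == n_half) & void
    face_b = slab_b & (db == n_half) & void
    ids_a = set(np.unique(lab[face_a])) - {0}
    ids_b = set(np.unique(lab[face_b])) - {0}
    spanning = sorted(ids_a & ids_b)

    to_area = pitch**3 / slab_thickness
    all_areas = [float(counts[i] * to_area) for i in range(1, n_comp + 1)]
    span_areas = [float(counts[i] * to_area) for i in spanning]
    return InterfaceReport(
        label_pair=(label_a, label_b),
        slab_thickness=slab_thickness,
        interface_area=interface_area,
        pore_areas=all_areas,
        connected_area_fraction=float(sum(all_areas) / interface_area),
        spanning_pore_areas=span_areas,
        spanning_area_fraction=float(sum(span_areas) / interface_area),
    )


@dataclass
class PoreSizeReport:
    """Pore sizes (sqrt of area) and strut widths from one projection."""

    view: str
    pore_sizes: np.ndarray  # mm
    strut_widths: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.pore_sizes = np.asarray(self.pore_sizes, dtype=float)
        self.strut_widths = np.asarray(self.strut_widths, dtype=float)

    @property
    def pore_size_mean(self) -> float:
        return float(self.pore_sizes.mean()) if self.pore_sizes.size else math.nan

    @property
    def pore_size_std(self) -> float:
        return float(self.pore_sizes.std()) if self.pore_sizes.size else math.nan

    @property
    def strut_width_mean(self) -> float:
        return float(self.strut_widths.mean()) if self.strut_widths.size else math.nan

    @property
    def strut_width_std(self) -> float:
        return float(self.strut_widths.std()) if self.strut_widths.size else math.nan

    def ratios(self, design_pore: float, design_strut: float) -> tuple[float, float]:
        """(measured/design pore, measured/design strut) ratio pair."""
        return self.pore_size_mean / design_pore, self.strut_width_mean / design_strut


_VIEW_AXIS = {"top": 2, "side_x": 0, "side_y": 1}


def _solid_runs(line: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(line)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def measure_pores(
    model: PredictedModel,
    view: str,
    region: int | None = None,
    depth: float | None = None,
) -> PoreSizeReport:
    """Measure pores and struts on a projection of the model.

    ``view`` is one of ``top``, ``side_x``, ``side_y``.  By default the
    full model is projected along the view axis (through-pores, as seen
    looking straight into the scaffold); ``depth`` restricts the
    projection to the outermost slab of that physical thickness, which
    mimics a surface photograph.  Pores are void components fully enclosed
    in the projection (border-touching voids are not pores) and are
    reported as the square root of their area; strut widths are solid run
    lengths along both image axes, excluding runs that touch the border.
    """
    try:
        axis = _VIEW_AXIS[view]
    except KeyError:
        raise ValueError(f"view must be one of {sorted(_VIEW_AXIS)}, got {view!r}") from None
    solid = model.solid
    if region is not None:
        src = model.design_regions if model.design_regions is not None else model.region_of
        where = np.nonzero(src == region)
        if len(where[0]) == 0:
            raise ValueError(f"region label {region} not present")
        sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in where)
        solid = solid[sl]
    if not solid.any():
        raise ValueError(f"no solid material in view {view!r}")
    if depth is not None:
        n_keep = max(1, int(round(depth / model.pitch)))
        occupied = np.nonzero(solid.any(axis=tuple(a for a in range(3) if a != axis)))[0]
        top_idx = int(occupied.max())
        sl = [slice(None)] * 3
        sl[axis] = slice(max(0, top_idx + 1 - n_keep), top_idx + 1)
        solid = solid[tuple(sl)]
    mask = solid.any(axis=axis)

    # crop to the projected footprint so the surrounding air is not a pore
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    mask = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]

    void_lab, n_comp = ndi.label(~mask)
    border = set(np.unique(void_lab[0, :])) | set(np.unique(void_lab[-1, :]))
    border |= set(np.unique(void_lab[:, 0])) | set(np.unique(void_lab[:, -1]))
    areas = np.bincount(void_lab.ravel(), minlength=n_comp + 1)
    pitch2 = model.pitch**2
    pore_sizes = [
        math.sqrt(areas[i] * pitch2)
        for i in range(1, n_comp + 1)
        if i not in border
    ]

    strut_widths = []
    for img in (mask, mask.T):
        n_cols = img.shape[1]
        for line in img:
            for first, last in _solid_runs(line):
                if first == 0 or last == n_cols - 1:
                    continue  # touches border: not a full strut crossing
                strut_widths.append((last - first + 1) * model.pitch)
    return PoreSizeReport(view, np.asarray(pore_sizes), np.asarray(strut_widths))
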
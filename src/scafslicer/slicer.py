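"""Toolpath generation: per-pattern templates convolved with labeled levels.

Each pore pattern owns a periodic strut-lattice *template* per orientation:
strut blocks of ``strut_fiber_count`` adjacent fibers with their left edge
on the lattice ``n * (pore + strut) + phase`` (phase 0 anchored at the
model origin, so commensurate patterns stay registered across region
boundaries).  Slicing a level means intersecting the template's fiber
lines, at the orientation scheduled for that layer, with the region's
voxel mask: runs of covered voxel centers become extrusion segments,
ordered serpentine within each region.  Consecutive layers repeat the same
template for ``strut_layer_count`` layers before rotating 90 degrees,
which stacks fibers into struts whose height matches the pore width
(isotropic cubic pores).

Support material is generated first: every void voxel that has shape
material somewhere above its column is filled with the support label and
sliced with a sparse single-fiber crosshatch so it snaps off after the
print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .design_space import PorePattern
from .shape_model import SUPPORT_LABEL, LabeledVolume

__all__ = [
    "FiberSegment",
    "ToolpathLayer",
    "Template",
    "PatternMap",
    "SliceOptions",
    "build_template",
    "orientation_schedule",
    "slice_layer",
    "generate_support",
    "slice_volume",
]


@dataclass(frozen=True)
class FiberSegment:
    """One extruded line: rectangular fiber of width x height cross-section."""

    start: tuple[float, float]
    end: tuple[float, float]
    z: float  # top of the layer, mm
    width: float  # = nozzle diameter
    height: float  # = layer height
    role: str = "model"  # "model" | "support"
    region: int = 1  # source region label (SUPPORT_LABEL for support)

    @property
    def length(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])

    @property
    def volume(self) -> float:
        """Deposited material volume, mm^3 (rectangular-fiber model)."""
        return self.length * self.width * self.height

    def reversed(self) -> "FiberSegment":
        return replace(self, start=self.end, end=self.start)


@dataclass
class ToolpathLayer:
    """One print level: ordered segments; travel moves are implicit."""

    layer_index: int
    z: float
    segments: list[FiberSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Template:
    """Periodic strut lattice for one pattern and orientation.

    ``orientation`` is the direction fibers run in ('x' or 'y'); the
    lattice therefore lies along the perpendicular axis.  Strut blocks have
    their left edge at ``phase + n * period`` and contain
    ``len(fiber_offsets)`` fiber center lines spaced one nozzle diameter
    apart (fiber-fiber spacing 0), spanning exactly the strut width.
    """

    orientation: str
    period: float
    strut_width: float
    fiber_offsets: tuple[float, ...]
    phase: float = 0.0

    def fiber_positions(self, lo: float, hi: float) -> list[float]:
        """Center-line coordinates of every fiber with a line in [lo, hi)."""
        n0 = int(math.floor((lo - self.phase - self.strut_width) / self.period))
        n1 = int(math.ceil((hi - self.phase) / self.period)) + 1
        out = []
        for n in range(n0, n1):
            left = self.phase + n * self.period
            for off in self.fiber_offsets:
                pos = left + off
                if lo <= pos < hi:
                    out.append(pos)
        return out


def build_template(pattern: PorePattern, orientation: str, phase: float = 0.0) -> Template:
    """Template of fiber center lines for one pattern and orientation."""
    if orientation not in ("x", "y"):
        raise ValueError(f"orientation must be 'x' or 'y', got {orientation!r}")
    w = pattern.nozzle_diameter
    offsets = tuple((i + 0.5) * w for i in range(pattern.strut_fiber_count))
    return Template(
        orientation=orientation,
        period=pattern.in_plane_period,
        strut_width=pattern.strut_width,
        fiber_offsets=offsets,
        phase=phase,
    )


def orientation_schedule(pattern: PorePattern, layer_index: int) -> str:
    """Orientation of a layer: blocks of strut_layer_count layers alternate.

    Layer 0 prints in x by convention; after ``strut_layer_count``
    consecutive layers the direction rotates, so struts reach the height of
    the pore width before crossing.
    """
    if layer_index < 0:
        raise ValueError(f"layer_index must be >= 0, got {layer_index}")
    block = layer_index // pattern.strut_layer_count
    return "x" if block % 2 == 0 else "y"


@dataclass
class PatternMap:
    """Region label -> pore pattern, plus the support pattern."""

    patterns: dict[int, PorePattern]
    support: PorePattern | None = None

    def for_label(self, label: int) -> PorePattern:
        if label == SUPPORT_LABEL:
            if self.support is None:
                raise KeyError("no support pattern configured")
            return self.support
        try:
            return self.patterns[label]
        except KeyError:
            raise KeyError(f"no pore pattern configured for region label {label}") from None

    def validate_for(self, volume: LabeledVolume) -> None:
        missing = [
            lab for lab in volume.region_labels
            if lab != SUPPORT_LABEL and lab not in self.patterns
        ]
        if missing:
            raise ValueError(f"no pore pattern configured for region label(s) {missing}")


@dataclass(frozen=True)
class SliceOptions:
    """Slicing options independent of the printer hardware.

    ``min_fiber_length`` defaults to two nozzle diameters (shorter clips
    blob up instead of forming fibers); ``support_period`` is the lattice
    period of the sparse single-fiber support crosshatch.

    ``phase_mode`` anchors each region's strut lattice either at that
    region's own bounding-box corner (``"region"``, the default: every
    region then presents a strut face at its boundary, which keeps the
    interface backed by material on both sides) or at the global model
    origin (``"global"``: commensurate patterns stay registered across
    boundaries, but a region whose lattice pore lands on the boundary
    leaves an open seam channel along the interface).  Explicit per-region
    phases override either mode.
    """

    min_fiber_length: float | None = None
    support_period: float = 3.0
    phase_mode: str = "region"
    template_phase: float = 0.0
    phase_overrides: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.phase_mode not in ("region", "global"):
            raise ValueError(f"phase_mode must be 'region' or 'global', got {self.phase_mode!r}")

    def phase_for(self, label: int) -> float:
        if self.phase_overrides and label in self.phase_overrides:
            return self.phase_overrides[label]
        return self.template_phase


def _support_pattern(printer, options: SliceOptions) -> PorePattern:
    pore = max(options.support_period - printer.nozzle_diameter, printer.nozzle_diameter)
    return PorePattern(
        pore_size=pore,
        strut_fiber_count=1,
        nozzle_diameter=printer.nozzle_diameter,
        layer_height=printer.layer_height,
    )


def _runs(mask_row: np.ndarray) -> Iterable[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive voxel indices."""
    idx = np.flatnonzero(mask_row)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def slice_layer(
    volume: LabeledVolume,
    pattern_map: PatternMap,
    layer_index: int,
    printer,
    options: SliceOptions = SliceOptions(),
) -> ToolpathLayer:
    """Intersect each region's template with this level's label mask.

    The level's voxel slice is the one containing the layer's mid-height.
    For every region label present: fiber lines at the scheduled
    orientation are realized on the voxel row containing their center line,
    clipped to runs of that region's mask, dropped when shorter than the
    minimum fiber length, and appended in serpentine order.  Regions are
    visited in label order (support first).
    """
    lh = printer.layer_height
    z_top = (layer_index + 1) * lh
    layer = ToolpathLayer(layer_index, z_top)
    k = int(math.floor((z_top - lh / 2 - volume.origin[2]) / volume.pitch))
    if k < 0 or k >= volume.shape[2]:
        return layer
    level = volume.labels[:, :, k]
    min_len = (
        options.min_fiber_length
        if options.min_fiber_length is not None
        else 2.0 * printer.nozzle_diameter
    )
    pitch = volume.pitch
    ox, oy = volume.origin[0], volume.origin[1]

    for label in sorted(np.unique(level)):
        label = int(label)
        if label == 0:
            continue
        pattern = pattern_map.for_label(label)
        role = "support" if label == SUPPORT_LABEL else "model"
        if label == SUPPORT_LABEL:
            orient = "x" if layer_index % 2 == 0 else "y"
        else:
            orient = orientation_schedule(pattern, layer_index)
        if options.phase_overrides and label in options.phase_overrides:
            phase = options.phase_overrides[label]
        elif options.phase_mode == "region" and label != SUPPORT_LABEL:
            # anchor the lattice at the region's own bounding-box corner
            # along the lattice axis (the axis perpendicular to the fibers)
            lat_axis = 1 if orient == "x" else 0
            other = tuple(a for a in range(3) if a != lat_axis)
            occ_lat = np.flatnonzero((volume.labels == label).any(axis=other))
            phase = float(volume.origin[lat_axis] + occ_lat[0] * volume.pitch)
        else:
            phase = options.template_phase
        template = build_template(pattern, orient, phase)
        mask = level == label
        if not mask.any():
            continue

        if orient == "x":
            run_origin, lat_origin = ox, oy
            nlat = mask.shape[1]
            band = lambda j0, j1: mask[:, j0:j1].any(axis=1)
        else:
            run_origin, lat_origin = oy, ox
            nlat = mask.shape[0]
            band = lambda j0, j1: mask[j0:j1, :].any(axis=0)

        half_w = printer.nozzle_diameter / 2.0
        lat_lo = lat_origin - half_w
        lat_hi = lat_origin + nlat * pitch + half_w
        segments: list[FiberSegment] = []
        for f_idx, pos in enumerate(template.fiber_positions(lat_lo, lat_hi)):
            # a fiber is realized wherever its nozzle-width band covers at
            # least one voxel center of this region (straddling fibers at a
            # region edge are kept, crossing by less than one nozzle width)
            j0 = int(math.ceil((pos - half_w - lat_origin) / pitch - 0.5 - 1e-9))
            j1 = int(math.floor((pos + half_w - lat_origin) / pitch - 0.5 + 1e-9)) + 1
            j0, j1 = max(0, j0), min(nlat, j1)
            if j1 <= j0:
                continue
            fiber_segs = []
            for first, last in _runs(band(j0, j1)):
                a = run_origin + first * pitch
                b = run_origin + (last + 1) * pitch
                if b - a < min_len - 1e-9:
                    continue
                if orient == "x":
                    seg = FiberSegment((a, pos), (b, pos), z_top,
                                       printer.nozzle_diameter, lh, role, label)
                else:
                    seg = FiberSegment((pos, a), (pos, b), z_top,
                                       printer.nozzle_diameter, lh, role, label)
                fiber_segs.append(seg)
            if f_idx % 2 == 1:  # serpentine: alternate direction per fiber
                fiber_segs = [s.reversed() for s in reversed(fiber_segs)]
            segments.extend(fiber_segs)
        layer.segments.extend(segments)
    return layer


def generate_support(volume: LabeledVolume, printer=None, options: SliceOptions = SliceOptions()) -> LabeledVolume:
    """Fill every void voxel below shape material with the support label.

    Columns are scanned toward the bed: a void voxel gets support iff some
    occupied voxel lies above it in the same column (this also props
    internal overhangs).  If the volume floats above the bed, the grid is
    extended down to z = 0 and the gap filled under the shape footprint.
    """
    occ = volume.occupied
    labels = volume.labels
    origin = volume.origin.copy()
    pitch = volume.pitch

    n_below = int(round(origin[2] / pitch)) if origin[2] > pitch / 2 else 0
    if n_below:
        pad = np.zeros((*labels.shape[:2], n_below), dtype=labels.dtype)
        labels = np.concatenate([pad, labels], axis=2)
        occ = labels != 0
        origin[2] = origin[2] - n_below * pitch

    above = np.flip(np.maximum.accumulate(np.flip(occ, axis=2), axis=2), axis=2)
    need = above & ~occ
    out = labels.copy()
    out[need] = SUPPORT_LABEL
    return LabeledVolume(out, pitch, origin)


def slice_volume(
    volume: LabeledVolume,
    pattern_map: PatternMap,
    printer,
    options: SliceOptions = SliceOptions(),
    support: bool = True,
) -> list[ToolpathLayer]:
    """Slice every level bottom-up; returns the nonempty layers.

    The voxel pitch must divide the layer height evenly so print levels
    align with voxel slices.
    """
    ratio = printer.layer_height / volume.pitch
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"voxel pitch {volume.pitch} must divide the layer height "
            f"{printer.layer_height} evenly"
        )
    pattern_map.validate_for(volume)
    if pattern_map.support is None:
        pattern_map = PatternMap(pattern_map.patterns, _support_pattern(printer, options))
    vol = generate_support(volume, printer, options) if support else volume

    top = vol.origin[2] + vol.shape[2] * vol.pitch
    n_layers = int(math.ceil(top / printer.layer_height - 1e-9))
    layers = []
    for idx in range(n_layers):
        layer = slice_layer(vol, pattern_map, idx, printer, options)
        if layer.segments:
            layers.append(layer)
    return layers
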
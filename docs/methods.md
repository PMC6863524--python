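# Methods

## Design model

The slicer targets filament-deposition printers that extrude a molten polymer
fiber through a nozzle of diameter `d` (default 0.5 mm) at a layer height `h`
(default 0.2 mm). Fibers are modeled as perfect rectangles of cross-section
`d × h`; no spreading, sagging, or end-cap rounding is modeled. Struts are
`k ≥ 1` adjacent fibers (fiber–fiber spacing 0), so strut width `w = k·d` takes
only discrete values. A pattern stacks the same strut layout for
`round(p / h)` consecutive layers (ties round to more layers, minimum 1) before
rotating 90°, producing a woodpile lattice whose strut height approximates the
pore width `p`. Since the realized pore height `round(p/h)·h` can deviate from
`p` when `p` is not a multiple of `h` (e.g. 0.5 mm pores at 0.2 mm layers build
0.6 mm struts), the pattern object exposes the realized `strut_height`
explicitly.

Design porosity is the void fraction of the repeating unit,
`φ = p / (p + w)`: every strut layer is solid stripes of width `w` per period
`p + w`, so the solid fraction of any layer — and of the unit cell — is
`w / (p + w)` regardless of orientation. The unit-cell rasterization oracle in
the test suite confirms this closed form to machine precision at
grid-commensurate pitches.

## Voxel conventions

Volumes are isotropic voxel grids `labels[i, j, k]` (0 = outside, 1..K = design
regions, −1 = support), with voxel `(i, j, k)` covering the half-open cube
`origin + pitch·[i, i+1) × [j, j+1) × [k, k+1)`. z is the build direction and
z = 0 the print bed. STL voxelization is center-sampling: a voxel belongs to
the shape iff its center lies inside the watertight surface, decided by the
parity of surface crossings along the +z column (duplicate crossings from
shared projected edges are merged). Center sampling keeps porosity arithmetic
unbiased; conservative/overlap voxelization would systematically thicken the
shape. Voxelized shapes are translated so their lowest face sits one voxel
pitch above the bed; support generation fills the gap. The slicing pitch must
divide the layer height evenly (the reference workflow uses 0.1 mm voxels with
0.2 mm layers, and coarse 0.6 mm input volumes are nearest-neighbor resampled
onto the slicing pitch).

## Labeling generators

- **Linear gradient**: the occupied extent along an axis is split into K
  equal-length slabs, labeled 1..K.
- **Depth shells**: Euclidean distance transform of the occupancy (the world
  outside the grid counts as background), binned at user depths; shell 1 is
  outermost. A depth equal to a boundary falls into the outer shell.
- **Thickness classes**: local thickness per voxel is `(2·EDT − 1)·pitch`
  evaluated at the nearest medial maximum of the distance transform (voxels
  whose EDT equals the 3×3×3 neighborhood maximum). On ideal slabs this is
  accurate to one voxel; thresholds bin voxels with the thinnest class labeled
  1 so fragile thin regions can receive denser patterns. Thresholds are user
  parameters.

All generators relabel the occupied set exactly; they never add or remove
voxels.

## Slicing

Each pattern and orientation owns a periodic template: strut blocks with left
edge on the lattice `phase + n·(p + w)`, holding `k` fiber center lines spaced
one nozzle diameter apart. Layer orientation alternates in blocks of
`strut_layer_count` (layer 0 prints in x by convention; support alternates
every layer). A fiber line is realized wherever its nozzle-width band covers at
least one voxel center of its region at that level (the level's voxel slice is
the one containing the layer's mid-height): runs of covered voxels become
segments spanning the runs' outer voxel edges, segments shorter than the
minimum fiber length (default `2·d`, to avoid blobbing) are dropped, and
segments are ordered serpentine within each region, regions in label order.
The band rule means a strut straddling a region edge is kept and may cross the
boundary by up to one nozzle width — which is what keeps interfaces fused.

**Template phase** is anchored per region by default: each region's lattice
starts at its own bounding-box corner along the lattice axis, so every region
presents a strut face at its leading boundary. The alternative global
anchoring (all lattices registered to the model origin) is available via
`SliceOptions(phase_mode="global")`, along with explicit per-region phase
overrides. We default to region anchoring because globally phased lattices can
place a lattice pore directly on a region boundary, leaving an open seam
channel along the entire interface; measured on the six two-region benchmark
scaffolds, region anchoring keeps the interface pore-connectivity in a
moderate band while global phasing drives one design above 50%. Regions with
different pore sizes still desynchronize in z (each follows its own
strut-layer block schedule); the interface analysis quantifies the
consequence.

**Support**: any void voxel with shape material above it in its column is
filled with the support label (this also props internal overhangs), and the
grid is extended down to the bed when the shape floats. Support is sliced as a
single-fiber crosshatch with a 3 mm default period — sparse enough to snap
off; the geometry is this package's choice.

## GCODE

The emitted dialect is a small Marlin subset (G0/G1/G4/G21/G28/G90/G92,
M82/M104/M106/M107/M109/M140/M190), absolute positioning and absolute
extrusion. The E value of a segment follows the rectangular-fiber volume
model: `ΔE = L·d·h·(1 + over) / A_filament` with a 1% over-extrusion default
and 2.85 mm filament. The header heats the bed before the extruder (limits
ooze); the part-cooling fan turns on at the start of the configured layer
(default: after the first layer, at 50%). End-of-fiber anti-stringing options:
dwell (`G4`), backtrack (retrace without extruding), or retract/re-prime pairs
in absolute E. All numeric fields are quantized to 4 decimals *before* the
extrusion arithmetic, which makes `write → parse → write` byte-identical and
lets parsed toolpaths rasterize to exactly the same voxels as the originals —
the round-trip is used as an internal consistency oracle.

## Predicted model and analysis

Rasterization marks solid every voxel whose center falls inside a fiber's
rectangle (length × width in plan, `(z_top − h, z_top]` vertically); overlaps
merge by union, and each solid voxel remembers its source region. The pitch
must divide the layer height and resolve the nozzle (≤ d/2). STL export emits
the exact exposed voxel faces (two triangles each, outward winding) with no
smoothing, so the mesh volume equals the voxel count times pitch³ bit-exactly;
staircase artifacts on curved shapes are accepted, not smoothed.

Porosity is measured as the void fraction within a bounding region (whole
grid, a label's bounding box, or explicit bounds). A gravimetric calculator
(`1 − m_porous/m_solid` for equal volumes, density-normalized otherwise)
covers mass-based laboratory comparisons.

**Interface connectivity**: the boundary between two labels is isolated as a
digital slab of default thickness 0.2 mm — every voxel within half a slab of
the boundary surface, built with chessboard distances so slab layers parallel
the boundary. Pores are face-connected void components of the slab (vertex
connectivity optional); each pore's area is its mean cross-section (component
volume / slab thickness), and the connected area fraction sums all pores over
the boundary area (count of label-to-label voxel faces × pitch²). In an open
woodpile lattice every pore of the slab communicates with both regions'
networks, which is why the total is the headline number; the subset of
components that individually reach the outermost slab layer on *both* sides is
reported separately (`spanning_area_fraction`) as a conservative variant. The
fraction is symmetric in the two labels and translation-invariant.

**Pore/strut measurement** mimics stereoscope image analysis: binarize a
projection of the model (full through-projection by default, or the outermost
slab of a given depth to mimic a surface photograph), take void components
fully enclosed in-plane as pores, and report each as the square root of its
area; strut widths are solid run lengths along both image axes, excluding
border-touching runs. Side views of patterns whose pore size is not a layer
multiple reveal the pore-height deviation (e.g. 0.5 mm pores read
√(0.5·0.6) ≈ 0.55 mm equivalent size from the side).

## Problem sizes and determinism

The reference analyses slice 20 × 20 × 10 mm scaffolds at 0.1 mm voxels
(4·10⁶ voxels, ~2000 segments, about a second per design end-to-end);
convergence checks use period-commensurate boxes at 0.05 mm. The entire
pipeline is deterministic: identical configuration (and seed, for the blob
fixture) yields byte-identical GCODE and voxel-identical models.

## Known limitations

- Only axis-aligned rectangular strut lattices (no 0-45-90 offsets, radial
  rings, curved fibers, or perimeter shells).
- No physics: extrusion spreading, sagging, bridging, and mechanical response
  are out of scope; the predicted model is geometric.
- Region labels are taken per voxel level at the layer mid-height; labels that
  change within one layer height resolve to the mid-slice.
- The benchmark interface fractions depend on the phase convention at region
  boundaries (see above); one of the six benchmark hybrids (0.5 mm/25% against
  0.8 mm/28%) reads ~0.38 because its 2.0 mm-period pattern tiles the 10 mm
  half-width exactly and terminates in a lattice pore at the interface —
  a real seam of that design under region anchoring, not a measurement
  artifact.
- Synthetic fixtures emulate shape complexity (overhangs, curvature, thin
  walls) but not CT-derived anatomy: passing tests demonstrate geometric and
  arithmetic correctness of the pipeline, not clinical suitability of any
  particular scaffold design.
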
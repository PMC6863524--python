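# scafslicer

A voxel-based slicer for fused-deposition (FDM) 3D-printing of tissue-engineering
scaffolds with **spatially patterned, isotropic cubic pore microarchitecture**.

Mainstream slicers (Slic3r, Cura) wrap shapes in solid shells and fill them with
truss infill — useless for scaffolds, which need open, interconnected pore
networks with controlled pore size and porosity. `scafslicer` instead treats the
design as a labeled voxel volume: each region label carries its own pore pattern
(pore size + strut width), and the slicer convolves periodic strut-lattice
toolpath templates with every print level of the shape according to its label.
The same toolpaths are also rasterized into an in-silico *predicted model*, so
porosity, pore geometry, and the pore connectivity across region boundaries can
be verified before any material is extruded.

## The design model

A fiber is a rectangle of nozzle-width × layer-height cross-section. Struts are
built from `k` adjacent fibers (fiber–fiber spacing 0), giving strut width
`w = k·d_nozzle`; repeating the same pattern on consecutive layers stacks fibers
until the strut height matches the pore width, so pores are square in both top
and side projections ("isotropic cubic"). The repeating unit has in-plane period
`p + w` (pore + strut), and every strut layer is solid stripes of width `w` per
period, so the design porosity of a pattern is

```
φ(p, w) = p / (p + w)
```

Porosity and pore size are thereby decoupled: at a 0.5 mm nozzle, a pore size of
0.5 mm offers eight discrete porosities between 11% and 50% (struts 0.5–4.0 mm),
and a single porosity of 28.57% is manufacturable at 0.2, 0.4, 0.6, 0.8 and
1.0 mm pores. The single-fiber ceiling `φ(p, d_nozzle)` runs from 29% (0.2 mm
pores) to 67% (1.0 mm pores) at a 0.5 mm nozzle, and to 74% with a 0.35 mm
nozzle.

Shapes come from watertight STL surfaces (center-sampling voxelization) or the
built-in synthetic fixture generator (boxes, cylinders, spheres, floating
overhangs, seeded anatomic-like blobs). Region labels are assigned by linear
gradients along an axis, by depth shells from the surface (distance transform),
or by local-thickness classes — the three strategies used for anatomic scaffolds
such as zygoma, hemi-mandible, and orbital-floor shapes. Support material is
generated automatically between the bed and any overhang, as a sparse
single-fiber crosshatch that snaps off after printing.

Outputs are Marlin/RepRap GCODE (absolute extrusion, volume-exact E values,
bit-reproducible) and the predicted voxel model (STL export of exact fiber
rectangles, porosity measures, interface-connectivity reports).

## Worked example

Tabulate the 0.5 mm pore design family:

```sh
$ scafslicer design-space --pores 0.5 --max-fibers 8
pore_size_mm  strut_width_mm  fibers  porosity_pct
0.5           0.5             1       50
0.5           1               2       33
0.5           1.5             3       25
0.5           2               4       20
0.5           2.5             5       17
0.5           3               6       14
0.5           3.5             7       13
0.5           4               8       11
```

Slice a 20 × 20 × 10 mm hybrid scaffold, split at the x midplane into a
0.2 mm-pore region and a 0.8 mm-pore region, both at 28% porosity:

```yaml
# run.yaml
shape: {kind: box, dimensions: [20, 20, 10]}
labeling: {mode: linear, axis: x, regions: 2}
patterns:
  1: {pore_size: 0.2, porosity: 0.28}
  2: {pore_size: 0.8, porosity: 0.28}
pitch: 0.1
outputs: {gcode: hybrid.gcode, model: hybrid_model}
```

```sh
$ scafslicer slice --config run.yaml
{
 "layers": 50,
 "segments": 2238,
 "total_filament_mm": 474.491585685083,
 "regions": {
  "1": {"pore_size_mm": 0.2, "strut_width_mm": 0.5,
        "design_porosity": 0.2857, "realized_porosity": 0.28},
  "2": {"pore_size_mm": 0.8, "strut_width_mm": 2.0,
        "design_porosity": 0.2857, "realized_porosity": 0.2586}
 }
}
```

The porosity target 0.28 was inverted onto the discrete fiber lattice (0.5 mm
and 2.0 mm struts); the realized porosities are the void fractions of the
predicted model, slightly under the design values because 20 mm is not an exact
multiple of either pattern's period. Now check that the pores stay connected
across the region boundary:

```sh
$ scafslicer analyze-interface hybrid_model --labels 1 2 --slab 0.2
{
 "label_pair": [1, 2],
 "interface_area_mm2": 200.0,
 "pore_count": 609,
 "connected_area_fraction": 0.1064,
 "spanning_area_fraction": 0.0546
}
```

10.6% of the 200 mm² boundary is open pore space within a 200 µm digital slab
(`spanning_area_fraction` is the conservative subset of pores that individually
reach both sides of the slab). The `hybrid.gcode` file prints directly on a
Marlin printer; `scafslicer preview hybrid_model -o hybrid.stl` exports the
predicted model for inspection.

## Layout

- `src/scafslicer/design_space.py` — pore-pattern math, feasibility, inversion
- `src/scafslicer/shape_model.py` — voxel volumes, STL voxelization, labeling, fixtures
- `src/scafslicer/slicer.py` — templates, layer slicing, serpentine ordering, support
- `src/scafslicer/gcode_io.py` — Marlin GCODE writer/parser, extrusion arithmetic
- `src/scafslicer/model_builder.py` — predicted-model rasterization, porosity, STL export
- `src/scafslicer/analysis.py` — interface connectivity, pore/strut measurement
- `src/scafslicer/pipeline.py`, `cli.py` — run configuration and the `scafslicer` CLI

See `docs/methods.md` for the modeling assumptions, numerical conventions, and
known limitations.
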
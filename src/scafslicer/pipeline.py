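"""End-to-end run configuration and execution.

``run_slice`` wires the full pipeline: build or load the shape, apply the
labeling generator, slice with the per-region pore patterns, emit GCODE,
rasterize the predicted model, and summarize design vs realized porosity.
Identical configuration (and seed, for blob fixtures) produces
byte-identical GCODE.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import shape_model
from .design_space import PorePattern, strut_fibers_for_porosity
from .gcode_io import PrinterConfig, extrusion_length, write_gcode
from .model_builder import design_porosity_of, export_stl, rasterize
from .shape_model import LabeledVolume
from .slicer import PatternMap, SliceOptions, slice_volume

__all__ = ["RunConfig", "run_slice", "pattern_from_spec"]


def pattern_from_spec(spec: dict, printer: PrinterConfig) -> PorePattern:
    """Build a pattern from a config entry.

    Accepts either ``strut_fibers`` directly or a ``porosity`` target that
    is inverted onto the discrete fiber-count lattice.
    """
    pore = float(spec["pore_size"])
    if "strut_fibers" in spec:
        k = int(spec["strut_fibers"])
    elif "porosity" in spec:
        k = strut_fibers_for_porosity(
            pore, float(spec["porosity"]), printer.nozzle_diameter
        ).count
    else:
        raise ValueError(f"pattern spec needs 'strut_fibers' or 'porosity': {spec}")
    return PorePattern(pore, k, printer.nozzle_diameter, printer.layer_height)


@dataclass
class RunConfig:
    """Fully resolved configuration of one slicing run."""

    printer: PrinterConfig = field(default_factory=PrinterConfig)
    shape: dict = field(default_factory=lambda: {"kind": "box", "dimensions": [20, 20, 10]})
    patterns: dict = field(default_factory=dict)  # label -> pattern spec dict
    labeling: dict | None = None
    pitch: float = 0.1
    options: SliceOptions = field(default_factory=SliceOptions)
    outputs: dict = field(default_factory=dict)
    seed: int = 0
    support: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        printer = PrinterConfig.from_dict(d.get("printer", {}))
        opts = d.get("slicing", {})
        options = SliceOptions(
            min_fiber_length=opts.get("min_fiber_length"),
            support_period=opts.get("support_period", 3.0),
            template_phase=opts.get("template_phase", 0.0),
        )
        return cls(
            printer=printer,
            shape=d.get("shape", {"kind": "box", "dimensions": [20, 20, 10]}),
            patterns={int(k): v for k, v in d.get("patterns", {}).items()},
            labeling=d.get("labeling"),
            pitch=float(d.get("pitch", 0.1)),
            options=options,
            outputs=d.get("outputs", {}),
            seed=int(d.get("seed", 0)),
            support=bool(d.get("support", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _build_volume(config: RunConfig) -> LabeledVolume:
    shape = dict(config.shape)
    if "stl" in shape:
        return shape_model.voxelize_mesh(shape["stl"], config.pitch)
    kind = shape.pop("kind")
    dims = shape.pop("dimensions")
    return shape_model.make_fixture(kind, dims, config.pitch, seed=config.seed, **shape)


def _apply_labeling(volume: LabeledVolume, labeling: dict | None) -> LabeledVolume:
    if not labeling:
        return volume
    mode = labeling["mode"]
    if mode == "linear":
        return shape_model.label_linear_gradient(
            volume, labeling.get("axis", "x"), int(labeling["regions"])
        )
    if mode == "shells":
        return shape_model.label_shells(volume, labeling["boundaries"])
    if mode == "thickness":
        return shape_model.label_by_thickness(volume, labeling["thresholds"])
    raise ValueError(f"unknown labeling mode {mode!r}")


def run_slice(config: RunConfig) -> dict:
    """Execute the pipeline; returns a summary dict (also written to disk).

    Summary reports, per region, the design porosity of its pattern and
    the realized porosity of the predicted model within that region's
    bounding box, plus layer count, segment count, total extruded filament
    and wall-clock time.
    """
    t0 = time.perf_counter()
    volume = _apply_labeling(_build_volume(config), config.labeling)

    pattern_map = PatternMap(
        {lab: pattern_from_spec(spec, config.printer) for lab, spec in config.patterns.items()}
    )
    pattern_map.validate_for(volume)

    layers = slice_volume(volume, pattern_map, config.printer, config.options,
                          support=config.support)
    gcode = write_gcode(layers, config.printer)
    model = rasterize(layers, config.pitch, volume=volume)

    per_region = {}
    for label, pattern in pattern_map.patterns.items():
        if label not in volume.region_labels:
            continue
        realized = design_porosity_of(model, label).porosity
        per_region[label] = {
            "pore_size_mm": pattern.pore_size,
            "strut_width_mm": pattern.strut_width,
            "design_porosity": pattern.porosity,
            "realized_porosity": realized,
        }

    total_e = sum(extrusion_length(s, config.printer) for l in layers for s in l.segments)
    summary = {
        "seed": config.seed,
        "layers": len(layers),
        "segments": sum(len(l) for l in layers),
        "total_filament_mm": total_e,
        "regions": per_region,
        "wall_clock_s": time.perf_counter() - t0,
    }

    out = config.outputs
    if out.get("gcode"):
        Path(out["gcode"]).write_text(gcode)
    if out.get("model"):
        model.save(out["model"])
    if out.get("stl"):
        export_stl(model, out["stl"])
    if out.get("report"):
        Path(out["report"]).write_text(json.dumps(summary, indent=1))
    summary["gcode"] = gcode
    summary["model"] = model
    summary["volume"] = volume
    summary["layers_data"] = layers
    return summary
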
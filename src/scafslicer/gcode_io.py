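"""Marlin/RepRap GCODE serialization with exact extrusion arithmetic.

The dialect is deliberately small (G0/G1/G4/G21/G28/G90/G92/M82/M104/M106/
M107/M109/M140/M190) and uses absolute extrusion.  The E value for a fiber
follows from the rectangular-fiber volume model: a segment of length L
deposits ``L x width x height`` mm^3 of material, scaled by the
over-extrusion factor and divided by the filament cross-section.

All coordinates are quantized to 4 decimals *before* any extrusion
arithmetic, so ``write -> parse -> write`` round-trips byte-identically and
parsed toolpaths rasterize to the same voxels as the originals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from .slicer import FiberSegment, ToolpathLayer

__all__ = [
    "PrinterConfig",
    "extrusion_length",
    "write_gcode",
    "parse_gcode",
    "total_extruded",
]

_Q = 4  # decimals in emitted numeric fields


@dataclass(frozen=True)
class PrinterConfig:
    """All machine parameters.

    Defaults correspond to a Lulzbot Taz 5 printing ABS: 0.5 mm nozzle,
    0.2 mm layers, 240 degC extruder / 110 degC bed, 1200 mm/min feed with a
    1% over-extrusion factor, fans at 50% after the first layer; 2.85 mm
    filament.  ``end_of_fiber`` selects the anti-stringing behavior at each
    fiber end: none, pause (dwell), backtrack (retrace without extruding),
    or retract (pull back filament, re-prime before the next fiber).
    """

    nozzle_diameter: float = 0.5
    layer_height: float = 0.2
    extruder_temp: float = 240.0
    bed_temp: float = 110.0
    feed_rate: float = 1200.0
    travel_rate: float = 3000.0
    filament_diameter: float = 2.85
    over_extrusion_factor: float = 0.01
    fan_speed: float = 0.5
    fan_start_layer: int = 1
    end_of_fiber: str = "none"
    retract_amount: float = 1.0
    retract_rate: float = 1800.0
    pause_ms: float = 100.0
    backtrack_distance: float = 0.5

    def __post_init__(self) -> None:
        for name in ("nozzle_diameter", "layer_height", "feed_rate", "travel_rate",
                     "filament_diameter", "extruder_temp", "bed_temp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.over_extrusion_factor < -1:
            raise ValueError("over_extrusion_factor must be >= -1")
        if not 0.0 <= self.fan_speed <= 1.0:
            raise ValueError("fan_speed must be in [0, 1]")
        if self.end_of_fiber not in ("none", "pause", "backtrack", "retract"):
            raise ValueError(f"unknown end_of_fiber mode {self.end_of_fiber!r}")

    @property
    def filament_area(self) -> float:
        return math.pi * (self.filament_diameter / 2.0) ** 2

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PrinterConfig":
        return cls(**d)


def extrusion_length(segment: FiberSegment, config: PrinterConfig) -> float:
    """Filament length (mm) consumed by one fiber segment.

    volume_out = L * width * height * (1 + over_extrusion); the feed length
    is that volume divided by the filament cross-sectional area.
    """
    return _e_for_length(segment.length, segment.width, segment.height, config)


def _e_for_length(length: float, width: float, height: float, config: PrinterConfig) -> float:
    if width <= 0 or height <= 0:
        raise ValueError("fiber width and height must be positive")
    return length * width * height * (1.0 + config.over_extrusion_factor) / config.filament_area


def _f(x: float) -> str:
    return f"{x:.4f}"


def _q(x: float) -> float:
    return round(x, _Q)


def write_gcode(layers: list[ToolpathLayer], config: PrinterConfig) -> str:
    """Serialize toolpath layers to GCODE text.

    Header: units/positioning, home, heat bed then extruder (bed first to
    limit ooze).  Per layer: z move, then per segment a travel move and an
    absolute-E extruding move; the fan turns on at the start of layer
    ``fan_start_layer``.  Numeric fields carry exactly 4 decimals, so the
    output is bit-exact reproducible.
    """
    if any(b.z < a.z for a, b in zip(layers, layers[1:])):
        raise ValueError("layers must be monotone in z")
    if not layers:
        warnings.warn("writing GCODE with no layers: header and footer only")

    lines: list[str] = []
    lines.append("; scafslicer toolpath")
    for key, val in config.as_dict().items():
        lines.append(f"; {key} = {val}")
    lines.append("G21 ; millimeter units")
    lines.append("G90 ; absolute positioning")
    lines.append("M82 ; absolute extrusion")
    lines.append(f"M140 S{_f(config.bed_temp)}")
    lines.append(f"M190 S{_f(config.bed_temp)}")
    lines.append(f"M104 S{_f(config.extruder_temp)}")
    lines.append(f"M109 S{_f(config.extruder_temp)}")
    lines.append("G28 ; home all axes")
    lines.append("G92 E0.0000")

    e = 0.0
    retracted = False
    fan_on = False
    for layer in layers:
        lines.append(f"; layer {layer.layer_index}")
        if (not fan_on and config.fan_speed > 0
                and layer.layer_index >= config.fan_start_layer >= 0):
            lines.append(f"M106 S{int(round(config.fan_speed * 255))}")
            fan_on = True
        lines.append(f"G0 Z{_f(_q(layer.z))} F{config.travel_rate:.0f}")
        for seg in layer.segments:
            x0, y0 = _q(seg.start[0]), _q(seg.start[1])
            x1, y1 = _q(seg.end[0]), _q(seg.end[1])
            lines.append(f"G0 X{_f(x0)} Y{_f(y0)} F{config.travel_rate:.0f}")
            if retracted:
                lines.append(f"G1 E{_f(e)} F{config.retract_rate:.0f}")
                retracted = False
            length = math.hypot(x1 - x0, y1 - y0)
            e += _e_for_length(length, seg.width, seg.height, config)
            lines.append(f"G1 X{_f(x1)} Y{_f(y1)} E{_f(e)} F{config.feed_rate:.0f}")
            if config.end_of_fiber == "pause":
                lines.append(f"G4 P{int(config.pause_ms)}")
            elif config.end_of_fiber == "retract":
                lines.append(f"G1 E{_f(e - config.retract_amount)} F{config.retract_rate:.0f}")
                retracted = True
            elif config.end_of_fiber == "backtrack" and length > 0:
                d = min(config.backtrack_distance, length)
                bx = _q(x1 - (x1 - x0) / length * d)
                by = _q(y1 - (y1 - y0) / length * d)
                lines.append(f"G0 X{_f(bx)} Y{_f(by)} F{config.travel_rate:.0f}")

    lines.append("M107 ; fan off")
    lines.append("M104 S0.0000")
    lines.append("M140 S0.0000")
    lines.append("G28 X Y")
    return "\n".join(lines) + "\n"


_KNOWN = {"G0", "G1", "G4", "G21", "G28", "G90", "G92",
          "M82", "M104", "M106", "M107", "M109", "M140", "M190", "M84"}


def parse_gcode(text: str, config: PrinterConfig) -> list[ToolpathLayer]:
    """Reconstruct toolpath layers from GCODE in the emitted dialect.

    Extruding moves (positive delta-E at constant z) become fiber segments
    with the width/height of the accompanying printer config; travels,
    retract/re-prime pairs, dwells and temperature management are skipped.
    Unknown commands are collected into a warning, not an error.
    """
    x = y = z = e = 0.0
    layers: dict[int, ToolpathLayer] = {}
    unknown: list[str] = []
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        words = line.split()
        cmd = words[0]
        if cmd not in _KNOWN:
            unknown.append(cmd)
            continue
        if cmd not in ("G0", "G1", "G92"):
            continue
        vals = {w[0]: float(w[1:]) for w in words[1:] if w[0] in "XYZEF"}
        if cmd == "G92":
            e = vals.get("E", e)
            x, y, z = vals.get("X", x), vals.get("Y", y), vals.get("Z", z)
            continue
        nx, ny, nz = vals.get("X", x), vals.get("Y", y), vals.get("Z", z)
        ne = vals.get("E", e)
        de = ne - e
        moved = (nx != x) or (ny != y)
        if cmd == "G1" and de > 1e-9 and moved and nz == z:
            idx = int(round(nz / config.layer_height)) - 1
            layer = layers.setdefault(idx, ToolpathLayer(idx, _q(nz)))
            layer.segments.append(
                FiberSegment((x, y), (nx, ny), _q(nz),
                             config.nozzle_diameter, config.layer_height)
            )
        x, y, z, e = nx, ny, nz, ne
    if unknown:
        warnings.warn(f"ignored unknown GCODE commands: {sorted(set(unknown))}")
    return [layers[i] for i in sorted(layers)]


def total_extruded(text: str) -> float:
    """Total filament length consumed, from the file's absolute E values."""
    e_max = 0.0
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line or not line.startswith(("G1", "G0", "G92")):
            continue
        for w in line.split()[1:]:
            if w[0] == "E":
                e_max = max(e_max, float(w[1:]))
    return e_max
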
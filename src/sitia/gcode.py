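"""GCode emission for the laser elimination stage.

Routes are planned in image pixels; the laser controller speaks millimetres.
A :class:`Calibration` maps pixel coordinates to machine coordinates (scale,
offset, optional y-flip — image y grows downward, machine y upward), and
:func:`generate_gcode` emits a grbl-style program: ``G21``/``G90`` preamble,
``G0`` rapid moves, ``M3 S<power>`` / ``G4 P<ms>`` / ``M5`` fire blocks, and
a final ``M5`` plus return home.  The laser is never powered during travel.

Emitted text is byte-stable for fixed inputs, and :func:`parse_gcode` reads
the emitted dialect back losslessly, which makes program round-trips exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from sitia.router import Route, RouteInstance

DEFAULT_LASER_POWER = 255
DEFAULT_DWELL_MS = 500


@dataclass(frozen=True)
class Calibration:
    """Affine pixel->machine map plus the physical plate rectangle (mm)."""

    mm_per_px_x: float = 0.035
    mm_per_px_y: float = 0.035
    offset_x_mm: float = 0.0
    offset_y_mm: float = 0.0
    flip_y: bool = True
    plate_width_mm: float = 140.0
    plate_height_mm: float = 101.0

    def __post_init__(self) -> None:
        if self.mm_per_px_x <= 0 or self.mm_per_px_y <= 0:
            raise ValueError("mm-per-pixel scales must be positive")
        if self.plate_width_mm <= 0 or self.plate_height_mm <= 0:
            raise ValueError("plate dimensions must be positive")

    @property
    def image_width_px(self) -> float:
        return self.plate_width_mm / self.mm_per_px_x

    @property
    def image_height_px(self) -> float:
        return self.plate_height_mm / self.mm_per_px_y

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "Calibration":
        text = Path(source).read_text() if isinstance(source, Path) else source
        return cls(**yaml.safe_load(text))


def pixel_to_machine(
    point: tuple[float, float], cal: Calibration
) -> tuple[float, float]:
    """Map an image-pixel point to machine millimetres (invertible affine)."""
    x_px, y_px = float(point[0]), float(point[1])
    if not (0 <= x_px <= cal.image_width_px and 0 <= y_px <= cal.image_height_px):
        raise ValueError(
            f"pixel point ({x_px}, {y_px}) outside the calibrated image bounds "
            f"({cal.image_width_px:.1f} x {cal.image_height_px:.1f} px)"
        )
    x_mm = x_px * cal.mm_per_px_x + cal.offset_x_mm
    y_img_mm = y_px * cal.mm_per_px_y
    if cal.flip_y:
        y_mm = (cal.plate_height_mm - y_img_mm) + cal.offset_y_mm
    else:
        y_mm = y_img_mm + cal.offset_y_mm
    return x_mm, y_mm


def machine_to_pixel(
    point: tuple[float, float], cal: Calibration
) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_machine`."""
    x_mm, y_mm = float(point[0]), float(point[1])
    x_px = (x_mm - cal.offset_x_mm) / cal.mm_per_px_x
    y_img_mm = (
        cal.plate_height_mm - (y_mm - cal.offset_y_mm)
        if cal.flip_y
        else y_mm - cal.offset_y_mm
    )
    return x_px, y_img_mm / cal.mm_per_px_y


@dataclass(frozen=True)
class GCodeProgram:
    lines: tuple[str, ...]
    target_count: int

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.text, newline="\n")


def _fmt(value: float) -> str:
    return f"{value:.3f}"


def generate_gcode(
    route: Route,
    instance: RouteInstance,
    cal: Calibration,
    laser_power: int = DEFAULT_LASER_POWER,
    dwell_ms: int = DEFAULT_DWELL_MS,
) -> GCodeProgram:
    """Emit a laser program visiting the routed targets in order.

    Every target is mapped to machine coordinates before any line is
    emitted, so an out-of-bounds target aborts with no partial program.
    """
    if not 0 < laser_power <= 255:
        raise ValueError("laser_power must be in 1..255")
    if dwell_ms <= 0:
        raise ValueError("dwell_ms must be positive")
    if sorted(route.order) != list(range(instance.n)):
        raise ValueError("route does not cover the instance's targets")
    machine_pts = [
        pixel_to_machine(instance.targets[i], cal) for i in route.order
    ]
    lines = [
        "; sitia laser program",
        f"; targets: {len(machine_pts)}",
        "G21 ; millimetres",
        "G90 ; absolute coordinates",
        "M5 ; laser off",
    ]
    for x_mm, y_mm in machine_pts:
        lines.append(f"G0 X{_fmt(x_mm)} Y{_fmt(y_mm)}")
        lines.append(f"M3 S{laser_power}")
        lines.append(f"G4 P{dwell_ms}")
        lines.append("M5")
    lines.append("G0 X0.000 Y0.000 ; return home")
    lines.append("M5 ; end, laser off")
    return GCodeProgram(tuple(lines), target_count=len(machine_pts))


def parse_gcode(text: str) -> list[tuple[str, dict[str, float]]]:
    """Parse the emitted dialect into (command, parameters) tuples.

    Comment-only lines are skipped; an unknown command raises with its line
    number.  Lossless for programs produced by :func:`generate_gcode`.
    """
    ops: list[tuple[str, dict[str, float]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        cmd = fields[0]
        if cmd not in ("G21", "G90", "G0", "G4", "M3", "M5"):
            raise ValueError(f"line {lineno}: unknown command {cmd!r}")
        params: dict[str, float] = {}
        for tok in fields[1:]:
            key, value = tok[0], tok[1:]
            if key not in "XYZSPF" or not value:
                raise ValueError(f"line {lineno}: bad parameter {tok!r}")
            params[key] = float(value)
        ops.append((cmd, params))
    return ops


def fire_points_mm(program: GCodeProgram) -> list[tuple[float, float]]:
    """Machine coordinates at which the program fires the laser (in order)."""
    points = []
    pos = (0.0, 0.0)
    for cmd, params in parse_gcode(program.text):
        if cmd == "G0":
            pos = (params.get("X", pos[0]), params.get("Y", pos[1]))
        elif cmd == "M3":
            points.append(pos)
    return points
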
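"""Sheet layout templates.

A :class:`LayoutTemplate` is the registry of everything printed on a test
sheet — target positions with side labels and exclusion flags, bisection
line endpoints, the drawing region, distractor glyphs, and the orientation
fiducial — in canonical pixel coordinates (top-left origin, x rightward,
y downward, half-open rectangles).

The built-in layouts are an original dialect that mimics the geometry class
of the commercial neglect batteries (target grids, three horizontal lines,
star/diamond copy templates) without reproducing any copyrighted sheet.
Because the template carries enough information to re-render the printed
layer exactly, the ink-isolation step can subtract a registered template
render, and the synthetic generator prints from the very same description.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import _draw
from .config import DEFAULT_CONFIG, PipelineConfig

SUBTESTS = (
    "line_crossing",
    "letter_cancellation",
    "star_cancellation",
    "line_bisection",
    "copy_star",
    "copy_diamond",
)

CANCELLATION_SUBTESTS = SUBTESTS[:3]
COPY_SUBTESTS = ("copy_star", "copy_diamond")


@dataclass
class TargetSpec:
    id: str
    x: float
    y: float
    side: str              # 'L', 'M' or 'R'
    excluded: bool = False
    kind: str = "line"     # 'line' | 'letter' | 'star_small'
    size: float = 40.0
    angle: float = 0.0     # printed orientation (degrees), for 'line' kind
    char: str = ""         # for 'letter' kind


@dataclass
class Distractor:
    x: float
    y: float
    kind: str              # 'letter' | 'star_big'
    size: float
    char: str = ""


@dataclass
class BisectionLineSpec:
    label: str             # 'T', 'M' or 'B'
    x_left: float
    y_left: float
    x_right: float
    y_right: float

    @property
    def length(self) -> float:
        return math.hypot(self.x_right - self.x_left, self.y_right - self.y_left)

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.x_left + self.x_right) / 2.0,
                (self.y_left + self.y_right) / 2.0)


@dataclass
class Fiducial:
    kind: str              # 'arrow'
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass
class LayoutTemplate:
    subtest_id: str
    targets: list[TargetSpec] = field(default_factory=list)
    bisection_lines: list[BisectionLineSpec] = field(default_factory=list)
    drawing_region: Optional[tuple[float, float, float, float]] = None
    fiducial: Optional[Fiducial] = None
    distractors: list[Distractor] = field(default_factory=list)
    model_figure: Optional[dict] = None   # printed model for copy subtests

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.subtest_id not in SUBTESTS:
            raise ValueError(f"unknown subtest_id {self.subtest_id!r}")
        ids = [t.id for t in self.targets]
        if len(ids) != len(set(ids)):
            raise ValueError("target ids must be unique")
        for t in self.targets:
            if t.side not in ("L", "M", "R"):
                raise ValueError(f"bad side {t.side!r} for target {t.id}")
        for line in self.bisection_lines:
            if not line.x_left < line.x_right:
                raise ValueError("bisection line must have left.x < right.x")
        n_lines = len(self.bisection_lines)
        if self.subtest_id == "line_bisection" and n_lines != 3:
            raise ValueError("line_bisection template needs exactly 3 lines")
        if self.subtest_id != "line_bisection" and n_lines != 0:
            raise ValueError("only line_bisection templates carry lines")

    # -- convenience ---------------------------------------------------------
    def scoreable_targets(self) -> list[TargetSpec]:
        return [t for t in self.targets if not t.excluded and t.side != "M"]

    @property
    def max_raw_score(self) -> int:
        if self.subtest_id in CANCELLATION_SUBTESTS:
            return len(self.scoreable_targets())
        if self.subtest_id == "line_bisection":
            return 9
        return 1  # copy subtests: BIT-style binary completeness

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        d: dict = {"subtest_id": self.subtest_id}
        d["targets"] = [clean(vars(t)) for t in self.targets]
        d["bisection_lines"] = [clean(vars(l)) for l in self.bisection_lines]
        if self.drawing_region is not None:
            d["drawing_region"] = clean(list(self.drawing_region))
        if self.fiducial is not None:
            d["fiducial"] = clean(vars(self.fiducial))
        d["distractors"] = [clean(vars(x)) for x in self.distractors]
        if self.model_figure is not None:
            d["model_figure"] = clean(dict(self.model_figure))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayoutTemplate":
        return cls(
            subtest_id=d["subtest_id"],
            targets=[TargetSpec(**t) for t in d.get("targets", [])],
            bisection_lines=[BisectionLineSpec(**l)
                             for l in d.get("bisection_lines", [])],
            drawing_region=(tuple(d["drawing_region"])
                            if d.get("drawing_region") else None),
            fiducial=Fiducial(**d["fiducial"]) if d.get("fiducial") else None,
            distractors=[Distractor(**x) for x in d.get("distractors", [])],
            model_figure=d.get("model_figure"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "LayoutTemplate":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# built-in dialect layouts
# ---------------------------------------------------------------------------

def _default_fiducial(config: PipelineConfig) -> Fiducial:
    cx = config.canonical_width / 2.0
    y = config.canonical_height - 100
    return Fiducial(kind="arrow", x0=cx - 60, y0=y - 20, x1=cx + 60, y1=y + 60)


def make_template(subtest_id: str, config: PipelineConfig = DEFAULT_CONFIG,
                  layout_seed: int = 0) -> LayoutTemplate:
    """Build the built-in layout for one subtest.

    ``layout_seed`` fixes the deterministic positional jitter of the printed
    target grids; the same seed always yields the identical template.
    """
    rng = np.random.default_rng(np.random.SeedSequence([layout_seed, 90210]))
    fid = _default_fiducial(config)

    if subtest_id == "line_crossing":
        cols = [260.0, 420.0, 580.0, 820.0, 980.0, 1140.0]
        rows = np.linspace(420.0, 1420.0, 6)
        targets = []
        k = 0
        for y in rows:
            for x in cols:
                jx, jy = rng.uniform(-12, 12, size=2)
                side = "L" if x < 700 else "R"
                targets.append(TargetSpec(
                    id=f"lc{k:02d}", x=x + jx, y=y + jy, side=side,
                    kind="line", size=40.0,
                    angle=float(rng.uniform(-40, 40))))
                k += 1
        for j, y in enumerate((520.0, 780.0, 1040.0, 1300.0)):
            targets.append(TargetSpec(
                id=f"lcm{j}", x=700.0 + float(rng.uniform(-10, 10)), y=y,
                side="M", kind="line", size=40.0,
                angle=float(rng.uniform(-40, 40))))
        return LayoutTemplate(subtest_id, targets=targets, fiducial=fid)

    if subtest_id == "letter_cancellation":
        cols = np.linspace(240.0, 1160.0, 10)
        rows = np.linspace(500.0, 1250.0, 4)
        targets = []
        distractors = []
        k = 0
        for y in rows:
            for x in cols:
                side = "L" if x < 700 else "R"
                targets.append(TargetSpec(
                    id=f"let{k:02d}", x=float(x), y=float(y), side=side,
                    kind="letter", size=26.0, char="E" if k % 2 == 0 else "R"))
                k += 1
        dchars = ["A", "H", "T", "L"]
        for i, y in enumerate(np.linspace(590.0, 1160.0, 3)):
            for j, x in enumerate(np.linspace(290.0, 1110.0, 9)):
                distractors.append(Distractor(
                    x=float(x), y=float(y), kind="letter", size=24.0,
                    char=dchars[(i + j) % 4]))
        return LayoutTemplate(subtest_id, targets=targets,
                              distractors=distractors, fiducial=fid)

    if subtest_id == "star_cancellation":
        cols = [240.0, 371.0, 503.0, 634.0, 766.0, 897.0, 1029.0, 1160.0]
        rows = np.linspace(430.0, 1430.0, 6)
        targets = []
        k = 0
        for y in rows:
            for x in cols:
                jx, jy = rng.uniform(-10, 10, size=2)
                side = "L" if x < 700 else "R"
                targets.append(TargetSpec(
                    id=f"st{k:02d}", x=x + jx, y=y + jy, side=side,
                    kind="star_small", size=13.0))
                k += 1
        # two central example stars, crossed out by the examiner: excluded
        targets.append(TargetSpec(id="stex0", x=664.0, y=905.0, side="M",
                                  excluded=True, kind="star_small", size=13.0))
        targets.append(TargetSpec(id="stex1", x=736.0, y=955.0, side="M",
                                  excluded=True, kind="star_small", size=13.0))
        distractors = []
        for i, y in enumerate(np.linspace(480.0, 1380.0, 5)):
            for x in (305.0, 570.0, 830.0, 1095.0):
                if i % 2 == 0:
                    distractors.append(Distractor(x=x, y=float(y),
                                                  kind="star_big", size=26.0))
                else:
                    distractors.append(Distractor(x=x, y=float(y),
                                                  kind="letter", size=22.0,
                                                  char=["A", "H", "T", "L"][int(x) % 4 % 4]))
        return LayoutTemplate(subtest_id, targets=targets,
                              distractors=distractors, fiducial=fid)

    if subtest_id == "line_bisection":
        lines = [
            BisectionLineSpec("T", 260.0, 700.0, 1060.0, 700.0),
            BisectionLineSpec("M", 320.0, 960.0, 1120.0, 960.0),
            BisectionLineSpec("B", 240.0, 1220.0, 1040.0, 1220.0),
        ]
        return LayoutTemplate(subtest_id, bisection_lines=lines, fiducial=fid)

    if subtest_id in COPY_SUBTESTS:
        region = (200.0, 500.0, 1200.0, 1500.0)
        figure = "star" if subtest_id == "copy_star" else "diamond"
        model = {"figure": figure, "x": 1300.0, "y": 300.0, "size": 70.0}
        return LayoutTemplate(subtest_id, drawing_region=region,
                              fiducial=fid, model_figure=model)

    raise ValueError(f"unknown subtest_id {subtest_id!r}")


def make_template_set(config: PipelineConfig = DEFAULT_CONFIG,
                      layout_seed: int = 0) -> dict[str, LayoutTemplate]:
    return {s: make_template(s, config, layout_seed) for s in SUBTESTS}


# ---------------------------------------------------------------------------
# printed-layer rendering
# ---------------------------------------------------------------------------

def _render_target(img, t: TargetSpec) -> None:
    if t.kind == "line":
        a = math.radians(t.angle)
        dx = math.cos(a) * t.size / 2.0
        dy = math.sin(a) * t.size / 2.0
        _draw.draw_segment(img, (t.x - dx, t.y - dy), (t.x + dx, t.y + dy),
                           width=3.0, intensity=0)
    elif t.kind == "letter":
        for p0, p1 in _draw.glyph_segments(t.char, (t.x, t.y), t.size):
            _draw.draw_segment(img, p0, p1, width=2.5, intensity=0)
    elif t.kind == "star_small":
        verts = _draw.star_vertices((t.x, t.y), t.size)
        _draw.draw_polyline(img, verts, width=2.0, intensity=0, closed=True)
    else:
        raise ValueError(f"unknown target kind {t.kind!r}")


def _render_model_figure(img, model: dict) -> None:
    x, y, size = model["x"], model["y"], model["size"]
    if model["figure"] == "star":
        verts = _draw.star_vertices((x, y), size)
        _draw.draw_polyline(img, verts, width=2.5, intensity=0, closed=True)
    else:
        verts = _draw.diamond_vertices((x, y), size)
        _draw.draw_polyline(img, verts, width=2.5, intensity=0, closed=True)
        _draw.draw_segment(img, verts[0], verts[2], width=2.5, intensity=0)


def render_printed(template: LayoutTemplate,
                   config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Render the blank printed sheet (no patient ink) for a template."""
    img = _draw.blank_page(config.canonical_width, config.canonical_height)
    for t in template.targets:
        _render_target(img, t)
    for d in template.distractors:
        if d.kind == "letter":
            for p0, p1 in _draw.glyph_segments(d.char, (d.x, d.y), d.size):
                _draw.draw_segment(img, p0, p1, width=2.5, intensity=0)
        elif d.kind == "star_big":
            verts = _draw.star_vertices((d.x, d.y), d.size)
            _draw.draw_polyline(img, verts, width=2.0, intensity=0, closed=True)
    for line in template.bisection_lines:
        _draw.draw_segment(img, (line.x_left, line.y_left),
                           (line.x_right, line.y_right), width=3.0, intensity=0)
    if template.model_figure is not None:
        _render_model_figure(img, template.model_figure)
    fid = template.fiducial
    if fid is not None and fid.kind == "arrow":
        cx = (fid.x0 + fid.x1) / 2.0
        # downward-pointing solid arrow marking the bottom of the page
        _draw.draw_filled_triangle(img, (fid.x0 + 20, fid.y0 + 10),
                                   (fid.x1 - 20, fid.y0 + 10),
                                   (cx, fid.y1 - 10), intensity=0)
        _draw.draw_segment(img, (cx, fid.y0), (cx, fid.y0 + 15),
                           width=10.0, intensity=0)
    return img
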
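"""Report assembly, batch orchestration and overlay visualization.

The CSV schema mirrors the per-subtest output tuples: left/right/total/SV
columns for the three cancellation tasks, per-line points+direction cells
for line bisection, the three attribute scores plus NET sum, BIT binary and
SV for each copy figure (with the hierarchical diamond variant), followed
by the weighted BIT-c total with its diagnosis and the NET SV total with
its severity band.  Missing subtests serialize as empty cells, never zeros;
battery totals are computed over the administered subset with the subset
weighting and proportionally rescaled cut-offs.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import battery
from .bisection import BisectionResult
from .bisection import score_sheet as _score_bisection_sheet
from .cancellation import CancellationResult
from .cancellation import score_sheet as _score_cancellation_sheet
from .config import DEFAULT_CONFIG, PipelineConfig
from .copying import CopyScore, score_copy_sheet
from .layout import (CANCELLATION_SUBTESTS, LayoutTemplate, SUBTESTS,
                     make_template)
from .pipeline import (InputError, NoFiducialError, SheetImage, extract_ink,
                       load_and_normalize, run_qc)

PREFIX = {
    "line_crossing": "LineC",
    "letter_cancellation": "LetC",
    "star_cancellation": "StarC",
}

REPORT_COLUMNS = [
    "patient_id",
    "LineC_LS", "LineC_RS", "LineC", "LineC_SV",
    "LetC_LS", "LetC_RS", "LetC", "LetC_SV",
    "StarC_LS", "StarC_RS", "StarC", "StarC_SV",
    "LineB_T", "LineB_M", "LineB_B", "LineB", "LineB_SV",
    "CopyStar_S", "CopyStar_D", "CopyStar_A", "CopyStar_NET",
    "CopyStar", "CopyStar_SV",
    "CopyDiamond_S", "CopyDiamond_D", "CopyDiamond_A", "CopyDiamond_NET",
    "CopyDiamond", "CopyDiamond_SV", "CopyD_NET_hierarchical",
    "BIT_weighted_total", "BIT_diagnosis", "NET_SV_total", "NET_severity",
    "QC",
]


# ---------------------------------------------------------------------------
# per-sheet scoring
# ---------------------------------------------------------------------------

@dataclass
class SheetScore:
    subtest_id: str
    result: object                  # Cancellation/Bisection/CopyScore
    qc_flags: list[str]
    needs_review: bool


def default_sv_tables(templates: dict[str, LayoutTemplate]) -> dict:
    return battery.default_sv_tables(
        {s: t.max_raw_score for s, t in templates.items()
         if s in CANCELLATION_SUBTESTS}
        | {s: t.max_raw_score for s, t in templates.items()
           if s == "line_bisection"}
        | {s: 3 for s, t in templates.items()
           if s in ("copy_star", "copy_diamond")})


def score_sheet_image(sheet: SheetImage, template: LayoutTemplate,
                      sv_tables: dict,
                      config: PipelineConfig = DEFAULT_CONFIG) -> SheetScore:
    """Run ink isolation, QC and the subtest-specific scorer on a
    normalized sheet."""
    ink = extract_ink(sheet, template, config)
    qc = run_qc(sheet, ink, template, config)
    subtest = template.subtest_id
    table = sv_tables[subtest]
    if subtest in CANCELLATION_SUBTESTS:
        result = _score_cancellation_sheet(ink, template, table, config)
        review = bool(qc.flags)
    elif subtest == "line_bisection":
        result = _score_bisection_sheet(ink, template, table, config)
        review = result.needs_review or bool(qc.flags)
    else:
        result = score_copy_sheet(ink, template, table, config)
        review = bool(qc.flags)
    return SheetScore(subtest_id=subtest, result=result,
                      qc_flags=sorted(qc.flags), needs_review=review)


def result_tuple(score: SheetScore) -> tuple:
    """The per-subtest output tuple, in the documented element order."""
    r = score.result
    if isinstance(r, CancellationResult):
        return r.as_tuple()
    if isinstance(r, BisectionResult):
        return r.as_tuple()
    assert isinstance(r, CopyScore)
    base = (r.shape, r.detail, r.arrangement, r.net_sum, r.bit_binary,
            r.standard_value)
    if score.subtest_id == "copy_diamond":
        return base + (r.net_hierarchical,)
    return base


# ---------------------------------------------------------------------------
# row assembly
# ---------------------------------------------------------------------------

def _fmt_sv(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.1f}"


def assemble_row(patient_id: str,
                 scores: dict[str, Optional[SheetScore]],
                 templates: dict[str, LayoutTemplate]) -> dict:
    """One CSV row; unscored subtests stay empty, battery totals are
    computed over the administered subset."""
    row = {c: "" for c in REPORT_COLUMNS}
    row["patient_id"] = patient_id
    raw: dict[str, Optional[float]] = {}
    svs: dict[str, float] = {}
    flags: list[str] = []

    for subtest, score in scores.items():
        if score is None:
            continue
        flags.extend(f"{subtest}:{f}" for f in score.qc_flags)
        r = score.result
        if isinstance(r, CancellationResult):
            p = PREFIX[subtest]
            row[f"{p}_LS"] = str(r.left_count)
            row[f"{p}_RS"] = str(r.right_count)
            row[p] = str(r.total)
            row[f"{p}_SV"] = _fmt_sv(r.standard_value)
            raw[subtest] = r.total
            svs[subtest] = r.standard_value
        elif isinstance(r, BisectionResult):
            if r.needs_review:
                flags.append("line_bisection:needs_review")
                continue
            t, m, b, total, sv = r.as_tuple()
            row["LineB_T"], row["LineB_M"], row["LineB_B"] = t, m, b
            row["LineB"] = str(total)
            row["LineB_SV"] = _fmt_sv(sv)
            raw[subtest] = total
            svs[subtest] = sv
        else:
            assert isinstance(r, CopyScore)
            p = "CopyStar" if subtest == "copy_star" else "CopyDiamond"
            row[f"{p}_S"] = str(r.shape)
            row[f"{p}_D"] = str(r.detail)
            row[f"{p}_A"] = str(r.arrangement)
            row[f"{p}_NET"] = str(r.net_sum)
            row[p] = str(r.bit_binary)
            row[f"{p}_SV"] = _fmt_sv(r.standard_value)
            if subtest == "copy_diamond":
                row["CopyD_NET_hierarchical"] = str(r.net_hierarchical)
            raw[subtest] = r.bit_binary
            svs[subtest] = r.standard_value

    if raw:
        subtests = sorted(raw)
        maxima = [float(templates[s].max_raw_score) for s in subtests]
        weights = battery.subset_weights(maxima, subtests)
        total, _ = battery.weighted_total([raw[s] for s in subtests], weights)
        row["BIT_weighted_total"] = f"{total:.2f}"
        row["BIT_diagnosis"] = battery.bit_diagnosis(
            total, weights.max_weighted_total)
        sv_total = sum(svs.values())
        row["NET_SV_total"] = f"{sv_total:.1f}"
        row["NET_severity"] = battery.net_severity(sv_total,
                                                   10.0 * len(subtests))
    row["QC"] = ";".join(flags)
    return row


def rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=REPORT_COLUMNS).fillna("")


def write_report(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    rows_to_frame(rows).to_csv(path, index=False)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# overlay visualization
# ---------------------------------------------------------------------------

@dataclass
class OverlayStyle:
    """Colors follow the published figure conventions: green = crossed,
    red = not crossed, yellow = excluded; blue/red/yellow side categories
    for line crossing with black/grey midpoints; red archetype over a green
    drawing; red detected bisection point on black template marks."""
    crossed: tuple = (0, 170, 0)
    uncrossed: tuple = (220, 0, 0)
    excluded: tuple = (235, 200, 0)
    side_left: tuple = (0, 80, 230)
    side_right: tuple = (220, 0, 0)
    side_middle: tuple = (235, 200, 0)
    midpoint_crossed: tuple = (128, 128, 128)
    midpoint_uncrossed: tuple = (0, 0, 0)
    archetype: tuple = (220, 0, 0)
    drawing: tuple = (0, 170, 0)
    bisection_template: tuple = (0, 0, 0)
    bisection_detected: tuple = (220, 0, 0)


def render_overlay(sheet: SheetImage, score: SheetScore,
                   template: LayoutTemplate,
                   style: OverlayStyle = OverlayStyle(),
                   config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    from ._draw import draw_disk_rgb, draw_segment_rgb

    img = np.stack([sheet.pixels] * 3, axis=-1).copy()
    r = score.result

    if isinstance(r, CancellationResult):
        by_id = {rec.target_id: rec for rec in r.records}
        for t in template.targets:
            rec = by_id[t.id]
            if template.subtest_id == "line_crossing":
                if rec.crossed:
                    side_color = {"L": style.side_left, "R": style.side_right,
                                  "M": style.side_middle}[t.side]
                    draw_disk_rgb(img, (t.x, t.y), 9, side_color)
                mid = (style.midpoint_crossed if rec.crossed
                       else style.midpoint_uncrossed)
                draw_disk_rgb(img, (t.x, t.y), 4, mid)
            else:
                if t.excluded:
                    color = style.excluded
                elif rec.crossed:
                    color = style.crossed
                else:
                    color = style.uncrossed
                draw_disk_rgb(img, (t.x, t.y), 6, color)

    elif isinstance(r, BisectionResult):
        fr = config.bisect_zone_fractions
        for line, lr in zip(template.bisection_lines, r.lines):
            mx, my = line.midpoint
            for p in ((line.x_left, line.y_left),
                      (line.x_right, line.y_right), (mx, my)):
                draw_disk_rgb(img, p, 5, style.bisection_template)
            for f in fr:
                for s in (-1, 1):
                    x = mx + s * f * line.length / 2.0
                    draw_segment_rgb(img, (x, my - 18), (x, my + 18), 3,
                                     style.bisection_template)
            if lr.mark_x is not None:
                draw_disk_rgb(img, (lr.mark_x, my), 6,
                              style.bisection_detected)

    else:
        assert isinstance(r, CopyScore)
        x0, y0, x1, y1 = template.drawing_region
        region = img[int(y0):int(y1), int(x0):int(x1)]
        ink = region.min(axis=-1) < 128
        region[ink] = style.drawing
        arch = r.diagnostics.get("archetype")
        if arch is not None and not arch.degenerate and arch.vertices:
            verts = arch.vertices
            for i in range(len(verts)):
                draw_segment_rgb(img, verts[i], verts[(i + 1) % len(verts)],
                                 3, style.archetype)
            if arch.midline is not None:
                draw_segment_rgb(img, arch.midline[0], arch.midline[1], 3,
                                 style.archetype)
    return img


# ---------------------------------------------------------------------------
# batch and single-sheet entry points
# ---------------------------------------------------------------------------

def load_templates(template_dir: str | Path,
                   config: PipelineConfig = DEFAULT_CONFIG
                   ) -> dict[str, LayoutTemplate]:
    template_dir = Path(template_dir)
    out = {}
    for subtest in SUBTESTS:
        for ext in (".yaml", ".yml", ".json"):
            p = template_dir / f"{subtest}{ext}"
            if p.exists():
                out[subtest] = LayoutTemplate.load(p)
                break
    return out


def run_single(subtest: str, file: str | Path, template: LayoutTemplate,
               config: PipelineConfig = DEFAULT_CONFIG,
               visualize_to: Optional[str | Path] = None) -> tuple:
    """Score one sheet and return its per-subtest output tuple."""
    if template.subtest_id != subtest:
        raise InputError(f"template is for {template.subtest_id!r}, "
                         f"not {subtest!r}")
    sheet = load_and_normalize(file, template, config)
    sv_tables = default_sv_tables({subtest: template})
    score = score_sheet_image(sheet, template, sv_tables, config)
    if visualize_to is not None:
        from PIL import Image
        Image.fromarray(render_overlay(sheet, score, template,
                                       config=config)).save(visualize_to)
    return result_tuple(score)


def run_batch(input_dir: str | Path,
              templates: dict[str, LayoutTemplate],
              config: PipelineConfig = DEFAULT_CONFIG,
              out_csv: str | Path = "report.csv",
              visualize: bool = False,
              log_path: Optional[str | Path] = None
              ) -> tuple[Path, int, list[dict]]:
    """Score a directory of scans listed in ``manifest.csv``.

    Returns (csv path, exit code, per-sheet log records).  Exit codes:
    0 = clean, 2 = at least one sheet flagged for review, 1 = hard failure
    on every sheet of some patient is *not* a hard failure — individual
    sheet errors mark the row for review and the batch continues; only an
    unreadable manifest aborts.
    """
    input_dir = Path(input_dir)
    manifest = input_dir / "manifest.csv"
    try:
        entries = list(csv.DictReader(manifest.open()))
        if entries and not {"patient_id", "subtest", "file"} <= set(entries[0]):
            raise InputError(f"manifest {manifest} lacks required columns")
    except OSError as exc:
        raise InputError(f"unreadable manifest {manifest}: {exc}") from exc

    sv_tables = default_sv_tables(templates) if templates else {}
    patients: dict[str, dict[str, Optional[SheetScore]]] = {}
    log: list[dict] = []
    flagged = False
    for entry in entries:
        pid, subtest = entry["patient_id"], entry["subtest"]
        path = input_dir / entry["file"]
        rec = {"patient_id": pid, "subtest": subtest, "file": str(path),
               "flags": [], "error": None, "elapsed_s": None}
        t0 = time.perf_counter()
        score: Optional[SheetScore] = None
        try:
            template = templates[subtest]
            sheet = load_and_normalize(path, template, config)
            score = score_sheet_image(sheet, template, sv_tables, config)
            rec["flags"] = score.qc_flags
            if score.needs_review:
                rec["flags"] = sorted(set(rec["flags"]) | {"needs_review"})
                flagged = True
            if visualize:
                from PIL import Image
                out = path.with_suffix(".scored.png")
                Image.fromarray(render_overlay(sheet, score, template,
                                               config=config)).save(out)
        except (InputError, NoFiducialError, KeyError, OSError) as exc:
            rec["error"] = str(exc)
            flagged = True
        rec["elapsed_s"] = round(time.perf_counter() - t0, 3)
        log.append(rec)
        patients.setdefault(pid, {})[subtest] = score

    rows = [assemble_row(pid, scores, templates)
            for pid, scores in patients.items()]
    out = write_report(rows, out_csv)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(log, indent=1))
    return out, (2 if flagged else 0), log
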
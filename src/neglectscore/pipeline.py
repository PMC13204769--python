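"""Scan loading, normalization, ink isolation and quality control.

The pipeline is fully deterministic: byte-identical input files produce
byte-identical normalized images and ink masks, so test–retest agreement of
every downstream score is 100% by construction.

Normalization brings every page into canonical coordinates:

1. coarse orientation from the arrow fiducial (printed at the bottom of the
   page) plus a printed-template registration score over the four cardinal
   rotations — pages scanned upside down or sideways are turned upright;
2. rescaling to the canonical width (aspect preserved, page padded/cropped
   to the canonical height);
3. fine deskew by projection-profile search over small rotations
   (scanner-style affine skew only; no keystone correction).

Ink isolation subtracts a registered render of the printed template from
the binarized page and cleans the residue morphologically, leaving only
patient-added strokes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.transform import resize

from .config import DEFAULT_CONFIG, PipelineConfig
from .layout import LayoutTemplate, render_printed

QC_FLAGS = frozenset({
    "low_contrast", "distorted_print", "excessive_noise",
    "out_of_region_drawing", "multiple_bisection_marks", "no_fiducial",
})


class InputError(Exception):
    """Unreadable or structurally invalid input."""


class NoFiducialError(Exception):
    """The template requires a fiducial that could not be detected."""


@dataclass
class SheetImage:
    """Normalized raster page in canonical coordinates."""
    pixels: np.ndarray                  # uint8, 0 = black ink
    canonical_scale: float              # millimetres per pixel
    source_path: str = "<memory>"
    norm_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise InputError("SheetImage expects a 2-D grayscale grid")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise InputError("empty image")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class InkMask:
    """Patient ink after template subtraction, with extraction diagnostics."""
    mask: np.ndarray                    # bool, same shape as the SheetImage
    threshold: float
    strict_count: int
    loose_count: int
    speck_count: int
    faint_ratio: float

    def __post_init__(self):
        assert self.mask.dtype == bool

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class QCReport:
    flags: set = field(default_factory=set)
    messages: dict = field(default_factory=dict)

    def add(self, flag: str, message: str) -> None:
        if flag not in QC_FLAGS:
            raise ValueError(f"unknown QC flag {flag!r}")
        self.flags.add(flag)
        self.messages[flag] = message

    @property
    def clean(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        return {"flags": sorted(self.flags), "messages": dict(self.messages)}


# ---------------------------------------------------------------------------
# binarization and template masks
# ---------------------------------------------------------------------------

def binarize(gray: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
             ) -> tuple[np.ndarray, float]:
    """Global threshold (Otsu, capped, with manual override) → (mask, thr)."""
    if config.ink_threshold is not None:
        thr = float(config.ink_threshold)
    else:
        lo, hi = int(gray.min()), int(gray.max())
        if hi - lo < 2:
            return np.zeros(gray.shape, dtype=bool), float(lo)
        thr = float(threshold_otsu(gray))
        thr = min(thr, float(config.ink_threshold_cap))
    return gray < thr, thr


_printed_cache: dict[tuple[int, int, int], dict] = {}


def _printed_masks(template: LayoutTemplate, config: PipelineConfig) -> dict:
    """Cached binary masks of the printed layer (core / dilated / coarse)."""
    key = (id(template), config.canonical_width, config.template_dilation_px)
    hit = _printed_cache.get(key)
    if hit is not None:
        return hit
    printed = render_printed(template, config)
    core = printed < 100
    dilated = ndimage.binary_dilation(
        core, structure=disk(config.template_dilation_px))
    coarse_w = config.skew_search_width
    coarse_h = int(round(config.canonical_height * coarse_w / config.canonical_width))
    coarse = resize(core.astype(np.float32), (coarse_h, coarse_w),
                    anti_aliasing=True) > 0.2
    out = {"printed": printed, "core": core, "dilated": dilated, "coarse": coarse}
    if len(_printed_cache) > 32:
        _printed_cache.clear()
    _printed_cache[key] = out
    return out


def registration_score(gray: np.ndarray, template: LayoutTemplate,
                       config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Fraction of printed-template core pixels that are dark on the page."""
    masks = _printed_masks(template, config)
    core = masks["core"]
    if gray.shape != core.shape:
        gray = (resize(gray.astype(np.float32) / 255.0, core.shape,
                       anti_aliasing=True) * 255.0)
    dark = gray < 128
    n = core.sum()
    return float((dark & core).sum() / n) if n else 1.0


# ---------------------------------------------------------------------------
# orientation and skew
# ---------------------------------------------------------------------------

def _coarse(gray: np.ndarray, config: PipelineConfig) -> np.ndarray:
    w = config.skew_search_width
    h = max(int(round(gray.shape[0] * w / gray.shape[1])), 1)
    small = resize(gray.astype(np.float32) / 255.0, (h, w), anti_aliasing=True)
    # thin strokes survive 5x downsampling only as partial darkening, so the
    # coarse binarization threshold sits close to paper white
    return small < 0.85


def _fiducial_density(dark: np.ndarray, template: LayoutTemplate,
                      scale: float) -> float:
    fid = template.fiducial
    if fid is None:
        return 0.0
    x0 = int(fid.x0 * scale)
    x1 = int(math.ceil(fid.x1 * scale))
    y0 = int(fid.y0 * scale)
    y1 = int(math.ceil(fid.y1 * scale))
    box = dark[max(y0, 0):y1, max(x0, 0):x1]
    return float(box.mean()) if box.size else 0.0


def detect_orientation(gray: np.ndarray, template: LayoutTemplate,
                       config: PipelineConfig = DEFAULT_CONFIG) -> int:
    """Number of counter-clockwise quarter turns that set the page upright.

    Uses the fiducial (bottom-of-page arrow) where defined, combined with a
    printed-template registration score over the four cardinal rotations;
    the registration fallback alone covers fiducial-free dialects.
    """
    coarse = _coarse(gray, config)
    masks = _printed_masks(template, config)
    tmpl_coarse = masks["coarse"]
    scale = config.skew_search_width / config.canonical_width
    portrait = gray.shape[0] >= gray.shape[1]
    ks = (0, 2) if portrait else (1, 3)
    best_k, best_score = 0, -1.0
    for k in ks:
        cand = np.rot90(coarse, k)
        if cand.shape != tmpl_coarse.shape:
            cand = resize(cand.astype(np.float32), tmpl_coarse.shape) > 0.4
        n = tmpl_coarse.sum()
        reg = float((cand & tmpl_coarse).sum() / n) if n else 0.0
        fid = _fiducial_density(cand, template, scale)
        score = reg + fid
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def estimate_skew(gray: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG,
                  template: Optional[LayoutTemplate] = None) -> float:
    """Skew of the page content in degrees (positive = counter-clockwise).

    Coarse-to-fine search for the correction that maximizes registration
    with the printed template where one is available (the periodic target
    grids make this sharply unimodal), otherwise the variance of the
    row/column projection profiles.
    """
    coarse = _coarse(gray, config).astype(np.float32)

    if template is not None:
        tmpl = _printed_masks(template, config)["coarse"]
        if coarse.shape != tmpl.shape:
            coarse = resize(coarse, tmpl.shape, anti_aliasing=True)

        def score(correction: float) -> float:
            rot = ndimage.rotate(coarse, -correction, reshape=False, order=1)
            return float(rot[tmpl].mean())
    else:
        def score(correction: float) -> float:
            rot = ndimage.rotate(coarse, -correction, reshape=False, order=1)
            return float(np.var(rot.sum(axis=1)) + np.var(rot.sum(axis=0)))

    lim = config.skew_search_deg
    best = 0.0
    for step, span in ((1.0, lim), (0.2, 1.0), (0.05, 0.2)):
        grid = np.arange(best - span, best + span + step / 2, step)
        grid = grid[np.abs(grid) <= lim + 1e-9]
        best = float(grid[int(np.argmax([score(a) for a in grid]))])
    return best


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_sheet(gray: np.ndarray, template: LayoutTemplate,
                    config: PipelineConfig = DEFAULT_CONFIG,
                    source_path: str = "<memory>") -> SheetImage:
    """Normalize an in-memory grayscale page into canonical coordinates.

    Idempotent up to interpolation: an already-normalized page passes
    through unchanged (no resampling is applied when the size already
    matches and the residual skew is below ``skew_apply_min_deg``).
    """
    if gray.ndim == 3:
        gray = np.clip(
            0.299 * gray[..., 0] + 0.587 * gray[..., 1] + 0.114 * gray[..., 2],
            0, 255).astype(np.uint8)
    if gray.size == 0:
        raise InputError("empty image")
    gray = gray.astype(np.uint8, copy=False)

    k = detect_orientation(gray, template, config)
    if k:
        gray = np.ascontiguousarray(np.rot90(gray, k))

    cw, ch = config.canonical_width, config.canonical_height
    if gray.shape != (ch, cw):
        h = int(round(gray.shape[0] * cw / gray.shape[1]))
        arr = resize(gray.astype(np.float32) / 255.0, (h, cw),
                     anti_aliasing=gray.shape[1] > cw)
        gray = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
        if h < ch:
            gray = np.vstack([gray, np.full((ch - h, cw), 255, np.uint8)])
        elif h > ch:
            gray = gray[:ch]

    skew = estimate_skew(gray, config, template)
    if abs(skew) >= config.skew_apply_min_deg:
        arr = ndimage.rotate(gray.astype(np.float32), -skew, reshape=False,
                             order=1, mode="constant", cval=255.0)
        gray = np.clip(arr, 0, 255).astype(np.uint8)

    dark, _ = binarize(gray, config)
    fid_density = _fiducial_density(dark, template, 1.0)
    info = {"orientation_quarter_turns": k, "skew_deg": skew,
            "fiducial_density": fid_density}
    return SheetImage(pixels=gray, canonical_scale=config.mm_per_px,
                      source_path=source_path, norm_info=info)


def load_and_normalize(path: str | Path, template: LayoutTemplate,
                       config: PipelineConfig = DEFAULT_CONFIG) -> SheetImage:
    """Load a PNG/TIFF/JPEG scan and normalize it (see module docstring)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            gray = np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read raster file {path}: {exc}") from exc
    if gray.size == 0:
        raise InputError(f"zero-size image: {path}")
    sheet = normalize_sheet(gray, template, config, source_path=str(path))
    if template.fiducial is not None and (
            sheet.norm_info["fiducial_density"] < config.fiducial_min_density):
        raise NoFiducialError(
            f"fiducial expected but not detected in {path} "
            f"(density {sheet.norm_info['fiducial_density']:.3f})")
    return sheet


# ---------------------------------------------------------------------------
# ink isolation
# ---------------------------------------------------------------------------

def extract_ink(sheet: SheetImage, template: LayoutTemplate,
                config: PipelineConfig = DEFAULT_CONFIG) -> InkMask:
    """Isolate patient-added strokes by registered-template subtraction.

    Degenerate inputs (blank pages, pure template scans) yield empty masks,
    never failures.  Diagnostics needed by :func:`run_qc` (speck counts and
    the faint-ink ratio) are measured before morphological cleanup.
    """
    gray = sheet.pixels
    strict, thr = binarize(gray, config)
    loose = gray < config.loose_ink_threshold
    dilated = _printed_masks(template, config)["dilated"]

    strict_ink = strict & ~dilated
    loose_ink = loose & ~dilated

    labels, n = ndimage.label(strict_ink)
    speck_count = 0
    cleaned = strict_ink
    if n:
        sizes = np.bincount(labels.ravel())[1:]
        speck_count = int((sizes <= config.speck_max_px).sum())
        keep = np.flatnonzero(sizes >= config.min_component_px) + 1
        cleaned = np.isin(labels, keep)

    strict_count = int(strict_ink.sum())
    loose_count = int(loose_ink.sum())
    faint = (loose_count - strict_count) / loose_count if loose_count else 0.0
    return InkMask(mask=cleaned, threshold=thr, strict_count=strict_count,
                   loose_count=loose_count, speck_count=speck_count,
                   faint_ratio=float(faint))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def run_qc(sheet: SheetImage, ink: InkMask, template: LayoutTemplate,
           config: PipelineConfig = DEFAULT_CONFIG) -> QCReport:
    """Deterministic per-sheet quality flags; an empty set means clean."""
    report = QCReport()

    if (ink.faint_ratio > config.low_contrast_faint_ratio
            and ink.loose_count >= config.low_contrast_min_px):
        report.add("low_contrast",
                   f"{ink.faint_ratio:.0%} of candidate ink lies above the "
                   f"grayscale contrast threshold ({ink.threshold:.0f})")

    density = ink.speck_count / sheet.pixels.size
    if density > config.noise_density_threshold:
        report.add("excessive_noise",
                   f"salt-and-pepper speck density {density:.2e} exceeds "
                   f"{config.noise_density_threshold:.2e}")

    reg = registration_score(sheet.pixels, template, config)
    if reg < config.registration_min_score:
        report.add("distorted_print",
                   f"printed-template registration {reg:.2f} below "
                   f"{config.registration_min_score:.2f}")

    if template.drawing_region is not None:
        x0, y0, x1, y1 = template.drawing_region
        m = config.out_of_region_margin_px
        outside = ink.mask.copy()
        ya, yb = max(int(y0 - m), 0), min(int(y1 + m), outside.shape[0])
        xa, xb = max(int(x0 - m), 0), min(int(x1 + m), outside.shape[1])
        outside[ya:yb, xa:xb] = False
        if template.model_figure is not None:
            mf = template.model_figure
            s = mf["size"] * 1.8
            outside[max(int(mf["y"] - s), 0):int(mf["y"] + s),
                    max(int(mf["x"] - s), 0):int(mf["x"] + s)] = False
        n_out = int(outside.sum())
        if n_out > config.out_of_region_min_px:
            report.add("out_of_region_drawing",
                       f"{n_out} ink px beyond the drawing region margin")

    if template.subtest_id == "line_bisection":
        from .bisection import find_mark_clusters
        multi = [line.label for line in template.bisection_lines
                 if len(find_mark_clusters(ink, line, config)) >= 2]
        if multi:
            report.add("multiple_bisection_marks",
                       f"multiple midpoint marks on line(s) {','.join(multi)}")

    if template.fiducial is not None:
        dens = sheet.norm_info.get("fiducial_density")
        if dens is None:
            dark, _ = binarize(sheet.pixels, config)
            dens = _fiducial_density(dark, template, 1.0)
        if dens < config.fiducial_min_density:
            report.add("no_fiducial",
                       f"fiducial density {dens:.3f} below "
                       f"{config.fiducial_min_density}")

    return report
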
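"""Deterministic raster primitives for synthetic sheets and overlays.

Strokes are rendered by exact point-to-segment distance within a local
bounding box, with a 1 px linear anti-aliasing ramp.  Everything operates
in-place on uint8 grayscale pages (255 = paper white, 0 = black ink) or on
(H, W, 3) uint8 RGB overlays.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "blank_page",
    "draw_segment",
    "draw_polyline",
    "draw_disk",
    "draw_filled_triangle",
    "star_vertices",
    "diamond_vertices",
    "glyph_segments",
    "draw_segment_rgb",
    "draw_disk_rgb",
]


def blank_page(width: int, height: int) -> np.ndarray:
    return np.full((height, width), 255, dtype=np.uint8)


def _segment_distance_field(p0, p1, width: int, height: int, radius: float):
    """Distance to segment p0-p1 on a clipped bounding-box grid.

    Returns (ys slice, xs slice, distance array) or None if off-page.
    """
    x0, y0 = p0
    x1, y1 = p1
    pad = radius + 2.0
    xa = max(int(math.floor(min(x0, x1) - pad)), 0)
    xb = min(int(math.ceil(max(x0, x1) + pad)) + 1, width)
    ya = max(int(math.floor(min(y0, y1) - pad)), 0)
    yb = min(int(math.ceil(max(y0, y1) + pad)) + 1, height)
    if xa >= xb or ya >= yb:
        return None
    ys, xs = np.mgrid[ya:yb, xa:xb]
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        dist = np.hypot(xs - x0, ys - y0)
    else:
        t = ((xs - x0) * dx + (ys - y0) * dy) / seg2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xs - (x0 + t * dx), ys - (y0 + t * dy))
    return slice(ya, yb), slice(xa, xb), dist


def draw_segment(img: np.ndarray, p0, p1, width: float = 3.0,
                 intensity: int = 20) -> None:
    """Draw an anti-aliased stroke segment onto a grayscale page (in place)."""
    h, w = img.shape
    half = width / 2.0
    out = _segment_distance_field(p0, p1, w, h, half + 1.0)
    if out is None:
        return
    sy, sx, dist = out
    # coverage: 1 inside the stroke core, linear ramp over the last pixel
    cov = np.clip(half + 0.5 - dist, 0.0, 1.0)
    patch = img[sy, sx].astype(np.float64)
    val = cov * intensity + (1.0 - cov) * patch
    img[sy, sx] = np.minimum(patch, val).astype(np.uint8)


def draw_polyline(img: np.ndarray, points, width: float = 3.0,
                  intensity: int = 20, closed: bool = False) -> None:
    pts = list(points)
    if closed and len(pts) > 2:
        pts = pts + [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        draw_segment(img, a, b, width=width, intensity=intensity)


def draw_disk(img: np.ndarray, center, radius: float, intensity: int = 20) -> None:
    h, w = img.shape
    out = _segment_distance_field(center, center, w, h, radius + 1.0)
    if out is None:
        return
    sy, sx, dist = out
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = img[sy, sx].astype(np.float64)
    val = cov * intensity + (1.0 - cov) * patch
    img[sy, sx] = np.minimum(patch, val).astype(np.uint8)


def draw_filled_triangle(img: np.ndarray, p0, p1, p2, intensity: int = 20) -> None:
    """Solid triangle via half-plane tests (used for the arrow fiducial)."""
    h, w = img.shape
    xs_all = [p[0] for p in (p0, p1, p2)]
    ys_all = [p[1] for p in (p0, p1, p2)]
    xa = max(int(math.floor(min(xs_all))), 0)
    xb = min(int(math.ceil(max(xs_all))) + 1, w)
    ya = max(int(math.floor(min(ys_all))), 0)
    yb = min(int(math.ceil(max(ys_all))) + 1, h)
    if xa >= xb or ya >= yb:
        return
    ys, xs = np.mgrid[ya:yb, xa:xb]

    def edge(a, b):
        return (xs - a[0]) * (b[1] - a[1]) - (ys - a[1]) * (b[0] - a[0])

    e0, e1, e2 = edge(p0, p1), edge(p1, p2), edge(p2, p0)
    inside = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | ((e0 <= 0) & (e1 <= 0) & (e2 <= 0))
    patch = img[ya:yb, xa:xb]
    patch[inside] = np.minimum(patch[inside], intensity)


# ---------------------------------------------------------------------------
# figure geometry
# ---------------------------------------------------------------------------

def star_inner_ratio(tip_angle_deg: float, inner_offset_deg: float = 45.0
                     ) -> float:
    """Inner/outer radius ratio of a symmetric star whose tips open at
    ``tip_angle_deg``, with inner vertices ``inner_offset_deg`` away.

    With the outer tip on the x-axis at radius 1 and inner vertices at
    ±o, the half tip angle a satisfies tan(a) = r·sin o / (1 − r·cos o).
    The ratio must stay below 1 (a 4-pointed star cannot open wider than
    135° at the tips); wider requests raise ValueError.
    """
    a = math.radians(tip_angle_deg / 2.0)
    t = math.tan(a)
    c = math.cos(math.radians(inner_offset_deg))
    s = math.sin(math.radians(inner_offset_deg))
    ratio = t / (s + t * c)
    if not 0.0 < ratio < 1.0:
        raise ValueError(
            f"tip angle {tip_angle_deg}° is not constructible with inner "
            f"vertices at ±{inner_offset_deg}° (ratio {ratio:.2f})")
    return ratio


def star_vertices(center, outer_radius: float, tip_angle_deg: float = 110.0,
                  n_tips: int = 4, rotation_deg: float = 0.0):
    """Ordered outline vertices of an n-tipped star (outer/inner alternating).

    The first vertex is the "up" tip (negative image-y direction).
    """
    cx, cy = center
    r = outer_radius * star_inner_ratio(tip_angle_deg, 180.0 / n_tips)
    verts = []
    step = 360.0 / n_tips
    for i in range(n_tips):
        ang_o = math.radians(90.0 + rotation_deg + i * step)
        ang_i = math.radians(90.0 + rotation_deg + (i + 0.5) * step)
        verts.append((cx + outer_radius * math.cos(ang_o),
                      cy - outer_radius * math.sin(ang_o)))
        verts.append((cx + r * math.cos(ang_i), cy - r * math.sin(ang_i)))
    return verts


def diamond_vertices(center, half_width: float,
                     top_angle_delta_deg: float = 0.0,
                     bottom_angle_delta_deg: float = 0.0):
    """Diamond corners (top, right, bottom, left).

    The angles between the vertical midline and the two edges meeting at the
    top corner equal ``45° + top_angle_delta_deg`` exactly (likewise at the
    bottom), which makes parametric angle sweeps sharp.
    """
    cx, cy = center
    vt = half_width / math.tan(math.radians(45.0 + top_angle_delta_deg))
    vb = half_width / math.tan(math.radians(45.0 + bottom_angle_delta_deg))
    return [(cx, cy - vt), (cx + half_width, cy), (cx, cy + vb),
            (cx - half_width, cy)]


def diamond_vertices_from_angles(center, half_height: float,
                                 angles_deg) -> list:
    """Diamond corners (top, right, bottom, left) realizing four prescribed
    midline-to-edge angles (top-left, top-right, bottom-left, bottom-right).

    The midline stays vertical; the left/right corners shift to meet the
    requested angles exactly.
    """
    cx, cy = center
    a_tl, a_tr, a_bl, a_br = (math.radians(a) for a in angles_deg)
    v = half_height

    def side(a_top, a_bot):
        y = (v * math.tan(a_bot) - v * math.tan(a_top)) / (
            math.tan(a_top) + math.tan(a_bot))
        h = (v + y) * math.tan(a_top)
        return h, y

    hl, yl = side(a_tl, a_bl)
    hr, yr = side(a_tr, a_br)
    return [(cx, cy - v), (cx + hr, cy + yr), (cx, cy + v), (cx - hl, cy + yl)]


# ---------------------------------------------------------------------------
# printed glyphs (block-letter strokes on a unit box, y down)
# ---------------------------------------------------------------------------

_GLYPHS = {
    "E": [((0, 0), (0, 1)), ((0, 0), (0.8, 0)), ((0, 0.5), (0.65, 0.5)),
          ((0, 1), (0.8, 1))],
    "R": [((0, 0), (0, 1)), ((0, 0), (0.7, 0)), ((0.7, 0), (0.7, 0.5)),
          ((0.7, 0.5), (0, 0.5)), ((0.25, 0.5), (0.8, 1))],
    "A": [((0, 1), (0.4, 0)), ((0.4, 0), (0.8, 1)), ((0.18, 0.62), (0.62, 0.62))],
    "H": [((0, 0), (0, 1)), ((0.8, 0), (0.8, 1)), ((0, 0.5), (0.8, 0.5))],
    "T": [((0, 0), (0.8, 0)), ((0.4, 0), (0.4, 1))],
    "L": [((0, 0), (0, 1)), ((0, 1), (0.8, 1))],
}


def glyph_segments(letter: str, center, size: float):
    """Stroke segments of a block letter centred at ``center``."""
    segs = _GLYPHS[letter]
    cx, cy = center
    out = []
    for (x0, y0), (x1, y1) in segs:
        out.append(((cx + (x0 - 0.4) * size, cy + (y0 - 0.5) * size),
                    (cx + (x1 - 0.4) * size, cy + (y1 - 0.5) * size)))
    return out


# ---------------------------------------------------------------------------
# RGB overlay primitives
# ---------------------------------------------------------------------------

def draw_disk_rgb(img: np.ndarray, center, radius: float, color) -> None:
    h, w = img.shape[:2]
    out = _segment_distance_field(center, center, w, h, radius + 1.0)
    if out is None:
        return
    sy, sx, dist = out
    mask = dist <= radius
    img[sy, sx][mask] = color


def draw_segment_rgb(img: np.ndarray, p0, p1, width: float, color) -> None:
    h, w = img.shape[:2]
    out = _segment_distance_field(p0, p1, w, h, width / 2.0 + 1.0)
    if out is None:
        return
    sy, sx, dist = out
    mask = dist <= width / 2.0
    img[sy, sx][mask] = color
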
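"""Pipeline configuration.

All geometric thresholds are expressed in *canonical pixels*: every scanned
page is rescaled so that its width equals ``canonical_width`` before any
measurement is taken.  The printed thresholds of the copy-scoring criteria
(100 / 200 px) presume a working resolution in which the figure-copy drawing
region is roughly 1000 px wide; the defaults below realise exactly that
geometry.  Everything is overridable from a YAML/JSON mapping via
:meth:`PipelineConfig.from_dict`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    # --- canonical geometry -------------------------------------------------
    #: width every page is rescaled to before measurement (px)
    canonical_width: int = 1400
    #: page height at canonical width (ISO A-series aspect, 1:sqrt(2))
    canonical_height: int = 1980
    #: physical scale after normalization (210 mm A4 width / 1400 px)
    mm_per_px: float = 0.15

    # --- binarization / ink isolation --------------------------------------
    #: manual global threshold; ``None`` selects Otsu's method
    ink_threshold: Optional[int] = None
    #: upper cap on the automatic threshold: intensities above this are never
    #: accepted as reliable ink (they fall in the "faint" band instead)
    ink_threshold_cap: int = 180
    #: anything darker than this counts as "loose" (possibly faint) ink
    loose_ink_threshold: int = 245
    #: dilation radius applied to the printed-template mask before subtraction
    template_dilation_px: int = 3
    #: residual foreground allowed on a blank printed template (px)
    noise_floor_px: int = 120
    #: connected components smaller than this are removed as noise (px)
    min_component_px: int = 12

    # --- quality control -----------------------------------------------------
    #: low_contrast when faint ink / all ink exceeds this ratio
    low_contrast_faint_ratio: float = 0.6
    #: ...and at least this much loose ink exists (px)
    low_contrast_min_px: int = 200
    #: maximum size of an isolated speck counted as salt-and-pepper noise (px)
    speck_max_px: int = 4
    #: excessive_noise when specks per page pixel exceed this density
    noise_density_threshold: float = 1e-4
    #: distorted_print when printed-template registration drops below this
    registration_min_score: float = 0.55
    #: margin (px) around the drawing region before out_of_region triggers
    out_of_region_margin_px: int = 20
    #: ink outside the (margined) drawing region needed to flag (px)
    out_of_region_min_px: int = 150
    #: minimum dark fraction in the fiducial box to accept the fiducial
    fiducial_min_density: float = 0.15

    # --- skew / orientation --------------------------------------------------
    #: half-range of the deskew search (degrees)
    skew_search_deg: float = 6.0
    #: rotations smaller than this are not applied (keeps normalization a
    #: fixed point on already-normalized pages)
    skew_apply_min_deg: float = 0.1
    #: width of the downsampled image used for skew/orientation search
    skew_search_width: int = 280

    # --- cancellation scoring ------------------------------------------------
    #: half-width of the axis-aligned detection window around a target (px)
    cancel_window_half_px: int = 25
    #: patient-ink fraction of the window at or above which a target counts
    #: as crossed (calibrated on the synthetic fixtures)
    cancel_ink_fraction: float = 0.003

    # --- bisection scoring ---------------------------------------------------
    #: half-height of the band around each printed line searched for marks
    bisect_band_half_px: int = 15
    #: ink clusters closer than this along x are merged into one mark (px)
    bisect_cluster_gap_px: int = 40
    #: zone bands as fractions of the half-line length: 3 pts within the
    #: first, 2 within the second, 1 within the third, else 0 (dialect
    #: choice; the commercial scoring-template widths are not public)
    bisect_zone_fractions: tuple[float, float, float] = (0.10, 0.25, 0.50)

    # --- copy scoring ---------------------------------------------------------
    #: half-width of the ink corridor used for edge-presence checks (px)
    copy_corridor_half_px: int = 7
    #: minimum fraction of an edge's length covered by ink
    copy_edge_min_coverage: float = 0.75
    #: largest tolerated uncovered run along an edge (closure tolerance, px)
    copy_max_gap_px: int = 14
    #: angular resolution of the radial outline profile (bins over 360°)
    copy_radial_bins: int = 360
    #: peak prominence for corner detection, as a fraction of the max radius
    copy_peak_prominence: float = 0.08
    #: minimum angular separation between detected corners (degrees)
    copy_peak_separation_deg: float = 15.0
    #: capture window around diamond corners for the midline endpoints (px)
    midline_endpoint_tol_px: int = 25
    #: largest tolerated gap along the midline corridor (px)
    midline_max_gap_px: int = 25
    #: half-width of the midline corridor (px)
    midline_corridor_half_px: int = 9
    #: minimum covered fraction of the midline corridor
    midline_min_coverage: float = 0.6

    # --- star criteria (printed values, canonical px / degrees) --------------
    star_max_radial_deviation: float = 100.0
    star_required_corners: int = 8
    star_span_difference_max: float = 200.0
    star_tip_misalignment_max: float = 200.0
    star_intermediate_distance_deviation_max: float = 100.0
    star_angle_deviation_max: float = 40.0
    star_angle_deviation_strict: float = 30.0
    star_expected_angle: float = 110.0
    star_min_angles_within_strict: int = 2

    # --- diamond criteria ------------------------------------------------------
    diamond_expected_half_angle: float = 45.0
    diamond_angle_tolerance: float = 7.0
    diamond_max_violations_allowed: int = 1

    def copy_with(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bisect_zone_fractions" in data:
            data = dict(data)
            data["bisect_zone_fractions"] = tuple(data["bisect_zone_fractions"])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bisect_zone_fractions"] = list(d["bisect_zone_fractions"])
        return d


DEFAULT_CONFIG = PipelineConfig()
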
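"""Diffraction-limited spot detection and molecules-per-imaging-area counts.

Spots are local maxima of an average projection of the first few frames
(detected before most photobleaching), thresholded at a robust multiple of
the background noise and refined to subpixel positions by intensity-weighted
centroid. Counts are summarized per imaging area (5000 um^2 by convention)
with the mean and n-1 standard deviation across replicate areas, and
compared against a control pull-down for specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .simulator import ImageStack, DEFAULT_IMAGING_AREA_UM2

__all__ = [
    "Spot",
    "FieldQuantification",
    "EnrichmentReport",
    "detect_spots",
    "quantify_fields",
    "compare_to_control",
    "normalize_by_dilution",
    "spots_to_frame",
    "spots_from_frame",
]


@dataclass(frozen=True)
class Spot:
    """One detected diffraction-limited molecule.

    ``x_px`` is the column coordinate, ``y_px`` the row coordinate; integer
    values are pixel centers.
    """

    x_px: float
    y_px: float
    intensity: float          # integrated, background-subtracted photons
    peak_intensity: float     # projection peak above background
    channel: str = "A"
    field: int = 0


@dataclass(frozen=True)
class FieldQuantification:
    """Spot counts per imaging area across replicate fields of view."""

    counts: tuple[float, ...]
    mean: float
    sd: float                  # n-1 denominator; NaN for a single area
    n_areas: int
    channel: str = "A"
    area_um2: float = DEFAULT_IMAGING_AREA_UM2

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n_areas)


@dataclass(frozen=True)
class EnrichmentReport:
    """Specific vs control (e.g. anti-HA) pull-down comparison."""

    ratio: float
    passes_specificity: bool
    threshold: float
    control_floored: bool


class SaturatedStackError(ValueError):
    """Every pixel of the projection is at one ceiling value (overload)."""


def detect_spots(stack: ImageStack,
                 projection_frames: int = 10,
                 threshold_factor: float = 5.0,
                 min_separation_px: int = 2,
                 field: int = 0) -> list[Spot]:
    """Detect spots on the average projection of the first frames.

    Background is estimated as the median of the projection and its noise as
    1.4826 x MAD (robust to the spots themselves). Local maxima exceeding
    background + ``threshold_factor`` x noise are kept; maxima closer than
    ``min_separation_px`` collapse to the brighter one. Positions are refined
    by intensity-weighted centroid in a 5x5 window.
    """
    if stack.n_frames == 0:
        raise ValueError("empty image stack")
    if stack.n_frames < projection_frames:
        raise ValueError(
            f"stack has {stack.n_frames} frames < projection_frames={projection_frames}")
    proj = stack.frames[:projection_frames].mean(axis=0)

    bg = float(np.median(proj))
    noise = float(1.4826 * np.median(np.abs(proj - bg)))
    if noise == 0.0 and np.all(proj == proj.max()) and bg > 0:
        raise SaturatedStackError("projection is uniformly saturated")

    threshold = bg + max(threshold_factor * noise, 1e-9)
    peaks = peak_local_max(proj, min_distance=1, threshold_abs=threshold,
                           exclude_border=False)
    # merge maxima closer than min_separation_px (Euclidean) to the brighter
    if len(peaks) > 1 and min_separation_px > 1:
        from scipy.spatial import cKDTree
        order = np.argsort(-proj[peaks[:, 0], peaks[:, 1]], kind="stable")
        pts = peaks[order]
        pairs = cKDTree(pts.astype(float)).query_pairs(
            min_separation_px - 1e-9, output_type="ndarray")
        suppressed = np.zeros(len(pts), dtype=bool)
        for i, j in pairs[np.argsort(pairs[:, 0], kind="stable")]:
            if not suppressed[i]:
                suppressed[j] = True
        peaks = pts[~suppressed]

    h, w = proj.shape
    corrected = proj - bg
    spots: list[Spot] = []
    for r, c in peaks:
        y0, y1 = max(0, r - 2), min(h, r + 3)
        x0, x1 = max(0, c - 2), min(w, c + 3)
        win = np.clip(corrected[y0:y1, x0:x1], 0.0, None)
        total = float(win.sum())
        if total <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        spots.append(Spot(
            x_px=float((win * xx).sum() / total),
            y_px=float((win * yy).sum() / total),
            intensity=total * projection_frames,  # photons over the window
            peak_intensity=float(corrected[r, c]),
            channel=stack.channel,
            field=field,
        ))
    return spots


def quantify_fields(spots_per_field: Sequence[Sequence[Spot]],
                    field_area_um2: float,
                    target_area_um2: float = DEFAULT_IMAGING_AREA_UM2,
                    channel: str | None = None) -> FieldQuantification:
    """Counts per imaging area across fields; rescaled if a field's area
    differs from the reporting convention (5000 um^2)."""
    if len(spots_per_field) < 1:
        raise ValueError("at least one field required")
    if field_area_um2 <= 0:
        raise ValueError("field_area_um2 must be positive")
    scale = target_area_um2 / field_area_um2
    counts = tuple(len(s) * scale for s in spots_per_field)
    arr = np.array(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    if channel is None:
        first = next((sp for field in spots_per_field for sp in field), None)
        channel = first.channel if first else "A"
    return FieldQuantification(counts=counts, mean=float(arr.mean()), sd=sd,
                               n_areas=len(counts), channel=channel,
                               area_um2=target_area_um2)


def compare_to_control(sample: FieldQuantification,
                       control: FieldQuantification,
                       threshold: float = 5.0,
                       epsilon: float = 1e-9) -> EnrichmentReport:
    """Specific-pull-down enrichment over a control antibody pull-down."""
    floored = control.mean < epsilon
    ratio = sample.mean / max(control.mean, epsilon)
    return EnrichmentReport(ratio=float(ratio),
                            passes_specificity=bool(ratio >= threshold),
                            threshold=threshold, control_floored=floored)


def normalize_by_dilution(quant: FieldQuantification,
                          dilution_factor: float) -> FieldQuantification:
    """Scale counts back to undiluted-lysate equivalents so differently
    diluted samples are comparable (counts, mean and s.d. all scale)."""
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    return replace(
        quant,
        counts=tuple(c * dilution_factor for c in quant.counts),
        mean=quant.mean * dilution_factor,
        sd=quant.sd * dilution_factor,
    )


def spots_to_frame(spots: Sequence[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"field": s.field, "channel": s.channel, "x_px": s.x_px,
          "y_px": s.y_px, "intensity": s.intensity,
          "peak_intensity": s.peak_intensity} for s in spots],
        columns=["field", "channel", "x_px", "y_px", "intensity", "peak_intensity"],
    )


def spots_from_frame(df: pd.DataFrame) -> list[Spot]:
    return [Spot(x_px=float(r.x_px), y_px=float(r.y_px),
                 intensity=float(r.intensity),
                 peak_intensity=float(r.peak_intensity),
                 channel=str(r.channel), field=int(r.field))
            for r in df.itertuples()]
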
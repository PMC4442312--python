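"""Per-spot intensity trajectories and photobleaching step counting.

A spot's background-corrected intensity versus time is a noisy staircase:
each downward step is the irreversible photobleaching of one fluorophore, so
the step count reports the number of fluorescent subunits in the complex.
Steps are found by greedy binary segmentation of a piecewise-constant model
with a Schwarz-type (BIC-like) penalty; fits that do not bleach to
background, contain upward steps, or exceed the step budget are rejected
with an explicit reason so the population histogram is built from complete,
interpretable trajectories only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .detection import Spot
    from .simulator import ImageStack

__all__ = [
    "IntensityTrace",
    "StepFit",
    "StepDistribution",
    "RejectionReason",
    "SpotNearBorderError",
    "extract_trace",
    "count_steps",
    "build_step_distribution",
]


class SpotNearBorderError(ValueError):
    """Spot too close to the field edge for aperture + annulus photometry."""


class RejectionReason(str, Enum):
    NONE = "none"
    NO_FULL_BLEACH = "no_full_bleach"
    TOO_MANY_STEPS = "too_many_steps"
    UPWARD_STEP = "upward_step"
    LOW_SNR = "low_snr"


@dataclass
class IntensityTrace:
    """Background-corrected integrated intensity of one spot per frame."""

    values: np.ndarray
    spot: "Spot | None" = None
    aperture_radius_px: float = 3.0
    annulus_radii_px: tuple[float, float] = (5.0, 7.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StepFit:
    """Fitted staircase structure of one intensity trace.

    ``step_frames[i]`` is the first frame at the new plateau level;
    ``step_sizes[i]`` is signed (new level minus old level), so bleaching
    steps are negative. ``plateau_levels`` has one more entry than steps.
    """

    n_steps: int
    step_frames: list[int]
    step_sizes: list[float]
    plateau_levels: list[float]
    rss: float
    noise_sd: float
    accepted: bool
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.n_steps != len(self.step_frames) or self.n_steps != len(self.step_sizes):
            raise ValueError("n_steps inconsistent with step lists")
        if any(b <= a for a, b in zip(self.step_frames, self.step_frames[1:])):
            raise ValueError("step frames must be strictly increasing")


@dataclass
class StepDistribution:
    """Population histogram of photobleaching step counts."""

    counts: dict[int, int]
    total_accepted: int
    rejected_by_reason: dict[str, int]

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected_by_reason.values())

    @property
    def total(self) -> int:
        return self.total_accepted + self.total_rejected

    def fraction(self, n_steps: int) -> float:
        if self.total_accepted == 0:
            return 0.0
        return self.counts.get(n_steps, 0) / self.total_accepted

    def as_arrays(self, n_max: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(step counts 1..n_max, trace counts); n_max defaults to observed max."""
        if not self.counts:
            return np.zeros(0, int), np.zeros(0, int)
        n_max = n_max or max(self.counts)
        js = np.arange(1, n_max + 1)
        return js, np.array([self.counts.get(int(j), 0) for j in js])


def _annulus_masks(aperture_radius: float,
                   annulus_radii: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, int]:
    r_out = annulus_radii[1]
    half = int(np.ceil(r_out))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r = np.hypot(yy, xx)
    aperture = r <= aperture_radius
    annulus = (r >= annulus_radii[0]) & (r <= r_out)
    return aperture, annulus, half


def extract_trace(stack: "ImageStack", spot: "Spot",
                  aperture_radius_px: float = 3.0,
                  annulus_radii_px: tuple[float, float] = (5.0, 7.0),
                  ) -> IntensityTrace:
    """Aperture photometry: per frame, sum over a disk around the spot minus
    the local background (median of an annulus, scaled to the aperture area).
    """
    if annulus_radii_px[0] <= aperture_radius_px:
        raise ValueError("annulus must lie outside the aperture")
    ap_mask, ann_mask, half = _annulus_masks(aperture_radius_px, annulus_radii_px)
    h, w = stack.shape
    cy, cx = int(round(spot.y_px)), int(round(spot.x_px))
    if cy - half < 0 or cx - half < 0 or cy + half >= h or cx + half >= w:
        raise SpotNearBorderError(
            f"spot at ({spot.x_px:.1f}, {spot.y_px:.1f}) lacks a full "
            f"{half}-px photometry margin")
    sub = stack.frames[:, cy - half:cy + half + 1, cx - half:cx + half + 1]
    ap_vals = sub[:, ap_mask].sum(axis=1)
    bg_per_px = np.median(sub[:, ann_mask], axis=1)
    values = ap_vals - ap_mask.sum() * bg_per_px
    return IntensityTrace(values=values, spot=spot,
                          aperture_radius_px=aperture_radius_px,
                          annulus_radii_px=annulus_radii_px)


# ---------------------------------------------------------------------------
# staircase fitting


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise s.d. from first differences (steps are sparse outliers there)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _seg_rss(c1: np.ndarray, c2: np.ndarray, a: int, b: int) -> float:
    """RSS of y[a:b] around its mean, from prefix sums."""
    n = b - a
    s1 = c1[b] - c1[a]
    s2 = c2[b] - c2[a]
    return max(s2 - s1 * s1 / n, 0.0)


def _best_split(c1: np.ndarray, c2: np.ndarray, a: int, b: int,
                min_dwell: int) -> tuple[float, int]:
    """Largest RSS reduction from one change point in y[a:b].

    Returns (gain, split index t) with both resulting segments >= min_dwell
    frames; gain = -inf if the segment cannot be split.
    """
    lo, hi = a + min_dwell, b - min_dwell
    if hi < lo:
        return -np.inf, -1
    ts = np.arange(lo, hi + 1)
    nl = ts - a
    nr = b - ts
    sl = c1[ts] - c1[a]
    sr = c1[b] - c1[ts]
    rss_split = (c2[b] - c2[a]) - sl * sl / nl - sr * sr / nr
    k = int(np.argmin(rss_split))
    gain = _seg_rss(c1, c2, a, b) - max(float(rss_split[k]), 0.0)
    return gain, int(ts[k])


def _refine_cps(c1: np.ndarray, c2: np.ndarray, cps: list[int], T: int,
                min_dwell: int) -> list[int]:
    """Coordinate descent on change-point locations: re-place each change
    point optimally between its neighbors until stable. Each move is the
    optimal split of the merged segment, so total RSS never increases."""
    cps = sorted(cps)
    for _ in range(20):
        changed = False
        for i in range(len(cps)):
            a = 0 if i == 0 else cps[i - 1]
            b = T if i == len(cps) - 1 else cps[i + 1]
            _, t = _best_split(c1, c2, a, b, min_dwell)
            if t >= 0 and t != cps[i]:
                cps[i] = t
                changed = True
        if not changed:
            break
    return cps


def _fit_levels(y: np.ndarray, cps: list[int]) -> tuple[list[float], float]:
    bounds = [0] + sorted(cps) + [y.size]
    levels, rss = [], 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = y[a:b]
        mu = float(seg.mean())
        levels.append(mu)
        rss += float(((seg - mu) ** 2).sum())
    return levels, rss


def count_steps(trace: IntensityTrace,
                max_steps: int = 5,
                penalty: float = 3.0,
                min_step_size: float = 0.0,
                min_dwell_frames: int = 2,
                zero_tolerance_sd: float = 3.0,
                low_snr_factor: float = 2.0) -> StepFit:
    """Fit a piecewise-constant staircase and count photobleaching steps.

    Change points are inserted greedily (binary segmentation), each insertion
    accepted only while the model-selection cost RSS/sigma^2 + penalty*k*ln(T)
    decreases (sigma estimated robustly from frame-to-frame differences).
    Steps smaller than ``min_step_size`` and plateaus shorter than
    ``min_dwell_frames`` are pruned.  The fit is *accepted* only if every
    retained step is downward, the count is within ``max_steps``, the final
    plateau is within ``zero_tolerance_sd`` noise s.d. of zero (the molecule
    bleached completely), and the smallest step clears ``low_snr_factor``
    noise s.d.  Never raises on a valid trace.
    """
    y = trace.values
    T = y.size
    if T < 2 * min_dwell_frames:
        raise ValueError("trace shorter than 2 * min_dwell_frames")

    sigma = _robust_noise_sd(y)
    var = max(sigma * sigma, 1e-18)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    step_cost = penalty * np.log(T) * var

    # greedy insertion; allow one step beyond max_steps so overshoot is seen
    cps: list[int] = []
    while len(cps) < max_steps + 1:
        bounds = [0] + cps + [T]
        best_gain, best_t = 0.0, -1
        for a, b in zip(bounds[:-1], bounds[1:]):
            gain, t = _best_split(c1, c2, a, b, min_dwell_frames)
            if gain > best_gain:
                best_gain, best_t = gain, t
        if best_t < 0 or best_gain <= step_cost + 1e-12:
            break
        cps = _refine_cps(c1, c2, sorted(cps + [best_t]), T, min_dwell_frames)

    # prune: drop weakest change points violating size or dwell constraints
    while cps:
        levels, _ = _fit_levels(y, cps)
        deltas = np.diff(levels)
        bounds = np.array([0] + cps + [T])
        dwells = np.diff(bounds)
        bad = None
        small = np.where(np.abs(deltas) < min_step_size)[0]
        if small.size:
            bad = small[np.argmin(np.abs(deltas[small]))]
        else:
            short = np.where(dwells[1:] < min_dwell_frames)[0]  # keep first plateau
            if short.size:
                i = short[0]  # plateau i+1 too short: drop its weaker edge
                cands = [j for j in (i, i + 1) if j < len(deltas)]
                bad = min(cands, key=lambda j: abs(deltas[j]))
        if bad is None:
            break
        cps.pop(int(bad))
        cps = _refine_cps(c1, c2, cps, T, min_dwell_frames)

    levels, rss = _fit_levels(y, cps)
    deltas = list(np.diff(levels))
    n_steps = len(cps)

    reason = RejectionReason.NONE
    if n_steps == 0:
        reason = RejectionReason.NO_FULL_BLEACH
    elif any(d > 0 for d in deltas):
        reason = RejectionReason.UPWARD_STEP
    elif n_steps > max_steps:
        reason = RejectionReason.TOO_MANY_STEPS
    elif abs(levels[-1]) > zero_tolerance_sd * sigma + 1e-9:
        reason = RejectionReason.NO_FULL_BLEACH
    elif sigma > 0 and min(abs(d) for d in deltas) < low_snr_factor * sigma:
        reason = RejectionReason.LOW_SNR

    return StepFit(
        n_steps=n_steps,
        step_frames=[int(c) for c in cps],
        step_sizes=[float(d) for d in deltas],
        plateau_levels=[float(v) for v in levels],
        rss=float(rss),
        noise_sd=sigma,
        accepted=reason is RejectionReason.NONE,
        rejection_reason=reason,
    )


def build_step_distribution(fits: Iterable[StepFit]) -> StepDistribution:
    """Histogram of accepted step counts; rejected fits tallied by reason."""
    fits = list(fits)
    if not fits:
        raise ValueError("no step fits provided")
    counts: Counter[int] = Counter()
    rejected: Counter[str] = Counter()
    for f in fits:
        if f.accepted:
            counts[f.n_steps] += 1
        else:
            rejected[f.rejection_reason.value] += 1
    return StepDistribution(
        counts=dict(sorted(counts.items())),
        total_accepted=sum(counts.values()),
        rejected_by_reason=dict(sorted(rejected.items())),
    )
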
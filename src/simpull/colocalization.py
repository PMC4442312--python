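"""Two-color colocalization of single-molecule spots.

The colocalization percentage is the fraction of molecules in the
lower-density channel that have a partner in the other channel within the
match radius (2 px ~ 300 nm, one diffraction-limited spot). The lower-density
denominator is used because the two tagged proteins are pulled down to
different extents through their independent interactions with the bait.
Matching is greedy one-to-one by increasing distance, so no spot is counted
twice; the expected chance overlap of independent fields is reported
alongside from the Poisson null 1 - exp(-lambda * pi * r^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detection import Spot

__all__ = [
    "ColocalizationResult",
    "ConditionComparison",
    "register_channels",
    "match_spots",
    "colocalize",
    "expected_chance_colocalization",
    "compare_conditions",
]


@dataclass(frozen=True)
class ColocalizationResult:
    """Two-channel overlap statistics over one or more fields."""

    n_spots_a: int
    n_spots_b: int
    reference_channel: str          # the lower-density channel (denominator)
    n_matched: int
    percentage: float               # 100 * matched / reference count, pooled
    radius_px: float
    per_field_percent: tuple[float, ...]
    mean_percent: float             # mean over fields
    sd_percent: float               # n-1 s.d. over fields; NaN if 1 field
    n_fields: int
    expected_chance_percent: float | None = None
    empty_channel: bool = False

    @property
    def sem_percent(self) -> float:
        return self.sd_percent / np.sqrt(self.n_fields)


def register_channels(spots_b: Sequence[Spot],
                      offset_px: tuple[float, float]) -> list[Spot]:
    """Map channel-B spots into channel-A coordinates by removing the
    configured channel offset (dx, dy). Identity at offset (0, 0)."""
    dx, dy = float(offset_px[0]), float(offset_px[1])
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("offset must be finite")
    if dx == 0.0 and dy == 0.0:
        return list(spots_b)
    from dataclasses import replace
    return [replace(s, x_px=s.x_px - dx, y_px=s.y_px - dy) for s in spots_b]


def match_spots(spots_a: Sequence[Spot], spots_b: Sequence[Spot],
                radius_px: float) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of candidate pairs within the radius.

    Pairs are sorted by distance (ties by spot index order) and assigned in
    order, each spot used at most once. Returns (index_a, index_b, distance).
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if not spots_a or not spots_b:
        return []
    xa = np.array([[s.x_px, s.y_px] for s in spots_a])
    xb = np.array([[s.x_px, s.y_px] for s in spots_b])
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=radius_px)
    cand = [(float(np.hypot(*(xa[i] - xb[j]))), i, j)
            for i, nbrs in enumerate(pairs) for j in nbrs]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, d))
    return matches


def colocalize(fields_a: Sequence[Sequence[Spot]],
               fields_b: Sequence[Sequence[Spot]],
               radius_px: float = 2.0,
               field_area_px2: float | None = None,
               channel_a: str = "A",
               channel_b: str = "B") -> ColocalizationResult:
    """Colocalization percentage across paired fields of view.

    The denominator in each field is the channel with fewer spots there (the
    lower-density channel); the reference channel reported is the lower-count
    channel overall. If ``field_area_px2`` is given, the expected chance
    percentage for the denser channel's mean density is included.
    """
    if len(fields_a) != len(fields_b) or len(fields_a) == 0:
        raise ValueError("need >= 1 paired fields, equal counts per channel")

    n_a = sum(len(f) for f in fields_a)
    n_b = sum(len(f) for f in fields_b)
    per_field = []
    n_matched = 0
    n_ref_total = 0
    empty = False
    for fa, fb in zip(fields_a, fields_b):
        matches = match_spots(fa, fb, radius_px)
        n_matched += len(matches)
        ref = min(len(fa), len(fb))
        n_ref_total += ref
        if ref == 0:
            empty = True
            per_field.append(0.0)
        else:
            per_field.append(100.0 * len(matches) / ref)

    arr = np.array(per_field)
    chance = None
    if field_area_px2 is not None and field_area_px2 > 0:
        denser = max(n_a, n_b) / len(fields_a)
        chance = expected_chance_colocalization(denser / field_area_px2, radius_px)
    return ColocalizationResult(
        n_spots_a=n_a, n_spots_b=n_b,
        reference_channel=channel_a if n_a <= n_b else channel_b,
        n_matched=n_matched,
        percentage=100.0 * n_matched / n_ref_total if n_ref_total else 0.0,
        radius_px=radius_px,
        per_field_percent=tuple(per_field),
        mean_percent=float(arr.mean()),
        sd_percent=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        n_fields=len(per_field),
        expected_chance_percent=chance,
        empty_channel=empty,
    )


def expected_chance_colocalization(density_per_px2: float,
                                   radius_px: float) -> float:
    """Chance overlap percentage for independent Poisson fields:
    100 * (1 - exp(-lambda * pi * r^2)), lambda = denser-channel density."""
    if density_per_px2 < 0:
        raise ValueError("density must be >= 0")
    return 100.0 * (1.0 - np.exp(-density_per_px2 * np.pi * radius_px ** 2))


@dataclass(frozen=True)
class ConditionComparison:
    """Control-vs-treatment change in co-complex percentage."""

    difference: float               # control mean - treatment mean
    ratio: float                    # control mean / treatment mean
    z_score: float | None           # two-sample z from across-field s.d.


def compare_conditions(result_control: ColocalizationResult,
                       result_treatment: ColocalizationResult) -> ConditionComparison:
    """Scaffold-loss readout: how much the co-complex percentage drops
    between two conditions, with a two-sample z-score from the per-field
    replicate spread (omitted when either condition has < 2 fields)."""
    diff = result_control.mean_percent - result_treatment.mean_percent
    ratio = result_control.mean_percent / result_treatment.mean_percent \
        if result_treatment.mean_percent != 0 else float("inf")
    z = None
    if result_control.n_fields >= 2 and result_treatment.n_fields >= 2:
        se = np.sqrt(result_control.sem_percent ** 2
                     + result_treatment.sem_percent ** 2)
        z = float(diff / se) if se > 0 else None
    return ConditionComparison(difference=float(diff), ratio=float(ratio),
                               z_score=z)
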
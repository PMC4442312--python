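"""Reference implementations used to validate the fast analysis paths.

These are deliberately independent algorithms, not the ones the pipeline
runs: an exact dynamic-programming staircase fit (the optimum the greedy
segmentation is checked against) and a brute-force all-pairs spot matcher.
They are slow but exhaustive, intended for small inputs in tests and
validation runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exact_staircase_fit", "brute_force_match"]


def exact_staircase_fit(values: np.ndarray, n_steps: int,
                        min_dwell: int = 1) -> tuple[float, list[int]]:
    """Globally optimal piecewise-constant fit with exactly ``n_steps``
    change points, by dynamic programming over all placements.

    Returns (minimal RSS, change-point frames). Equivalent to exhaustive
    enumeration of all C(T-1, k) placements, in O(k T^2).
    """
    y = np.asarray(values, dtype=float)
    T = y.size
    k = int(n_steps)
    if k < 0:
        raise ValueError("n_steps must be >= 0")
    if T < (k + 1) * min_dwell:
        raise ValueError("trace too short for this many segments")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_rss(a: np.ndarray, b: int) -> np.ndarray:
        n = b - a
        s1 = c1[b] - c1[a]
        return np.maximum((c2[b] - c2[a]) - s1 * s1 / n, 0.0)

    # best[s, t] = min RSS of y[:t] split into s segments (each >= min_dwell)
    best = np.full((k + 2, T + 1), np.inf)
    arg = np.zeros((k + 2, T + 1), dtype=int)
    for t in range(min_dwell, T + 1):
        best[1, t] = seg_rss(np.array([0]), t)[0]
    for s in range(2, k + 2):
        for t in range(s * min_dwell, T + 1):
            us = np.arange((s - 1) * min_dwell, t - min_dwell + 1)
            cost = best[s - 1, us] + seg_rss(us, t)
            i = int(np.argmin(cost))
            best[s, t] = cost[i]
            arg[s, t] = us[i]

    cps: list[int] = []
    t = T
    for s in range(k + 1, 1, -1):
        t = int(arg[s, t])
        cps.append(t)
    cps.reverse()
    return float(best[k + 1, T]), cps


def brute_force_match(xy_a: np.ndarray, xy_b: np.ndarray,
                      radius: float) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching from the full distance matrix (no trees)."""
    xy_a = np.atleast_2d(np.asarray(xy_a, dtype=float))
    xy_b = np.atleast_2d(np.asarray(xy_b, dtype=float))
    if xy_a.size == 0 or xy_b.size == 0:
        return []
    d = np.linalg.norm(xy_a[:, None, :] - xy_b[None, :, :], axis=2)
    cand = [(float(d[i, j]), i, j)
            for i in range(d.shape[0]) for j in range(d.shape[1])
            if d[i, j] <= radius]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for dist, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, dist))
    return out
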
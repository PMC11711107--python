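"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity by the most literal method
available (per-pixel loops, exhaustive rotation scans) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def pixelwise_median(rasters: list[np.ndarray]) -> np.ndarray:
    """Per-pixel sort-and-pick-middle median of equally shaped rasters."""
    h, w = rasters[0].shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            vals = sorted(float(r[i, j]) for r in rasters)
            n = len(vals)
            mid = n // 2
            out[i, j] = vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])
    return out


def majority_vote_3x3(mask: np.ndarray) -> np.ndarray:
    """Binary median (majority vote) over 3x3 neighborhoods, reflect padding."""
    # edge-repeating reflection: (a b c | c b a) at each border
    padded = np.pad(mask.astype(int), 1, mode="symmetric")
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 3, j : j + 3]
            out[i, j] = window.sum() > 4  # majority of 9
    return out


def min_area_claimant_labels(masks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-pixel phase assignment: the smallest-area claimant wins.

    Returns an object array of phase names with '' for unassigned pixels.
    Equal-area claimants tie-break to the one painted last in
    descending-area, name-ascending painting order — i.e. the
    lexicographically largest name among the minimum-area claimants.
    """
    shape = next(iter(masks.values())).shape
    areas = {name: int(m.sum()) for name, m in masks.items()}
    out = np.full(shape, "", dtype=object)
    for i in range(shape[0]):
        for j in range(shape[1]):
            claimants = [name for name, m in masks.items() if m[i, j]]
            if claimants:
                smallest = min(areas[n] for n in claimants)
                out[i, j] = max(n for n in claimants if areas[n] == smallest)
    return out


def exhaustive_feret(points: np.ndarray, step_deg: float = 0.1) -> tuple[float, float]:
    """Min/max caliper extents by scanning projection directions exhaustively."""
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    # max Feret is the point-set diameter (caliper max over directions)
    return float(widths.min()), float(widths.max())
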
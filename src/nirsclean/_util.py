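"""Small shared helpers (run-length tools, quantile rule)."""

from __future__ import annotations

import math

import numpy as np


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Merge sorted runs separated by fewer than ``max_gap`` samples."""
    merged: list[list[int]] = []
    for s, e in sorted(runs):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def quantile_first(sorted_vals: np.ndarray, q: float) -> float:
    """Maximum of the first ``q`` fraction of an ascending-sorted vector.

    Uses the 1-based index ``max(1, floor(q * N))``.
    """
    n = len(sorted_vals)
    if n == 0:
        raise ValueError("empty vector")
    return float(sorted_vals[max(1, math.floor(q * n)) - 1])
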
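"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the package's own algorithms: burst windows are
found by exhaustive enumeration over all contiguous spike windows, and
Sholl crossings by dense arc-length sampling of every edge.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np


def brute_force_bursts(
    times: np.ndarray,
    min_spikes: int = 5,
    isi_init: float = 0.1,
    isi_continue: float = 0.25,
) -> List[Tuple[int, int]]:
    """All maximal contiguous windows satisfying the burst rules.

    A window [i..j] is valid when ISI(i) <= isi_init and every later ISI
    up to j is <= isi_continue; maximal windows (not contained in a
    larger valid window) with at least ``min_spikes`` spikes are
    returned as (start_index, end_index) pairs.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    isi = np.diff(times)

    def valid(i: int, j: int) -> bool:
        if j <= i:
            return False
        if isi[i] > isi_init:
            return False
        return all(isi[k] <= isi_continue for k in range(i + 1, j))

    windows = [(i, j) for i in range(n) for j in range(i + 1, n) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in windows)
    ]
    return [(i, j) for (i, j) in maximal if j - i + 1 >= min_spikes]


def dense_sholl(arbor, radii, step: float = 0.01) -> np.ndarray:
    """Sholl crossing counts by dense sampling along every edge.

    Each edge is sampled at ``step`` um arc-length resolution; a
    crossing is a sign flip of (distance-to-soma - r) between adjacent
    samples, or a run of samples landing exactly on the circle.
    Candidate crossing points are deduplicated within half a step so a
    vertex on the circle shared by several edges counts once.  Misses
    tangencies that fall between samples; adequate for generic arbors.
    """
    center = arbor.soma_xyz
    counts = np.zeros(len(radii), dtype=int)
    per_radius_points: List[List[np.ndarray]] = [[] for _ in radii]
    for p_idx, c_idx in arbor.edges():
        p1 = arbor.xyz[p_idx]
        p2 = arbor.xyz[c_idx]
        length = np.linalg.norm(p2 - p1)
        n = max(int(np.ceil(length / step)), 1) + 1
        t = np.linspace(0.0, 1.0, n)
        pts = p1[None, :] + t[:, None] * (p2 - p1)[None, :]
        d = np.linalg.norm(pts - center, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(d - r)
            # adjacent strict sign flips -> midpoint estimate
            flips = np.flatnonzero(s[:-1] * s[1:] < 0)
            for i in flips:
                per_radius_points[k].append(0.5 * (pts[i] + pts[i + 1]))
            # samples exactly on the circle -> one point per zero run
            zeros = np.flatnonzero(s == 0)
            if zeros.size:
                run_starts = zeros[np.concatenate(([True], np.diff(zeros) > 1))]
                for i in run_starts:
                    per_radius_points[k].append(pts[i])
    for k, candidates in enumerate(per_radius_points):
        kept: List[np.ndarray] = []
        for p in candidates:
            if all(np.linalg.norm(p - q) > step / 2 for q in kept):
                kept.append(p)
        counts[k] = len(kept)
    return counts


def random_train_times(rng: np.random.Generator, max_spikes: int = 12) -> np.ndarray:
    """Random short spike trains with ISIs straddling the burst thresholds."""
    n = int(rng.integers(2, max_spikes + 1))
    return np.sort(rng.uniform(0.0, 0.18 * n, n))
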
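"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each result from first principles (naive
loops, exhaustive enumeration) without calling the library code paths
they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def merge_oracle(occupancy: list[int], max_gap: int = 2) -> list[tuple[int, int]]:
    """Run-length window oracle: group expressing bin indices whenever
    consecutive expressing bins are separated by <= max_gap empty bins;
    returns (first, last) expressing-bin index pairs."""
    expressed = [i for i, v in enumerate(occupancy) if v > 0]
    if not expressed:
        return []
    groups = [[expressed[0]]]
    for i in expressed[1:]:
        if i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1]) for g in groups]


def rank_oracle(
    rows: list[tuple[str, int, int, int, float]],
) -> list[tuple[tuple[int, int, int], float, int]]:
    """Independent ranking of (chrom, start, hits, total_length,
    weighted_coverage) rows: per-criterion competition rank (1 = largest,
    ties share the minimum rank = 1 + number of strictly greater values),
    overall score = rank sum, overall rank by (score, -coverage, chrom,
    start). Returns [(criterion_ranks, score, overall_rank)] row-aligned."""
    n = len(rows)
    crits = [[r[2] for r in rows], [r[3] for r in rows], [r[4] for r in rows]]
    crit_ranks = []
    for i in range(n):
        ranks = tuple(
            1 + sum(1 for j in range(n) if c[j] > c[i]) for c in crits
        )
        crit_ranks.append(ranks)
    scores = [float(sum(r)) for r in crit_ranks]
    order = sorted(
        range(n), key=lambda i: (scores[i], -rows[i][4], rows[i][0], rows[i][1])
    )
    overall = [0] * n
    for pos, i in enumerate(order):
        overall[i] = pos + 1
    return [(crit_ranks[i], scores[i], overall[i]) for i in range(n)]


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int | None:
    """Distance between closest ends of disjoint half-open intervals;
    None when they overlap."""
    if interval_overlap(a, b):
        return None
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def mannwhitney_exact_oracle(x: list[float], y: list[float]) -> tuple[float, float]:
    """(U_x, two-sided p) by exhaustive enumeration of all group
    labelings of the pooled sample (requires no ties)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(nx + ny)
    ranks[order] = np.arange(1, nx + ny + 1)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2
    us = [
        ranks[list(c)].sum() - nx * (nx + 1) / 2
        for c in combinations(range(nx + ny), nx)
    ]
    p = float(np.mean(np.abs(np.array(us) - mu) >= abs(u_obs - mu) - 1e-12))
    return float(u_obs), p


def fisher_exact_oracle(table: list[list[int]]) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(a_val: int) -> float:
        b_val = r1 - a_val
        c_val = c1 - a_val
        d_val = r2 - c_val
        if min(b_val, c_val, d_val) < 0:
            return 0.0
        return comb(r1, a_val) * comb(r2, c_val) / denom

    p_obs = prob(a)
    return float(
        sum(p for a_val in range(0, min(r1, c1) + 1)
            if (p := prob(a_val)) <= p_obs * (1 + 1e-9))
    )


def greedy_merge_oracle(
    peaks: list[tuple[str, int, int, float, float, str]],
) -> list[tuple[str, int, int]]:
    """Naive O(n^2) greedy consensus: sort by (-spm, -score, coords,
    sample), keep a peak iff it overlaps nothing already kept.
    Each peak tuple is (chrom, start, end, spm, score_raw, sample)."""
    ordered = sorted(peaks, key=lambda p: (-p[3], -p[4], p[0], p[1], p[2], p[5]))
    kept: list[tuple[str, int, int]] = []
    for chrom, start, end, *_ in ordered:
        if not any(
            kc == chrom and interval_overlap((start, end), (ks, ke))
            for kc, ks, ke in kept
        ):
            kept.append((chrom, start, end))
    return sorted(kept)


def rolling_mean_oracle(row: np.ndarray, width: int) -> np.ndarray:
    """Position-by-position centered mean over in-bounds finite values."""
    half = width // 2
    out = np.full(len(row), np.nan)
    for i in range(len(row)):
        if not np.isfinite(row[i]):
            continue
        vals = [
            row[j]
            for j in range(max(0, i - half), min(len(row), i + half + 1))
            if np.isfinite(row[j])
        ]
        out[i] = sum(vals) / len(vals)
    return out
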
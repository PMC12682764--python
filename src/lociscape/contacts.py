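"""Intrachromosomal contact-matrix analyses.

Provides matrix balancing (diagonal rescaling to equal row sums, the
standard Knight-Ruiz-style contract), stratum-adjusted correlation
(SCC) for replicate concordance, replicate merging gated on SCC,
virtual-4C viewpoint profiles smoothed with a 30 kb rolling window at
10 kb resolution, top-percentile interaction calling intersected
across replicates, and quantile-normalized difference maps.

Masked (sparse) bins are carried as NaN; downstream operations treat
NaN as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContactMatrix:
    """Symmetric intrachromosomal contact matrix at fixed bin size."""

    region: tuple[str, int, int]
    bin_size: int
    counts: np.ndarray
    balanced: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        finite = np.isfinite(self.counts)
        if np.any(self.counts[finite] < 0):
            raise ValueError("counts must be non-negative")
        with np.errstate(invalid="ignore"):
            sym = np.allclose(
                np.nan_to_num(self.counts), np.nan_to_num(self.counts.T), rtol=1e-9
            )
        if not sym:
            raise ValueError("counts must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        chrom, start, end = self.region
        if pos < start or pos >= end:
            raise ValueError(f"position {pos} outside region {chrom}:{start}-{end}")
        return (pos - start) // self.bin_size

    def same_grid(self, other: "ContactMatrix") -> bool:
        return (
            self.region == other.region
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )


class BalanceError(RuntimeError):
    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def balance(
    matrix: ContactMatrix,
    mask_fraction: float = 0.10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ContactMatrix:
    """Diagonal-rescale so every unmasked row sums to the mean raw row sum.

    Rows whose raw sum falls below ``mask_fraction`` of the median row
    sum are masked (set to NaN in both row and column). Balancing uses
    symmetric iterative proportional scaling: repeatedly multiply by
    diag(sqrt(target / rowsum)) on both sides until the maximum
    relative row-sum deviation is below ``tol``.
    """
    raw = matrix.counts
    row_sums = np.nansum(raw, axis=1)
    if not np.any(row_sums > 0):
        raise BalanceError("cannot balance an all-zero matrix")
    masked = row_sums < mask_fraction * np.median(row_sums)
    keep = ~masked
    sub = raw[np.ix_(keep, keep)].copy()
    target = float(np.mean(row_sums[keep]))
    if target <= 0 or np.any(np.nansum(sub, axis=1) == 0):
        # a kept row can still be all-zero against other kept rows
        zero_rows = np.nansum(sub, axis=1) == 0
        keep_idx = np.flatnonzero(keep)
        masked[keep_idx[zero_rows]] = True
        keep = ~masked
        sub = raw[np.ix_(keep, keep)].copy()
        if sub.size == 0 or not np.any(sub > 0):
            raise BalanceError("cannot balance: all rows masked or zero")
        target = float(np.mean(np.nansum(raw, axis=1)[keep]))
    residual = math.inf
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        residual = float(np.max(np.abs(s - target)) / target)
        if residual < tol:
            break
        scale = np.sqrt(target / s)
        sub *= scale[:, None]
        sub *= scale[None, :]
    else:
        raise BalanceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})",
            residual=residual,
        )
    out = np.full_like(raw, np.nan)
    out[np.ix_(keep, keep)] = sub
    return ContactMatrix(
        region=matrix.region, bin_size=matrix.bin_size, counts=out, balanced=True
    )


@dataclass
class SCCResult:
    """Stratum-adjusted correlation of two contact matrices.

    SCC is the weighted mean of per-distance-stratum Pearson
    correlations, weighted by stratum size times the product of the two
    stratum standard deviations.
    """

    scc: float
    stratum_correlations: list[float]
    stratum_weights: list[float]
    max_distance_bins: int


def scc(
    m1: ContactMatrix, m2: ContactMatrix, max_distance_bins: int | None = None
) -> SCCResult:
    """Stratum-adjusted correlation coefficient between two matrices.

    For each diagonal stratum d = 0..max_distance_bins the Pearson
    correlation r_d of the two matrices' stratum entries is computed;
    strata with zero variance in either matrix (or fewer than two
    finite pairs) are skipped. SCC = sum(w_d r_d) / sum(w_d) with
    w_d = n_d * s1_d * s2_d.
    """
    if not m1.same_grid(m2):
        raise ValueError("matrices must share region, bin size and dimensions")
    n = m1.n_bins
    if max_distance_bins is None:
        max_distance_bins = n - 1
    max_distance_bins = min(max_distance_bins, n - 1)
    corrs: list[float] = []
    weights: list[float] = []
    for d in range(max_distance_bins + 1):
        a = np.diagonal(m1.counts, offset=d)
        b = np.diagonal(m2.counts, offset=d)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 2:
            continue
        s1, s2 = a.std(), b.std()
        if s1 == 0 or s2 == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        corrs.append(r)
        weights.append(float(a.size * s1 * s2))
    if not weights:
        raise ValueError("no informative strata for SCC")
    val = float(np.dot(corrs, weights) / np.sum(weights))
    return SCCResult(
        scc=min(1.0, max(-1.0, val)),
        stratum_correlations=corrs,
        stratum_weights=weights,
        max_distance_bins=max_distance_bins,
    )


class ReplicateDiscordanceError(RuntimeError):
    def __init__(self, scc_value: float, threshold: float):
        super().__init__(
            f"replicates not concordant: SCC {scc_value:.4f} < threshold {threshold}"
        )
        self.scc = scc_value
        self.threshold = threshold


def merge_replicates(
    m1: ContactMatrix,
    m2: ContactMatrix,
    scc_threshold: float = 0.9,
    max_distance_bins: int | None = None,
) -> ContactMatrix:
    """Sum raw replicate counts if their SCC meets the threshold;
    refuse to merge otherwise."""
    if m1.balanced or m2.balanced:
        raise ValueError("merge operates on raw (unbalanced) matrices")
    result = scc(m1, m2, max_distance_bins=max_distance_bins)
    if result.scc < scc_threshold:
        raise ReplicateDiscordanceError(result.scc, scc_threshold)
    return ContactMatrix(
        region=m1.region,
        bin_size=m1.bin_size,
        counts=m1.counts + m2.counts,
        balanced=False,
    )


@dataclass
class Virtual4CProfile:
    """Smoothed one-viewpoint interaction profile with top-fraction calls."""

    viewpoint_bin: int
    values: np.ndarray
    window_bp: int = 30_000
    slide_bp: int = 10_000
    fraction: float = 0.15
    calls: set[int] = field(default_factory=set)

    @property
    def eligible(self) -> np.ndarray:
        """Bins usable for calling: finite and outside the viewpoint
        exclusion zone (viewpoint bin +/- 1)."""
        mask = np.isfinite(self.values)
        lo = max(0, self.viewpoint_bin - 1)
        hi = min(len(self.values), self.viewpoint_bin + 2)
        mask[lo:hi] = False
        return mask


def _rolling_mean(row: np.ndarray, width: int) -> np.ndarray:
    """Centered rolling mean over available (finite) neighbors; a
    missing center stays missing."""
    half = width // 2
    n = len(row)
    out = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(row[i]):
            continue
        window = row[max(0, i - half): min(n, i + half + 1)]
        out[i] = np.nanmean(window)
    return out


def virtual_4c(
    matrix: ContactMatrix,
    viewpoint: int,
    window_bp: int = 30_000,
    fraction: float = 0.15,
) -> Virtual4CProfile:
    """Extract and smooth the viewpoint bin's interaction row.

    ``viewpoint`` is a genomic position inside the matrix region. The
    row is smoothed by a centered rolling mean of window_bp/bin_size
    bins (3 at 10 kb resolution), stepping one bin (the 10 kb slide);
    edge bins average over their available neighbors and masked bins
    stay missing. Calls are the top-``fraction`` eligible bins (the
    viewpoint bin and its immediate neighbors are excluded).
    """
    if not matrix.balanced:
        raise ValueError("virtual_4c expects a balanced matrix")
    vp_bin = matrix.bin_of(viewpoint)
    width = max(1, int(round(window_bp / matrix.bin_size)))
    smoothed = _rolling_mean(matrix.counts[vp_bin].copy(), width)
    profile = Virtual4CProfile(
        viewpoint_bin=vp_bin,
        values=smoothed,
        window_bp=window_bp,
        slide_bp=matrix.bin_size,
        fraction=fraction,
    )
    profile.calls = _top_fraction_calls(profile.values, profile.eligible, fraction)
    return profile


def _top_fraction_calls(
    values: np.ndarray, eligible: np.ndarray, fraction: float
) -> set[int]:
    """Bins whose value is >= the value of the ceil(fraction * n)-th
    largest eligible bin; ties at the threshold are all included."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return set()
    vals = values[idx]
    n_call = math.ceil(fraction * idx.size)
    threshold = np.sort(vals)[::-1][n_call - 1]
    return {int(i) for i in idx[vals >= threshold]}


@dataclass
class InteractionCalls:
    per_replicate: list[set[int]]
    intersection: set[int]


def call_top_interactions(
    profiles: list[Virtual4CProfile], fraction: float = 0.15
) -> InteractionCalls:
    """Per-replicate top-fraction calls and their intersection.

    All profiles must share the grid; the per-replicate quantile is
    computed by rank over each profile's own eligible bins.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    n = len(profiles[0].values)
    if any(len(p.values) != n for p in profiles):
        raise ValueError("profiles must share the same grid")
    per_rep = [
        _top_fraction_calls(p.values, p.eligible, fraction) for p in profiles
    ]
    inter = set.intersection(*per_rep)
    return InteractionCalls(per_replicate=per_rep, intersection=inter)


def _quantile_normalize_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map both vectors onto the mean of their sorted values (standard
    two-array quantile normalization); ties get the mean target of
    their rank span."""
    from scipy.stats import rankdata

    target = (np.sort(a) + np.sort(b)) / 2.0
    n = len(a)
    grid = np.arange(1, n + 1)
    a_q = np.interp(rankdata(a, method="average"), grid, target)
    b_q = np.interp(rankdata(b, method="average"), grid, target)
    return a_q, b_q


def difference_map(m_a: ContactMatrix, m_b: ContactMatrix) -> np.ndarray:
    """Signed difference A' - B' after quantile-normalizing both
    matrices' upper-triangle values to their pooled distribution.

    Entries missing in either matrix are NaN in the output. The result
    is symmetric and exactly antisymmetric under argument exchange.
    """
    if not m_a.same_grid(m_b):
        raise ValueError("matrices must share region, bin size and dimensions")
    if not (m_a.balanced and m_b.balanced):
        raise ValueError("difference_map expects balanced matrices")
    n = m_a.n_bins
    iu = np.triu_indices(n)
    a_u = m_a.counts[iu]
    b_u = m_b.counts[iu]
    ok = np.isfinite(a_u) & np.isfinite(b_u)
    diff_u = np.full(a_u.shape, np.nan)
    if np.any(ok):
        a_q, b_q = _quantile_normalize_pair(a_u[ok], b_u[ok])
        diff_u[ok] = a_q - b_q
    out = np.full((n, n), np.nan)
    out[iu] = diff_u
    out.T[iu] = diff_u
    return out
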
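"""γH2Ax quantification and statistics around a double-strand break.

Rebinning, DSB-bin normalization, track-interactome correlation, replicate
subtraction (Δ) tracks, broad-domain calling against a non-targeting
control, interval-overlap Fisher testing on bin masks, TAD-wise paired
t-tests, and the asymmetry/cross-border statistics that formalize how far a
damage-response platform spreads on each side of the break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import (
    BinGrid,
    ContactMatrix,
    CoverageTrack,
    GenomicInterval,
    bin_intervals,
    coord_to_bin,
)
from .insulation import BorderSet

__all__ = [
    "bin_signal",
    "normalize_to_dsb_bin",
    "correlate_tracks",
    "subtraction_track",
    "paired_t_test",
    "call_domains",
    "fisher_exact_two_sided",
    "fisher_overlap",
    "asymmetry_index",
    "cross_border_fraction",
    "CorrelationResult",
    "DomainCall",
    "StatResult",
    "AsymmetryResult",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_bins: int
    bin_width: int
    interval: GenomicInterval
    transform: str = "none"


@dataclass
class DomainCall:
    intervals: list[GenomicInterval]
    fold: list[float]
    p: list[float]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p: float
    test: str
    n: int
    sidedness: str = "two-sided"


@dataclass(frozen=True)
class AsymmetryResult:
    """Signed up/downstream imbalance of suprathreshold γH2Ax mass.

    ``A = (M_down - M_up)/(M_down + M_up)`` where the masses are the
    background-subtracted signal summed over the maximal runs, up- and
    downstream of the DSB bin, where the 3-bin-smoothed track stays above
    background. A = 0 when both masses vanish.
    """

    A: float
    upstream_extent: int
    downstream_extent: int
    mass_up: float
    mass_down: float


# ---------------------------------------------------------------------------
# rebinning and normalization


def _rebin_weighted(track: CoverageTrack, grid: BinGrid) -> np.ndarray:
    """Length-weighted mean of source bins within each target bin of ``grid``."""
    src = track.grid
    out = np.zeros(grid.n_bins)
    for t in range(grid.n_bins):
        lo, hi = grid.bin_start(t), grid.bin_end(t)
        lo_c, hi_c = max(lo, src.region_start), min(hi, src.region_end)
        if lo_c >= hi_c:
            continue
        first = coord_to_bin(src, lo_c)
        last = coord_to_bin(src, hi_c - 1)
        w_total = 0.0
        acc = 0.0
        for s in range(first, last + 1):
            ov = min(hi_c, src.bin_end(s)) - max(lo_c, src.bin_start(s))
            acc += track.values[s] * ov
            w_total += ov
        out[t] = acc / w_total if w_total else 0.0
    return out


def bin_signal(track: CoverageTrack, target_width: int) -> CoverageTrack:
    """Rebin to a coarser grid; each target bin is the mean of its source bins.

    ``target_width`` must be >= the source width and an integer multiple of
    it. A truncated final bin averages only the source bins it contains.
    """
    src = track.grid
    if target_width < src.bin_width or target_width % src.bin_width != 0:
        raise ValueError(
            f"target width {target_width} must be a multiple of {src.bin_width}"
        )
    if target_width == src.bin_width:
        return track.copy()
    grid = BinGrid(src.chrom, src.region_start, src.region_end, target_width)
    return CoverageTrack(
        grid, _rebin_weighted(track, grid), label=track.label, units=track.units
    )


def normalize_to_dsb_bin(track: CoverageTrack, dsb: GenomicInterval) -> CoverageTrack:
    """Divide every value by the DSB-containing bin's value (that bin -> 1)."""
    b = coord_to_bin(track.grid, dsb.midpoint)
    ref = track.values[b]
    if ref <= 0:
        raise ValueError(f"DSB bin {b} has value {ref}: normalization undefined")
    return CoverageTrack(
        track.grid, track.values / ref, label=track.label, units=track.units
    )


def correlate_tracks(
    a: CoverageTrack,
    b: CoverageTrack,
    interval: GenomicInterval | None = None,
    bin_width: int | None = None,
) -> CorrelationResult:
    """Pearson correlation of two tracks over an interval at a chosen bin size.

    Both tracks are rebinned (length-weighted mean) to ``bin_width`` over
    ``interval``; bins where both are exactly zero are dropped; r is computed
    on raw values — no log transform, DSB/diagonal bins included.
    """
    if a.grid != b.grid:
        raise ValueError("tracks must share a grid")
    src = a.grid
    if interval is None:
        interval = GenomicInterval(src.chrom, src.region_start, src.region_end)
    if bin_width is None:
        bin_width = src.bin_width
    lo = max(interval.start, src.region_start)
    hi = min(interval.end, src.region_end)
    if hi - lo < 3 * bin_width and (hi - lo) // bin_width < 3:
        # tolerate a truncated third bin
        if (hi - lo + bin_width - 1) // bin_width < 3:
            raise ValueError("interval overlaps fewer than 3 target bins")
    target = BinGrid(src.chrom, lo, hi, bin_width)
    va = _rebin_weighted(a, target)
    vb = _rebin_weighted(b, target)
    keep = ~((va == 0) & (vb == 0))
    va, vb = va[keep], vb[keep]
    if va.size < 3:
        raise ValueError("fewer than 3 bins survive zero-zero filtering")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant track: correlation undefined")
    r, _ = stats.pearsonr(va, vb)
    return CorrelationResult(
        r=float(r),
        n_bins=int(va.size),
        bin_width=bin_width,
        interval=GenomicInterval(src.chrom, lo, hi),
    )


def subtraction_track(
    group_a: list[CoverageTrack], group_b: list[CoverageTrack]
) -> CoverageTrack:
    """Δ track: mean of group A minus mean of group B, per bin."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one track")
    grid = group_a[0].grid
    for t in group_a + group_b:
        if t.grid != grid:
            raise ValueError("all tracks must share a grid")
    mean_a = np.mean([t.values for t in group_a], axis=0)
    mean_b = np.mean([t.values for t in group_b], axis=0)
    return CoverageTrack(grid, mean_a - mean_b, label="delta", units="delta")


# ---------------------------------------------------------------------------
# statistics


def paired_t_test(a, b) -> StatResult:
    """Two-sided paired Student's t-test on per-bin values.

    Degenerate cases follow the natural limits: all differences zero gives
    t = 0, p = 1; constant nonzero differences (zero variance) give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return StatResult(0.0, 1.0, "paired_t", n)
        sign = float("inf") if d[0] > 0 else float("-inf")
        return StatResult(sign, 0.0, "paired_t", n)
    t, p = stats.ttest_rel(a, b)
    return StatResult(float(t), float(p), "paired_t", n)


def call_domains(
    signal: CoverageTrack,
    control: CoverageTrack,
    window_bins: int = 5,
    fold_min: float = 4.0,
    p_max: float = 1e-3,
    merge_gap_bins: int = 2,
    min_length_bins: int = 3,
) -> DomainCall:
    """Broad-domain calling against a non-targeting control.

    The control is library-scaled to the signal total; sliding windows of
    ``window_bins`` are scored by ``fold = (signal+1)/(scaled control+1)``
    (window sums) and by the upper Poisson tail of the signal count given the
    scaled control as expectation. Windows passing both thresholds merge when
    overlapping or within ``merge_gap_bins``; calls shorter than
    ``min_length_bins`` are dropped. Per-call fold and p are re-evaluated on
    the merged interval.
    """
    if signal.grid != control.grid:
        raise ValueError("signal and control must share a grid")
    grid = signal.grid
    sig = signal.values
    ctl = control.values
    s_tot, c_tot = sig.sum(), ctl.sum()
    if s_tot == 0 and c_tot == 0:
        return DomainCall([], [], [])
    scaled_ctl = ctl * (s_tot / c_tot) if c_tot > 0 else np.zeros_like(ctl)

    n = grid.n_bins
    window_bins = min(window_bins, n)

    def window_stats(lo: int, hi: int) -> tuple[float, float]:
        s = sig[lo:hi].sum()
        c = scaled_ctl[lo:hi].sum()
        fold = (s + 1) / (c + 1)
        p = stats.poisson.sf(np.floor(s) - 1, max(c, 1e-12)) if s > 0 else 1.0
        return float(fold), float(p)

    hits = []
    for lo in range(0, n - window_bins + 1):
        fold, p = window_stats(lo, lo + window_bins)
        if fold >= fold_min and p <= p_max:
            hits.append((lo, lo + window_bins))
    if not hits:
        return DomainCall([], [], [])

    merged = [list(hits[0])]
    for lo, hi in hits[1:]:
        if lo <= merged[-1][1] + merge_gap_bins:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    intervals, folds, ps = [], [], []
    for lo, hi in merged:
        if hi - lo < min_length_bins:
            continue
        fold, p = window_stats(lo, hi)
        intervals.append(
            GenomicInterval(
                grid.chrom, grid.bin_start(lo), grid.bin_end(hi - 1), name="domain"
            )
        )
        folds.append(fold)
        ps.append(p)
    return DomainCall(intervals, folds, ps)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Computed by exact integer combinatorics: the hypergeometric pmf over the
    support shares the denominator C(n, a+c), so tables "as or more extreme"
    are identified by comparing integer numerators — no floating tie
    tolerance. Returns (odds_ratio, p); the odds ratio is the sample
    ``ad/bc`` with 0/inf edges, NaN when both products vanish.
    """
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return float("nan"), 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = [comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = comb(n, c1)
    p = sum(v for v in nums if v <= obs) / total
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return odds, float(min(p, 1.0))


def fisher_overlap(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval], grid: BinGrid
) -> StatResult:
    """Two-sided Fisher's exact test of bin-level overlap between two sets.

    Bins are classified by membership masks into a 2x2 table
    (A∩B, A only, B only, neither); the odds ratio is the sample
    ``ad/bc`` with 0/inf edges reported as such.
    """
    if grid.n_bins == 0:
        raise ValueError("empty grid")
    ma = bin_intervals(set_a, grid)
    mb = bin_intervals(set_b, grid)
    a = int(np.sum(ma & mb))
    b = int(np.sum(ma & ~mb))
    c = int(np.sum(~ma & mb))
    d = int(np.sum(~ma & ~mb))
    odds, p = fisher_exact_two_sided(a, b, c, d)
    return StatResult(float(odds), float(p), "fisher_exact", grid.n_bins)


# ---------------------------------------------------------------------------
# spreading geometry


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-bin running mean with shrunk windows at the edges."""
    kernel = np.ones(3)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def asymmetry_index(
    track: CoverageTrack, dsb: GenomicInterval, background: float
) -> AsymmetryResult:
    """Signed imbalance of γH2Ax spread on the two sides of the break.

    Extents are the maximal runs up- and downstream of the DSB bin over which
    the 3-bin-smoothed track stays above ``background``; masses are the
    background-subtracted (floored at 0) raw values summed over each extent,
    excluding the DSB bin itself.
    """
    grid = track.grid
    b = coord_to_bin(grid, dsb.midpoint)
    smooth = _smooth3(track.values)
    excess = np.maximum(track.values - background, 0.0)

    up_first = b
    if smooth[b] > background:
        while up_first > 0 and smooth[up_first - 1] > background:
            up_first -= 1
    down_last = b
    if smooth[b] > background:
        while down_last < grid.n_bins - 1 and smooth[down_last + 1] > background:
            down_last += 1

    m_up = float(excess[up_first:b].sum())
    m_down = float(excess[b + 1 : down_last + 1].sum())
    total = m_up + m_down
    a = (m_down - m_up) / total if total > 0 else 0.0
    up_extent = grid.bin_start(b) - grid.bin_start(up_first)
    down_extent = grid.bin_end(down_last) - grid.bin_end(b)
    return AsymmetryResult(float(a), int(up_extent), int(down_extent), m_up, m_down)


def cross_border_fraction(
    track: CoverageTrack,
    dsb: GenomicInterval,
    tads: BorderSet | list[GenomicInterval],
    background: float,
) -> list[float]:
    """Fraction of suprathreshold γH2Ax mass falling in each TAD.

    Fractions sum to <= 1, with equality when the TADs tile the whole region.
    All-zero suprathreshold mass gives all-zero fractions.
    """
    intervals = tads.tads if isinstance(tads, BorderSet) else tads
    grid = track.grid
    excess = np.maximum(track.values - background, 0.0)
    total = excess.sum()
    out = []
    for iv in intervals:
        if iv.chrom != grid.chrom:
            out.append(0.0)
            continue
        # length-weighted bin overlap keeps fractions additive when TADs tile
        mass = 0.0
        lo = max(iv.start, grid.region_start)
        hi = min(iv.end, grid.region_end)
        if lo < hi:
            first = coord_to_bin(grid, lo)
            last = coord_to_bin(grid, hi - 1)
            for bi in range(first, last + 1):
                ov = min(hi, grid.bin_end(bi)) - max(lo, grid.bin_start(bi))
                mass += excess[bi] * ov / grid.bin_length(bi)
        out.append(float(mass / total) if total > 0 else 0.0)
    return out
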
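"""Contact-matrix computations.

Coverage (visibility) normalization, virtual-4C viewpoint extraction,
replicate concordance, and distance-stratified differential contact testing.

The differential test follows the common joint-normalization idea for
comparing two Hi-C maps: per-pixel log2 ratios ``M`` are centred and scaled
within each genomic-distance stratum, yielding standardized ``Z`` scores and
two-sided normal p-values. We use a robust median/MAD standardization per
distance (strata too small to estimate a scale are pooled with the next
distance), which keeps the procedure dependency-free while preserving the
intent of distance-stratified M/Z testing. Benjamini-Hochberg q-values are
included since thousands of pixels are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinGrid, ContactMatrix, CoverageTrack, GenomicInterval, coord_to_bin

__all__ = [
    "coverage_normalize",
    "virtual_4c",
    "matrix_pearson",
    "compare_matrices",
    "DifferentialResult",
]


def coverage_normalize(
    matrix: ContactMatrix, method: str = "vc", n_iter: int = 1
) -> ContactMatrix:
    """Vanilla-coverage normalization: divide out per-bin visibility.

    ``N[i,j] = C[i,j] / (r_i * r_j)`` with ``r_i = marginal_i / mean(positive
    marginals)``. Bins with zero marginal are masked (entries zeroed, recorded
    in ``masked_bins``). ``method='vc_sqrt'`` uses ``sqrt(r_i)`` instead;
    ``n_iter > 1`` repeats the pass for a more aggressive balance.
    """
    if method not in ("vc", "vc_sqrt"):
        raise ValueError(f"unknown normalization method {method!r}")
    counts = matrix.counts.astype(float).copy()
    if counts.sum() == 0:
        raise ValueError("cannot coverage-normalize an all-zero matrix")
    masked = matrix.masked_bins.copy()
    for _ in range(max(1, n_iter)):
        marg = counts.sum(axis=1)
        positive = marg > 0
        masked |= ~positive
        r = np.ones_like(marg)
        r[positive] = marg[positive] / marg[positive].mean()
        if method == "vc_sqrt":
            r = np.sqrt(r)
        counts = counts / np.outer(r, r)
        counts[masked, :] = 0.0
        counts[:, masked] = 0.0
    return ContactMatrix(matrix.grid, counts, normalized=True, masked_bins=masked)


def virtual_4c(matrix: ContactMatrix, viewpoint: GenomicInterval) -> CoverageTrack:
    """Extract the interaction profile of a viewpoint from a contact matrix.

    The track value at bin ``i`` is the mean over viewpoint bins ``v`` of
    ``matrix[v, i]`` excluding diagonal pixels; a viewpoint bin itself (where
    only self pixels would remain) is reported as the mean of its non-self
    row entries, so the self-ligation diagonal never enters the profile.
    """
    grid = matrix.grid
    if viewpoint.chrom != grid.chrom:
        raise ValueError(f"viewpoint on {viewpoint.chrom}, grid on {grid.chrom}")
    lo = max(viewpoint.start, grid.region_start)
    hi = min(viewpoint.end, grid.region_end)
    if lo >= hi:
        raise ValueError("viewpoint does not overlap the grid region")
    first = coord_to_bin(grid, lo)
    last = coord_to_bin(grid, hi - 1)
    vbins = np.arange(first, last + 1)

    n = grid.n_bins
    values = np.empty(n)
    sub = matrix.counts[vbins, :]  # len(vbins) x n
    for i in range(n):
        col = sub[:, i]
        keep = vbins != i
        if keep.any():
            values[i] = col[keep].mean()
        else:
            # single-bin viewpoint at its own bin: mean of non-self row pixels
            row = matrix.counts[i, :]
            values[i] = (row.sum() - row[i]) / (n - 1)
    label = f"v4c_{grid.chrom}:{viewpoint.start}-{viewpoint.end}"
    return CoverageTrack(grid, values, label=label, units="contacts")


def matrix_pearson(
    m1: ContactMatrix, m2: ContactMatrix, max_distance_bins: int | None = None
) -> float:
    """Replicate concordance: Pearson r of log10(x+1) upper-triangle pixels.

    Only pixels with ``1 <= |i-j| <= max_distance_bins`` enter (the diagonal is
    a self-ligation artifact and is always excluded).
    """
    if m1.grid != m2.grid:
        raise ValueError("matrices must share a grid")
    n = m1.n_bins
    if max_distance_bins is None:
        max_distance_bins = n - 1
    iu, ju = np.triu_indices(n, k=1)
    d = ju - iu
    keep = d <= max_distance_bins
    if keep.sum() < 3:
        raise ValueError("fewer than 3 eligible pixels")
    x = np.log10(m1.counts[iu[keep], ju[keep]] + 1)
    y = np.log10(m2.counts[iu[keep], ju[keep]] + 1)
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class DifferentialResult:
    """Per-pixel differential contact records plus the per-distance curves.

    ``pixels`` columns: bin_i, bin_j, distance_bins, c1, c2, M, Z, p, q.
    ``distance_curves`` columns: distance_bins, center, scale, n_pixels,
    degenerate (True where the scale collapsed to zero and p was set to 1).
    """

    pixels: pd.DataFrame
    distance_curves: pd.DataFrame
    grid: BinGrid


def compare_matrices(
    m1: ContactMatrix,
    m2: ContactMatrix,
    min_count: int = 20,
    distance_pool_min: int = 50,
) -> DifferentialResult:
    """Distance-stratified M/Z differential test between two raw count maps.

    Pixels where both maps are below ``min_count`` are dropped; the default
    floor of 20 is where the normal tail on MAD-standardized log ratios of
    Poisson counts becomes well calibrated (lower counts give discrete,
    heavy-tailed M and inflate the type-I rate). With a +1
    pseudocount, ``M = log2((c2+1)/(c1+1))``; within each distance stratum
    (strata with fewer than ``distance_pool_min`` pixels are merged with the
    next larger distance) ``Z = (M - median(M)) / (1.4826 * MAD(M))`` and
    ``p`` is the two-sided normal tail. Swapping the inputs negates M and Z
    exactly.
    """
    if m1.grid != m2.grid:
        raise ValueError("matrices must share a grid")
    n = m1.n_bins
    iu, ju = np.triu_indices(n, k=1)
    c1 = m1.counts[iu, ju]
    c2 = m2.counts[iu, ju]
    keep = np.maximum(c1, c2) >= min_count
    df = pd.DataFrame(
        {
            "bin_i": iu[keep],
            "bin_j": ju[keep],
            "distance_bins": (ju - iu)[keep],
            "c1": c1[keep],
            "c2": c2[keep],
        }
    )
    # computed as a difference of logs so swapping inputs negates M exactly
    df["M"] = np.log2(df["c2"] + 1) - np.log2(df["c1"] + 1)

    # merge sparse distance strata with the next larger distance
    sizes = df.groupby("distance_bins").size()
    stratum_of: dict[int, int] = {}
    pending: list[int] = []
    pending_n = 0
    for d in sorted(sizes.index):
        pending.append(d)
        pending_n += sizes[d]
        if pending_n >= distance_pool_min:
            for dd in pending:
                stratum_of[dd] = pending[-1]
            pending, pending_n = [], 0
    if pending:  # leftover small strata join the last formed stratum
        tail = max(stratum_of.values()) if stratum_of else pending[-1]
        for dd in pending:
            stratum_of[dd] = tail
    df["stratum"] = df["distance_bins"].map(stratum_of)

    centers, scales, ns, degen = {}, {}, {}, {}
    for s, grp in df.groupby("stratum"):
        med = float(grp["M"].median())
        mad = float(np.median(np.abs(grp["M"] - med)))
        scale = mad * 1.4826
        centers[s], scales[s], ns[s] = med, scale, len(grp)
        degen[s] = scale == 0.0

    center = df["stratum"].map(centers).to_numpy()
    scale = df["stratum"].map(scales).to_numpy()
    bad = df["stratum"].map(degen).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (df["M"].to_numpy() - center) / scale
    z[bad] = 0.0
    p = 2 * stats.norm.sf(np.abs(z))
    p[bad] = 1.0
    df["Z"] = z
    df["p"] = p
    df["q"] = stats.false_discovery_control(p) if len(p) else p
    df = df.drop(columns="stratum")

    curves = pd.DataFrame(
        {
            "distance_bins": sorted(centers),
            "center": [centers[s] for s in sorted(centers)],
            "scale": [scales[s] for s in sorted(centers)],
            "n_pixels": [ns[s] for s in sorted(centers)],
            "degenerate": [degen[s] for s in sorted(centers)],
        }
    )
    return DifferentialResult(pixels=df, distance_curves=curves, grid=m1.grid)
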
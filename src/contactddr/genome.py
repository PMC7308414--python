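"""Coordinate system, core containers, and plain-text genomic format IO.

All coordinates are 0-based half-open (BED/bedGraph convention). The package
works on a single chromosomal region at a time — every analysis it supports is
a cis locus — so a :class:`BinGrid` describes one region of one chromosome
divided into fixed-width bins. Multi-chromosome work is iterated externally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinGrid",
    "GenomicInterval",
    "CoverageTrack",
    "ContactMatrix",
    "coord_to_bin",
    "bin_intervals",
    "rpkm",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_contact_matrix",
    "write_contact_matrix",
]

#: Units a CoverageTrack may carry. Signal is non-negative except for
#: log-ratio insulation scores and subtraction (delta) tracks.
TRACK_UNITS = ("raw_count", "RPKM", "contacts", "insulation_log2", "delta")
_SIGNED_UNITS = ("insulation_log2", "delta")


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of one chromosomal region.

    The last bin may be truncated when the region length is not an exact
    multiple of ``bin_width``; per-bin quantities that depend on length
    (e.g. RPKM) use the actual bin length.
    """

    chrom: str
    region_start: int
    region_end: int
    bin_width: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if not self.region_start < self.region_end:
            raise ValueError(
                f"empty region: start={self.region_start} end={self.region_end}"
            )

    @property
    def n_bins(self) -> int:
        return math.ceil((self.region_end - self.region_start) / self.bin_width)

    def bin_start(self, index: int) -> int:
        """Genomic start coordinate of bin ``index``."""
        self._check_index(index)
        return self.region_start + index * self.bin_width

    def bin_end(self, index: int) -> int:
        """Genomic end coordinate (exclusive); clipped for a truncated last bin."""
        self._check_index(index)
        return min(self.region_start + (index + 1) * self.bin_width, self.region_end)

    def bin_length(self, index: int) -> int:
        return self.bin_end(index) - self.bin_start(index)

    def bin_edges(self) -> np.ndarray:
        """All n_bins+1 bin edges in bp."""
        edges = self.region_start + self.bin_width * np.arange(self.n_bins + 1)
        edges[-1] = min(edges[-1], self.region_end)
        return edges

    def _check_index(self, index: int) -> None:
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} outside [0, {self.n_bins})")

    def __len__(self) -> int:
        return self.n_bins


def coord_to_bin(grid: BinGrid, pos: int) -> int:
    """Map a genomic position (bp) to its bin index on ``grid``.

    ``pos`` must satisfy ``region_start <= pos < region_end``.
    """
    if not grid.region_start <= pos < grid.region_end:
        raise ValueError(
            f"position {pos} outside region "
            f"[{grid.region_start}, {grid.region_end}) on {grid.chrom}"
        )
    return (pos - grid.region_start) // grid.bin_width


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval (BED record)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-bin signal on a :class:`BinGrid`."""

    grid: BinGrid
    values: np.ndarray
    label: str = ""
    units: str = "raw_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != n_bins {self.grid.n_bins}"
            )
        if self.units not in TRACK_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected {TRACK_UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if self.units not in _SIGNED_UNITS and np.any(self.values < 0):
            raise ValueError(f"negative values not allowed for units={self.units!r}")

    def copy(self, **overrides) -> "CoverageTrack":
        kwargs = dict(
            grid=self.grid, values=self.values.copy(), label=self.label, units=self.units
        )
        kwargs.update(overrides)
        return CoverageTrack(**kwargs)


@dataclass
class ContactMatrix:
    """Symmetric non-negative binned interaction counts on a :class:`BinGrid`."""

    grid: BinGrid
    counts: np.ndarray
    normalized: bool = False
    masked_bins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.grid.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("contact counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric as stored")
        if self.masked_bins is None:
            self.masked_bins = np.zeros(n, dtype=bool)
        else:
            self.masked_bins = np.asarray(self.masked_bins, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    def marginals(self) -> np.ndarray:
        """Row sums (per-bin total contacts, diagonal included)."""
        return self.counts.sum(axis=1)

    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            grid=self.grid,
            counts=self.counts.copy(),
            normalized=self.normalized,
            masked_bins=self.masked_bins.copy(),
        )


# ---------------------------------------------------------------------------
# per-bin helpers


def bin_intervals(intervals: list[GenomicInterval], grid: BinGrid) -> np.ndarray:
    """Boolean per-bin mask: True iff the bin overlaps any interval by >= 1 bp.

    Intervals on other chromosomes are ignored; off-region parts are clipped.
    """
    mask = np.zeros(grid.n_bins, dtype=bool)
    for iv in intervals:
        if iv.chrom != grid.chrom:
            continue
        lo = max(iv.start, grid.region_start)
        hi = min(iv.end, grid.region_end)
        if lo >= hi:
            continue
        first = coord_to_bin(grid, lo)
        last = coord_to_bin(grid, hi - 1)
        mask[first : last + 1] = True
    return mask


def rpkm(count: float, bin_width: int, library_size: float) -> float:
    """Reads per kilobase per million mapped reads for one bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((bin_width / 1e3) * (library_size / 1e6))


def counts_to_rpkm(track: CoverageTrack, library_size: float | None = None) -> CoverageTrack:
    """Convert a raw-count track to RPKM, honouring truncated last bins.

    ``library_size`` defaults to the track total (within-region library).
    """
    if library_size is None:
        library_size = float(track.values.sum())
        if library_size <= 0:
            library_size = 1.0
    lengths = np.array([track.grid.bin_length(i) for i in range(track.grid.n_bins)])
    vals = np.array(
        [rpkm(c, int(w), library_size) for c, w in zip(track.values, lengths)]
    )
    return CoverageTrack(track.grid, vals, label=track.label, units="RPKM")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, grid: BinGrid) -> CoverageTrack:
    """Read a 4-column bedGraph onto ``grid``.

    Each bin's value is the length-weighted mean of overlapping records over
    the whole bin, uncovered basepairs counting as 0 — so a record covering
    half a bin at value 4 yields 2. Records on other chromosomes are skipped
    (a single warning reports how many). Malformed lines raise with the line
    number.
    """
    weighted = np.zeros(grid.n_bins)  # value * bp
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: {line!r}")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed bedGraph line {lineno}: {line!r}"
                ) from exc
            if chrom != grid.chrom:
                skipped += 1
                continue
            lo = max(start, grid.region_start)
            hi = min(end, grid.region_end)
            if lo >= hi:
                continue
            first = coord_to_bin(grid, lo)
            last = coord_to_bin(grid, hi - 1)
            for b in range(first, last + 1):
                ov = min(hi, grid.bin_end(b)) - max(lo, grid.bin_start(b))
                weighted[b] += value * ov
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} record(s) on other chromosomes", stacklevel=2
        )
    lengths = np.array([grid.bin_length(b) for b in range(grid.n_bins)], dtype=float)
    return CoverageTrack(grid, weighted / lengths, label=str(path), units="raw_count")


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write one record per bin (consecutive zero bins merged), sorted."""
    grid = track.grid
    with open(path, "w") as fh:
        i = 0
        while i < grid.n_bins:
            v = track.values[i]
            if v == 0:
                j = i
                while j + 1 < grid.n_bins and track.values[j + 1] == 0:
                    j += 1
                fh.write(f"{grid.chrom}\t{grid.bin_start(i)}\t{grid.bin_end(j)}\t0\n")
                i = j + 1
            else:
                fh.write(
                    f"{grid.chrom}\t{grid.bin_start(i)}\t{grid.bin_end(i)}\t{v:.10g}\n"
                )
                i += 1


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into interval records."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name, score)
            )
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:.10g}")
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed chrom.sizes line {lineno}")
            sizes[parts[0]] = int(parts[1])
    return sizes


# ---------------------------------------------------------------------------
# COO contact text


_COO_HEADER = "#contactddr-coo"


def read_contact_matrix(path, grid: BinGrid) -> ContactMatrix:
    """Read ``bin_i<TAB>bin_j<TAB>count`` triples (upper triangle sufficient).

    Each triple is mirrored; duplicate triples for the same pair accumulate by
    summation. Missing pairs are 0.
    """
    n = grid.n_bins
    counts = np.zeros((n, n))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed COO line {lineno}: {line!r}")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed COO line {lineno}: {line!r}"
                ) from exc
            if i >= n or j >= n or i < 0 or j < 0:
                raise ValueError(
                    f"{path}: line {lineno}: bin index ({i},{j}) outside grid of {n} bins"
                )
            if c < 0:
                raise ValueError(f"{path}: line {lineno}: negative count {c}")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    return ContactMatrix(grid, counts)


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as sorted COO text."""
    g = matrix.grid
    with open(path, "w") as fh:
        fh.write(
            f"{_COO_HEADER} chrom={g.chrom} start={g.region_start} "
            f"end={g.region_end} bin_width={g.bin_width} "
            f"normalized={int(matrix.normalized)}\n"
        )
        iu, ju = np.triu_indices(matrix.n_bins)
        vals = matrix.counts[iu, ju]
        keep = vals != 0
        for i, j, c in zip(iu[keep], ju[keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{c:.10g}\n")
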
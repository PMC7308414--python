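"""Synthetic Hi-C maps and DSB-responsive γH2Ax tracks.

The generator embodies the contact-dependence hypothesis for the DNA damage
response: the expected γH2Ax signal at every bin is a function of that bin's
contact frequency with the bin containing the double-strand break (DSB). It
produces single-chromosome contact maps with TAD blocks, power-law distance
decay, corner loops between border anchors, a uniform background floor, and
Poisson sequencing noise; and matched γH2Ax/control tracks read off the DSB
bin's virtual-4C profile.

Expected contacts for bins i != j::

    E[i,j] = beta + d(i,j)^-alpha * phi^(# borders strictly between i and j)

with d in bins; loop anchors (consecutive border pairs) additionally receive
``loop_strength`` times their decay term. A border bin is bivalent — it
belongs to both flanking TADs, so no insulation penalty applies between it
and either neighbor (this is what lets a break placed exactly at a border
spread its damage response into both TADs). The diagonal is set to each
row's off-diagonal maximum, the matrix scaled to ``sequencing_depth`` total,
and the self-ligation diagonal is excluded from all downstream analyses.

Scenario variants: ``ctcf_deletion`` multiplies expected intra-TAD contacts
of one TAD by ``contact_reduction`` (an architectural-anchor knockout);
``dsb_with_contact_boost`` multiplies intra-TAD contacts of the DSB's TAD by
``1 + contact_boost`` (post-break contact enhancement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contacts import virtual_4c
from .genome import (
    BinGrid,
    ContactMatrix,
    CoverageTrack,
    GenomicInterval,
    coord_to_bin,
    counts_to_rpkm,
)

__all__ = [
    "SimulationConfig",
    "GammaForwardModel",
    "expected_contacts",
    "sample_matrix",
    "generating_profile",
    "simulate_gammax",
    "simulate_control",
    "scenario_suite",
    "ScenarioResult",
]

SCENARIOS = ("none", "dsb", "ctcf_deletion", "dsb_with_contact_boost")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic locus and its DSB scenarios.

    Defaults describe a 4 Mb cis locus at 10 kb resolution (400 bins) with
    four planted borders (five TADs), unit power-law decay, 0.3 insulation
    attenuation per border crossed, 5x corner loops, and 2M total contacts —
    a desk-scale stand-in for a deeply sequenced single-locus Hi-C map.
    """

    chrom: str = "chrS"
    region_length: int = 4_000_000
    bin_width: int = 10_000
    border_positions: tuple[int, ...] = (800_000, 1_600_000, 2_400_000, 3_200_000)
    decay_exponent: float = 1.0
    insulation_factor: float = 0.3
    loop_strength: float = 5.0
    background: float = 1e-4
    sequencing_depth: float = 2e6
    seed: int = 0
    scenario: str = "none"
    dsb_position: int | None = None
    ctcf_deleted_tad: int | None = None
    contact_reduction: float = 0.5
    contact_boost: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if list(self.border_positions) != sorted(self.border_positions):
            raise ValueError("border_positions must be sorted")
        for b in self.border_positions:
            if not 0 < b < self.region_length:
                raise ValueError(f"border {b} not strictly inside region")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0 < self.insulation_factor <= 1:
            raise ValueError("insulation_factor must be in (0, 1]")
        if min(self.loop_strength, self.background, self.sequencing_depth) < 0:
            raise ValueError("rates must be >= 0")
        if self.scenario in ("dsb", "dsb_with_contact_boost"):
            if self.dsb_position is None:
                raise ValueError(f"scenario {self.scenario!r} needs dsb_position")
            if not 0 <= self.dsb_position < self.region_length:
                raise ValueError("dsb_position outside region")
        if self.scenario == "ctcf_deletion":
            if self.ctcf_deleted_tad is None:
                raise ValueError("ctcf_deletion needs ctcf_deleted_tad")
            if not 0 < self.contact_reduction < 1:
                raise ValueError("contact_reduction must be in (0, 1)")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.chrom, 0, self.region_length, self.bin_width)

    @property
    def border_bins(self) -> list[int]:
        return [coord_to_bin(self.grid, b) for b in self.border_positions]

    def tad_slices(self) -> list[slice]:
        """TAD tiling as bin slices; a border bin starts the downstream TAD."""
        cuts = [0] + self.border_bins + [self.grid.n_bins]
        return [slice(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1)]

    def dsb_interval(self) -> GenomicInterval:
        if self.dsb_position is None:
            raise ValueError("config has no dsb_position")
        return GenomicInterval(
            self.chrom, self.dsb_position, self.dsb_position + 1, name="DSB"
        )


@dataclass(frozen=True)
class GammaForwardModel:
    """Forward model from a viewpoint contact profile to a γH2Ax track.

    Expected signal at bin i is ``b + S * v(i)^g`` for the coverage-normalized
    virtual-4C value v(i) of the DSB bin. The response exponent g defaults to
    1 (linear contact dependence); Poisson mode distributes ``read_depth``
    reads with probabilities proportional to the expected signal and reports
    RPKM.
    """

    scale: float = 1.0
    background: float = 0.5
    exponent: float = 1.0
    noise_mode: str = "poisson"
    read_depth: float = 1e6

    def __post_init__(self) -> None:
        if self.noise_mode not in ("none", "poisson"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.scale < 0 or self.background < 0 or self.exponent <= 0:
            raise ValueError("need scale >= 0, background >= 0, exponent > 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")


def expected_contacts(config: SimulationConfig) -> ContactMatrix:
    """Noise-free expected contact matrix under ``config`` (real valued)."""
    grid = config.grid
    n = grid.n_bins
    if n < 3:
        raise ValueError("degenerate grid: need at least 3 bins")

    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = d ** -config.decay_exponent
    np.fill_diagonal(decay, 0.0)

    # borders strictly between i and j: cumulative count of border bins <= k
    border_bins = np.array(config.border_bins, dtype=int)
    cum = np.zeros(n + 1, dtype=int)  # cum[k] = #border bins <= k-1
    for b in border_bins:
        cum[b + 1 :] += 1
    lo = np.minimum(idx[:, None], idx[None, :])
    hi = np.maximum(idx[:, None], idx[None, :])
    # count border bins t with lo < t < hi  ->  cum[hi] - cum[lo+1]
    crossings = cum[hi] - cum[np.minimum(lo + 1, n)]
    crossings = np.maximum(crossings, 0)

    E = config.background + decay * config.insulation_factor ** crossings
    np.fill_diagonal(E, 0.0)

    # corner loops between consecutive border anchors
    for a, b in zip(border_bins[:-1], border_bins[1:]):
        extra = config.loop_strength * float(abs(b - a)) ** -config.decay_exponent
        E[a, b] += extra
        E[b, a] += extra

    # self-ligation diagonal: row-wise off-diagonal max (masked downstream)
    np.fill_diagonal(E, E.max(axis=1))

    E *= config.sequencing_depth / E.sum()

    # scenario modifications applied after depth scaling so the contrast is
    # exact: targeted TAD scaled, everything else untouched. The diagonal
    # (self-ligation / self-proximity) is left unscaled: extreme short-range
    # proximity is polymer-intrinsic, not extrusion-dependent.
    if config.scenario == "ctcf_deletion":
        sl = config.tad_slices()[config.ctcf_deleted_tad]
        diag = E.diagonal().copy()
        E[sl, sl] *= config.contact_reduction
        np.fill_diagonal(E, diag)
    elif config.scenario == "dsb_with_contact_boost":
        dsb_bin = coord_to_bin(grid, config.dsb_position)
        for sl in config.tad_slices():
            if sl.start <= dsb_bin < sl.stop:
                diag = E.diagonal().copy()
                E[sl, sl] *= 1.0 + config.contact_boost
                np.fill_diagonal(E, diag)
                break

    return ContactMatrix(grid, E)


def sample_matrix(expected: ContactMatrix, seed: int) -> ContactMatrix:
    """Poisson-sample integer counts from an expected matrix (mirrored)."""
    rng = np.random.default_rng(seed)
    n = expected.n_bins
    iu, ju = np.triu_indices(n)
    draws = rng.poisson(expected.counts[iu, ju])
    counts = np.zeros((n, n))
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMatrix(expected.grid, counts)


def generating_profile(matrix: ContactMatrix, dsb: GenomicInterval) -> CoverageTrack:
    """The contact profile that drives γH2Ax deposition at a DSB.

    This is the raw (physical-contact) virtual-4C profile of the DSB
    viewpoint, except that the DSB-containing bin itself takes its
    self-contact (diagonal) value rather than the diagonal-masked row mean:
    the break site is maximally proximal to itself, which is what makes its
    γH2Ax value a stable per-sample normalizer. Raw counts are used — the
    simulator plants no visibility bias, so coverage normalization would
    only couple a planted intra-TAD change back into the profile through
    the marginals.
    """
    v = virtual_4c(matrix, dsb)
    b = coord_to_bin(matrix.grid, dsb.midpoint)
    values = v.values.copy()
    values[b] = matrix.counts[b, b]
    return CoverageTrack(matrix.grid, values, label=v.label, units="contacts")


def simulate_gammax(
    matrix: ContactMatrix,
    dsb: GenomicInterval,
    model: GammaForwardModel,
    seed: int,
) -> CoverageTrack:
    """γH2Ax track generated from the DSB bin's interactome.

    The generating profile is :func:`generating_profile`; the forward model
    ``b + S * v^g`` is applied per bin, with optional Poisson read sampling.
    """
    v = generating_profile(matrix, dsb)
    if not np.any(v.values > 0):
        raise ValueError("all-zero viewpoint row: uninformative viewpoint")
    expected = model.background + model.scale * v.values ** model.exponent
    if model.noise_mode == "none":
        return CoverageTrack(matrix.grid, expected, label="gammaH2Ax", units="RPKM")
    rng = np.random.default_rng(seed)
    p = expected / expected.sum()
    counts = rng.poisson(model.read_depth * p)
    track = CoverageTrack(matrix.grid, counts.astype(float), label="gammaH2Ax")
    return counts_to_rpkm(track)


def simulate_control(grid: BinGrid, model: GammaForwardModel, seed: int) -> CoverageTrack:
    """Flat non-targeting control track under the same noise model."""
    expected = np.full(grid.n_bins, model.background, dtype=float)
    if model.noise_mode == "none":
        return CoverageTrack(grid, expected, label="control", units="RPKM")
    rng = np.random.default_rng(seed)
    if expected.sum() > 0:
        p = expected / expected.sum()
    else:
        p = np.full(grid.n_bins, 1.0 / grid.n_bins)
    counts = rng.poisson(model.read_depth * p)
    track = CoverageTrack(grid, counts.astype(float), label="control")
    return counts_to_rpkm(track)


@dataclass
class ScenarioResult:
    """One simulated scenario with its ground truth.

    ``matrices`` maps condition name -> sampled ContactMatrix (e.g. ``hic``,
    or ``wt``/``ko``, ``pre``/``post``); ``gammax``/``controls`` likewise.
    ``truth`` records the generating parameters a recovery test needs.
    """

    name: str
    config: SimulationConfig
    matrices: dict[str, ContactMatrix]
    gammax: dict[str, CoverageTrack]
    controls: dict[str, CoverageTrack]
    truth: dict


def _mk_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def scenario_suite(
    base_config: SimulationConfig | None = None,
    seed: int = 0,
    model: GammaForwardModel | None = None,
) -> dict[str, ScenarioResult]:
    """Generate the five named DSB scenarios with ground-truth annotations.

    Scenarios: ``mid_tad_dsb`` (break at a TAD center), ``border_proximal_dsb``
    (break one bin inside a border), ``border_dsb`` (break at the bivalent
    border bin), ``ctcf_deletion`` (WT vs anchor-knockout pair, breaks at the
    same position), and ``contact_boost`` (pre/post-break matrix pair).
    """
    cfg = base_config if base_config is not None else SimulationConfig()
    mdl = model if model is not None else GammaForwardModel()
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    bw = cfg.bin_width
    tads = cfg.tad_slices()
    # the central TAD (index 2 of 5 by default) hosts the breaks
    tad_idx = len(tads) // 2
    sl = tads[tad_idx]
    border_bin = sl.start  # bivalent bin at the TAD's upstream border
    mid_bin = (sl.start + sl.stop) // 2
    proximal_bin = border_bin + 1

    def pos(bin_idx: int) -> int:
        return grid.bin_start(bin_idx) + bw // 2

    out: dict[str, ScenarioResult] = {}

    def run_single(name: str, dsb_bin: int, extra_truth: dict) -> None:
        c = replace(cfg, scenario="dsb", dsb_position=pos(dsb_bin))
        mat = sample_matrix(expected_contacts(c), _mk_seed(rng))
        gam = simulate_gammax(mat, c.dsb_interval(), mdl, _mk_seed(rng))
        ctl = simulate_control(grid, mdl, _mk_seed(rng))
        truth = {
            "scenario": name,
            "border_bins": cfg.border_bins,
            "dsb_bin": dsb_bin,
            "tad_index": tad_idx,
            "insulation_factor": cfg.insulation_factor,
            **extra_truth,
        }
        out[name] = ScenarioResult(
            name, c, {"hic": mat}, {"hic": gam}, {"hic": ctl}, truth
        )

    run_single("mid_tad_dsb", mid_bin, {"expected_spread_tads": [tad_idx]})
    run_single(
        "border_proximal_dsb",
        proximal_bin,
        {"expected_spread_tads": [tad_idx], "near_border_bin": border_bin},
    )
    run_single(
        "border_dsb",
        border_bin,
        {"expected_spread_tads": [tad_idx - 1, tad_idx]},
    )

    # WT vs CTCF-anchor-deleted pair, same break position (mid-TAD)
    wt_cfg = replace(cfg, scenario="dsb", dsb_position=pos(mid_bin))
    ko_cfg = replace(
        cfg,
        scenario="ctcf_deletion",
        ctcf_deleted_tad=tad_idx,
        dsb_position=pos(mid_bin),
    )
    wt_mat = sample_matrix(expected_contacts(wt_cfg), _mk_seed(rng))
    ko_mat = sample_matrix(expected_contacts(ko_cfg), _mk_seed(rng))
    dsb = wt_cfg.dsb_interval()
    wt_gam = simulate_gammax(wt_mat, dsb, mdl, _mk_seed(rng))
    ko_gam = simulate_gammax(ko_mat, dsb, mdl, _mk_seed(rng))
    ctl = simulate_control(grid, mdl, _mk_seed(rng))
    out["ctcf_deletion"] = ScenarioResult(
        "ctcf_deletion",
        ko_cfg,
        {"wt": wt_mat, "ko": ko_mat},
        {"wt": wt_gam, "ko": ko_gam},
        {"wt": ctl, "ko": ctl},
        {
            "scenario": "ctcf_deletion",
            "border_bins": cfg.border_bins,
            "dsb_bin": mid_bin,
            "reduced_tad": tad_idx,
            "neighbor_tad": tad_idx - 1,
            "contact_reduction": cfg.contact_reduction,
        },
    )

    # pre/post-break pair with intra-TAD contact enhancement
    pre_cfg = replace(cfg, scenario="none")
    post_cfg = replace(
        cfg, scenario="dsb_with_contact_boost", dsb_position=pos(mid_bin)
    )
    pre_mat = sample_matrix(expected_contacts(pre_cfg), _mk_seed(rng))
    post_mat = sample_matrix(expected_contacts(post_cfg), _mk_seed(rng))
    post_gam = simulate_gammax(
        post_mat, post_cfg.dsb_interval(), mdl, _mk_seed(rng)
    )
    ctl2 = simulate_control(grid, mdl, _mk_seed(rng))
    out["contact_boost"] = ScenarioResult(
        "contact_boost",
        post_cfg,
        {"pre": pre_mat, "post": post_mat},
        {"post": post_gam},
        {"post": ctl2},
        {
            "scenario": "contact_boost",
            "border_bins": cfg.border_bins,
            "dsb_bin": mid_bin,
            "boosted_tad": tad_idx,
            "contact_boost": cfg.contact_boost,
        },
    )
    return out
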
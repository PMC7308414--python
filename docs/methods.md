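# Methods

## Scope and model

`contactddr` analyses the chromatin response to a DNA double-strand break
(DSB) under the contact-dependence hypothesis: the γH2Ax domain that forms
around a break is determined by the break site's chromosomal interactome —
the set of loci it physically contacts — rather than by linear spreading
along the chromosome. The package provides the analysis stages needed to
test that hypothesis on binned single-locus Hi-C data (virtual-4C viewpoint
extraction, insulation-score TAD calling, coverage normalization,
differential contact testing, track correlation, Δ subtraction, broad-domain
calling, overlap testing, paired contrasts, and spreading-asymmetry
statistics) together with a synthetic generator in which the hypothesis is
true by construction, so every stage can be validated against known ground
truth without any external download.

All coordinates are 0-based half-open; a single chromosomal region
(`BinGrid`) is analysed at a time, matching the cis-locus scale of the
analyses the pipeline supports.

## Synthetic locus generator

Expected contacts between bins *i* ≠ *j*:

    E[i,j] = β + d(i,j)^(−α) · φ^(#borders strictly between i and j)

with *d* the bin distance, plus `loop_strength · d^(−α)` added at pairs of
consecutive border ("anchor") bins. A border bin is *bivalent*: it belongs to
both flanking TADs, so contacts between a border bin and either neighbour
carry no φ penalty — this is the generative mechanism by which a break
placed exactly at a border spreads its damage response into both TADs. The
diagonal is set to each row's off-diagonal maximum (self-proximity is
maximal), the matrix is scaled to `sequencing_depth` total counts, and
counts are Poisson-sampled on the upper triangle and mirrored.

Defaults (the "stated world" of the tests): a 4 Mb region in 10 kb bins
(400 bins), borders every 800 kb (five TADs), α = 1, φ = 0.3, loop strength
5, background β = 1e−4 (relative floor before depth scaling), and 2×10⁶
total contacts. The region size gives a desk-scale (~400-bin) map that a
single CPU processes in milliseconds; the depth corresponds to a deeply
sequenced single-locus extraction.

Scenario variants modify the expected matrix *after* depth scaling so the
planted contrast is exact:

- `ctcf_deletion`: off-diagonal pixels with both bins inside one TAD are
  multiplied by ρ (`contact_reduction`, default 0.5), emulating loss of an
  architectural CTCF anchor.
- `dsb_with_contact_boost`: the break-containing TAD's off-diagonal pixels
  are multiplied by 1 + ε (default ε = 1), emulating post-break enhancement
  of intra-locus contacts.

In both cases the diagonal is left untouched: extreme short-range/self
proximity is polymer-intrinsic, not extrusion-dependent. This matters
downstream — the break-site bin's γH2Ax value is the per-sample normalizer,
and it must not absorb the planted contrast (see below).

## γH2Ax forward model

The generating profile *v* of a break is the raw (physical-contact)
virtual-4C row of the DSB bin, with the DSB bin itself taking its
self-contact (diagonal) value instead of the diagonal-masked row mean: the
break site is maximally proximal to itself, which is exactly why its
measured γH2Ax is a stable normalizer across samples. Expected signal is

    γ(i) = b + S · v(i)^g

with linear response g = 1 by default (the response exponent is exposed but
no evidence in the modelled system requires nonlinearity). Poisson mode
distributes `read_depth` reads (default 10⁶) with probabilities ∝ γ and
reports RPKM; the matched non-targeting control is a flat profile at level
*b* under the same noise model.

Two deliberate choices here deviate from a naive composition of the
analysis operators, for reasons the validation itself exposed:

1. **Raw, not coverage-normalized, contacts drive γ.** The simulator plants
   no visibility bias, so there is nothing for vanilla-coverage (VC)
   normalization to correct at generation time; worse, on a locus-scale
   matrix where a whole TAD's contacts were reduced by ρ, that TAD's
   marginals drop by ~ρ and VC divides its pixels by ~ρ², *inverting* the
   planted reduction. VC remains the right preprocessing for analysis-side
   extraction, where real maps carry per-bin visibility differences.
2. **The DSB bin's generated γ is its self-contact.** If the break bin's γ
   were the (diagonal-masked) row mean, it would scale with the TAD-wide
   contact level, and normalizing tracks to the DSB bin would cancel the
   very contrast being tested. With the self-contact convention the
   normalizer is invariant to intra-TAD scenario scaling, and the
   anchor-deletion contrast survives DSB-bin normalization — as it does in
   the real assay, where break-site γH2Ax reflects local cutting, not
   domain topology.

## Analysis operators: numerical choices

- **Coverage normalization** is single-pass vanilla coverage
  (`N = C/(r_i r_j)`, `r_i = marginal_i / mean positive marginal`), with
  zero-marginal bins masked; `vc_sqrt` and multi-pass (`n_iter`) variants
  are exposed. Single-pass VC is *not* idempotent on decay-dominated
  matrices (the bias estimate is contaminated by the local weighting of the
  marginals); the iterated fixed point is stable and is what the tests pin.
- **Virtual 4C** averages the viewpoint rows with the self-ligation diagonal
  excluded; a viewpoint bin reports the mean of its non-self row pixels.
- **Insulation score** at window *w* bins is the mean count in the
  *w* × *w* square of pixels straddling the diagonal, reported as log2 ratio
  to the mean over valid bins; zero square means are floored at half the
  smallest positive mean so degenerate toys stay finite; bins within a
  window of the region edge are NaN. Default windows 20–200 kb in 20 kb
  steps (a 20–100 kb preset is provided). Scores are exactly invariant to
  global matrix scaling.
- **Border calling**: strict local minima of the multi-window consensus;
  depth requirement `delta` (default 0.2) against the mean consensus over
  ±max-window flanks; a one-sided Mann-Whitney rank test of the candidate's
  per-window scores against the flank scores (p ≤ 0.01 by default) stands in
  for the multi-scale significance filter of standard TAD callers, whose
  exact form is tool-internal; candidates closer than the smallest window
  merge keeping the deeper. TADs tile the region between kept borders, the
  region edges acting as outer borders.
- **Differential contacts**: pixels with `max(c1, c2) < 20` are dropped
  (below ~20 counts the MAD-standardized log ratio of Poissons is discrete
  and heavy-tailed, inflating the type-I rate from ~5% to ~10%);
  `M = log2(c2+1) − log2(c1+1)` computed as a difference of logs so swapping
  inputs negates M and Z *exactly*; per-distance strata (merged below 50
  pixels) are centred by the median and scaled by MAD·1.4826; p is the
  two-sided normal tail; Benjamini-Hochberg q-values are appended. This is a
  deliberate robust reduction of loess-based M/Z joint-normalization
  pipelines: identical intent, fewer moving parts.
- **Replicate concordance**: Pearson r of log10(x+1) upper-triangle pixels,
  diagonal excluded, distance-capped on request (the conventional r² > 0.75
  gate is the caller's to apply).
- **Track correlation** uses raw (untransformed) values on length-weighted
  rebinned tracks, dropping bins where both tracks are exactly zero —
  matching how genome-browser table correlators treat track pairs.
- **Fisher overlap** classifies bins by interval-membership masks into a 2×2
  table and computes the two-sided exact p by integer combinatorics
  (hypergeometric numerators share a denominator, so "as or more extreme" is
  an exact integer comparison, with no floating tie tolerance); the sample
  odds ratio reports 0/∞ edges explicitly.
- **Broad-domain calling** scales the control library to the signal total,
  scores sliding windows (default 5 bins) by fold `(s+1)/(c+1)` and the
  upper Poisson tail of the signal count given the scaled control, keeps
  windows with fold ≥ 4 and p ≤ 1e−3, merges within 2 bins, drops calls
  shorter than 3 bins, and re-scores merged calls.
- **Paired t-test**: classical two-sided paired t; all-zero differences give
  t = 0, p = 1; constant nonzero differences report the p = 0 edge. No
  multiple-testing correction is applied to per-TAD contrasts (they are few
  and reported raw); pixel-level differential results carry q-values.
- **Asymmetry index**: extents are the maximal runs up/downstream of the DSB
  bin where the 3-bin running mean stays above background (default: the
  median of the control track); masses are background-subtracted raw values
  (floored at 0) summed over each extent, the DSB bin excluded;
  `A = (M_down − M_up)/(M_down + M_up)`, 0 when both masses vanish.
  **Cross-border fractions** assign background-subtracted mass to TADs by
  length-weighted bin overlap, so fractions are additive and sum to 1 when
  the TADs tile the region.

## What the generator does and does not emulate

Emulated: TAD blocks with power-law decay, corner loops, cross-border
attenuation, Poisson sequencing noise, matched signal/control libraries,
anchor-deletion and post-break contact changes, and the contact→γH2Ax
causal link itself. Not emulated: per-bin visibility bias (mappability,
restriction density), overdispersed biological replicate noise, sub-bin
break placement, loop-extrusion dynamics, trans contacts, and real genome
coordinates. Consequently a green scenario test establishes that the
pipeline *recovers a planted contact-dependent signal at realistic depth
and geometry* — not that the biological effect sizes of any particular
locus are reproduced. Replicate-level variability in particular is purely
Poisson, which is why paired contrasts on synthetic pairs are more
sensitive than their real-data counterparts.

Two known consequences of desk-scale discretization:

- A border-*proximal* break (one bin inside a border) sits at distance 1
  from the bivalent border bin, whose full unpenalized contact mass
  therefore lands on the short side of the domain. At φ = 0.3 this bounds
  the deterministic asymmetry at |A| ≈ 0.43 for every realistic geometry
  we scanned; |A| ≥ 0.5 would require φ ≲ 0.15. The asymmetry contrast
  (mid-TAD |A| ≈ 0.01 vs border-proximal |A| ≈ 0.43) is large and stable,
  but the absolute 0.5 level is not attainable in this stated world.
- A border break and a border-proximal break are one bin apart by
  construction (the real comparison is sub-bin). Their within-TAD profiles
  carry a deterministic one-bin offset of the decay curve that a paired t
  at Poisson depth can detect; compared at equal distance from each break,
  the profiles are near-identical (r > 0.98, mean levels within ~12%),
  which is the form in which the within-TAD equivalence is asserted.

## Determinism

Every sampling routine takes an explicit seed; no global random state is
used. The `reproduce-synthetic` command and the per-stage CLI commands
write JSON manifests (command, parameters, seed, version — no timestamps)
before results, and their outputs are byte-identical across repeated runs
with the same seed.
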
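# contactddr

Analysis toolkit for **contact-dependent DNA damage response (DDR)
profiling**: given binned Hi-C contact maps and γH2Ax coverage tracks around
a DNA double-strand break (DSB), it quantifies how far — and into which
topological domains — the phosphorylated-H2Ax platform spreads, and tests
whether that spread follows the break site's chromosomal interactome.

It is written for chromatin/DDR researchers working at single-locus scale:
virtual-4C extraction, insulation-score TAD calling, coverage normalization,
differential contact testing, γH2Ax domain statistics, and a synthetic-data
generator in which γH2Ax landscapes are contact-determined by construction,
so the whole pipeline is testable without any sequencing data.

## The model

The synthetic locus is a single chromosomal region in fixed-width bins with
expected contacts

```
E[i,j] = β + d(i,j)^(−α) · φ^(# borders strictly between i and j)
```

plus corner loops between consecutive border anchors, Poisson-sampled to a
target depth. A border bin belongs to **both** flanking TADs (no insulation
penalty toward either side). A break at bin *k* deposits γH2Ax according to

```
γ(i) = b + S · v(i)^g ,    v = contact profile of bin k (self-contact at i = k)
```

with Poisson read sampling to RPKM. Analysis operators recover the planted
structure: square-window insulation scores (log2 ratio to expectation) call
the borders; virtual-4C rows correlate with the γ tracks; a
distance-stratified M/Z pixel test (median/MAD per distance, normal tails,
BH q-values) detects planted contact changes; asymmetry and cross-border
statistics formalize "one long and one short domain" and "spreading into
both TADs".

## Worked example

```python
import numpy as np
from contactddr import (
    SimulationConfig, GammaForwardModel, expected_contacts, sample_matrix,
    simulate_gammax, coverage_normalize, virtual_4c, multiscale_insulation,
    call_borders, correlate_tracks, asymmetry_index,
)

cfg = SimulationConfig(scenario="dsb", dsb_position=2_000_000)  # mid-TAD break
hic = sample_matrix(expected_contacts(cfg), seed=1)
gamma = simulate_gammax(hic, cfg.dsb_interval(), GammaForwardModel(), seed=2)

norm = coverage_normalize(hic)
borders = call_borders(multiscale_insulation(norm), delta=0.2, p_threshold=0.01)
print("called border bins:", borders.border_bins)

v4c = virtual_4c(norm, cfg.dsb_interval())
print("gamma vs viewpoint r =", round(correlate_tracks(gamma, v4c).r, 3))

A = asymmetry_index(gamma, cfg.dsb_interval(), background=float(np.median(gamma.values)))
print("asymmetry index A =", round(A.A, 3))
```

prints (seed-exact):

```
called border bins: [79, 160, 239, 320]
gamma vs viewpoint r = 0.883
asymmetry index A = -0.006
```

The four planted borders (truth: bins 80, 160, 240, 320) are recovered
within one bin; the γ track correlates with the break's virtual-4C profile
(r against the raw generating profile exceeds 0.999 — the 0.88 here reflects
the diagonal-masked viewpoint convention of the extraction operator, and
decoy viewpoints reach only r ≈ 0.2–0.46); and a mid-TAD break spreads
symmetrically (A ≈ 0).

## Analysis drivers and CLI

Numbered drivers under `analysis/` run the full synthetic study and write
tables under `results/` (large regenerable artifacts go to `scratch/`):

| driver | what it does |
|---|---|
| `01_simulate_locus.py` | generate the five DSB scenarios + ground truth |
| `02_call_tad_borders.py` | insulation → border calls → recall vs truth |
| `03_viewpoint_correlation.py` | γ vs true/decoy virtual-4C viewpoints |
| `04_differential_contacts.py` | WT/KO and pre/post M/Z pixel tests + null calibration |
| `05_ddr_quantification.py` | asymmetry, cross-border mass, paired contrasts, domain calls |

The same stages are exposed as a CLI (`contactddr simulate | v4c |
insulation | borders | correlate | subtract | domains | fisher | asymmetry |
paired-test | hic-corr | hic-compare | reproduce-synthetic`); every
subcommand writes a JSON manifest (parameters, seed, version) and output is
byte-deterministic for a fixed seed.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the end-to-end synthetic reproduction from scratch — 20 seeded
scenario suites pushed through border calling, viewpoint correlation,
asymmetry/cross-border quantification, paired contrasts, and differential
contact testing — and writes the results JSON to `--out` (with a
human-readable per-scenario summary alongside).
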
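"""Quantify the damage-response platforms: spreading, asymmetry, contrasts.

Runs the γH2Ax quantifications over 20 seeded scenario suites: asymmetry
indices for mid-TAD vs border-proximal breaks, cross-border mass fractions
for a break placed at the border bin, DSB-bin-normalized paired t contrasts
for the CTCF-deletion pair, and broad-domain calls against the non-targeting
control. Writes results/ddr_quantification_*.tsv.

Findings at the stated world: a mid-TAD break is balanced (|A| < 0.03), a
border-proximal break is strongly skewed (|A| ~ 0.43; the bivalent border
bin adjacent to the break carries full contact mass, which bounds |A| below
~0.45 at phi = 0.3), a border break sends >= 42% of its γ mass into each
flanking TAD, and the anchor-deleted TAD loses γ coverage significantly
while its neighbor never does.
"""

import numpy as np
import pandas as pd

from contactddr.cli import run_synthetic_reproduction
from contactddr.ddr import call_domains
from contactddr.genome import bin_intervals, GenomicInterval
from contactddr.simulate import scenario_suite

N_SEEDS = 20


def main() -> None:
    tables = run_synthetic_reproduction(n_seeds=N_SEEDS, base_seed=0)
    for key in ("asymmetry", "cross_border", "paired_tests"):
        tables[key].to_csv(f"results/ddr_quantification_{key}.tsv",
                           sep="\t", index=False)

    asym = tables["asymmetry"]
    piv = asym.pivot(index="seed", columns="scenario", values="A").abs()
    print("asymmetry |A| (mid vs border-proximal):")
    print(piv.describe().loc[["mean", "min", "max"]].to_string())

    cbf = tables["cross_border"]
    print(f"\nborder-DSB flanking-TAD mass fractions: "
          f"min upstream {cbf.frac_upstream_tad.min():.3f}, "
          f"min DSB-TAD {cbf.frac_dsb_tad.min():.3f}")

    pt = tables["paired_tests"]
    ctcf = pt[pt.contrast == "ctcf_deletion"]
    print(f"CTCF deletion: target-TAD p<0.05 in "
          f"{int((ctcf.p_target_tad < 0.05).sum())}/{len(ctcf)}, "
          f"neighbor-TAD in {int((ctcf.p_neighbor_tad < 0.05).sum())}/{len(ctcf)}")

    # broad-domain calling on one representative seed
    suite = scenario_suite(seed=0)
    sc = suite["mid_tad_dsb"]
    call = call_domains(sc.gammax["hic"], sc.controls["hic"])
    grid = sc.config.grid
    dsb_mask = bin_intervals([sc.config.dsb_interval()], grid)
    rows = [dict(start=iv.start, end=iv.end, fold=f, p=p)
            for iv, f, p in zip(call.intervals, call.fold, call.p)]
    pd.DataFrame(rows).to_csv("results/ddr_quantification_domains.tsv",
                              sep="\t", index=False)
    covers = any(
        iv.start <= grid.bin_start(int(np.flatnonzero(dsb_mask)[0])) < iv.end
        for iv in call.intervals
    )
    print(f"\ndomain calls (seed 0, mid-TAD break): {len(call.intervals)}; "
          f"break covered: {covers}")


if __name__ == "__main__":
    main()
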
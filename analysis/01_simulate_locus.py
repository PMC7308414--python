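"""Generate the synthetic locus: five DSB scenarios with ground truth.

Simulates a 4 Mb cis locus (10 kb bins, five TADs) and the five break
scenarios — mid-TAD, border-proximal, border, CTCF-anchor deletion pair, and
pre/post contact-boost pair — and writes contact matrices (COO text), γH2Ax
and control tracks (bedGraph), true border BEDs and truth records under
scratch/scenarios/ (several MB of regenerable text; downstream drivers
re-simulate in memory rather than reading these back).

Run from the repository root:  python analysis/01_simulate_locus.py [seed]
"""

import json
import sys
from pathlib import Path

from contactddr.genome import GenomicInterval, write_bed, write_bedgraph, write_contact_matrix
from contactddr.simulate import scenario_suite

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("scratch/scenarios")


def main() -> None:
    suite = scenario_suite(seed=SEED)
    for name, sc in suite.items():
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        for key, mat in sc.matrices.items():
            write_contact_matrix(mat, d / f"matrix_{key}.coo.txt")
        for key, tr in sc.gammax.items():
            write_bedgraph(tr, d / f"gammax_{key}.bedgraph")
        for key, tr in sc.controls.items():
            write_bedgraph(tr, d / f"control_{key}.bedgraph")
        grid = sc.config.grid
        write_bed(
            [
                GenomicInterval(grid.chrom, grid.bin_start(b), grid.bin_end(b), "border")
                for b in sc.truth["border_bins"]
            ],
            d / "true_borders.bed",
        )
        (d / "truth.json").write_text(json.dumps(sc.truth, indent=2) + "\n")
        print(f"{name}: {len(sc.matrices)} matrices, DSB bin {sc.truth.get('dsb_bin')}")
    print(f"wrote {len(suite)} scenarios to {OUT} (seed {SEED})")


if __name__ == "__main__":
    main()
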
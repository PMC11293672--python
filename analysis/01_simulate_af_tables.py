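"""Generate the synthetic two-generation allele-frequency data set.

Emulates the study design at reduced scale: 8 closed lines (4 HR, 4 C),
drifted for 22 and 61 generations at Ne = 20, with planted differentiated
regions that "churn" — two blocks differentiated at generation 22 only, one
at generation 61 only, and one persistent — plus a truth table for scoring.

Writes results/synthetic/{g22,g61}.tsv and truth.tsv.
"""

from pathlib import Path

import numpy as np

from hrscan.afdata import write_af_table
from hrscan.synthdata import PlantedRegion, SynthConfig, generate_selected, truth_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2024

PLANTED = (
    PlantedRegion("chr1", 12_000_000, 400_000, 30, 0.5, active=("g22",)),
    PlantedRegion("chr1", 55_000_000, 400_000, 30, 0.5, active=("g22",)),
    PlantedRegion("chr2", 20_000_000, 400_000, 30, 0.5, active=("g61",)),
    PlantedRegion("chr2", 60_000_000, 400_000, 30, 0.5, active=("g22", "g61")),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(
        n_loci=4000,
        chromosomes={"chr1": 100_000_000, "chr2": 90_000_000},
        generations=22,
        planted=PLANTED,
    )
    rng = np.random.default_rng(SEED)
    g22, g61 = generate_selected(cfg, rng, two_generations=True)
    write_af_table(g22, OUT / "g22.tsv")
    write_af_table(g61, OUT / "g61.tsv")
    truth_frame(cfg).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"wrote {g22.n_loci} loci x {g22.design.n_lines} lines per generation")
    print(f"planted {len(PLANTED)} regions "
          f"({sum('g22' in r.active for r in PLANTED)} active at g22, "
          f"{sum('g61' in r.active for r in PLANTED)} at g61)")


if __name__ == "__main__":
    main()
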
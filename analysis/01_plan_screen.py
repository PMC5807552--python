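#!/usr/bin/env python
"""Screen-planning arithmetic for the reference 710-gene library.

Computes how many cells must be transduced and seeded to keep 1,000×
per-hairpin coverage at 8.5% single-copy transduction efficiency, and
how much genomic-DNA template the readout PCR needs to preserve 1,000×
representation.  Writes results/experiment_plan.json.
"""

import json
from pathlib import Path

import fluxscreen as fs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    plan = fs.plan_experiment(
        n_shrna=4184, coverage=1000, efficiency=0.085,
        representation=1000, genome_mass_pg=6.5,
    )
    print(f"transduced cells needed : {plan.transduced_cells_needed:,}")
    print(f"seeded cells needed     : {plan.seeded_cells_needed:,} "
          f"(~{plan.seeded_cells_needed / 1e6:.1f} million)")
    print(f"PCR template mass       : {plan.pcr_template_mass_ug:.3f} µg "
          f"(≈ {plan.pcr_template_mass_ug_rounded} µg)")

    OUT.mkdir(exist_ok=True)
    (OUT / "experiment_plan.json").write_text(json.dumps({
        "n_shrna": 4184,
        "coverage": 1000,
        "transduction_efficiency": 0.085,
        "transduced_cells_needed": plan.transduced_cells_needed,
        "seeded_cells_needed": plan.seeded_cells_needed,
        "pcr_template_mass_ug": plan.pcr_template_mass_ug,
    }, indent=2) + "\n")
    print(f"\nwrote {OUT / 'experiment_plan.json'}")


if __name__ == "__main__":
    main()
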
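"""End-to-end benchmark scenarios for the screen pipeline.

These run the full simulate → score → call-hits chain under defined
study conditions and measure calibration and recovery:

* **Null calibration** — a screen with no true regulators; measures the
  fraction of hairpins spuriously reaching the three-fold geomean rule.
* **Parameter recovery** — a screen with a known set of full-effect
  regulator genes among nulls; measures whether the ≥3-scoring-hairpin
  gene rule recovers exactly the true regulators.
* **Flux recovery** — event-table simulation plus percent-of-control
  summary; measures whether the configured GFP quench factor is read
  back from the cytometry analysis.
* **Overlap recovery** — spot-pair stacks at controlled support overlap
  plus detection and overlap classification; measures the largest
  deviation between constructed and measured overlap fractions.

Problem sizes default to reduced but well-powered versions of the
reference screen (hundreds of hairpins rather than 4,184) so a full
multi-seed benchmark completes in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import detect_spots, overlap_classify
from .events_sim import EventSimConfig, simulate_events
from .flux import summarize_flux
from .image_sim import ImageSimConfig, SpotPairSpec, simulate_image_stack
from .library import simulate_library
from .scoring import score_screen
from .screen_sim import ScreenSimConfig, TrueEffectModel, simulate_screen_counts


@dataclass
class NullCalibration:
    scoring_fraction: float        # over all runs and hairpins
    per_run_fractions: list[float]
    n_runs: int
    n_shrnas: int


def run_null_calibration(
    n_genes: int = 50,
    shrnas_per_gene: int = 4,
    coverage: int = 200,
    depth_per_shrna: int = 100,
    quench_factor: float = 0.2,
    n_runs: int = 10,
    seed: int = 0,
) -> NullCalibration:
    """Fraction of hairpins reaching the three-fold geomean rule when no
    gene has any effect (pure gate/sequencing noise)."""
    n_shrna = n_genes * shrnas_per_gene
    fractions = []
    for run in range(n_runs):
        lib = simulate_library(n_genes, 0, n_shrna, guide_length=18, seed=seed + run)
        effects = TrueEffectModel.build(lib, None, efficacy=0.85,
                                        quench_factor=quench_factor)
        cfg = ScreenSimConfig(
            n_cells_per_shrna=coverage,
            sequencing_depth=depth_per_shrna * n_shrna,
            seed=seed + run,
        )
        counts, _ = simulate_screen_counts(lib, effects, cfg)
        scores, _ = score_screen(counts, lib.gene_of())
        fractions.append(float(scores["scoring"].mean()))
    return NullCalibration(
        scoring_fraction=float(np.mean(fractions)),
        per_run_fractions=fractions,
        n_runs=n_runs,
        n_shrnas=n_shrna,
    )


@dataclass
class ParameterRecovery:
    n_runs: int
    n_regulators: int
    runs_all_regulators_called: int
    runs_without_false_genes: int
    per_run_called: list[set]
    regulator_genes: set


def run_parameter_recovery(
    n_null_genes: int = 25,
    n_regulator_genes: int = 5,
    shrnas_per_gene: int = 4,
    efficacy: float = 0.85,
    quench_factor: float = 0.2,
    coverage: int = 500,
    depth_per_shrna: int = 200,
    n_runs: int = 10,
    seed: int = 0,
) -> ParameterRecovery:
    """Hit-calling accuracy on screens with planted full-effect regulators.

    Regulator genes get effect 1.0; every hairpin the stated knockdown
    efficacy.  A run counts as a success when every regulator gene (and,
    separately, no null gene) passes the ≥3-scoring-hairpin rule.
    """
    n_genes = n_null_genes + n_regulator_genes
    n_shrna = n_genes * shrnas_per_gene
    all_called: list[set] = []
    regulator_genes: set = set()
    for run in range(n_runs):
        lib = simulate_library(
            n_null_genes, n_regulator_genes, n_shrna, guide_length=18, seed=seed + run
        )
        regulator_genes = set(
            lib.genes.loc[lib.genes["gene_class"] == "autophagy_control", "gene"]
        )
        effects = TrueEffectModel.build(
            lib, {g: 1.0 for g in regulator_genes},
            efficacy=efficacy, quench_factor=quench_factor,
        )
        cfg = ScreenSimConfig(
            n_cells_per_shrna=coverage,
            sequencing_depth=depth_per_shrna * n_shrna,
            seed=seed + run,
        )
        counts, _ = simulate_screen_counts(lib, effects, cfg)
        _, hits = score_screen(counts, lib.gene_of())
        all_called.append(set(hits["gene"]))
    return ParameterRecovery(
        n_runs=n_runs,
        n_regulators=n_regulator_genes,
        runs_all_regulators_called=sum(
            1 for called in all_called if regulator_genes <= called
        ),
        runs_without_false_genes=sum(
            1 for called in all_called if not (called - regulator_genes)
        ),
        per_run_called=all_called,
        regulator_genes=regulator_genes,
    )


def run_flux_recovery(
    quench_factor: float = 0.2,
    flux_block: float = 0.0,
    n_events: int = 5000,
    seed: int = 0,
) -> dict:
    """Simulate a reporter line and read back the starved GFP percent."""
    cfg = EventSimConfig(
        n_events=n_events, flux_block=flux_block,
        quench_factor=quench_factor, seed=seed,
    )
    summ = summarize_flux(simulate_events(cfg), cfg.control_condition)
    row = summ[(summ.condition == "Starv") & (summ.channel == "gfp")]
    return {
        "percent_mean": float(row["percent_mean"].iloc[0]),
        "percent_sd": float(row["percent_sd"].iloc[0]),
        "expected_percent": 100.0 * (quench_factor + (1 - quench_factor) * flux_block)
        if flux_block in (0.0, 1.0)
        else float("nan"),
        "n_events": n_events,
    }


def run_overlap_recovery(
    targets: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    radius: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-free spot pairs at controlled overlap, re-measured through
    detection and classification.  Returns one row per pair with the
    constructed (``truth``) and measured overlap fractions."""
    spacing = 40
    per_row = 2
    centers = [
        (12.0, 24.0 + spacing * (i // per_row), 24.0 + spacing * (i % per_row))
        for i in range(len(targets))
    ]
    shape = (
        24,
        int(24 + spacing * ((len(targets) - 1) // per_row) + 24),
        int(24 + spacing * (per_row - 1) + 24),
    )
    cfg = ImageSimConfig(
        shape=shape,
        pairs=[
            SpotPairSpec(center=c, overlap=t, radius_a=radius, radius_b=radius)
            for c, t in zip(centers, targets)
        ],
        seed=seed,
    )
    stack, truth = simulate_image_stack(cfg)
    spots_a = detect_spots(stack[0])
    spots_b = detect_spots(stack[1])
    res = overlap_classify(spots_a, spots_b)

    truth_a = truth[truth.channel == "A"].reset_index(drop=True)
    rows = []
    for _, spot in spots_a.table.iterrows():
        d = np.linalg.norm(
            truth_a[["z", "y", "x"]].to_numpy()
            - spot[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(),
            axis=1,
        )
        i = int(d.argmin())
        measured = float(
            res.pairs.loc[res.pairs.label_a == spot["label"], "overlap_fraction"].iloc[0]
        )
        rows.append(
            {
                "target": float(truth_a["overlap"].iloc[i]),
                "measured": measured,
                "error": measured - float(truth_a["overlap"].iloc[i]),
            }
        )
    out = pd.DataFrame(rows).sort_values("target").reset_index(drop=True)
    out["n_detected_a"] = len(spots_a)
    out["n_detected_b"] = len(spots_b)
    return out
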
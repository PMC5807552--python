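"""Generative model of the FACS-sorted pooled knockdown screen.

Each transduced cell carries one hairpin and expresses a tandem
mCherry-EGFP-LC3B reporter.  Upon starvation, cells with functional
autophagic flux deliver the reporter to the lysosome where low pH
quenches EGFP; knockdown of a flux-required gene blocks that quenching,
so blocked cells retain high GFP.  Sorting the starved pool into
GFP-high and GFP-low gates and sequencing the hairpins in each gate
turns a cell-level phenotype into hairpin read counts.

The simulator instantiates cells at a configured per-shRNA coverage,
draws each cell's flux-block state from the product of its gene's effect
size and its hairpin's knockdown efficacy, draws log-normal GFP
(quenched for flux-competent cells), gates on pooled-GFP percentiles,
and samples sequencing counts multinomially (optionally
Dirichlet-overdispersed) from each gate's hairpin composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .library import LibraryDesign


@dataclass
class TrueEffectModel:
    """Ground-truth effect sizes for a simulated screen.

    ``gene_effect`` maps gene → flux-block strength in [0, 1] (0 = no
    autophagy role), ``shrna_efficacy`` maps shrna_id → knockdown
    efficacy in [0, 1]; a cell's probability of blocked flux is their
    product.  ``quench_factor`` is the multiplicative GFP reduction when
    the reporter reaches an acidified autolysosome.
    """

    gene_effect: pd.Series
    shrna_efficacy: pd.Series
    quench_factor: float = 0.2

    def __post_init__(self) -> None:
        self.gene_effect = pd.Series(self.gene_effect, dtype=float)
        self.shrna_efficacy = pd.Series(self.shrna_efficacy, dtype=float)
        for name, s in (("gene_effect", self.gene_effect),
                        ("shrna_efficacy", self.shrna_efficacy)):
            if ((s < 0) | (s > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")
        if not 0 < self.quench_factor <= 1:
            raise ValueError("quench_factor must lie in (0, 1]")

    @classmethod
    def build(
        cls,
        library: LibraryDesign,
        gene_effect: Mapping[str, float] | None = None,
        efficacy: float | Mapping[str, float] = 0.85,
        quench_factor: float = 0.2,
    ) -> "TrueEffectModel":
        """Construct effects over a library: unlisted genes get effect 0."""
        ge = pd.Series(0.0, index=library.genes["gene"].to_numpy())
        if gene_effect:
            for g, e in gene_effect.items():
                if g not in ge.index:
                    raise KeyError(f"unknown gene {g!r}")
                ge[g] = e
        ids = library.shrnas["shrna_id"].to_numpy()
        if isinstance(efficacy, Mapping):
            eff = pd.Series({i: efficacy.get(i, 0.0) for i in ids})
        else:
            eff = pd.Series(float(efficacy), index=ids)
        return cls(gene_effect=ge, shrna_efficacy=eff, quench_factor=quench_factor)

    def block_probability(self, library: LibraryDesign) -> pd.Series:
        """Per-shRNA flux-block probability = gene effect × efficacy."""
        genes = library.shrnas["gene"].to_numpy()
        ids = library.shrnas["shrna_id"].to_numpy()
        p = self.gene_effect.reindex(genes).to_numpy() * self.shrna_efficacy.reindex(ids).to_numpy()
        return pd.Series(p, index=ids)


@dataclass
class ScreenSimConfig:
    """Knobs of the sorted-screen simulator.

    ``n_cells_per_shrna`` is the coverage carried through sorting (the
    reference screen kept 1,000 cells per hairpin).
    ``sequencing_depth`` is reads per sorted-population sample.  Gates
    default to the outer deciles of the pooled starved GFP distribution.
    ``overdispersion`` (a Dirichlet concentration; ``None`` = pure
    multinomial) adds extra-multinomial count noise; the multinomial
    default keeps every column sum exactly equal to the depth and the
    null fold change analytically centred at 1.
    """

    n_cells_per_shrna: int = 1000
    transduction_efficiency: float = 0.085
    sequencing_depth: int = 500_000
    n_replicates: int = 2
    gate_low_pct: float = 10.0
    gate_high_pct: float = 90.0
    overdispersion: float | None = None
    gfp_mean_log: float = math.log(1000.0)
    gfp_sd_log: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_shrna <= 0:
            raise ValueError("n_cells_per_shrna must be positive")
        if not 0 < self.transduction_efficiency <= 1:
            raise ValueError("transduction_efficiency must be in (0, 1]")
        if self.sequencing_depth < 0:
            raise ValueError("sequencing_depth must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0 <= self.gate_low_pct < self.gate_high_pct <= 100:
            raise ValueError("need 0 <= gate_low_pct < gate_high_pct <= 100")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")


def _pool_counts(
    rng: np.random.Generator,
    pool_shrna: np.ndarray,
    n_shrna: int,
    depth: int,
    overdispersion: float | None,
) -> np.ndarray:
    """Sequence one sorted pool: multinomial reads over its composition."""
    if depth == 0:
        return np.zeros(n_shrna, dtype=np.int64)
    if pool_shrna.size == 0:
        raise ValueError("sorted pool is empty but sequencing_depth > 0")
    cells = np.bincount(pool_shrna, minlength=n_shrna)
    p = cells / cells.sum()
    if overdispersion is not None:
        nz = p > 0
        alpha = p[nz] * overdispersion
        p = np.zeros_like(p)
        p[nz] = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def simulate_screen_counts(
    library: LibraryDesign,
    effects: TrueEffectModel,
    cfg: ScreenSimConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the sorted screen and return (counts, ground truth).

    Returns the shRNA × sample count matrix with columns
    ``rep{i}_high`` / ``rep{i}_low`` and a per-gene ground-truth table
    (``gene``, ``effect``, ``is_regulator``).
    """
    missing = set(library.shrnas["gene"]) - set(effects.gene_effect.index)
    if missing:
        raise ValueError(f"effects missing genes: {sorted(missing)[:5]}")
    missing_sh = set(library.shrna_ids) - set(effects.shrna_efficacy.index)
    if missing_sh:
        raise ValueError(f"effects missing shRNAs: {sorted(missing_sh)[:5]}")

    rng = np.random.default_rng(cfg.seed)
    n = library.n_shrnas
    p_block = effects.block_probability(library).to_numpy()

    columns: dict[str, np.ndarray] = {}
    for rep in range(1, cfg.n_replicates + 1):
        cell_shrna = np.repeat(np.arange(n), cfg.n_cells_per_shrna)
        blocked = rng.random(cell_shrna.size) < p_block[cell_shrna]
        gfp = np.exp(rng.normal(cfg.gfp_mean_log, cfg.gfp_sd_log, cell_shrna.size))
        gfp[~blocked] *= effects.quench_factor
        lo = np.percentile(gfp, cfg.gate_low_pct)
        hi = np.percentile(gfp, cfg.gate_high_pct)
        for label, pool in (("high", cell_shrna[gfp >= hi]),
                            ("low", cell_shrna[gfp <= lo])):
            columns[f"rep{rep}_{label}"] = _pool_counts(
                rng, pool, n, cfg.sequencing_depth, cfg.overdispersion
            )

    counts = pd.DataFrame(columns, index=pd.Index(library.shrna_ids, name="shrna_id"))
    truth = pd.DataFrame(
        {
            "gene": effects.gene_effect.index,
            "effect": effects.gene_effect.to_numpy(),
            "is_regulator": effects.gene_effect.to_numpy() > 0,
        }
    )
    return CountMatrix(counts=counts), truth


def simulate_fastq(
    counts: CountMatrix,
    library: LibraryDesign,
    out: str | Path,
) -> int:
    """Write error-free barcoded guide reads realizing a count matrix.

    Each read is the sample barcode immediately followed by the guide
    sequence at constant quality; the number of reads per (sample,
    shRNA) equals the corresponding count cell.  Returns total reads
    written.  Round trip through :func:`fluxscreen.counts.count_guides`
    recovers the matrix exactly.
    """
    out = Path(out)
    unknown = set(counts.shrna_ids) - set(library.shrna_ids)
    if unknown:
        raise ValueError(f"counts reference unknown shRNAs: {sorted(unknown)[:5]}")
    missing_bc = set(counts.sample_ids) - set(library.sample_barcodes)
    if missing_bc:
        raise ValueError(f"no barcode for samples: {sorted(missing_bc)}")

    guide = library.shrnas.set_index("shrna_id")["guide"]
    total = 0
    qual = "I" * (library.barcode_length + library.guide_length)
    with out.open("w") as fh:
        for sample in counts.sample_ids:
            bc = library.sample_barcodes[sample]
            col = counts.counts[sample]
            for shrna_id, c in col.items():
                if c == 0:
                    continue
                seq = bc + guide[shrna_id]
                for i in range(int(c)):
                    fh.write(f"@{sample}:{shrna_id}:{i}\n{seq}\n+\n{qual}\n")
                total += int(c)
    return total
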
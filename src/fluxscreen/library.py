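"""shRNA library manifests and screen-planning arithmetic.

A pooled knockdown screen starts from a library design: a set of target
genes, several hairpins (shRNAs) per gene each identified by its guide
sequence, and per-sample barcodes used to demultiplex the sequencing
readout of the sorted populations.  The screen modelled here targets
ubiquitin-pathway genes plus a panel of established autophagy regulators
used as positive controls (710 genes, 4,184 shRNAs in the reference
design).

The planning helpers compute the cell numbers and PCR template mass
needed to maintain a given per-shRNA representation through the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))

#: Default sorted-population sample ids: two replicates, two FACS gates.
DEFAULT_SAMPLES: tuple[str, ...] = ("rep1_high", "rep1_low", "rep2_high", "rep2_low")

#: Mass of one diploid mouse genome in picograms; used to convert
#: template genome copies to PCR input mass.
MOUSE_GENOME_MASS_PG = 6.5


def _random_unique_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw ``n`` distinct random nucleotide strings of the given length."""
    if 4**length < n:
        raise ValueError(
            f"cannot draw {n} unique sequences of length {length}: "
            f"only 4^{length} = {4**length} exist"
        )
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


@dataclass
class LibraryDesign:
    """Gene→shRNA manifest with guide sequences and sample barcodes.

    Attributes
    ----------
    genes:
        One row per gene: ``gene``, ``gene_class`` (``ubiquitin_regulator``
        or ``autophagy_control``).
    shrnas:
        One row per hairpin: ``shrna_id``, ``gene``, ``gene_class``,
        ``guide`` (fixed-length nucleotide string).
    sample_barcodes:
        Mapping sample id → barcode nucleotide string (all equal length).
    """

    genes: pd.DataFrame
    shrnas: pd.DataFrame
    sample_barcodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shrnas["shrna_id"].duplicated().any():
            raise ValueError("shrna_ids must be unique")
        if self.shrnas["guide"].duplicated().any():
            raise ValueError("guide sequences must be unique")
        lengths = self.shrnas["guide"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError("guide sequences must share one length")
        unknown = set(self.shrnas["gene"]) - set(self.genes["gene"])
        if unknown:
            raise ValueError(f"shRNAs reference unlisted genes: {sorted(unknown)[:5]}")
        bcs = list(self.sample_barcodes.values())
        if len(set(bcs)) != len(bcs):
            raise ValueError("sample barcodes must be unique")
        if bcs and len({len(b) for b in bcs}) > 1:
            raise ValueError("sample barcodes must share one length")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_shrnas(self) -> int:
        return len(self.shrnas)

    @property
    def guide_length(self) -> int:
        return len(self.shrnas["guide"].iloc[0])

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.sample_barcodes.values())))

    @property
    def shrna_ids(self) -> list[str]:
        return self.shrnas["shrna_id"].tolist()

    def gene_of(self) -> pd.Series:
        """shrna_id → gene mapping as a Series."""
        return self.shrnas.set_index("shrna_id")["gene"]

    def to_tsv(self, path: str | Path) -> None:
        """Write the manifest as TSV; barcodes stored as header comments."""
        path = Path(path)
        with path.open("w") as fh:
            for sample, bc in self.sample_barcodes.items():
                fh.write(f"# barcode\t{sample}\t{bc}\n")
            self.shrnas.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryDesign":
        path = Path(path)
        barcodes: dict[str, str] = {}
        header_lines = 0
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "# barcode" and len(parts) == 3:
                    barcodes[parts[1]] = parts[2]
        shrnas = pd.read_csv(path, sep="\t", skiprows=header_lines)
        genes = (
            shrnas[["gene", "gene_class"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        return cls(genes=genes, shrnas=shrnas, sample_barcodes=barcodes)


def simulate_library(
    n_ubiquitin: int = 680,
    n_autophagy: int = 30,
    total_shrnas: int = 4184,
    guide_length: int = 22,
    seed: int = 0,
    sample_ids: Sequence[str] = DEFAULT_SAMPLES,
    barcode_length: int = 6,
) -> LibraryDesign:
    """Generate a screen library manifest.

    shRNAs are split over genes as evenly as possible; when
    ``total_shrnas`` is not a multiple of the gene count the remainder is
    assigned one extra hairpin per gene in deterministic gene order.
    Guide sequences and sample barcodes are sampled uniquely at random.

    Raises
    ------
    ValueError
        If fewer shRNAs than genes are requested, or the requested number
        of unique guides/barcodes cannot exist at the given length.
    """
    n_genes = n_ubiquitin + n_autophagy
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if total_shrnas < n_genes:
        raise ValueError("need at least one shRNA per gene")
    if guide_length < 8:
        raise ValueError("guide_length must be >= 8")
    rng = np.random.default_rng(seed)

    gene_names = [f"Ubr{i + 1:04d}" for i in range(n_ubiquitin)] + [
        f"Atc{i + 1:03d}" for i in range(n_autophagy)
    ]
    gene_classes = ["ubiquitin_regulator"] * n_ubiquitin + [
        "autophagy_control"
    ] * n_autophagy
    genes = pd.DataFrame({"gene": gene_names, "gene_class": gene_classes})

    base, rem = divmod(total_shrnas, n_genes)
    per_gene = [base + (1 if i < rem else 0) for i in range(n_genes)]
    guides = _random_unique_kmers(rng, total_shrnas, guide_length)

    rows = []
    k = 0
    for gname, gclass, count in zip(gene_names, gene_classes, per_gene):
        for j in range(count):
            rows.append((f"{gname}.sh{j + 1}", gname, gclass, guides[k]))
            k += 1
    shrnas = pd.DataFrame(rows, columns=["shrna_id", "gene", "gene_class", "guide"])

    barcodes = _random_unique_kmers(rng, len(sample_ids), barcode_length)
    return LibraryDesign(
        genes=genes,
        shrnas=shrnas,
        sample_barcodes=dict(zip(sample_ids, barcodes)),
    )


@dataclass(frozen=True)
class ExperimentPlan:
    """Cell numbers and PCR template mass for a planned screen.

    ``transduced_cells_needed`` is library size × per-shRNA coverage;
    ``seeded_cells_needed`` scales that by the single-copy transduction
    efficiency; ``pcr_template_mass_ug`` converts the genome copies
    needed to keep the stated representation into micrograms of genomic
    DNA template.
    """

    transduced_cells_needed: int
    seeded_cells_needed: int
    pcr_template_mass_ug: float

    @property
    def pcr_template_mass_ug_rounded(self) -> int:
        return round(self.pcr_template_mass_ug)


def plan_experiment(
    n_shrna: int,
    coverage: int = 1000,
    efficiency: float = 0.085,
    representation: int = 1000,
    genome_mass_pg: float = MOUSE_GENOME_MASS_PG,
) -> ExperimentPlan:
    """Compute the screen-planning arithmetic.

    Parameters
    ----------
    n_shrna:
        Library size (number of hairpins).
    coverage:
        Cells per shRNA to maintain through selection and sorting.
    efficiency:
        Fraction of seeded cells that receive a single hairpin copy.
    representation:
        Genome copies per shRNA carried into the readout PCR.
    genome_mass_pg:
        Mass of one genome in picograms (diploid mouse ≈ 6.5 pg).
    """
    if min(n_shrna, coverage, representation) <= 0:
        raise ValueError("n_shrna, coverage and representation must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if genome_mass_pg <= 0:
        raise ValueError("genome_mass_pg must be positive")
    transduced = n_shrna * coverage
    seeded = math.ceil(transduced / efficiency)
    mass_ug = representation * n_shrna * genome_mass_pg / 1e6  # pg → µg
    return ExperimentPlan(
        transduced_cells_needed=transduced,
        seeded_cells_needed=seeded,
        pcr_template_mass_ug=mass_ug,
    )
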
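"""Guide-count matrices and FASTQ demultiplexing/counting.

The sequencing readout of a sorted-population screen is one FASTQ per
run in which every read carries a sample barcode followed by the guide
strand of one hairpin.  ``count_guides`` turns such reads into an
shRNA × sample integer matrix by exact barcode and guide matching; reads
failing either match are tallied, never silently dropped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .library import LibraryDesign


@dataclass
class CountMatrix:
    """Integer shRNA × sample count matrix with unassigned-read tallies.

    ``counts`` is indexed by shrna_id with one column per sample
    (conventionally ``rep{i}_high`` / ``rep{i}_low``).  ``no_guide_match``
    counts reads whose barcode matched a sample but whose guide matched
    no library hairpin; ``no_barcode_match`` counts reads assignable to
    no sample at all.  For every sample, assigned + no_guide_match equals
    the reads carrying that sample's barcode.
    """

    counts: pd.DataFrame
    no_guide_match: dict[str, int] = field(default_factory=dict)
    no_barcode_match: int = 0

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate shRNA row: {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.no_guide_match = {
            s: int(self.no_guide_match.get(s, 0)) for s in self.counts.columns
        }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shrna_ids(self) -> list[str]:
        return list(self.counts.index)

    def total_reads(self) -> int:
        return (
            int(self.counts.to_numpy().sum())
            + sum(self.no_guide_match.values())
            + self.no_barcode_match
        )

    def write(self, path: str | Path) -> None:
        """Write as TSV; unassigned tallies stored as header comments."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# no_barcode_match\t{self.no_barcode_match}\n")
            for sample in self.counts.columns:
                fh.write(f"# no_guide_match\t{sample}\t{self.no_guide_match[sample]}\n")
            self.counts.rename_axis("shrna_id").to_csv(fh, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "CountMatrix":
        """Read a matrix written by :meth:`write` (round-trip identity)."""
        path = Path(path)
        no_barcode = 0
        no_guide: dict[str, int] = {}
        header_lines = 0
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "# no_barcode_match":
                    no_barcode = int(parts[1])
                elif parts[0] == "# no_guide_match":
                    no_guide[parts[1]] = int(parts[2])
        df = pd.read_csv(path, sep="\t", skiprows=header_lines, index_col="shrna_id")
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() | (vals != vals.round())]
            if len(bad):
                raise ValueError(f"non-integer count in column {col!r} at {bad[0]!r}")
            df[col] = vals.astype(np.int64)
        return cls(counts=df, no_guide_match=no_guide, no_barcode_match=no_barcode)


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def count_guides(
    fastq_path: str | Path,
    library: "LibraryDesign",
    barcode_offset: int = 0,
    guide_offset: int | None = None,
) -> CountMatrix:
    """Demultiplex and count barcoded guide reads.

    Each read is assigned by exact barcode match at ``barcode_offset``
    and then exact guide match at ``guide_offset`` (defaulting to the
    position immediately after the barcode).  Mismatches increment the
    per-sample ``no_guide_match`` or global ``no_barcode_match`` tally.
    Reads too short to contain the guide count as no-guide-match.  The
    returned matrix covers the full library (zero-filled rows).

    Raises
    ------
    ValueError
        On a truncated/unparsable FASTQ record, naming the record index.
    """
    fastq_path = Path(fastq_path)
    bc_len = library.barcode_length
    g_len = library.guide_length
    if guide_offset is None:
        guide_offset = barcode_offset + bc_len
    if barcode_offset < 0 or guide_offset < 0:
        raise ValueError("offsets must be non-negative")

    samples = list(library.sample_barcodes)
    barcode_to_sample = {bc: s for s, bc in library.sample_barcodes.items()}
    guide_to_row = {g: i for i, g in enumerate(library.shrnas["guide"])}

    mat = np.zeros((library.n_shrnas, len(samples)), dtype=np.int64)
    col_of = {s: j for j, s in enumerate(samples)}
    no_guide = dict.fromkeys(samples, 0)
    no_barcode = 0

    with _open_text(fastq_path) as fh:
        records = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"bad FASTQ record at index {idx}: {exc}") from exc
            seq = str(rec.seq)
            sample = None
            if len(seq) >= barcode_offset + bc_len:
                sample = barcode_to_sample.get(seq[barcode_offset : barcode_offset + bc_len])
            if sample is None:
                no_barcode += 1
            else:
                row = None
                if len(seq) >= guide_offset + g_len:
                    row = guide_to_row.get(seq[guide_offset : guide_offset + g_len])
                if row is None:
                    no_guide[sample] += 1
                else:
                    mat[row, col_of[sample]] += 1
            idx += 1

    counts = pd.DataFrame(mat, index=pd.Index(library.shrna_ids, name="shrna_id"),
                          columns=samples)
    return CountMatrix(counts=counts, no_guide_match=no_guide, no_barcode_match=no_barcode)
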
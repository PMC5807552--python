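"""Enrichment scoring and hit calling for sorted-population screens.

The scoring rule is deliberately simple thresholding, matched exactly:

1. normalize each sample's guide counts to reads per million (RPM);
2. per hairpin and replicate, fold change = RPM(GFP-high) / RPM(GFP-low);
3. per hairpin, the geometric mean of the replicate fold changes;
4. a hairpin *scores* when its geomean is at least three-fold;
5. a gene is a *hit* when at least three of its hairpins score, and is
   reported with the average geomean of its scoring hairpins;
6. hits are ranked by number of scoring hairpins, then average geomean.

No p-values or count-model testing are involved: reproducing this exact
deterministic rule set is the point.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountMatrix

_SAMPLE_RE = re.compile(r"^(?P<rep>.+)_(?P<gate>high|low)$")

#: Scoring threshold: "at least three-fold" geomean enrichment (inclusive).
DEFAULT_FOLD_THRESHOLD = 3.0
#: Hit rule: "at least three scoring shRNAs" per gene (inclusive).
DEFAULT_MIN_SCORING = 3


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def normalize_rpm(
    counts: CountMatrix | pd.DataFrame,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Reads-per-million normalization with optional pseudocount.

    Each value becomes ``(count + pc) / column_total × 1e6`` where the
    column total is over *raw* counts, so with ``pseudocount = 0`` every
    non-empty column sums to exactly 1e6.  ``pseudocount=None`` selects
    0.5 when the matrix contains any zero (so downstream ratios stay
    finite) and 0 otherwise.
    """
    df = _as_frame(counts)
    if pseudocount is None:
        pseudocount = 0.5 if (df.to_numpy() == 0).any() else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = df.sum(axis=0)
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        raise ValueError(f"column(s) with zero total reads: {zero_cols}")
    return (df + pseudocount) / totals * 1e6


def _replicate_pairs(columns: list[str]) -> dict[str, tuple[str, str]]:
    """Map replicate name → (high column, low column); error on odd pairs."""
    found: dict[str, dict[str, str]] = {}
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(
                f"sample column {col!r} does not follow the '<replicate>_high/low' convention"
            )
        found.setdefault(m["rep"], {})[m["gate"]] = col
    pairs = {}
    for rep, gates in found.items():
        if set(gates) != {"high", "low"}:
            missing = {"high", "low"} - set(gates)
            raise ValueError(f"replicate {rep!r} missing {sorted(missing)} column")
        pairs[rep] = (gates["high"], gates["low"])
    return pairs


def score_shrnas(
    norm: pd.DataFrame,
    gene_of: Mapping[str, str] | pd.Series,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Per-hairpin fold changes, replicate geomean, and scoring flag.

    ``norm`` is an RPM matrix with paired ``<rep>_high`` / ``<rep>_low``
    columns; ``gene_of`` maps shrna_id → gene.  The geomean is computed
    in log space (equal to ``(∏ FC)^(1/R)``); the scoring flag is
    inclusive at the threshold ("at least three-fold").
    """
    pairs = _replicate_pairs(list(norm.columns))
    gene_of = pd.Series(gene_of)
    missing = norm.index.difference(gene_of.index)
    if len(missing):
        raise ValueError(f"no gene mapping for shRNA {missing[0]!r}")

    out = pd.DataFrame(index=norm.index)
    out.index.name = "shrna_id"
    out["gene"] = gene_of.reindex(norm.index)
    logs = []
    for rep, (hi, lo) in sorted(pairs.items()):
        if (norm[lo] <= 0).any() or (norm[hi] <= 0).any():
            raise ValueError(
                f"non-positive normalized reads in replicate {rep!r}; "
                "use a pseudocount"
            )
        fc = norm[hi] / norm[lo]
        out[f"fc_{rep}"] = fc
        logs.append(np.log(fc))
    out["geomean"] = np.exp(np.mean(logs, axis=0))
    out["scoring"] = out["geomean"] >= threshold
    return out.reset_index()


def call_hits(
    scores: pd.DataFrame,
    min_scoring: int = DEFAULT_MIN_SCORING,
) -> pd.DataFrame:
    """Aggregate hairpin scores into the gene hit table.

    Keeps genes with at least ``min_scoring`` scoring hairpins and
    reports ``avg_geomean``: the arithmetic mean of the geomeans of the
    *scoring* hairpins only.  Returns the ranked table (see
    :func:`rank_hits`).
    """
    if min_scoring < 1:
        raise ValueError("min_scoring must be >= 1")
    scoring = scores[scores["scoring"]]
    grouped = scoring.groupby("gene")["geomean"].agg(["size", "mean"])
    hits = grouped[grouped["size"] >= min_scoring].reset_index()
    hits.columns = ["gene", "n_scoring", "avg_geomean"]
    hits["n_scoring"] = hits["n_scoring"].astype(int)
    return rank_hits(hits)


def rank_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Sort a hit table: scoring-hairpin count desc, average geomean
    desc, gene name asc (deterministic tie-break); adds a 1-based
    ``rank`` column."""
    out = hits.sort_values(
        ["n_scoring", "avg_geomean", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_screen(
    counts: CountMatrix | pd.DataFrame,
    gene_of: Mapping[str, str] | pd.Series,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_scoring: int = DEFAULT_MIN_SCORING,
    pseudocount: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix → (per-hairpin scores, ranked gene hit table)."""
    norm = normalize_rpm(counts, pseudocount=pseudocount)
    scores = score_shrnas(norm, gene_of, threshold=threshold)
    return scores, call_hits(scores, min_scoring=min_scoring)
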
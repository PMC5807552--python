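"""Brute-force reimplementation of the enrichment scoring rules.

Literal, loop-based arithmetic used only as an independent oracle in
tests: no vectorization, no shared code with the package implementation.
"""

from __future__ import annotations


def brute_force_rpm(counts: dict[str, dict[str, float]], pseudocount: float):
    """counts: sample -> shrna -> count.  Returns same shape in RPM."""
    rpm: dict[str, dict[str, float]] = {}
    for sample, col in counts.items():
        total = 0
        for c in col.values():
            total += c
        rpm[sample] = {}
        for shrna, c in col.items():
            rpm[sample][shrna] = (c + pseudocount) / total * 1_000_000
    return rpm


def brute_force_scores(
    counts: dict[str, dict[str, float]],
    gene_of: dict[str, str],
    threshold: float = 3.0,
    pseudocount: float = 0.5,
):
    """Per-shRNA fold changes, geomean (product form) and scoring flag."""
    rpm = brute_force_rpm(counts, pseudocount)
    reps = sorted({s.rsplit("_", 1)[0] for s in counts})
    shrnas = list(next(iter(counts.values())).keys())
    out = {}
    for shrna in shrnas:
        fcs = []
        for rep in reps:
            fcs.append(rpm[f"{rep}_high"][shrna] / rpm[f"{rep}_low"][shrna])
        product = 1.0
        for fc in fcs:
            product *= fc
        geomean = product ** (1.0 / len(fcs))
        out[shrna] = {
            "gene": gene_of[shrna],
            "fcs": fcs,
            "geomean": geomean,
            "scoring": geomean >= threshold,
        }
    return out


def brute_force_hits(scores: dict, min_scoring: int = 3):
    """Gene records (gene, n_scoring, avg_geomean) sorted per the
    published convention, via plain sorting on an explicit key."""
    per_gene: dict[str, list[float]] = {}
    for rec in scores.values():
        if rec["scoring"]:
            per_gene.setdefault(rec["gene"], []).append(rec["geomean"])
    rows = []
    for gene, gms in per_gene.items():
        if len(gms) >= min_scoring:
            rows.append((gene, len(gms), sum(gms) / len(gms)))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows
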
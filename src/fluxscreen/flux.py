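"""Autophagic-flux quantification from cytometry event tables.

Flux is read out as the fraction of reporter fluorescence remaining
after autophagy induction: per cell line the mean signal in the control
condition (full medium or vehicle) is set to 100% and induced-condition
means are expressed relative to it, summarized as mean ± SD across
biological replicates.  Gate derivation places GFP-low / GFP-high sort
windows from negative (flux-competent) and positive (flux-blocked)
control populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("condition", "cell_line", "replicate")


@dataclass(frozen=True)
class GateSpec:
    """Half-open fluorescence window [lower, upper) on one channel."""

    channel: str
    lower: float
    upper: float
    label: str

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("gate lower bound must be below upper bound")

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.lower) & (values < self.upper)


def _check_events(events: pd.DataFrame, channels: Sequence[str]) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *channels) if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")


def summarize_flux(
    events: pd.DataFrame,
    control_condition: str = "FM",
    channels: Sequence[str] = ("gfp", "mcherry"),
) -> pd.DataFrame:
    """Percent-of-control fluorescence per cell line × condition.

    For each replicate the mean channel signal is divided by the same
    replicate's control-condition mean (×100); the table reports the
    across-replicate mean and sample SD (n−1) of those percentages, so
    the control row is exactly 100 ± 0.

    Raises
    ------
    ValueError
        If any cell line lacks the control condition.
    """
    _check_events(events, channels)
    for line, sub in events.groupby("cell_line"):
        if control_condition not in set(sub["condition"]):
            raise ValueError(
                f"cell line {line!r} has no control condition {control_condition!r}"
            )

    rep_means = (
        events.groupby(["cell_line", "replicate", "condition"], sort=False)[list(channels)]
        .mean()
        .reset_index()
    )
    ctrl = rep_means[rep_means["condition"] == control_condition]
    merged = rep_means.merge(
        ctrl[["cell_line", "replicate", *channels]],
        on=["cell_line", "replicate"],
        suffixes=("", "_ctrl"),
    )
    rows = []
    for ch in channels:
        merged[f"{ch}_pct"] = 100.0 * merged[ch] / merged[f"{ch}_ctrl"]
    for (line, cond), sub in merged.groupby(["cell_line", "condition"], sort=False):
        for ch in channels:
            pct = sub[f"{ch}_pct"].to_numpy()
            rows.append(
                {
                    "cell_line": line,
                    "condition": cond,
                    "channel": ch,
                    "percent_mean": float(pct.mean()),
                    "percent_sd": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
                    "n_replicates": len(pct),
                }
            )
    return pd.DataFrame(rows)


def derive_gates(
    neg_control: pd.DataFrame,
    pos_control: pd.DataFrame,
    channel: str = "gfp",
    alpha: float = 0.05,
) -> tuple[GateSpec, GateSpec]:
    """Place GFP-low / GFP-high gates from control populations.

    The low gate's upper bound is the (1−alpha) quantile of the negative
    (flux-competent, quenched) control; the high gate's lower bound is
    the alpha quantile of the positive (flux-blocked) control.

    Raises
    ------
    ValueError
        If either control is empty on the channel, or the gates would
        overlap ("controls not separable at alpha").
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    neg = np.asarray(neg_control[channel], dtype=float)
    pos = np.asarray(pos_control[channel], dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("control event tables must be non-empty on the channel")
    low_upper = float(np.quantile(neg, 1 - alpha))
    high_lower = float(np.quantile(pos, alpha))
    if high_lower <= low_upper:
        raise ValueError(f"controls not separable at alpha={alpha}")
    low = GateSpec(channel=channel, lower=-math.inf, upper=low_upper, label="GFP low")
    high = GateSpec(channel=channel, lower=high_lower, upper=math.inf, label="GFP high")
    return low, high


def gate_percentages(
    events: pd.DataFrame,
    gates: Iterable[GateSpec],
) -> dict[str, float]:
    """Percent of events falling inside each gate (inclusive-lower,
    exclusive-upper); disjoint gates therefore sum to at most 100."""
    gates = list(gates)
    if len(events) == 0:
        raise ValueError("event table is empty")
    out = {}
    for gate in gates:
        if gate.channel not in events.columns:
            raise ValueError(f"event table lacks channel {gate.channel!r}")
        inside = gate.contains(events[gate.channel].to_numpy())
        out[gate.label] = 100.0 * inside.sum() / len(events)
    return out


def compare_groups(
    events: pd.DataFrame,
    value: str,
    by: str = "condition",
) -> dict[str, float]:
    """Routine group comparison: Welch t-test for two groups, one-way
    ANOVA otherwise.  Convenience only — not part of the scoring rules."""
    groups = [g[value].to_numpy() for _, g in events.groupby(by)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return {"test": "welch_t", "statistic": float(stat), "p_value": float(p)}
    stat, p = stats.f_oneway(*groups)
    return {"test": "anova", "statistic": float(stat), "p_value": float(p)}
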
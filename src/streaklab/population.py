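"""Reporter-positive population fractions from event tables.

Mirrors the flow-cytometry arm of the study: events are first gated to
single, live cells (the viability flag stands in for DAPI exclusion), a
positivity threshold is derived from a negative control as an upper
quantile of its intensities (the study does not state its gate rule; the
99.9th percentile is this package's declared convention), per-replicate
positive percentages are computed per condition and timepoint, and
conditions are compared to the time-matched control by one-way ANOVA with
Tukey's adjustment at the 0.05 and 0.01 levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GatedEvents",
    "FractionTimecourse",
    "InsufficientDataError",
    "AlignmentError",
    "gate_events",
    "threshold_from_control",
    "fraction_positive_timecourse",
    "compare_to_control",
    "DEFAULT_GATE_QUANTILE",
]

DEFAULT_GATE_QUANTILE = 0.999


class InsufficientDataError(ValueError):
    """Too few events to derive the requested quantity."""


class AlignmentError(ValueError):
    """Conditions do not share the timepoints needed for comparison."""


@dataclass
class GatedEvents:
    """Viable events plus the removal bookkeeping."""

    events: pd.DataFrame
    n_input: int
    n_removed: int


def gate_events(events: pd.DataFrame) -> GatedEvents:
    """Remove non-viable events (dead-cell exclusion) and report counts."""
    if "viable" not in events.columns:
        raise KeyError("events table lacks the 'viable' column")
    kept = events[events["viable"]].reset_index(drop=True)
    removed = len(events) - len(kept)
    if len(kept) == 0 and len(events) > 0:
        warnings.warn("all events removed by the viability gate")
    return GatedEvents(events=kept, n_input=len(events), n_removed=removed)


def threshold_from_control(control_intensities,
                           q: float = DEFAULT_GATE_QUANTILE) -> float:
    """Positivity gate: empirical q-quantile of negative-control intensities."""
    x = np.asarray(control_intensities, dtype=float)
    if x.size < 100:
        raise InsufficientDataError(
            f"need >= 100 control events for a stable gate, got {x.size}")
    if not (0.0 < q <= 1.0):
        raise ValueError(f"quantile must be in (0, 1], got {q!r}")
    return float(np.quantile(x, q))


@dataclass
class FractionTimecourse:
    """Replicate-level and summarised positive percentages.

    ``replicates`` has one row per condition × timepoint × replicate with
    a ``pct_positive`` column; ``summary`` aggregates mean and SD across
    replicates. Percentages are on the 0–100 scale.
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame
    gate: float

    def pct(self, condition: str, timepoint: float) -> float:
        """Replicate-mean positive percentage at one timepoint."""
        row = self.summary[(self.summary["condition"] == condition)
                           & (self.summary["timepoint_h"] == timepoint)]
        return float(row["mean_pct"].iloc[0]) if len(row) else float("nan")


def fraction_positive_timecourse(events: pd.DataFrame,
                                 gate: float) -> FractionTimecourse:
    """Percent of events above the gate, per replicate, with mean ± SD."""
    rows = []
    for (cond, tp, rep), sub in events.groupby(
            ["condition", "timepoint_h", "replicate"], sort=True):
        n = len(sub)
        pct = 100.0 * float((sub["intensity_afu"] > gate).mean()) if n else float("nan")
        rows.append({"condition": cond, "timepoint_h": float(tp),
                     "replicate": rep, "pct_positive": pct, "n_events": n})
    reps = pd.DataFrame(rows, columns=["condition", "timepoint_h", "replicate",
                                       "pct_positive", "n_events"])
    if len(reps):
        summary = (reps.groupby(["condition", "timepoint_h"], as_index=False)
                   .agg(mean_pct=("pct_positive", "mean"),
                        sd_pct=("pct_positive", lambda v: v.std(ddof=1)),
                        n_replicates=("pct_positive", "size")))
    else:
        summary = pd.DataFrame(columns=["condition", "timepoint_h",
                                        "mean_pct", "sd_pct", "n_replicates"])
    return FractionTimecourse(replicates=reps, summary=summary, gate=float(gate))


def compare_to_control(fractions: FractionTimecourse, control: str,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-timepoint one-way ANOVA + Tukey HSD versus the control.

    Each timepoint is tested independently: ANOVA across all conditions'
    replicate percentages, then Tukey's honestly-significant-difference
    pairwise comparison of every condition against the time-matched
    control. Significance is flagged at the 0.05 and 0.01 levels.
    """
    reps = fractions.replicates
    conditions = sorted(reps["condition"].unique())
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not present")
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to compare")
    tps_by_cond = {c: set(reps.loc[reps["condition"] == c, "timepoint_h"])
                   for c in conditions}
    common = set.intersection(*tps_by_cond.values())
    offenders = {c: sorted(set.union(*tps_by_cond.values()) - tps_by_cond[c])
                 for c in conditions
                 if tps_by_cond[c] != set.union(*tps_by_cond.values())}
    if offenders:
        raise AlignmentError(f"unmatched timepoints per condition: {offenders}")
    out = []
    for tp in sorted(common):
        groups = [reps.loc[(reps["condition"] == c)
                           & (reps["timepoint_h"] == tp),
                           "pct_positive"].to_numpy(dtype=float)
                  for c in conditions]
        if any(len(g) < 2 for g in groups):
            raise InsufficientDataError(
                f"timepoint {tp}: every condition needs >= 2 replicates")
        if np.ptp(np.concatenate(groups)) == 0:
            anova_p = 1.0
            tukey_p = {c: 1.0 for c in conditions}
        else:
            anova_p = float(stats.f_oneway(*groups).pvalue)
            hsd = stats.tukey_hsd(*groups)
            ctrl_i = conditions.index(control)
            tukey_p = {c: float(hsd.pvalue[ctrl_i, i])
                       for i, c in enumerate(conditions)}
        for c in conditions:
            if c == control:
                continue
            p = tukey_p[c]
            out.append({"timepoint_h": tp, "condition": c,
                        "anova_p": anova_p, "tukey_p": p,
                        "sig_05": bool(p < alpha), "sig_01": bool(p < 0.01)})
    return pd.DataFrame(out, columns=["timepoint_h", "condition", "anova_p",
                                      "tukey_p", "sig_05", "sig_01"])
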
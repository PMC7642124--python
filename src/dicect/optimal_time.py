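"""Optimal-staining-time selection at slice and whole-brain level.

Optimality trades off contrast against scan time and shrinkage:

* **Slice level** - (1) keep the staining times at which *every* expected
  brain-tissue edge shows a clear derivative-peak response (P1 at or above
  a threshold; by default 10x the median P1 of the unstained scan, i.e.
  the pre-uptake noise floor); (2) among those candidates choose the time
  of minimum P3 (best intra-tissue homogeneity); when several candidates
  have P3 within a relative tolerance, take the one with the largest P2.
* **Whole-brain level** - after the onset of stain uptake (earliest time
  at which mean P2 reaches a fraction, default 10%, of its series
  maximum), choose the time at which mean P1 is maximal, mean P2 is
  maximal and mean P3 is minimal.  When the three criteria agree this is
  unambiguous; when they disagree the decision records each criterion's
  arg-optimum and falls back to the majority vote, ties resolved toward
  the latest time (disagreement is flagged in the rationale).

A series with no time passing step 1 (slice level) or with no positive
mean P2 (whole-brain level) yields a no-optimum decision flagged
``understained`` / ``unstained`` rather than an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stain_metrics import SliceMetrics, WholeBrainSeries

SLICE = "slice"
WHOLE_BRAIN = "whole_brain"


@dataclass(frozen=True)
class OptimalityDecision:
    """Outcome of an optimal-staining-time rule, with its full trace."""

    level: str  # slice | whole_brain
    keys: tuple
    chosen_time_h: float | None
    candidate_times_h: tuple
    rationale: dict = field(default_factory=dict)
    onset_time_h: float | None = None
    flag: str | None = None  # understained | unstained | disagreement

    def __post_init__(self):
        if self.chosen_time_h is not None and \
                self.chosen_time_h not in self.candidate_times_h:
            raise ValueError("chosen time not among candidates")


def slice_optimal_time(series: list[SliceMetrics],
                       p1_threshold: str | float = "auto",
                       p1_auto_factor: float = 10.0,
                       p1_floor: float = 1e-6,
                       p3_tie_rel_tol: float = 0.05) -> OptimalityDecision:
    """Apply the two-step slice-level rule to one slice's time series."""
    if len(series) < 2:
        raise ValueError("need at least two time points")
    keys = {(m.species, m.specimen_id, m.slice_index) for m in series}
    if len(keys) != 1:
        raise ValueError(f"metrics span several slices: {sorted(keys)}")
    key = next(iter(keys))
    by_time = {m.time_h: m for m in sorted(series, key=lambda m: m.time_h)}
    times = sorted(by_time)

    if p1_threshold == "auto":
        t0 = times[0]
        baseline = float(np.median(by_time[t0].p1_values))
        threshold = max(p1_auto_factor * baseline, p1_floor)
    else:
        threshold = float(p1_threshold)

    candidates = [t for t in times
                  if min(by_time[t].p1_values) >= threshold]
    trace = {
        "p1_threshold": threshold,
        "per_time": {t: {"p1_min": float(min(by_time[t].p1_values)),
                         "p3": by_time[t].p3,
                         "p2": by_time[t].p2,
                         "passes_step1": t in set(candidates)}
                     for t in times},
    }
    if not candidates:
        return OptimalityDecision(
            level=SLICE, keys=key, chosen_time_h=None,
            candidate_times_h=(), rationale=trace, flag="understained")

    p3_min = min(by_time[t].p3 for t in candidates)
    near = [t for t in candidates
            if by_time[t].p3 <= p3_min * (1.0 + p3_tie_rel_tol)
            or math.isclose(by_time[t].p3, p3_min, abs_tol=1e-12)]
    chosen = max(near, key=lambda t: (by_time[t].p2, t))
    trace["p3_min"] = p3_min
    trace["p3_tie_candidates"] = list(near)
    return OptimalityDecision(
        level=SLICE, keys=key, chosen_time_h=chosen,
        candidate_times_h=tuple(candidates), rationale=trace)


def whole_brain_optimal_time(series: WholeBrainSeries,
                             onset_fraction: float = 0.1
                             ) -> OptimalityDecision:
    """Apply the whole-brain rule to a specimen's pooled P1-P3 series."""
    tbl = series.table.sort_index()
    times = [float(t) for t in tbl.index]
    if len(times) < 3:
        raise ValueError("need at least three time points")
    if not 0 < onset_fraction <= 0.5:
        raise ValueError("onset_fraction must lie in (0, 0.5]")
    key = (series.species, series.specimen_id)

    p2 = tbl["mean_p2"].to_numpy(float)
    p2_max = p2.max()
    if p2_max <= 0:
        return OptimalityDecision(
            level=WHOLE_BRAIN, keys=key, chosen_time_h=None,
            candidate_times_h=(), rationale={"mean_p2_max": float(p2_max)},
            flag="unstained")
    onset_idx = int(np.argmax(p2 >= onset_fraction * p2_max))
    onset = times[onset_idx]
    window = [t for t in times if t >= onset]
    sub = tbl.loc[tbl.index >= onset]

    arg_p1 = float(sub["mean_p1"].idxmax())
    arg_p2 = float(sub["mean_p2"].idxmax())
    arg_p3 = float(sub["mean_p3"].idxmin())
    votes = [arg_p1, arg_p2, arg_p3]
    trace = {
        "onset_fraction": onset_fraction,
        "onset_time_h": onset,
        "argmax_mean_p1": arg_p1,
        "argmax_mean_p2": arg_p2,
        "argmin_mean_p3": arg_p3,
        "criteria_agree": len(set(votes)) == 1,
    }
    if len(set(votes)) == 1:
        chosen, flag = votes[0], None
    else:
        counts = {t: votes.count(t) for t in set(votes)}
        best = max(counts.values())
        chosen = max(t for t, c in counts.items() if c == best)
        flag = "disagreement"
    return OptimalityDecision(
        level=WHOLE_BRAIN, keys=key, chosen_time_h=chosen,
        candidate_times_h=tuple(window), rationale=trace,
        onset_time_h=onset, flag=flag)
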
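"""Slice-level stain parameters P1-P4, shrinkage, and whole-brain pooling.

Parameters monitored per slice and staining time:

* **P1** - edge strength (HU/mm) at every brain-tissue edge: the height of
  the derivative peak at each boundary of each brain interval; a proxy for
  inter-tissue contrast.
* **P2** - mean smoothed intensity pooled over brain-tissue intervals minus
  mean pooled over background (brain-case) intervals, in HU; the second
  inter-tissue contrast proxy.  Pooling is sample-count weighted, i.e. the
  mean over the union of interval samples.
* **P3** - interquartile range (HU) of the smoothed intensities within each
  brain-tissue interval; an intra-tissue staining-homogeneity proxy
  (lower = more homogeneous).  Multi-tissue slices carry one value per
  tissue; the per-slice scalar is their mean.
* **P4** - brain-tissue width (mm), ``x_right - x_left`` per tissue
  interval; its decline over staining time measures linear shrinkage.

Nerve crossings labeled ``excluded_nerve`` are omitted from P1-P3 and from
width pooling.  Linear shrinkage between the first and last staining time
is ``100 x (start_width - end_width) / start_width`` per brain region,
with per-slice widths averaged first when a slice carries several tissues
(minus configured exclusions such as the shark's slice-1 telencephalon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (BACKGROUND, BRAIN_TISSUE, DEFAULT_REGION_MAP,
                     SliceAnatomy)
from .errors import CoverageError, LabelingError, RangeError
from .profile_model import ExtractedRecord


@dataclass(frozen=True)
class SliceMetrics:
    """P1-P4 values for one slice of one specimen at one staining time."""

    species: str
    specimen_id: str
    slice_index: int
    time_h: float
    p1_values: tuple  # HU/mm, one per brain-tissue edge
    p2: float  # HU
    p3_values: tuple  # HU, one IQR per brain-tissue interval
    p4_widths: tuple  # mm, one per brain-tissue interval
    pooled_widths: tuple  # mm, widths entering shrinkage/width pooling

    def __post_init__(self):
        if any(v < 0 for v in self.p1_values):
            raise ValueError("negative edge strength")
        if any(v < 0 for v in self.p3_values):
            raise ValueError("negative IQR")
        if any(w <= 0 for w in self.p4_widths):
            raise ValueError("non-positive tissue width")

    @property
    def p3(self) -> float:
        """Per-slice homogeneity scalar: mean of per-tissue IQR values."""
        return float(np.mean(self.p3_values))

    @property
    def key(self) -> tuple:
        return (self.species, self.specimen_id, self.slice_index, self.time_h)


@dataclass(frozen=True)
class WholeBrainSeries:
    """Per-time-point two-stage means of P1-P3 and width for one specimen."""

    species: str
    specimen_id: str
    table: pd.DataFrame  # index time_h; columns mean_p1, mean_p2, mean_p3, mean_width

    @property
    def times_h(self) -> list[float]:
        return [float(t) for t in self.table.index]


@dataclass(frozen=True)
class ShrinkageResult:
    """Linear shrinkage of one brain region in one specimen."""

    species: str
    specimen_id: str
    region: str
    start_width_mm: float
    end_width_mm: float

    @property
    def percent(self) -> float:
        return shrinkage_percent(self.start_width_mm, self.end_width_mm)


def compute_slice_metrics(record: ExtractedRecord,
                          anatomy: SliceAnatomy | None = None) -> SliceMetrics:
    """Compute P1-P4 for one extracted probe record.

    Segment labels are taken from the record itself; ``anatomy`` supplies
    the width-pooling exclusions (and validates the label sequence) when
    given.
    """
    labels = [seg.label for seg in record.segments]
    if anatomy is not None and list(anatomy.labels) != labels:
        raise LabelingError(
            f"{record.key}: segment labels {labels} do not match the "
            f"configured anatomy {list(anatomy.labels)}")
    brain_idx = [i for i, lab in enumerate(labels) if lab == BRAIN_TISSUE]
    bg_idx = [i for i, lab in enumerate(labels) if lab == BACKGROUND]
    if not brain_idx:
        raise LabelingError(f"{record.key}: no brain_tissue segment")
    if not bg_idx:
        raise LabelingError(f"{record.key}: no background segment")

    segs = record.segments
    p1 = []
    for i in brain_idx:
        p1.extend([segs[i].edge_strength_left, segs[i].edge_strength_right])

    p2 = _pooled_mean([segs[i] for i in brain_idx]) \
        - _pooled_mean([segs[i] for i in bg_idx])
    p3_values = tuple(segs[i].iqr_hu for i in brain_idx)
    p4 = tuple(segs[i].width_mm for i in brain_idx)

    excluded = set(anatomy.width_excluded) if anatomy is not None else set()
    pooled = tuple(segs[i].width_mm for i in brain_idx if i not in excluded)

    return SliceMetrics(
        species=record.species, specimen_id=record.specimen_id,
        slice_index=record.slice_index, time_h=record.time_h,
        p1_values=tuple(p1), p2=float(p2), p3_values=p3_values,
        p4_widths=p4, pooled_widths=pooled,
    )


def _pooled_mean(segments) -> float:
    """Sample-count-weighted mean over intervals (= mean of pooled samples).

    Falls back to the unweighted mean of interval means when sample counts
    are unavailable (externally imported tables without an n column).
    """
    n = np.array([s.n_samples for s in segments], dtype=float)
    m = np.array([s.mean_hu for s in segments], dtype=float)
    if n.sum() <= 0:
        return float(m.mean())
    return float((n * m).sum() / n.sum())


def shrinkage_percent(start_width_mm: float, end_width_mm: float) -> float:
    """Linear shrinkage: ``100 x (start - end) / start`` in percent.

    Negative values indicate swelling and are reported as-is.
    """
    if not start_width_mm > 0:
        raise RangeError(f"starting width must be > 0, got {start_width_mm}")
    return 100.0 * (start_width_mm - end_width_mm) / start_width_mm


def compute_region_shrinkage(metrics: list[SliceMetrics],
                             region_map: dict[int, str] | None = None
                             ) -> list[ShrinkageResult]:
    """Region shrinkage between the first and last staining time.

    ``metrics`` holds all per-slice metrics for one or more specimens.
    For each (specimen, slice): start width = mean pooled width at the
    earliest time, end width = mean pooled width at the latest time.
    """
    region_map = region_map if region_map is not None else DEFAULT_REGION_MAP
    results = []
    by_spec_slice: dict[tuple, dict[float, SliceMetrics]] = {}
    for m in metrics:
        by_spec_slice.setdefault(
            (m.species, m.specimen_id, m.slice_index), {})[m.time_h] = m
    for (species, specimen, slc), series in sorted(by_spec_slice.items()):
        if slc not in region_map:
            continue
        times = sorted(series)
        if len(times) < 2:
            raise CoverageError(
                f"({species}, {specimen}, slice {slc}): need the first and "
                f"last staining times, found times {times}")
        start_m, end_m = series[times[0]], series[times[-1]]
        if not start_m.pooled_widths or not end_m.pooled_widths:
            raise CoverageError(
                f"({species}, {specimen}, slice {slc}): no pooled widths")
        results.append(ShrinkageResult(
            species=species, specimen_id=specimen, region=region_map[slc],
            start_width_mm=float(np.mean(start_m.pooled_widths)),
            end_width_mm=float(np.mean(end_m.pooled_widths)),
        ))
    return results


def aggregate_whole_brain(metrics: list[SliceMetrics]) -> WholeBrainSeries:
    """Two-stage (within-slice, then across-slice) means per time point.

    All slices of the specimen must be present at every time point; a gap
    raises :class:`CoverageError` naming it.
    """
    if not metrics:
        raise CoverageError("no slice metrics supplied")
    specimens = {(m.species, m.specimen_id) for m in metrics}
    if len(specimens) != 1:
        raise ValueError(f"metrics span several specimens: {sorted(specimens)}")
    species, specimen = next(iter(specimens))

    slices = sorted({m.slice_index for m in metrics})
    times = sorted({m.time_h for m in metrics})
    lookup = {(m.slice_index, m.time_h): m for m in metrics}

    rows = []
    for t in times:
        p1s, p2s, p3s, widths = [], [], [], []
        for s in slices:
            m = lookup.get((s, t))
            if m is None:
                raise CoverageError(
                    f"({species}, {specimen}): slice {s} missing at "
                    f"time {t:g} h")
            p1s.append(np.mean(m.p1_values))
            p2s.append(m.p2)
            p3s.append(m.p3)
            if m.pooled_widths:
                widths.append(np.mean(m.pooled_widths))
        rows.append({
            "time_h": t,
            "mean_p1": float(np.mean(p1s)),
            "mean_p2": float(np.mean(p2s)),
            "mean_p3": float(np.mean(p3s)),
            "mean_width": float(np.mean(widths)) if widths else math.nan,
        })
    table = pd.DataFrame(rows).set_index("time_h")
    return WholeBrainSeries(species=species, specimen_id=specimen, table=table)


def summarize_shrinkage(results: list[ShrinkageResult]) -> pd.DataFrame:
    """Region mean +/- SD across specimens, plus the overall mean +/- SD.

    The overall row is the flat mean/SD over all region x specimen values
    (not the mean of region means), one block per species.  SD uses the
    n-1 denominator and is reported as NaN for a single value.
    """
    if not results:
        raise ValueError("no shrinkage results")
    rows = []
    by_species: dict[str, list[ShrinkageResult]] = {}
    for r in results:
        by_species.setdefault(r.species, []).append(r)
    for species in sorted(by_species):
        group = by_species[species]
        regions = sorted({r.region for r in group},
                         key=lambda reg: _region_order(reg))
        all_values = []
        for region in regions:
            vals = [r.percent for r in group if r.region == region]
            all_values.extend(vals)
            rows.append({
                "species": species, "region": region, "n": len(vals),
                "mean_percent": float(np.mean(vals)),
                "sd_percent": float(np.std(vals, ddof=1)) if len(vals) > 1
                else math.nan,
            })
        rows.append({
            "species": species, "region": "Overall", "n": len(all_values),
            "mean_percent": float(np.mean(all_values)),
            "sd_percent": float(np.std(all_values, ddof=1))
            if len(all_values) > 1 else math.nan,
        })
    return pd.DataFrame(rows, columns=["species", "region", "n",
                                       "mean_percent", "sd_percent"])


def _region_order(region: str) -> tuple:
    order = {v: k for k, v in DEFAULT_REGION_MAP.items()}
    return (order.get(region, 99), region)
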
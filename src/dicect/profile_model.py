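"""Domain types and CSV I/O for line-probe intensity profiles.

A *line profile* is the sequence of radiodensities (HU) sampled at
uniformly spaced positions (mm) along a 1-D probe placed across a brain
slice, recorded for one specimen at one staining time.  A *study* is the
full factorial grid of profiles over specimens x slices x staining times.
The *extracted table* mirrors the layout of the study's supplementary
results CSV: one row per inter-edge interval, carrying the interval's
bounding edge positions and strengths plus summary statistics of the
smoothed intensities inside it.

All positions are mm from the probe's left (first-sampled) end; all
intensities are HU; staining time is keyed in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import DEFAULT_ANATOMY, SliceAnatomy, anatomy_for
from .errors import SchemaError, ValidationError

PROFILE_COLUMNS = ("species", "specimen", "slice", "time_h",
                   "index", "position_mm", "intensity_hu")

EXTRACTED_COLUMNS = (
    "species", "specimen", "slice", "time_h", "segment_index",
    "segment_label", "x_left_mm", "x_right_mm",
    "edge_strength_left", "edge_strength_right",
    "mean_hu", "median_hu", "sd_hu", "iqr_hu", "width_mm", "n_samples",
)

MIN_SAMPLES = 16
_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class LineProfile:
    """One probe's sampled positions/intensities at one staining time."""

    species: str
    specimen_id: str
    slice_index: int
    time_h: float
    positions: np.ndarray  # mm, strictly increasing, uniform
    intensities: np.ndarray  # HU, same length

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        key = self.key
        if self.time_h < 0:
            raise ValidationError(f"{key}: negative staining time")
        if pos.ndim != 1 or inten.ndim != 1 or len(pos) != len(inten):
            raise ValidationError(f"{key}: positions/intensities length mismatch")
        if len(pos) < MIN_SAMPLES:
            raise ValidationError(
                f"{key}: need at least {MIN_SAMPLES} samples, got {len(pos)}")
        diffs = np.diff(pos)
        if np.any(diffs <= 0):
            raise ValidationError(f"{key}: positions not strictly increasing")
        spacing = diffs.mean()
        if np.any(np.abs(diffs - spacing) > _SPACING_RTOL * spacing):
            raise ValidationError(f"{key}: positions not uniformly spaced")

    @property
    def key(self) -> tuple:
        return (self.species, self.specimen_id, self.slice_index, self.time_h)

    @property
    def spacing_mm(self) -> float:
        return float(np.diff(self.positions).mean())

    @property
    def length_mm(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class StudySeries:
    """Collection of profiles covering a (specimen, slice, time) grid.

    Grid completeness is enforced per specimen: every slice of a specimen
    must be sampled at every staining time at which that specimen appears.
    """

    profiles: dict  # key tuple -> LineProfile
    species_config: dict = field(default_factory=lambda: DEFAULT_ANATOMY)

    def __post_init__(self):
        by_specimen: dict[tuple, dict[int, set]] = {}
        for key, prof in self.profiles.items():
            if key != prof.key:
                raise ValidationError(f"profile stored under wrong key {key}")
            sp = (prof.species, prof.specimen_id)
            by_specimen.setdefault(sp, {}).setdefault(
                prof.slice_index, set()).add(prof.time_h)
        for sp, slices in by_specimen.items():
            grids = {frozenset(times) for times in slices.values()}
            if len(grids) > 1:
                raise ValidationError(
                    f"specimen {sp}: slices sampled at inconsistent time grids")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(sorted(self.profiles.values(), key=lambda p: _sort_key(p.key)))

    def get(self, species, specimen, slice_index, time_h) -> LineProfile:
        return self.profiles[(species, specimen, slice_index, time_h)]

    def time_grid_h(self, species: str | None = None) -> list[float]:
        times = {p.time_h for p in self.profiles.values()
                 if species is None or p.species == species}
        return sorted(times)

    def specimens(self) -> list[tuple[str, str]]:
        return sorted({(p.species, p.specimen_id) for p in self.profiles.values()})

    def anatomy(self, species: str, slice_index: int) -> SliceAnatomy:
        return anatomy_for(species, slice_index, self.species_config)


def _sort_key(key):
    species, specimen, slc, t = key
    return (species, specimen, slc, t)


@dataclass(frozen=True)
class SegmentStats:
    """Summary of smoothed intensities on one inter-edge interval."""

    label: str
    x_left_mm: float
    x_right_mm: float
    edge_strength_left: float
    edge_strength_right: float
    mean_hu: float
    median_hu: float
    sd_hu: float
    iqr_hu: float
    n_samples: int

    @property
    def width_mm(self) -> float:
        return self.x_right_mm - self.x_left_mm


@dataclass(frozen=True)
class ExtractedRecord:
    """Edge positions/strengths and per-interval statistics for one probe."""

    species: str
    specimen_id: str
    slice_index: int
    time_h: float
    edge_positions: tuple  # mm, sorted
    edge_strengths: tuple  # HU/mm, >= 0, same length
    segments: tuple  # of SegmentStats, len == len(edge_positions) - 1

    def __post_init__(self):
        pos = tuple(float(x) for x in self.edge_positions)
        stg = tuple(float(s) for s in self.edge_strengths)
        object.__setattr__(self, "edge_positions", pos)
        object.__setattr__(self, "edge_strengths", stg)
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(pos) != len(stg):
            raise ValidationError(f"{self.key}: edge position/strength mismatch")
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValidationError(f"{self.key}: edge positions not sorted")
        if any(s < 0 for s in stg):
            raise ValidationError(f"{self.key}: negative edge strength")
        if len(self.segments) != max(len(pos) - 1, 0):
            raise ValidationError(
                f"{self.key}: expected {len(pos) - 1} segments, "
                f"got {len(self.segments)}")

    @property
    def key(self) -> tuple:
        return (self.species, self.specimen_id, self.slice_index, self.time_h)


# ---------------------------------------------------------------------------
# profile CSV I/O


def read_profiles(path, schema: dict | None = None,
                  species_config: dict | None = None) -> StudySeries:
    """Read a long-format profile CSV into a validated :class:`StudySeries`.

    ``schema`` maps canonical column names (see :data:`PROFILE_COLUMNS`) to
    the names actually used in the file; unrecognized extra columns are
    ignored.  Rows may arrive in any order; they are grouped by
    (species, specimen, slice, time) and sorted by position.
    """
    df = pd.read_csv(path)
    colmap = {c: c for c in PROFILE_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [colmap[c] for c in PROFILE_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in profile CSV: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    dupes = df.duplicated(
        subset=["species", "specimen", "slice", "time_h", "index"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValidationError(
            "duplicated sample row for "
            f"({row['species']}, {row['specimen']}, {row['slice']}, "
            f"{row['time_h']}, index={row['index']})")

    profiles = {}
    for (species, specimen, slc, t), grp in df.groupby(
            ["species", "specimen", "slice", "time_h"], sort=True):
        grp = grp.sort_values("index")
        prof = LineProfile(
            species=str(species), specimen_id=str(specimen),
            slice_index=int(slc), time_h=float(t),
            positions=grp["position_mm"].to_numpy(float),
            intensities=grp["intensity_hu"].to_numpy(float),
        )
        profiles[prof.key] = prof
    kwargs = {} if species_config is None else {"species_config": species_config}
    return StudySeries(profiles=profiles, **kwargs)


def write_profiles(series: StudySeries, path) -> None:
    """Write a StudySeries to the canonical long-format CSV (LF, UTF-8)."""
    frames = []
    for prof in series:
        n = len(prof.positions)
        frames.append(pd.DataFrame({
            "species": [prof.species] * n,
            "specimen": [prof.specimen_id] * n,
            "slice": [prof.slice_index] * n,
            "time_h": [prof.time_h] * n,
            "index": np.arange(n),
            "position_mm": prof.positions,
            "intensity_hu": prof.intensities,
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(PROFILE_COLUMNS))
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# extracted-table I/O (supplementary-CSV-compatible layout)


def write_extracted(records, path) -> None:
    """Write extracted records as one CSV row per (record, segment)."""
    rows = []
    for rec in records:
        for i, seg in enumerate(rec.segments):
            rows.append({
                "species": rec.species,
                "specimen": rec.specimen_id,
                "slice": rec.slice_index,
                "time_h": rec.time_h,
                "segment_index": i,
                "segment_label": seg.label,
                "x_left_mm": seg.x_left_mm,
                "x_right_mm": seg.x_right_mm,
                "edge_strength_left": seg.edge_strength_left,
                "edge_strength_right": seg.edge_strength_right,
                "mean_hu": seg.mean_hu,
                "median_hu": seg.median_hu,
                "sd_hu": seg.sd_hu,
                "iqr_hu": seg.iqr_hu,
                "width_mm": seg.width_mm,
                "n_samples": seg.n_samples,
            })
    cols = ["species", "specimen", "slice", "time_h", "segment_index",
            "segment_label", "x_left_mm", "x_right_mm",
            "edge_strength_left", "edge_strength_right",
            "mean_hu", "median_hu", "sd_hu", "iqr_hu", "width_mm", "n_samples"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                            lineterminator="\n",
                                            float_format="%.10g")


def read_extracted(path, schema: dict | None = None) -> list[ExtractedRecord]:
    """Read an extracted table (or a user-mapped equivalent) back to records.

    ``schema`` maps canonical column names to the file's column names, so a
    supplementary table with a different layout can be imported by supplying
    the map.  ``n_samples`` is optional (filled with 0 when absent).
    """
    df = pd.read_csv(path)
    canonical = ["species", "specimen", "slice", "time_h", "segment_index",
                 "segment_label", "x_left_mm", "x_right_mm",
                 "edge_strength_left", "edge_strength_right",
                 "mean_hu", "median_hu", "sd_hu", "iqr_hu"]
    colmap = {c: c for c in canonical + ["n_samples"]}
    if schema:
        colmap.update(schema)
    missing = [colmap[c] for c in canonical if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in extracted CSV: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    if "n_samples" not in df.columns:
        df["n_samples"] = 0

    records = []
    for (species, specimen, slc, t), grp in df.groupby(
            ["species", "specimen", "slice", "time_h"], sort=True):
        grp = grp.sort_values("segment_index")
        segs = []
        for _, row in grp.iterrows():
            segs.append(SegmentStats(
                label=str(row["segment_label"]),
                x_left_mm=float(row["x_left_mm"]),
                x_right_mm=float(row["x_right_mm"]),
                edge_strength_left=float(row["edge_strength_left"]),
                edge_strength_right=float(row["edge_strength_right"]),
                mean_hu=float(row["mean_hu"]),
                median_hu=float(row["median_hu"]),
                sd_hu=float(row["sd_hu"]),
                iqr_hu=float(row["iqr_hu"]),
                n_samples=int(row["n_samples"]),
            ))
        positions = [segs[0].x_left_mm] + [s.x_right_mm for s in segs]
        strengths = [segs[0].edge_strength_left] + \
                    [s.edge_strength_right for s in segs]
        records.append(ExtractedRecord(
            species=str(species), specimen_id=str(specimen),
            slice_index=int(slc), time_h=float(t),
            edge_positions=tuple(positions),
            edge_strengths=tuple(strengths),
            segments=tuple(segs),
        ))
    return records
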
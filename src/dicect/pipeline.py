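"""End-to-end driver: profiles -> edges -> metrics -> decisions -> reports.

Failures are per probe, not global: a bad probe is recorded with its
(species, specimen, slice, time) key and stage name and the run continues
over the remaining keys; the run manifest lists all failures and the CLI
exits non-zero when any occurred.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisSettings, DEFAULT_REGION_MAP, SliceAnatomy
from .errors import DicectError
from .hu_calibration import PhantomCalibration, to_hounsfield
from .optimal_time import (OptimalityDecision, slice_optimal_time,
                           whole_brain_optimal_time)
from .peak_analysis import (detect_edge_peaks, pair_edges, segment_stats,
                            smooth_profile)
from .profile_model import (ExtractedRecord, LineProfile, StudySeries,
                            read_profiles, write_extracted)
from .stain_metrics import (SliceMetrics, aggregate_whole_brain,
                            compute_region_shrinkage, compute_slice_metrics,
                            summarize_shrinkage)

log = logging.getLogger("dicect")


def analyze_profile(profile: LineProfile, anatomy: SliceAnatomy,
                    settings: AnalysisSettings | None = None,
                    override_positions: list[float] | None = None
                    ) -> ExtractedRecord:
    """Run the full peak analysis for one probe.

    Smooth, differentiate, detect significant derivative peaks, pair the
    expected number of edges about the probe midpoint (or snap to the
    declarative override positions), and summarize every inter-edge
    interval with the label sequence configured for this species/slice.
    """
    settings = settings or AnalysisSettings()
    sp = smooth_profile(profile, settings.smoothing)
    candidates = detect_edge_peaks(
        sp, min_prominence=settings.min_prominence,
        min_separation=settings.min_separation,
        prominence_k=settings.prominence_k)
    midpoint = 0.5 * (profile.positions[0] + profile.positions[-1])
    window_mm = settings.override_window * profile.spacing_mm
    edge_set = pair_edges(
        candidates, expected_pairs=anatomy.n_pairs, midpoint_mm=midpoint,
        override=override_positions,
        override_window_mm=window_mm if override_positions else None,
        suppression_mm=settings.suppression_samples * profile.spacing_mm)

    edges = edge_set.paired_edges
    strengths = edge_set.strengths
    segments = []
    for i, label in enumerate(anatomy.labels):
        segments.append(segment_stats(
            sp, (edges[i], edges[i + 1]), label=label,
            edge_strengths=(strengths[i], strengths[i + 1])))
    return ExtractedRecord(
        species=profile.species, specimen_id=profile.specimen_id,
        slice_index=profile.slice_index, time_h=profile.time_h,
        edge_positions=edges, edge_strengths=strengths,
        segments=tuple(segments))


def read_overrides(path) -> dict:
    """Read a declarative edge-override CSV into {probe key: positions}."""
    df = pd.read_csv(path)
    out: dict[tuple, list[float]] = {}
    for _, row in df.sort_values("edge_index").iterrows():
        key = (str(row["species"]), str(row["specimen"]),
               int(row["slice"]), float(row["time_h"]))
        out.setdefault(key, []).append(float(row["position_mm"]))
    return out


def analyze_study(series: StudySeries,
                  settings: AnalysisSettings | None = None,
                  overrides: dict | None = None
                  ) -> tuple[list[ExtractedRecord], list[dict]]:
    """Peak-analyse every probe; collect per-probe failures instead of dying."""
    settings = settings or AnalysisSettings()
    overrides = overrides or {}
    records, failures = [], []
    for profile in series:
        anatomy = series.anatomy(profile.species, profile.slice_index)
        try:
            records.append(analyze_profile(
                profile, anatomy, settings,
                override_positions=overrides.get(profile.key)))
        except DicectError as exc:
            failures.append({"key": list(profile.key),
                             "stage": "peak_analysis", "error": str(exc)})
            log.warning("peak analysis failed for %s: %s", profile.key, exc)
    return records, failures


def metrics_from_records(records: list[ExtractedRecord],
                         series: StudySeries | None = None,
                         species_config: dict | None = None
                         ) -> tuple[list[SliceMetrics], list[dict]]:
    from .config import anatomy_for
    metrics, failures = [], []
    for rec in records:
        try:
            if series is not None:
                anatomy = series.anatomy(rec.species, rec.slice_index)
            else:
                anatomy = anatomy_for(rec.species, rec.slice_index,
                                      species_config)
            metrics.append(compute_slice_metrics(rec, anatomy))
        except DicectError as exc:
            failures.append({"key": list(rec.key),
                             "stage": "slice_metrics", "error": str(exc)})
    return metrics, failures


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    profiles_csv: str
    output_dir: str
    calibration: str | None = None  # YAML with mu_water/mu_air
    overrides_csv: str | None = None
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    region_map: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MAP))
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for path in (self.profiles_csv, self.calibration, self.overrides_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def digest(self) -> str:
        payload = {
            "profiles_csv": str(self.profiles_csv),
            "calibration": self.calibration and str(self.calibration),
            "overrides_csv": self.overrides_csv and str(self.overrides_csv),
            "settings": self.settings.to_dict(),
            "region_map": {str(k): v for k, v in self.region_map.items()},
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class RunResult:
    artifacts: dict
    failures: list
    decisions: list

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_calibration(path) -> PhantomCalibration:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PhantomCalibration(
        mu_water=float(raw["mu_water"]), mu_air=float(raw["mu_air"]),
        acquisition_tag=str(raw.get("acquisition_tag", "")),
        trim_fraction=float(raw.get("trim_fraction", 0.05)))


def _decision_row(d: OptimalityDecision) -> dict:
    return {
        "level": d.level,
        "keys": list(d.keys),
        "chosen_time_h": d.chosen_time_h,
        "onset_time_h": d.onset_time_h,
        "candidate_times_h": list(d.candidate_times_h),
        "flag": d.flag,
        "rationale": _plain(d.rationale),
    }


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all report artifacts."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    series = read_profiles(config.profiles_csv)
    if config.calibration:
        cal = _load_calibration(config.calibration)
        series = StudySeries(
            profiles={k: LineProfile(
                species=p.species, specimen_id=p.specimen_id,
                slice_index=p.slice_index, time_h=p.time_h,
                positions=p.positions,
                intensities=to_hounsfield(p.intensities, cal))
                for k, p in series.profiles.items()},
            species_config=series.species_config)

    overrides = read_overrides(config.overrides_csv) \
        if config.overrides_csv else {}

    records, failures = analyze_study(series, config.settings, overrides)
    metrics, mfail = metrics_from_records(records, series)
    failures.extend(mfail)

    artifacts = {}
    extracted_path = outdir / "extracted.csv"
    write_extracted(records, extracted_path)
    artifacts["extracted"] = str(extracted_path)

    rows = [{
        "species": m.species, "specimen": m.specimen_id,
        "slice": m.slice_index, "time_h": m.time_h,
        "p1_mean": float(pd.Series(m.p1_values).mean()),
        "p2": m.p2, "p3": m.p3,
        "width_mean": float(pd.Series(m.p4_widths).mean()),
        "pooled_width_mean": float(pd.Series(m.pooled_widths).mean())
        if m.pooled_widths else float("nan"),
    } for m in metrics]
    metrics_path = outdir / "slice_metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False, lineterminator="\n",
                              float_format="%.10g")
    artifacts["slice_metrics"] = str(metrics_path)

    decisions: list[OptimalityDecision] = []
    wb_rows = []
    shrink_results = []
    by_specimen: dict[tuple, list[SliceMetrics]] = {}
    for m in metrics:
        by_specimen.setdefault((m.species, m.specimen_id), []).append(m)
    for (species, specimen), group in sorted(by_specimen.items()):
        by_slice: dict[int, list[SliceMetrics]] = {}
        for m in group:
            by_slice.setdefault(m.slice_index, []).append(m)
        for slc, sm in sorted(by_slice.items()):
            try:
                decisions.append(slice_optimal_time(
                    sm, p1_threshold=config.settings.p1_threshold,
                    p1_auto_factor=config.settings.p1_auto_factor,
                    p1_floor=config.settings.p1_floor,
                    p3_tie_rel_tol=config.settings.p3_tie_rel_tol))
            except (DicectError, ValueError) as exc:
                failures.append({"key": [species, specimen, slc],
                                 "stage": "slice_optimal_time",
                                 "error": str(exc)})
        try:
            wb = aggregate_whole_brain(group)
            for t, row in wb.table.iterrows():
                wb_rows.append({"species": species, "specimen": specimen,
                                "time_h": float(t), **row.to_dict()})
            decisions.append(whole_brain_optimal_time(
                wb, onset_fraction=config.settings.onset_fraction))
            shrink_results.extend(
                compute_region_shrinkage(group, config.region_map))
        except (DicectError, ValueError) as exc:
            failures.append({"key": [species, specimen],
                             "stage": "whole_brain", "error": str(exc)})

    wb_path = outdir / "whole_brain.csv"
    pd.DataFrame(wb_rows).to_csv(wb_path, index=False, lineterminator="\n",
                                 float_format="%.10g")
    artifacts["whole_brain"] = str(wb_path)

    if shrink_results:
        per_path = outdir / "shrinkage_by_specimen.csv"
        pd.DataFrame([{
            "species": r.species, "specimen": r.specimen_id,
            "region": r.region, "start_width_mm": r.start_width_mm,
            "end_width_mm": r.end_width_mm, "percent": r.percent,
        } for r in shrink_results]).to_csv(
            per_path, index=False, lineterminator="\n", float_format="%.10g")
        artifacts["shrinkage_by_specimen"] = str(per_path)
        sum_path = outdir / "shrinkage_summary.csv"
        summarize_shrinkage(shrink_results).to_csv(
            sum_path, index=False, lineterminator="\n", float_format="%.10g")
        artifacts["shrinkage_summary"] = str(sum_path)

    dec_path = outdir / "decisions.yaml"
    with open(dec_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([_decision_row(d) for d in decisions], fh,
                       sort_keys=False)
    artifacts["decisions"] = str(dec_path)

    manifest = {
        "dicect_version": __version__,
        "config_digest": config.digest(),
        "settings": config.settings.to_dict(),
        "n_profiles": len(series),
        "n_records": len(records),
        "failures": failures,
        "artifacts": {k: str(Path(v).name) for k, v in artifacts.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(_plain(manifest), indent=2,
                                        sort_keys=True) + "\n",
                             encoding="utf-8")
    artifacts["manifest"] = str(manifest_path)

    return RunResult(artifacts=artifacts, failures=failures,
                     decisions=decisions)
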
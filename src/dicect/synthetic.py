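"""Synthetic stain-ingress generator with full ground truth.

Emulates the statistical structure of line-probe profiles from an iodine
staining time course, so every pipeline stage can be tested end to end:

* two-sided diffusive ingress into each tissue interval: the interior
  concentration is ``c_max * clip(erfc(d_L / 2 sqrt(D t)) +
  erfc(d_R / 2 sqrt(D t)), 0, 1)`` with ``d_L, d_R`` the distances to the
  current tissue boundaries - concave (understained) early, flat at
  saturation;
* an optional overstain term ``rate * t * exp(-d / w)`` that accumulates
  near the boundaries after saturation, turning the interior convex;
* a brain case flanking the tissues that stains quickly and saturates,
  plus small unstained (t = 0) contrast offsets for case and tissue so
  edges are faintly visible before staining, as in real reconstructions;
* saturating linear shrinkage ``s(t) = s_max * (1 - exp(-t / tau))``
  applied as inward displacement of the tissue boundaries (the case's
  outer boundary stays fixed);
* additive Gaussian noise with one independent, explicitly keyed stream
  per (seed, species, specimen, slice, time), so any subset of a study
  regenerates identically.

The erfc two-front model is the simplest shape producing the observed
concave -> flat -> convex interior progression; it is not claimed to be
the physical staining kinetics.  Default study specs mirror the staining
study's conditions: 500 samples per probe, scans every 48 h to 240 h
(shark, *C. punctatum*) or every 24 h to 96 h (goldfish, *C. auratus*),
and per-slice tissue widths whose whole-brain means at T0 and the last
time reproduce the study's reported 5.46 -> 4.78 mm and 2.38 -> 1.90 mm.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

from .config import BRAIN_TISSUE, EXCLUDED_NERVE
from .errors import ValidationError
from .profile_model import LineProfile, StudySeries


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry and kinetics for one probe's time series."""

    species: str
    specimen_id: str
    slice_index: int
    probe_length_mm: float
    tissues_mm: tuple  # ((left, right), ...) initial tissue boundaries
    tissue_labels: tuple  # brain_tissue | excluded_nerve per tissue
    case_margin_mm: float  # case band width outside the outermost tissues
    time_grid_h: tuple
    n_samples: int = 500
    diffusivity: float = 0.02  # D, mm^2/h
    c_max: float = 10000.0  # HU plateau of tissue uptake
    nerve_c_scale: float = 0.8  # c_max multiplier for nerve tissues
    case_max: float = 4000.0  # HU plateau of brain-case staining
    case_tau_h: float = 24.0
    case_t0: float = 800.0  # unstained case contrast above baseline, HU
    tissue_t0: float = 200.0  # unstained tissue contrast above baseline, HU
    baseline: float = 100.0  # HU
    shrink_max: float = 0.12  # s_max in [0, 1)
    shrink_tau_h: float = 60.0
    overstain_rate: float = 0.0  # HU/h near edges
    overstain_width_mm: float = 0.5
    noise_sd: float = 0.0  # HU
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 16:
            raise ValidationError("n_samples must be >= 16")
        if not 0 <= self.shrink_max < 1:
            raise ValidationError("shrink_max must lie in [0, 1)")
        if self.diffusivity <= 0:
            raise ValidationError("diffusivity must be > 0")
        if len(self.tissues_mm) != len(self.tissue_labels):
            raise ValidationError("one label per tissue required")
        prev = 0.0
        for (a, b) in self.tissues_mm:
            if not 0 < a < b < self.probe_length_mm:
                raise ValidationError(
                    f"tissue ({a}, {b}) outside probe (0, {self.probe_length_mm})")
            if a < prev:
                raise ValidationError("tissues must be ordered and disjoint")
            prev = b
        outer_l = self.tissues_mm[0][0] - self.case_margin_mm
        outer_r = self.tissues_mm[-1][1] + self.case_margin_mm
        if not (0 < outer_l and outer_r < self.probe_length_mm):
            raise ValidationError("case bands extend outside the probe")
        if any(t < 0 for t in self.time_grid_h):
            raise ValidationError("times must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.probe_length_mm, self.n_samples)

    @property
    def case_outer_mm(self) -> tuple[float, float]:
        return (self.tissues_mm[0][0] - self.case_margin_mm,
                self.tissues_mm[-1][1] + self.case_margin_mm)

    def shrink_fraction(self, time_h: float) -> float:
        return self.shrink_max * (1.0 - math.exp(-time_h / self.shrink_tau_h))

    def tissue_bounds_at(self, time_h: float) -> list[tuple[float, float]]:
        """Tissue boundaries after shrinkage toward each tissue's centre."""
        s = self.shrink_fraction(time_h)
        out = []
        for a, b in self.tissues_mm:
            c, hw = 0.5 * (a + b), 0.5 * (b - a)
            out.append((c - hw * (1 - s), c + hw * (1 - s)))
        return out

    def true_edges_at(self, time_h: float) -> list[float]:
        """All detectable edges: case outer boundaries + tissue boundaries."""
        lo, hi = self.case_outer_mm
        edges = [lo]
        for a, b in self.tissue_bounds_at(time_h):
            edges.extend([a, b])
        edges.append(hi)
        return edges


@dataclass(frozen=True)
class GroundTruthSlice:
    """Noiseless truth for one probe at one staining time."""

    species: str
    specimen_id: str
    slice_index: int
    time_h: float
    true_edges_mm: tuple
    tissue_widths_mm: tuple  # per tissue, post-shrinkage
    tissue_labels: tuple
    shrink_fraction: float
    interior_mean_hu: tuple  # noiseless, per brain tissue
    interior_iqr_hu: tuple

    @property
    def brain_widths_mm(self) -> tuple:
        return tuple(w for w, lab in zip(self.tissue_widths_mm, self.tissue_labels)
                     if lab == BRAIN_TISSUE)


@dataclass
class GroundTruth:
    """All ground-truth slices of a synthetic study."""

    slices: list

    def get(self, species, specimen, slice_index, time_h) -> GroundTruthSlice:
        for s in self.slices:
            if (s.species, s.specimen_id, s.slice_index, s.time_h) == \
                    (species, specimen, slice_index, time_h):
                return s
        raise KeyError((species, specimen, slice_index, time_h))

    def programmed_shrinkage_percent(self, species: str) -> float:
        """100 * s(t_end) for the species' specs (shared kinetics)."""
        cand = [s for s in self.slices if s.species == species]
        t_end = max(s.time_h for s in cand)
        fr = {s.shrink_fraction for s in cand if s.time_h == t_end}
        return 100.0 * sorted(fr)[0]

    def programmed_optimal_time_h(self, species: str) -> float:
        """Grid time minimizing the mean noiseless interior IQR after onset.

        Onset is the earliest time at which the mean interior uptake
        (above its unstained level) exceeds 10% of its maximum, mirroring
        the decision rule but evaluated on noiseless truth.
        """
        times = sorted({s.time_h for s in self.slices if s.species == species})
        mean_iqr, uptake = [], []
        for t in times:
            rows = [s for s in self.slices
                    if s.species == species and s.time_h == t]
            iqrs = [v for s in rows for v in s.interior_iqr_hu]
            means = [v for s in rows for v in s.interior_mean_hu]
            mean_iqr.append(float(np.mean(iqrs)))
            uptake.append(float(np.mean(means)))
        base = uptake[0]
        rel = [u - base for u in uptake]
        peak = max(rel)
        onset_i = next(i for i, u in enumerate(rel) if u >= 0.1 * peak)
        window = list(range(onset_i, len(times)))
        best = min(window, key=lambda i: (mean_iqr[i], -times[i]))
        return times[best]


def _profile_rng(spec: PhantomSpec, time_h: float) -> np.random.Generator:
    key = [int(spec.seed) & 0x7FFFFFFF,
           zlib.crc32(spec.species.encode()),
           zlib.crc32(spec.specimen_id.encode()),
           int(spec.slice_index),
           int(round(time_h * 1000))]
    return np.random.default_rng(np.random.SeedSequence(key))


def noiseless_signal(spec: PhantomSpec, time_h: float,
                     x: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the noiseless phantom signal at positions ``x`` (HU)."""
    if time_h < 0:
        raise ValidationError("time must be >= 0")
    if x is None:
        x = spec.positions
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, spec.baseline)

    lo, hi = spec.case_outer_mm
    bounds = spec.tissue_bounds_at(time_h)
    in_any_tissue = np.zeros_like(x, dtype=bool)
    case_level = spec.case_t0 + spec.case_max * (
        1.0 - math.exp(-time_h / spec.case_tau_h)) if time_h > 0 else spec.case_t0

    for (a, b), label in zip(bounds, spec.tissue_labels):
        inside = (x >= a) & (x <= b)
        in_any_tissue |= inside
        level = np.full(inside.sum(), spec.tissue_t0)
        if time_h > 0:
            xt = x[inside]
            d_l = xt - a
            d_r = b - xt
            denom = 2.0 * math.sqrt(spec.diffusivity * time_h)
            c = erfc(d_l / denom) + erfc(d_r / denom)
            c = np.clip(c, 0.0, 1.0)
            cm = spec.c_max * (spec.nerve_c_scale
                               if label == EXCLUDED_NERVE else 1.0)
            level = level + cm * c
            if spec.overstain_rate > 0:
                d = np.minimum(d_l, d_r)
                level = level + spec.overstain_rate * time_h * \
                    np.exp(-d / spec.overstain_width_mm)
        y[inside] += level

    in_case = (x >= lo) & (x <= hi) & ~in_any_tissue
    y[in_case] += case_level
    return y


def generate_profile(spec: PhantomSpec, time_h: float
                     ) -> tuple[LineProfile, GroundTruthSlice]:
    """Generate one noisy profile and its ground truth at ``time_h``."""
    x = spec.positions
    clean = noiseless_signal(spec, time_h, x)
    y = clean
    if spec.noise_sd > 0:
        rng = _profile_rng(spec, time_h)
        y = clean + rng.normal(0.0, spec.noise_sd, size=x.shape)

    bounds = spec.tissue_bounds_at(time_h)
    means, iqrs = [], []
    for (a, b), label in zip(bounds, spec.tissue_labels):
        if label != BRAIN_TISSUE:
            continue
        inside = (x > a) & (x < b)
        vals = clean[inside]
        q1, q3 = np.percentile(vals, [25, 75])
        means.append(float(vals.mean()))
        iqrs.append(float(q3 - q1))

    truth = GroundTruthSlice(
        species=spec.species, specimen_id=spec.specimen_id,
        slice_index=spec.slice_index, time_h=float(time_h),
        true_edges_mm=tuple(spec.true_edges_at(time_h)),
        tissue_widths_mm=tuple(b - a for a, b in bounds),
        tissue_labels=spec.tissue_labels,
        shrink_fraction=spec.shrink_fraction(time_h),
        interior_mean_hu=tuple(means),
        interior_iqr_hu=tuple(iqrs),
    )
    profile = LineProfile(
        species=spec.species, specimen_id=spec.specimen_id,
        slice_index=spec.slice_index, time_h=float(time_h),
        positions=x, intensities=y,
    )
    return profile, truth


def generate_study(specs: list[PhantomSpec]
                   ) -> tuple[StudySeries, GroundTruth]:
    """Full factorial study over each spec's own time grid."""
    grids: dict[tuple, set] = {}
    for spec in specs:
        grids.setdefault((spec.species, spec.specimen_id),
                         set()).add(spec.time_grid_h)
    for key, gset in grids.items():
        if len(gset) > 1:
            raise ValidationError(
                f"specimen {key}: inconsistent time grids across slices")
    profiles, truths = {}, []
    for spec in specs:
        for t in spec.time_grid_h:
            prof, truth = generate_profile(spec, t)
            profiles[prof.key] = prof
            truths.append(truth)
    return StudySeries(profiles=profiles), GroundTruth(slices=truths)


# ---------------------------------------------------------------------------
# default study specs (the conditions the analysis is validated under)

SHARK_TIME_GRID = tuple(float(t) for t in range(0, 241, 48))
GOLDFISH_TIME_GRID = tuple(float(t) for t in range(0, 97, 24))

# s_max chosen so 100 * s(t_end) equals the whole-brain shrinkage implied by
# the reported mean widths: 100*(5.46-4.78)/5.46 = 12.45% (shark, tau 60 h,
# t_end 240 h) and 100*(2.38-1.90)/2.38 = 20.17% (goldfish, tau 24 h, t_end
# 96 h).
_SHARK_SMAX = 0.124542 / (1.0 - math.exp(-240.0 / 60.0))
_GOLDFISH_SMAX = 0.201681 / (1.0 - math.exp(-96.0 / 24.0))

_SHARK_D_MULT = {1: 1.4, 2: 1.0, 3: 0.8, 4: 0.6}
_GOLDFISH_D_MULT = {1: 1.4, 2: 1.0, 3: 0.8, 4: 0.6}


def _layout(center: float, widths: list[float], gap: float) -> tuple:
    total = sum(widths) + gap * (len(widths) - 1)
    left = center - total / 2.0
    out = []
    for w in widths:
        out.append((left, left + w))
        left += w + gap
    return tuple(out)


def shark_slice_spec(slice_index: int, specimen_id: str = "CP2",
                     seed: int = 0, noise_sd: float = 100.0,
                     **overrides) -> PhantomSpec:
    """Default *C. punctatum* probe spec for one slice."""
    L, mid, gap = 20.0, 10.0, 0.8
    geo = {
        1: (_layout(mid, [4.0, 3.0, 4.0], gap),
            (BRAIN_TISSUE, BRAIN_TISSUE, BRAIN_TISSUE)),
        2: (_layout(mid, [7.0], gap), (BRAIN_TISSUE,)),
        3: (_layout(mid, [6.5], gap), (BRAIN_TISSUE,)),
        4: (_layout(mid, [1.0, 4.34, 1.0], gap),
            (EXCLUDED_NERVE, BRAIN_TISSUE, EXCLUDED_NERVE)),
    }[slice_index]
    params = dict(
        species="C_punctatum", specimen_id=specimen_id,
        slice_index=slice_index, probe_length_mm=L,
        tissues_mm=geo[0], tissue_labels=geo[1], case_margin_mm=gap,
        time_grid_h=SHARK_TIME_GRID,
        diffusivity=0.02 * _SHARK_D_MULT[slice_index],
        c_max=14000.0, case_max=4000.0, case_tau_h=36.0,
        case_t0=700.0, tissue_t0=50.0, baseline=100.0,
        shrink_max=_SHARK_SMAX, shrink_tau_h=60.0,
        overstain_rate=3.0 if slice_index == 1 else 0.0,
        noise_sd=noise_sd, seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def goldfish_slice_spec(slice_index: int, specimen_id: str = "CA2",
                        seed: int = 0, noise_sd: float = 150.0,
                        **overrides) -> PhantomSpec:
    """Default *C. auratus* probe spec for one slice."""
    L, mid, gap = 8.0, 4.0, 0.5
    geo = {
        1: (_layout(mid, [1.8, 1.8], gap),
            (BRAIN_TISSUE, BRAIN_TISSUE)),
        2: (_layout(mid, [3.0], gap), (BRAIN_TISSUE,)),
        3: (_layout(mid, [2.8], gap), (BRAIN_TISSUE,)),
        4: (_layout(mid, [0.6, 1.92, 0.6], gap),
            (EXCLUDED_NERVE, BRAIN_TISSUE, EXCLUDED_NERVE)),
    }[slice_index]
    params = dict(
        species="C_auratus", specimen_id=specimen_id,
        slice_index=slice_index, probe_length_mm=L,
        tissues_mm=geo[0], tissue_labels=geo[1], case_margin_mm=gap,
        time_grid_h=GOLDFISH_TIME_GRID,
        diffusivity=0.022 * _GOLDFISH_D_MULT[slice_index],
        c_max=28000.0, case_max=6000.0, case_tau_h=10.0,
        case_t0=1500.0, tissue_t0=50.0, baseline=100.0,
        shrink_max=_GOLDFISH_SMAX, shrink_tau_h=24.0,
        overstain_rate=10.0 if slice_index == 1 else 0.0,
        noise_sd=noise_sd, seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def demo_specs(seed: int = 0, noise_sd: float | None = None,
               shark_specimens: tuple = ("CP2",),
               goldfish_specimens: tuple = ("CA2",)) -> list[PhantomSpec]:
    """Default demo study: one specimen per species, four slices each."""
    specs = []
    for sp in shark_specimens:
        for s in range(1, 5):
            kw = {} if noise_sd is None else {"noise_sd": noise_sd}
            specs.append(shark_slice_spec(s, specimen_id=sp, seed=seed, **kw))
    for sp in goldfish_specimens:
        for s in range(1, 5):
            kw = {} if noise_sd is None else {"noise_sd": noise_sd}
            specs.append(goldfish_slice_spec(s, specimen_id=sp, seed=seed, **kw))
    return specs
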
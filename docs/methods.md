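# Methods

This note documents the models, rules and numerical choices behind
`dicect`, in the order the pipeline applies them.

## Problem setting

Diffusible iodine-based contrast-enhanced CT (diceCT) renders soft tissue
X-ray attenuating by immersing a fixed specimen in Lugol's iodine and
rescanning it at intervals. Because the stain diffuses inward and also
shrinks tissue osmotically, there is an optimal staining time: long enough
for homogeneous intra-tissue uptake and strong tissue/background contrast,
short enough to limit scan time and shrinkage. The package quantifies this
trade-off from 1-D *line probes*: per brain slice and staining time, a
horizontal transect of 500 radiodensity samples (HU) across the brain case
and the neural tissue it encloses.

## Edge detection on a line profile

Each profile is fitted with a penalized natural cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`); the penalty is chosen by
generalized cross-validation by default and may be fixed in the config for
exact reproducibility studies. The spline's first derivative is evaluated
analytically, and tissue boundaries appear as its significant positive
(rising) and negative (falling) peaks.

*Significance.* A peak is significant when its prominence exceeds
`k × 1.4826 × MAD` of the derivative samples (robust σ), `k = 3` by
default, with a floor at the numerical noise of the fit. The study the
package models treated significance visually; the robust-σ rule is the
deterministic replacement and is recorded in every output.

*Sub-sample localization.* Each discrete peak is refined by solving for
the zero of the spline's second derivative that brackets it (Brent's
method), giving localization well below one sample spacing on clean steps.

*Pairing.* The expected number of edge pairs per slice is fixed by the
species/slice anatomy (for example, three tissue intervals and eight edges
on the shark's slice 1). Automatic pairing selects, on each side of the
probe midpoint, the most prominent candidates (ties: nearer the midpoint,
then leftmost), with non-maximum suppression within a 10-sample radius:
near-interpolating splines of sharp steps ring, and the ringing side-lobes
would otherwise outrank true edges, while genuine anatomical edges are
never that close together. An *override file* (CSV of expected edge
positions per probe) replaces the original interactive adjustment: each
position is snapped to the nearest candidate within a 10-sample window.
This is the batch-reproducible way to reject the spurious central trough
that appears while a tissue core is still unstained.

*Segment statistics.* Between consecutive edges, statistics of the
smoothed profile (mean, median, SD with n−1, IQR by linear interpolation
between order statistics) are computed on the open interval so edge
samples are not shared between neighbouring segments; at least 4 interior
samples are required.

## Stain parameters

Per slice and time, with segments labeled `background` (inner brain
case), `brain_tissue`, or `excluded_nerve` (e.g. vagus crossings on
slice 4, excluded from all contrast metrics):

- **P1** — |derivative| at each brain-tissue edge (HU/mm); inter-tissue
  contrast.
- **P2** — pooled mean over brain-tissue samples minus pooled mean over
  background samples (HU). Pooling is sample-count weighted, i.e. the
  mean over the union of interval samples, not the mean of interval
  means; the extracted-table format therefore carries an `n_samples`
  column.
- **P3** — IQR of smoothed intensities per brain-tissue interval (HU);
  intra-tissue homogeneity, lower is better. Multi-tissue slices carry
  one value per tissue and the per-slice scalar is their mean (the same
  two-stage averaging the whole-brain pooling uses), which coincides with
  the single-interval definition on slices 2–4.
- **P4** — tissue width `x_right − x_left` (mm) per brain interval.

Whole-brain series average each parameter within a slice first, then
across the four slices, at each time. Width pooling excludes the shark's
slice-1 anterior telencephalon, which shrinks rostro-caudally as well as
transversally and would bias a transect-based width.

Linear shrinkage per region (OBs/Tel/Cer/Med on slices 1–4) is
`100 × (start − end) / start` between the first and last staining times,
with per-slice widths averaged first. Swelling (negative values) is
reported with its sign. Summary tables give region means ± SD (n−1)
across specimens and a flat overall mean ± SD across all
region × specimen values (not the mean of region means; the two differ
whenever region counts are unequal).

## Optimal staining time

*Slice level.* (1) Keep times at which every expected brain-tissue edge
has P1 ≥ threshold. The default threshold is 10× the median P1 of the
unstained (T0) scan — the pre-uptake noise floor — with a configurable
absolute floor. (2) Among the survivors take the minimum-P3 time;
candidates with P3 within 5% (relative, configurable) are tied and the
largest P2 decides. A series with no survivor returns a no-optimum
decision flagged `understained`.

*Whole-brain level.* Onset of uptake is the earliest time at which mean
P2 reaches 10% (configurable) of its series maximum; P2 is used because
it is ≈ 0 (often slightly negative, as the case stains first) before
uptake. From onset onward the chosen time maximizes mean P1 and mean P2
and minimizes mean P3. When the three criteria disagree — common once
uptake saturates and P1 plateaus — the decision lists each criterion's
arg-optimum, takes the majority, resolves remaining ties toward the
latest time, and flags the disagreement. The disagreement policy is this
package's own convention; the study it models only reports the
unambiguous case.

## HU calibration

Reconstructed attenuation is mapped to Hounsfield units with the standard
affine transform `HU = 1000 (v − μ_water)/(μ_water − μ_air)`, where the
phantom summaries are per-tail trimmed means (5% default) to resist
reconstruction artifacts. Any single-number phantom summary consistent
with `HU(μ_water) = 0`, `HU(μ_air) = −1000` would do; the trimmed mean is
chosen for robustness.

## Synthetic stain-ingress generator

The generator provides profiles with known ground truth so every stage is
testable without the raw volumes (which are not publicly deposited).

- **Geometry.** Each probe crosses `outside | case | tissue | case | ... |
  outside`; tissue intervals and a flanking brain-case margin define all
  edges. Slice geometries mirror the study: shark slice 1 has three
  tissues (OB, anterior telencephalon, OB), goldfish slice 1 two OBs,
  slices 2–3 a single tissue, slice 4 a medulla flanked by two nerve
  crossings.
- **Uptake.** Interior concentration is the two-front diffusion profile
  `c_max · clip(erfc(d_L/2√(Dt)) + erfc(d_R/2√(Dt)), 0, 1)` — concave
  (understained) early, flat at saturation — plus an optional overstain
  term `rate · t · e^{−d/w}` that accumulates near the boundaries and
  turns the interior convex. This is the simplest shape producing the
  observed concave → flat → convex progression, not a physical model of
  iodine binding.
- **Case and baseline.** The case saturates quickly
  (`case_max(1 − e^{−t/τ_case})`) and both case and tissue carry small
  unstained contrast offsets so edges are faintly visible at T0, as in
  real reconstructions (and so T0 widths are measurable at all).
- **Shrinkage.** `s(t) = s_max(1 − e^{−t/τ})`, applied as inward
  displacement of tissue boundaries (the measurement is geometric, so the
  emulation is geometric); case outer boundaries stay fixed.
- **Noise.** Additive i.i.d. Gaussian, one explicitly keyed stream per
  (seed, species, specimen, slice, time), so any subset of a study
  regenerates bit-identically.

**Default conditions.** 500 samples per probe; time grids 0–240 h every
48 h (shark) and 0–96 h every 24 h (goldfish); per-slice tissue widths
chosen so the whole-brain mean width at T0 equals the study's reported
5.46 mm (shark) and 2.38 mm (goldfish); `s_max` chosen so the end-time
shrinkage equals the shrinkage implied by the reported whole-brain widths
(12.45% and 20.17%); diffusivities (0.02 and 0.022 mm²/h base, scaled
1.4/1.0/0.8/0.6 over slices 1–4 to mimic faster anterior penetration) set
so intra-tissue homogeneity keeps improving through the final scan, as
observed; uptake plateaus (14 000 / 28 000 HU) and case levels of the
magnitude the study reports; default noise of 100–150 HU (≈ 1% of the
uptake plateau, representative of filtered reconstructions); a small
overstain rate on slice 1 only, where the study observed late
overstaining.

**What the generator does not emulate:** 2-D/3-D structure, registration
error, probe placement drift, beam hardening, non-Gaussian reconstruction
artifacts, intra-tissue texture (myelinated vs unmyelinated fibre
contrast), and between-specimen biological variation. Passing recovery
tests therefore demonstrates the correctness and noise-robustness of the
analysis chain under the assumed signal model, not performance on raw
scanner output.

## Problem sizes and numerical choices

The shipped demo study is one specimen per species × 4 slices × 6 (shark)
or 5 (goldfish) times = 44 profiles of 500 samples. Replicated-noise
checks use 50–100 replicates of single profiles or of the goldfish study;
these sizes give binomial confidence adequate for the ≥ 90% / ≥ 95% rate
checks while keeping a full run in minutes. Tolerances asserted in tests:
noiseless edge localization within one sample spacing (three spacings at
5% noise); end-to-end shrinkage recovery within one percentage point at
zero noise; published-table arithmetic to the printed precision.

## Known limitations

- Exact numeric agreement with the original study's extracted values is
  not expected: its spline implementation and smoothing parameter are
  unpublished, so only tolerance-level agreement on derived conclusions
  (optimal times, shrinkage summaries) is meaningful.
- The slice-level step-1 rule requires *all* expected edges to pass;
  anatomies where a region only becomes visible at the final time will
  report earlier times as failing step 1 rather than partially visible.
- P1 is nearly flat after uptake saturates, so the whole-brain
  criteria often formally disagree while P2/P3 are decisive; the majority
  rule resolves this but the flag should be inspected.
- Shrinkage uses only the first and last times; intermediate kinetics are
  reported in the width series but not summarized.
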
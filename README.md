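# dicect

Quantitative assessment of iodine stain uptake for diceCT imaging of fish
heads.

Diffusible iodine-based contrast-enhanced CT (diceCT) makes soft tissue
visible to micro-CT by immersing fixed specimens in Lugol's iodine
(aqueous I₂KI) and rescanning at intervals. The stain diffuses inward and
simultaneously shrinks tissue, so staining time must be optimized: long
enough for homogeneous intra-tissue uptake and strong tissue/background
contrast, short enough to limit scan time and shrinkage. `dicect`
implements the line-probe workflow used to make that decision for a
cartilaginous fish (brownbanded bamboo shark, *Chiloscyllium punctatum*)
and a bony fish (goldfish, *Carassius auratus*), and ships a synthetic
stain-ingress generator so the whole chain is testable without raw CT
volumes.

## What it computes

For each brain slice and staining time *T*, a horizontal line probe
(*n* = 500 samples, positions in mm, intensities in HU) is analysed:

1. a penalized cubic smoothing spline (GCV-selected penalty) is fitted
   and its first derivative computed analytically;
2. significant derivative peaks (prominence ≥ 3 robust σ) mark tissue
   edges x₁, x₂, …; pairs are selected about the probe midpoint, with a
   declarative override for difficult profiles;
3. per edge and inter-edge interval:
   - **P1** = |dI/dx| at each brain-tissue edge (HU/mm) — edge strength,
   - **P2** = mean(brain tissue) − mean(background case) (HU),
   - **P3** = IQR within brain tissue (HU) — staining homogeneity,
   - **P4** = tissue width x_right − x_left (mm);
4. linear shrinkage per brain region:
   `100 × (start width − end width) / start width` (%);
5. optimal staining time: per slice, the minimum-P3 time among times
   where every edge shows a clear P1 response (ties broken by largest
   P2); for the whole brain, the time maximizing mean P1 and P2 and
   minimizing post-onset mean P3.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate the default two-species demo study and analyse it:

```sh
dicect simulate --out profiles.csv --seed 1
dicect analyze --profiles profiles.csv --out results/
dicect optimal-time --metrics results/whole_brain.csv
```

The last command prints (noise realisations vary slightly with the seed):

```
C_auratus CA2: optimal T = 96.0 h (onset 24.0 h) [disagreement]
C_punctatum CP2: optimal T = 240.0 h (onset 48.0 h) [disagreement]
```

i.e. stain uptake begins within the first scan interval and the optimal
whole-brain staining time is the final scan — 240 h for the shark and
96 h for the goldfish, matching the study conditions the generator
emulates. (The `disagreement` flag notes that the P1 criterion is flat
after uptake saturates while P2/P3 are decisive; the decision trace in
`results/decisions.yaml` records each criterion's arg-optimum.)
`results/shrinkage_summary.csv` reports the whole-brain linear shrinkage
implied by the measured widths, e.g. for the shark a mean width falling
from ≈ 5.45 mm (T₀) to ≈ 4.76 mm (240 h), ≈ 12.7 % linear shrinkage.

The same operations are available as a library:

```python
from dicect import (demo_specs, generate_study, analyze_study,
                    metrics_from_records, aggregate_whole_brain,
                    whole_brain_optimal_time)

series, truth = generate_study(demo_specs(seed=1))
records, failures = analyze_study(series)
metrics, _ = metrics_from_records(records, series)
goldfish = [m for m in metrics if m.species == "C_auratus"]
print(whole_brain_optimal_time(aggregate_whole_brain(goldfish)).chosen_time_h)
# 96.0
```

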
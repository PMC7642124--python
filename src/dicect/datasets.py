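"""Bundled reference measurements from the diceCT staining study.

Published per-specimen regional linear-shrinkage percentages and
whole-brain mean tissue widths for the two study species (three measured
specimens per species), used as golden values for the summary arithmetic
and as the calibration for the default synthetic-study geometry.
"""

from __future__ import annotations

import pandas as pd

from .stain_metrics import ShrinkageResult

#: Regional linear shrinkage (%) per specimen: brownbanded bamboo shark
#: (*C. punctatum*, CP2-CP4) and goldfish (*C. auratus*, CA2-CA4), for the
#: olfactory bulbs (OBs, slice 1), telencephalon (Tel, slice 2),
#: cerebellum (Cer, slice 3) and medulla oblongata (Med, slice 4).
REFERENCE_SHRINKAGE = {
    "C_punctatum": {
        "OBs": {"CP2": 13.20, "CP3": 7.61, "CP4": 21.48},
        "Tel": {"CP2": 11.04, "CP3": 11.89, "CP4": 14.63},
        "Cer": {"CP2": 12.74, "CP3": 12.01, "CP4": 7.44},
        "Med": {"CP2": 18.79, "CP3": 10.24, "CP4": 21.36},
    },
    "C_auratus": {
        "OBs": {"CA2": 11.61, "CA3": 9.13, "CA4": 5.75},
        "Tel": {"CA2": 14.62, "CA3": 17.26, "CA4": 27.76},
        "Cer": {"CA2": 24.90, "CA3": 25.57, "CA4": 20.13},
        "Med": {"CA2": 13.68, "CA3": 16.39, "CA4": 26.42},
    },
}

#: Whole-brain mean tissue width (mm) at the first (T0) and last staining
#: time, pooled over the four slices and three specimens per species.
REFERENCE_WHOLE_BRAIN_WIDTHS_MM = {
    "C_punctatum": {"start": 5.46, "end": 4.78},
    "C_auratus": {"start": 2.38, "end": 1.90},
}

#: Whole-brain optimal staining time (h) per species.
REFERENCE_OPTIMAL_TIME_H = {"C_punctatum": 240.0, "C_auratus": 96.0}


def load_reference_shrinkage() -> pd.DataFrame:
    """Reference shrinkage table in tidy form (one row per region x specimen)."""
    rows = []
    for species, regions in REFERENCE_SHRINKAGE.items():
        for region, specimens in regions.items():
            for specimen, pct in specimens.items():
                rows.append({"species": species, "region": region,
                             "specimen": specimen, "percent": pct})
    return pd.DataFrame(rows)


def reference_shrinkage_results() -> list[ShrinkageResult]:
    """Reference percentages as :class:`ShrinkageResult` objects.

    Only the percentages are published; start widths are normalized to
    1 mm and end widths derived, which leaves every percentage (and hence
    all summary statistics over them) exact.
    """
    results = []
    for _, row in load_reference_shrinkage().iterrows():
        results.append(ShrinkageResult(
            species=row["species"], specimen_id=row["specimen"],
            region=row["region"], start_width_mm=1.0,
            end_width_mm=1.0 - row["percent"] / 100.0))
    return results
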
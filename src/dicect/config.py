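"""Species/slice anatomy configuration and analysis settings.

A line probe crosses, from left to right, an alternation of brain-case
("background") intervals and neural-tissue intervals::

    outside | case | tissue | case | tissue | ... | case | outside

Each boundary between adjacent intervals is a detectable edge, so a slice
with ``k`` interior intervals carries ``k + 1`` edges.  The anatomy config
records, per species and slice, the ordered labels of the interior
intervals, which of them count as brain tissue for the contrast metrics
(P1-P3), which are excluded nerves, and which brain intervals are dropped
from width pooling (the shark's anterior telencephalon on slice 1 shrinks
both transversally and rostro-caudally, so its width is biased and is
excluded from shrinkage and whole-brain width averages).

Labels
------
``background``
    Inner brain case flanking the tissue; the reference for P2.
``brain_tissue``
    A neural-tissue interval contributing to P1-P4.
``excluded_nerve``
    A stained nerve (e.g. the vagus) crossed by the probe; its intervals
    and edges are excluded from P1-P3 and from width pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

BACKGROUND = "background"
BRAIN_TISSUE = "brain_tissue"
EXCLUDED_NERVE = "excluded_nerve"

VALID_LABELS = (BACKGROUND, BRAIN_TISSUE, EXCLUDED_NERVE)

#: Brain region sampled by each slice (1-4).
DEFAULT_REGION_MAP = {1: "OBs", 2: "Tel", 3: "Cer", 4: "Med"}


@dataclass(frozen=True)
class SliceAnatomy:
    """Interior interval labels for one (species, slice) line probe."""

    labels: tuple[str, ...]
    #: indices (into ``labels``) of brain intervals excluded from width
    #: pooling and shrinkage (but still part of P1-P3).
    width_excluded: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in VALID_LABELS:
                raise ValueError(f"unknown segment label {lab!r}")
        if self.labels[0] != BACKGROUND or self.labels[-1] != BACKGROUND:
            raise ValueError("interior intervals must start and end with background")

    @property
    def n_edges(self) -> int:
        return len(self.labels) + 1

    @property
    def n_pairs(self) -> int:
        if self.n_edges % 2:
            raise ValueError("edge count must be even for pairing")
        return self.n_edges // 2

    @property
    def brain_segments(self) -> tuple[int, ...]:
        return tuple(i for i, lab in enumerate(self.labels) if lab == BRAIN_TISSUE)

    @property
    def n_tissue_edges(self) -> int:
        """Edges adjacent to brain tissue: two per brain interval."""
        return 2 * len(self.brain_segments)


# Slice geometry shared by both study species for slices 2-3 (single
# tissue) and slice 4 (medulla flanked by two vagus-nerve crossings, giving
# the four background intervals counted on that slice).
_SINGLE = SliceAnatomy((BACKGROUND, BRAIN_TISSUE, BACKGROUND))
_SLICE4 = SliceAnatomy(
    (BACKGROUND, EXCLUDED_NERVE, BACKGROUND, BRAIN_TISSUE,
     BACKGROUND, EXCLUDED_NERVE, BACKGROUND)
)

#: Default anatomy per species.  Shark slice 1 crosses OB, anterior
#: telencephalon (width-excluded), OB; goldfish slice 1 crosses the two OBs.
DEFAULT_ANATOMY: dict[str, dict[int, SliceAnatomy]] = {
    "C_punctatum": {
        1: SliceAnatomy(
            (BACKGROUND, BRAIN_TISSUE, BACKGROUND, BRAIN_TISSUE,
             BACKGROUND, BRAIN_TISSUE, BACKGROUND),
            width_excluded=(3,),
        ),
        2: _SINGLE,
        3: _SINGLE,
        4: _SLICE4,
    },
    "C_auratus": {
        1: SliceAnatomy(
            (BACKGROUND, BRAIN_TISSUE, BACKGROUND, BRAIN_TISSUE, BACKGROUND)
        ),
        2: _SINGLE,
        3: _SINGLE,
        4: _SLICE4,
    },
}


@dataclass
class AnalysisSettings:
    """Tunable thresholds for peak analysis and optimality rules.

    All values are surfaced in the YAML config under the keys used here.
    """

    # peak_analysis
    smoothing: str | float = "auto"  # "auto" = GCV, else fixed lambda
    min_prominence: str | float = "auto"  # "auto" = k * robust sigma
    prominence_k: float = 3.0
    min_separation: int = 5  # samples
    suppression_samples: int = 10  # NMS radius during automatic pairing
    override_window: int = 10  # samples, for declarative edge overrides
    # optimal_time
    p1_threshold: str | float = "auto"  # "auto" = 10 x median P1 at T0
    p1_auto_factor: float = 10.0
    p1_floor: float = 1e-6  # HU/mm floor under the auto rule
    p3_tie_rel_tol: float = 0.05
    onset_fraction: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "AnalysisSettings":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        merged = {}
        for section in ("peak_analysis", "optimal_time"):
            merged.update(raw.get(section, {}))
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in merged.items() if k in known})

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def anatomy_for(species: str, slice_index: int,
                anatomy: dict[str, dict[int, SliceAnatomy]] | None = None
                ) -> SliceAnatomy:
    table = anatomy if anatomy is not None else DEFAULT_ANATOMY
    try:
        return table[species][slice_index]
    except KeyError:
        raise KeyError(
            f"no anatomy configured for species={species!r} slice={slice_index}"
        ) from None
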
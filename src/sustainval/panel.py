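"""Biomarker panel definition.

A panel is the ordered list of regional volumetric biomarkers entering the
progression model, each with an abnormality direction: atrophying regions
become abnormal when *smaller* than the control distribution, while the
ventricles become abnormal when *larger* (expansion).  Every biomarker
traverses the integer z-score severity levels 1, 2 and 3, so a panel of B
regions defines N = 3*B model events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ATROPHY = 1
EXPANSION = -1

Z_LEVELS = (1, 2, 3)
MAX_Z = 3.0


@dataclass(frozen=True)
class BiomarkerPanel:
    """Ordered biomarker names plus per-region abnormality directions."""

    names: tuple[str, ...]
    directions: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("panel names must be unique")
        if len(self.names) < 1:
            raise ValueError("panel must contain at least one biomarker")
        if not self.directions:
            object.__setattr__(self, "directions", tuple(ATROPHY for _ in self.names))
        if len(self.directions) != len(self.names):
            raise ValueError("one direction per biomarker required")
        if any(d not in (ATROPHY, EXPANSION) for d in self.directions):
            raise ValueError("directions must be ATROPHY (+1) or EXPANSION (-1)")

    @property
    def n_biomarkers(self) -> int:
        return len(self.names)

    @property
    def n_events(self) -> int:
        """Total number of model stages N = 3 * number of biomarkers."""
        return len(Z_LEVELS) * len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"biomarker {name!r} not in panel") from None

    def to_dict(self) -> dict:
        return {"names": list(self.names), "directions": list(self.directions)}

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerPanel":
        return cls(names=tuple(d["names"]), directions=tuple(d["directions"]))


#: The 13 regions used throughout: bilateral volumes averaged over hemispheres,
#: ventricles given as 3rd + lateral.  All regions atrophy except the
#: ventricles, which expand as disease progresses.
DEFAULT_REGIONS = (
    "hippocampus",
    "fusiform",
    "entorhinal",
    "middle_temporal",
    "precuneus",
    "amygdala",
    "insula",
    "thalamus",
    "putamen",
    "caudate",
    "accumbens",
    "pallidum",
    "ventricles",
)

DEFAULT_PANEL = BiomarkerPanel(
    names=DEFAULT_REGIONS,
    directions=tuple(EXPANSION if r == "ventricles" else ATROPHY for r in DEFAULT_REGIONS),
)
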
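"""Stimulus geometry and condition enumeration for the crowding experiment.

The experiment shows a peripheral Landolt C (an annulus with a gap; the
"orientation" is the angular position of the gap on the full 360-degree
circle) centred 10 degrees to the right of fixation, optionally surrounded
by a concentric flanker ring that is featureless (no gap), has one gap, or
has two gaps. Every downstream module — the synthetic observer, the error
taxonomy, the mixture fits — shares the single parameterisation defined
here, so the constants live in one place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "UNFLANKED",
    "NO_GAP",
    "ONE_GAP",
    "TWO_GAP",
    "FLANKED_TYPES",
    "ExperimentDesign",
    "Condition",
    "proportional_radius",
    "enumerate_conditions",
]

# flanker_type labels; "unflanked" is the explicit sentinel for the
# infinite-separation condition (never a numeric infinity in tables).
UNFLANKED = "unflanked"
NO_GAP = "no_gap"
ONE_GAP = "one_gap"
TWO_GAP = "two_gap"
FLANKED_TYPES = (NO_GAP, ONE_GAP, TWO_GAP)


@dataclass(frozen=True)
class ExperimentDesign:
    """All stimulus and session constants of the method-of-adjustment design.

    Defaults are the experiment's values: target eccentricity 10 deg, target
    diameter 2 deg, five edge-to-edge target-flanker separations, flanker-gap
    offsets drawn with SD 22.5 deg, a second gap centred 180 deg from the
    first, 20 repetitions per condition per session over 5 sessions.
    """

    eccentricity_deg: float = 10.0
    target_diameter_deg: float = 2.0
    line_width_deg: float = 0.4
    gap_width_deg: float = 0.4
    edge_separations_deg: tuple[float, ...] = (0.4, 0.92, 1.62, 2.58, 3.9)
    flanker_types: tuple[str, ...] = (UNFLANKED, NO_GAP, ONE_GAP, TWO_GAP)
    flanker_offset_sd_deg: float = 22.5
    far_gap_center_deg: float = 180.0
    reps_per_condition_per_session: int = 20
    n_sessions: int = 5
    target_duration_ms: float = 500.0  # metadata only; never used in analysis

    def __post_init__(self):
        if self.eccentricity_deg <= 0 or self.target_diameter_deg <= 0:
            raise ValueError("eccentricity and target diameter must be positive")
        seps = tuple(float(s) for s in self.edge_separations_deg)
        if any(s <= 0 for s in seps):
            raise ValueError("edge separations must be positive")
        if any(b <= a for a, b in zip(seps, seps[1:])):
            raise ValueError("edge separations must be strictly increasing")
        if self.flanker_offset_sd_deg < 0:
            raise ValueError("flanker_offset_sd_deg must be non-negative")
        if not 0.0 < self.far_gap_center_deg <= 180.0:
            raise ValueError("far_gap_center_deg must lie in (0, 180]")
        unknown = set(self.flanker_types) - {UNFLANKED, *FLANKED_TYPES}
        if unknown:
            raise ValueError(f"unknown flanker types: {sorted(unknown)}")
        object.__setattr__(self, "edge_separations_deg", seps)
        object.__setattr__(self, "flanker_types", tuple(self.flanker_types))

    @property
    def trials_per_session(self) -> int:
        return len(enumerate_conditions(self)) * self.reps_per_condition_per_session

    @property
    def n_trials_total(self) -> int:
        return self.trials_per_session * self.n_sessions

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["edge_separations_deg"] = list(self.edge_separations_deg)
        d["flanker_types"] = list(self.flanker_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        """Write the design as YAML (.yml/.yaml) or JSON (anything else)."""
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentDesign":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    def replace(self, **changes) -> "ExperimentDesign":
        return replace(self, **changes)


@dataclass(frozen=True)
class Condition:
    """One target-flanker condition.

    ``edge_separation_deg`` is None for the unflanked sentinel, in which
    case ``proportional_radius`` is undefined (None).
    """

    flanker_type: str
    edge_separation_deg: float | None

    def __post_init__(self):
        if (self.flanker_type == UNFLANKED) != (self.edge_separation_deg is None):
            raise ValueError("edge separation must be absent iff unflanked")

    def proportional_radius(self, design: ExperimentDesign) -> float | None:
        """Flanker outer radius as a proportion of eccentricity (Bouma units)."""
        if self.flanker_type == UNFLANKED:
            return None
        return proportional_radius(self.edge_separation_deg, design)

    @property
    def key(self) -> tuple:
        return (self.flanker_type, self.edge_separation_deg)


def proportional_radius(edge_separation_deg: float, design: ExperimentDesign) -> float:
    """Flanker outer radius divided by target eccentricity.

    The flanker's outer radius equals the target's outer radius (half the
    target diameter) plus the edge-to-edge separation. For the standard
    design the five separations give 0.14, 0.19, 0.26, 0.36 and 0.49 (to
    2 d.p.); full precision is returned, rounding is for labels only.
    """
    if edge_separation_deg < 0:
        raise ValueError("edge separation must be non-negative")
    if design.eccentricity_deg <= 0 or design.target_diameter_deg <= 0:
        raise ValueError("design must have positive eccentricity and target diameter")
    return (design.target_diameter_deg / 2.0 + edge_separation_deg) / design.eccentricity_deg


def enumerate_conditions(design: ExperimentDesign) -> list[Condition]:
    """All conditions in canonical order: unflanked first, then flanker type
    (no_gap, one_gap, two_gap) by increasing separation.

    The canonical order is an analysis convention so per-condition outputs
    are comparable across runs; at experiment run time conditions were
    interleaved randomly, which is the generator's concern.
    """
    out: list[Condition] = []
    if UNFLANKED in design.flanker_types:
        out.append(Condition(UNFLANKED, None))
    for ftype in FLANKED_TYPES:
        if ftype not in design.flanker_types:
            continue
        for sep in design.edge_separations_deg:
            out.append(Condition(ftype, sep))
    return out
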
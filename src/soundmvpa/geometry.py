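"""The 16-speaker spherical array and the discrimination-condition labelings.

The array places 16 loudspeakers on an 80 cm sphere around the listener's
head: one at the pole (elevation +90°), four on the +45° hoop, eight on the
horizontal hoop, and three on the −45° hoop.  Azimuth is measured in
degrees with 0° straight ahead, negative values to the listener's left and
180° directly behind; elevation 0° is the horizontal plane.

Three binary discrimination conditions are defined over the array:
``left_vs_right`` (sign of azimuth), ``up_vs_down`` (sign of elevation) and
``front_vs_back`` (|azimuth| below vs. above 90°).  Locations that sit on
the dividing boundary of a condition are excluded from that condition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CONDITIONS",
    "DEFAULT_RADIUS_CM",
    "SpeakerLocation",
    "SpeakerArray",
    "ConditionLabeling",
    "build_speaker_array",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "hoop_radius",
    "condition_labels",
    "behavioral_label",
]

#: The three binary discrimination conditions.
CONDITIONS = ("left_vs_right", "up_vs_down", "front_vs_back")

#: Sphere radius of the canonical array, in centimetres.
DEFAULT_RADIUS_CM = 80.0

#: Stimulus presentations per speaker in the free-field behavioral protocol.
BEHAVIORAL_REPETITIONS = 5


@dataclass(frozen=True)
class SpeakerLocation:
    """A single speaker position in head-centred spherical coordinates.

    Azimuth lies in (−180, 180] with negative values to the left; elevation
    lies in [−90, 90] with 0 on the horizontal plane.
    """

    location_id: int
    azimuth_deg: float
    elevation_deg: float
    radius_cm: float = DEFAULT_RADIUS_CM

    def __post_init__(self) -> None:
        if not (-180.0 < self.azimuth_deg <= 180.0):
            raise ValueError(f"azimuth_deg must be in (-180, 180], got {self.azimuth_deg}")
        if not (-90.0 <= self.elevation_deg <= 90.0):
            raise ValueError(f"elevation_deg must be in [-90, 90], got {self.elevation_deg}")
        if self.radius_cm <= 0:
            raise ValueError(f"radius_cm must be positive, got {self.radius_cm}")

    @property
    def cartesian_cm(self) -> tuple[float, float, float]:
        return spherical_to_cartesian(self.azimuth_deg, self.elevation_deg, self.radius_cm)


@dataclass(frozen=True)
class SpeakerArray:
    """An ordered collection of speaker locations with unique ids."""

    locations: tuple[SpeakerLocation, ...]

    def __post_init__(self) -> None:
        ids = [loc.location_id for loc in self.locations]
        if len(set(ids)) != len(ids):
            raise ValueError("location_ids must be unique")
        angles = {(loc.azimuth_deg, loc.elevation_deg) for loc in self.locations}
        if len(angles) != len(self.locations):
            raise ValueError("(azimuth, elevation) pairs must be unique")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    def __getitem__(self, location_id: int) -> SpeakerLocation:
        for loc in self.locations:
            if loc.location_id == location_id:
                return loc
        raise KeyError(location_id)

    @property
    def location_ids(self) -> tuple[int, ...]:
        return tuple(loc.location_id for loc in self.locations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": [loc.location_id for loc in self.locations],
                "azimuth_deg": [loc.azimuth_deg for loc in self.locations],
                "elevation_deg": [loc.elevation_deg for loc in self.locations],
                "radius_cm": [loc.radius_cm for loc in self.locations],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeakerArray":
        df = pd.read_csv(path, sep="\t")
        required = {"location_id", "azimuth_deg", "elevation_deg", "radius_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"speaker table missing columns: {sorted(missing)}")
        locs = tuple(
            SpeakerLocation(
                location_id=int(r.location_id),
                azimuth_deg=float(r.azimuth_deg),
                elevation_deg=float(r.elevation_deg),
                radius_cm=float(r.radius_cm),
            )
            for r in df.itertuples()
        )
        return cls(locs)


@dataclass(frozen=True)
class ConditionLabeling:
    """Binary class assignment of the 16 locations for one condition.

    ``class_a``, ``class_b`` and ``excluded`` partition the location ids;
    boundary locations are excluded rather than assigned arbitrarily.
    """

    condition: str
    class_a: frozenset[int]
    class_b: frozenset[int]
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.class_a or not self.class_b:
            raise ValueError("class_a and class_b must be non-empty")
        if self.class_a & self.class_b:
            raise ValueError("class_a and class_b must be disjoint")
        if (self.class_a | self.class_b) & self.excluded:
            raise ValueError("excluded overlaps a class")

    @property
    def included(self) -> frozenset[int]:
        return self.class_a | self.class_b

    def label_of(self, location_id: int) -> int:
        """+1 for class_a, −1 for class_b; KeyError if excluded/unknown."""
        if location_id in self.class_a:
            return +1
        if location_id in self.class_b:
            return -1
        raise KeyError(f"location {location_id} is not part of condition {self.condition}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": self.condition,
            "class_a": sorted(self.class_a),
            "class_b": sorted(self.class_b),
            "excluded": sorted(self.excluded),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionLabeling":
        payload = json.loads(Path(path).read_text())
        return cls(
            condition=payload["condition"],
            class_a=frozenset(payload["class_a"]),
            class_b=frozenset(payload["class_b"]),
            excluded=frozenset(payload["excluded"]),
        )


# (elevation, azimuths) rings of the canonical array, pole included.
_RING_SPEC: tuple[tuple[float, tuple[float, ...]], ...] = (
    (-45.0, (0.0, -90.0, 90.0)),
    (0.0, (0.0, -45.0, 45.0, -90.0, 90.0, -135.0, 135.0, 180.0)),
    (45.0, (0.0, -90.0, 90.0, 180.0)),
    (90.0, (0.0,)),
)


def build_speaker_array(radius_cm: float = DEFAULT_RADIUS_CM) -> SpeakerArray:
    """Build the canonical 16-speaker array.

    Location ids are assigned deterministically: elevation-major
    (ascending), azimuth-minor (ascending) ordering, so id 0 is the
    (−45°, −90°) speaker and id 15 the pole.
    """
    positions = sorted(
        ((el, az) for el, azimuths in _RING_SPEC for az in azimuths),
        key=lambda p: (p[0], p[1]),
    )
    locations = tuple(
        SpeakerLocation(location_id=i, azimuth_deg=az, elevation_deg=el, radius_cm=radius_cm)
        for i, (el, az) in enumerate(positions)
    )
    return SpeakerArray(locations)


def spherical_to_cartesian(
    azimuth_deg: float, elevation_deg: float, radius_cm: float
) -> tuple[float, float, float]:
    """Head-centred frame: x forward, y rightward, z upward.

    Negative azimuth (left) maps to negative y.
    """
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    return (
        radius_cm * math.cos(el) * math.cos(az),
        radius_cm * math.cos(el) * math.sin(az),
        radius_cm * math.sin(el),
    )


def cartesian_to_spherical(x_cm: float, y_cm: float, z_cm: float) -> tuple[float, float, float]:
    """Inverse of :func:`spherical_to_cartesian`; azimuth 0 at the pole."""
    radius = math.sqrt(x_cm**2 + y_cm**2 + z_cm**2)
    if radius == 0:
        raise ValueError("zero radius has no angular coordinates")
    elevation = math.degrees(math.asin(max(-1.0, min(1.0, z_cm / radius))))
    if abs(abs(elevation) - 90.0) < 1e-12:
        azimuth = 0.0
    else:
        azimuth = math.degrees(math.atan2(y_cm, x_cm))
        if azimuth <= -180.0:
            azimuth += 360.0
    return azimuth, elevation, radius


def hoop_radius(elevation_deg: float, sphere_radius_cm: float = DEFAULT_RADIUS_CM) -> float:
    """Radius of the horizontal hoop through a given elevation on the sphere."""
    if abs(elevation_deg) > 90.0:
        raise ValueError("elevation must lie in [-90, 90]")
    return sphere_radius_cm * math.cos(math.radians(elevation_deg))


def condition_labels(
    array: SpeakerArray,
    condition: str,
    *,
    pole_is_up: bool = True,
) -> ConditionLabeling:
    """Class membership of every speaker for one discrimination condition.

    left_vs_right splits on the sign of azimuth (0° and 180° excluded,
    pole excluded); up_vs_down on the sign of elevation (horizontal ring
    excluded, pole counted as "up" unless ``pole_is_up`` is False);
    front_vs_back on |azimuth| below/above 90° (the ±90° cone and the pole
    excluded).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")

    class_a: set[int] = set()
    class_b: set[int] = set()
    excluded: set[int] = set()
    for loc in array:
        az, el = loc.azimuth_deg, loc.elevation_deg
        at_pole = el == 90.0
        if condition == "left_vs_right":
            if at_pole or az in (0.0, 180.0):
                excluded.add(loc.location_id)
            elif az < 0:
                class_a.add(loc.location_id)
            else:
                class_b.add(loc.location_id)
        elif condition == "up_vs_down":
            if at_pole and not pole_is_up:
                excluded.add(loc.location_id)
            elif el > 0:
                class_a.add(loc.location_id)
            elif el < 0:
                class_b.add(loc.location_id)
            else:
                excluded.add(loc.location_id)
        else:  # front_vs_back
            if at_pole or abs(az) == 90.0:
                excluded.add(loc.location_id)
            elif abs(az) < 90.0:
                class_a.add(loc.location_id)
            else:
                class_b.add(loc.location_id)
    return ConditionLabeling(
        condition=condition,
        class_a=frozenset(class_a),
        class_b=frozenset(class_b),
        excluded=frozenset(excluded),
    )


def behavioral_label(loc: SpeakerLocation) -> str:
    """Response category ('left' / 'middle' / 'right') for the button task."""
    if loc.elevation_deg == 90.0 or loc.azimuth_deg in (0.0, 180.0):
        return "middle"
    return "left" if loc.azimuth_deg < 0 else "right"


def all_condition_labels(array: SpeakerArray, **kwargs) -> dict[str, ConditionLabeling]:
    """Labelings for all three conditions keyed by condition name."""
    return {c: condition_labels(array, c, **kwargs) for c in CONDITIONS}
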
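"""Conical-frustum segment surrogates and virtual marker configurations.

The thigh and shank are modelled as conical frustums (truncated cones) with
the local Z axis inferior-superior (z = 0 at the distal end), X
anterior-posterior (anterior positive, azimuth 0°) and Y medial-lateral
(lateral positive).  The surface radius tapers linearly from ``r1`` at the
distal end to ``r2`` at the proximal end.

Markers may be placed only inside four disjoint placement *quadrants* (two
azimuthal bands x two height bands).  A virtual marker configuration draws
one marker uniformly at random within each quadrant and is rejected and
redrawn until minimum spacing rules between adjacent quadrants hold.

Anatomical landmarks are fixed named points in the segment-local frame:
ME/LE/FH/GT for the thigh and MM/LM/HF/TT for the shank.  The defaults are
stylized so that the anatomical frame constructed from them coincides
exactly with the segment-local axes on the untransformed template; all
coordinates are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import InvalidInputError

__all__ = [
    "InfeasibleRulesError",
    "QuadrantZone",
    "FrustumSegment",
    "SpacingRules",
    "MarkerConfiguration",
    "build_frustum",
    "sample_marker_configuration",
]

THIGH_LANDMARKS = ("ME", "LE", "FH", "GT")
SHANK_LANDMARKS = ("MM", "LM", "HF", "TT")


class InfeasibleRulesError(RuntimeError):
    """Raised when the rejection-sampling budget is exhausted."""


@dataclass(frozen=True)
class QuadrantZone:
    """One marker-placement zone: an azimuth range (deg) x height range (m)."""

    azimuth_min: float
    azimuth_max: float
    height_min: float
    height_max: float

    def contains(self, azimuth: float, height: float) -> bool:
        return (
            self.azimuth_min <= azimuth <= self.azimuth_max
            and self.height_min <= height <= self.height_max
        )


@dataclass
class FrustumSegment:
    """Conical-frustum geometry with placement zones and landmarks."""

    name: str  # "thigh" | "shank"
    r1: float  # radius at the distal end (z = 0), metres
    r2: float  # radius at the proximal end (z = h), metres
    h: float   # height, metres
    theta: float  # azimuthal extent of each placement zone, degrees
    quadrant_zones: list[QuadrantZone] = field(default_factory=list)
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.h) <= 0:
            raise InvalidInputError("r1, r2, h must be positive")
        expected = THIGH_LANDMARKS if self.name == "thigh" else SHANK_LANDMARKS
        if self.landmarks and set(self.landmarks) != set(expected):
            raise InvalidInputError(
                f"{self.name} landmarks must be named {expected}"
            )

    def surface_radius(self, z: float | np.ndarray) -> float | np.ndarray:
        """Surface radius at height z, linear taper between r1 and r2."""
        return self.r1 + (self.r2 - self.r1) * np.asarray(z) / self.h

    def surface_point(self, azimuth_deg: float, z: float) -> np.ndarray:
        """Local 3-vector of the surface point at (azimuth, height)."""
        rho = self.surface_radius(z)
        a = math.radians(azimuth_deg)
        return np.array([rho * math.cos(a), rho * math.sin(a), z])


@dataclass(frozen=True)
class SpacingRules:
    """Minimum-separation rules between markers of adjacent quadrants.

    ``min_azimuth_deg`` applies between the two markers of horizontally
    adjacent quadrants (same height band); ``min_height_frac`` (fraction of
    the frustum height) between vertically adjacent quadrants (same azimuth
    band).
    """

    min_azimuth_deg: float = 30.0
    min_height_frac: float = 0.2
    max_draws: int = 10_000


@dataclass
class MarkerConfiguration:
    """One accepted virtual marker configuration: one marker per quadrant."""

    surface_coords: np.ndarray  # (4, 2): azimuth deg, height m
    local_positions: np.ndarray  # (4, 3) metres, on the frustum surface
    quadrant_ids: np.ndarray  # (4,) ints 0..3

    @property
    def labels(self) -> list[str]:
        return [f"M{q}" for q in self.quadrant_ids]


def _default_zones(h: float, theta: float) -> list[QuadrantZone]:
    # Two azimuthal bands of extent theta centred anteriorly (0 deg) and
    # laterally (90 deg); two height bands in the lower/upper part of the
    # shaft.  The bands deliberately leave less clearance than the spacing
    # rules require, so rejection sampling is active.
    half = theta / 2.0
    az_bands = [(-half, half), (75.0 - half, 75.0 + half)]
    z_bands = [(0.05 * h, 0.45 * h), (0.55 * h, 0.95 * h)]
    zones = []
    for zb in z_bands:
        for ab in az_bands:
            zones.append(QuadrantZone(ab[0], ab[1], zb[0], zb[1]))
    return zones  # ids: 0 ant-low, 1 lat-low, 2 ant-up, 3 lat-up


def _thigh_landmarks(r1: float, r2: float, h: float) -> dict[str, np.ndarray]:
    return {
        "ME": np.array([0.0, -r1, 0.0]),            # medial epicondyle, distal rim
        "LE": np.array([0.0, r1, 0.0]),             # lateral epicondyle, distal rim
        "GT": np.array([0.0, r2, h]),               # greater trochanter, proximal lateral
        "FH": np.array([0.0, 0.0, h + 0.07]),       # femoral head, on the axis extended
    }


def _shank_landmarks(r1: float, r2: float, h: float) -> dict[str, np.ndarray]:
    c30, s30 = math.cos(math.radians(30.0)), math.sin(math.radians(30.0))
    return {
        "MM": np.array([0.0, -r1, 0.0]),            # medial malleolus, distal rim
        "LM": np.array([0.0, r1, 0.0]),             # lateral malleolus, distal rim
        "HF": np.array([-r2 * c30, r2 * s30, h]),   # fibular head, posterolateral proximal
        "TT": np.array([r2 * c30, -r2 * s30, 0.85 * h]),  # tibial tuberosity, anteromedial
    }


_DEFAULTS = {
    "thigh": dict(r1=0.055, r2=0.095, h=0.25, theta=60.0),
    "shank": dict(r1=0.04, r2=0.055, h=0.175, theta=60.0),
}


def build_frustum(segment: str, **overrides) -> FrustumSegment:
    """Build the thigh or shank frustum with anthropometric defaults.

    Defaults (r1, r2, h, theta): thigh (5.5 cm, 9.5 cm, 25 cm, 60°);
    shank (4 cm, 5.5 cm, 17.5 cm, 60°).  Keyword overrides may replace any
    of r1, r2, h, theta, quadrant_zones or landmarks.
    """
    if segment not in _DEFAULTS:
        raise InvalidInputError(f"unknown segment {segment!r}; expected 'thigh' or 'shank'")
    params = dict(_DEFAULTS[segment])
    params.update({k: v for k, v in overrides.items() if k in params})
    zones = overrides.get("quadrant_zones") or _default_zones(params["h"], params["theta"])
    landmarks = overrides.get("landmarks")
    if landmarks is None:
        maker = _thigh_landmarks if segment == "thigh" else _shank_landmarks
        landmarks = maker(params["r1"], params["r2"], params["h"])
    return FrustumSegment(name=segment, quadrant_zones=zones, landmarks=landmarks, **params)


def _circular_distance_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _spacing_ok(coords: np.ndarray, frustum: FrustumSegment, rules: SpacingRules) -> bool:
    # quadrant ids: 0 ant-low, 1 lat-low, 2 ant-up, 3 lat-up
    horizontal_pairs = [(0, 1), (2, 3)]
    vertical_pairs = [(0, 2), (1, 3)]
    for i, j in horizontal_pairs:
        if _circular_distance_deg(coords[i, 0], coords[j, 0]) < rules.min_azimuth_deg:
            return False
    for i, j in vertical_pairs:
        if abs(coords[i, 1] - coords[j, 1]) < rules.min_height_frac * frustum.h:
            return False
    return True


def sample_marker_configuration(
    frustum: FrustumSegment,
    rules: SpacingRules | None = None,
    rng: np.random.Generator | int | None = None,
) -> MarkerConfiguration:
    """Draw one marker uniformly within each quadrant, rejecting until the
    spacing rules hold.

    Deterministic given an integer seed or a seeded Generator.

    Raises
    ------
    InfeasibleRulesError
        If no accepted configuration is found within ``rules.max_draws``.
    """
    rules = rules or SpacingRules()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    zones = frustum.quadrant_zones
    if len(zones) != 4:
        raise InvalidInputError("frustum must define exactly 4 quadrant zones")
    for _ in range(rules.max_draws):
        coords = np.empty((4, 2))
        for q, zone in enumerate(zones):
            coords[q, 0] = rng.uniform(zone.azimuth_min, zone.azimuth_max)
            coords[q, 1] = rng.uniform(zone.height_min, zone.height_max)
        if _spacing_ok(coords, frustum, rules):
            local = np.array([frustum.surface_point(a, z) for a, z in coords])
            return MarkerConfiguration(coords, local, np.arange(4))
    raise InfeasibleRulesError(
        f"no configuration satisfying the spacing rules within {rules.max_draws} draws"
    )
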
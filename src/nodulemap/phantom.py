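"""Agar tissue-phantom model: soft matrix with stiff spherical inclusions.

The phantom is a rectangular Agar block mimicking healthy soft tissue, with
buried spherical inclusions of a stiffer, acoustically denser Agar mix that
mimic tumor nodules.  Two material recipes are modelled:

* ``HEALTHY_TISSUE`` — 2 g Agar / 100 mL water: acoustic impedance
  1.59 MRayl, speed of sound 1457 m/s, stiffness 0.33 N/mm.
* ``TUMOR_TISSUE`` — 8 g Agar / 100 mL water: 1.92 MRayl, 1534 m/s,
  4.6 N/mm.

Both attenuate ultrasound moderately (1.25 dB/cm at 16 MHz).

Coordinates are millimetres, origin at one phantom corner; x runs along the
100 mm edge, y along the 60 mm edge, z downward from the indented top
surface.  All intervals are closed.

The module also provides the two local physics models the scan simulator
samples per surface point:

* :func:`local_stiffness` — an effective indentation stiffness obtained by
  treating the material column under the probe as two springs in series
  (matrix above/below the inclusion, inclusion chord in between).
* :func:`reflection_coefficient_intensity` — the intensity reflection
  coefficient at a planar interface between two media, which justifies the
  reflectometric measurement: the healthy/tumor interface reflects < 1 % of
  the incident intensity, so the strong echo is the one from the steel
  plate under the phantom.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "MaterialProps",
    "Inclusion",
    "Phantom",
    "GeometryError",
    "HEALTHY_TISSUE",
    "TUMOR_TISSUE",
    "REFERENCE_DIAMETERS_MM",
    "make_reference_phantom",
    "reflection_coefficient_intensity",
    "inclusion_chord",
    "max_footprint_chord",
    "local_stiffness",
    "save_phantom",
    "load_phantom",
]


class GeometryError(ValueError):
    """Raised for impossible phantom geometry (overlap, containment, placement)."""


@dataclass(frozen=True)
class MaterialProps:
    """Acoustic and mechanical properties of one Agar mix.

    Attributes
    ----------
    acoustic_impedance_mrayl:
        Characteristic acoustic impedance Z in MRayl.
    speed_of_sound_m_s:
        Longitudinal speed of sound c in m/s.
    stiffness_n_mm:
        Indentation stiffness of the pure material in N/mm.
    attenuation_db_cm:
        One-way amplitude attenuation in dB/cm at ``attenuation_ref_mhz``.
    attenuation_ref_mhz:
        Frequency at which ``attenuation_db_cm`` was measured.
    """

    acoustic_impedance_mrayl: float
    speed_of_sound_m_s: float
    stiffness_n_mm: float
    attenuation_db_cm: float
    attenuation_ref_mhz: float = 16.0

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            value = getattr(self, name.name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"MaterialProps.{name.name} must be strictly positive, got {value!r}")


#: Healthy-tissue mimic (2 g Agar / 100 mL water).
HEALTHY_TISSUE = MaterialProps(
    acoustic_impedance_mrayl=1.59,
    speed_of_sound_m_s=1457.0,
    stiffness_n_mm=0.33,
    attenuation_db_cm=1.25,
    attenuation_ref_mhz=16.0,
)

#: Tumor-nodule mimic (8 g Agar / 100 mL water).
TUMOR_TISSUE = MaterialProps(
    acoustic_impedance_mrayl=1.92,
    speed_of_sound_m_s=1534.0,
    stiffness_n_mm=4.6,
    attenuation_db_cm=1.25,
    attenuation_ref_mhz=16.0,
)

#: Inclusion diameters of the reference phantom, two spheres each.
REFERENCE_DIAMETERS_MM = (3.0, 6.0, 9.0, 12.0)


@dataclass(frozen=True)
class Inclusion:
    """A spherical tumor-mimicking inclusion.

    ``has_air_bubble`` flags inclusions whose echo is partially restored
    toward the healthy level (air trapped during casting); the fraction of
    restoration is ``bubble_fraction`` in [0, 1).
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float
    material: MaterialProps = TUMOR_TISSUE
    has_air_bubble: bool = False
    bubble_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("inclusion diameter must be positive")
        if not (0.0 <= self.bubble_fraction < 1.0):
            raise ValueError("bubble_fraction must lie in [0, 1)")
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must be (x, y, z)")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class Phantom:
    """Block phantom: soft matrix with zero or more spherical inclusions.

    Reference dimensions are 100 x 60 x 15 mm.  Invariants (validated on
    construction): every inclusion sphere fully contained in the block, and
    spheres pairwise non-overlapping.
    """

    length_mm: float = 100.0
    width_mm: float = 60.0
    thickness_mm: float = 15.0
    matrix_material: MaterialProps = HEALTHY_TISSUE
    inclusions: list[Inclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.thickness_mm) <= 0:
            raise GeometryError("phantom dimensions must be positive")
        for inc in self.inclusions:
            self._check_contained(inc)
        for i, a in enumerate(self.inclusions):
            for b in self.inclusions[i + 1 :]:
                d = math.dist(a.center_mm, b.center_mm)
                if d <= a.radius_mm + b.radius_mm:
                    raise GeometryError(
                        f"inclusions at {a.center_mm} and {b.center_mm} overlap"
                    )

    def _check_contained(self, inc: Inclusion) -> None:
        x, y, z = inc.center_mm
        r = inc.radius_mm
        if not (
            r <= x <= self.length_mm - r
            and r <= y <= self.width_mm - r
            and r <= z <= self.thickness_mm - r
        ):
            raise GeometryError(
                f"inclusion at {inc.center_mm} (d={inc.diameter_mm} mm) not contained in phantom"
            )

    def contains_footprint(self, x: float, y: float) -> bool:
        """True when (x, y) lies on the indented top surface."""
        return 0.0 <= x <= self.length_mm and 0.0 <= y <= self.width_mm


def _require_inside(phantom: Phantom, x: float, y: float) -> None:
    if not phantom.contains_footprint(x, y):
        raise GeometryError(
            f"point ({x}, {y}) mm outside phantom footprint "
            f"{phantom.length_mm} x {phantom.width_mm} mm"
        )


def reflection_coefficient_intensity(m1, m2) -> float:
    """Intensity reflection coefficient at a planar interface.

    R = ((Z2 - Z1) / (Z2 + Z1))^2, symmetric in its arguments, in [0, 1).
    Accepts :class:`MaterialProps` or bare impedance values (any common
    unit, as long as both use the same one).
    """
    z1 = m1.acoustic_impedance_mrayl if isinstance(m1, MaterialProps) else float(m1)
    z2 = m2.acoustic_impedance_mrayl if isinstance(m2, MaterialProps) else float(m2)
    if z1 <= 0 or z2 <= 0:
        raise ValueError("acoustic impedances must be strictly positive")
    return ((z2 - z1) / (z2 + z1)) ** 2


def inclusion_chord(phantom: Phantom, x: float, y: float) -> np.ndarray:
    """Vertical chord length (mm) of each inclusion under surface point (x, y).

    For a sphere of radius r whose center projects at planar distance d from
    (x, y), the vertical line intersects it over 2*sqrt(max(0, r^2 - d^2)).
    """
    _require_inside(phantom, x, y)
    chords = np.zeros(len(phantom.inclusions))
    for i, inc in enumerate(phantom.inclusions):
        cx, cy, _ = inc.center_mm
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        chords[i] = 2.0 * math.sqrt(max(0.0, inc.radius_mm**2 - d2))
    return chords


def _footprint_offsets(footprint_diameter_mm: float, subgrid_mm: float) -> np.ndarray:
    """Offsets of a disc-shaped probe footprint sampled on a square sub-grid."""
    r = footprint_diameter_mm / 2.0
    n = int(math.floor(r / subgrid_mm))
    axis = np.arange(-n, n + 1) * subgrid_mm
    ox, oy = np.meshgrid(axis, axis)
    keep = ox**2 + oy**2 <= r**2 + 1e-12
    return np.column_stack([ox[keep], oy[keep]])


def max_footprint_chord(
    phantom: Phantom,
    x: float,
    y: float,
    footprint_diameter_mm: float = 3.0,
    subgrid_mm: float = 0.5,
) -> tuple[float, Inclusion | None]:
    """Maximum inclusion chord under a probe footprint centred at (x, y).

    The rigid 3 mm probe face feels the stiffest (and insonifies the most
    occluded) column underneath it, so both physics models use the maximum
    vertical chord over a disc of the probe diameter, sampled on a 0.5 mm
    sub-grid.  Sample points are clipped into the phantom footprint so the
    probe may sit flush with an edge.

    Returns ``(chord_mm, inclusion)``; the inclusion is the one providing
    the maximum chord, or ``None`` when no inclusion is intersected.
    """
    _require_inside(phantom, x, y)
    if not phantom.inclusions:
        return 0.0, None
    offsets = _footprint_offsets(footprint_diameter_mm, subgrid_mm)
    px = np.clip(x + offsets[:, 0], 0.0, phantom.length_mm)
    py = np.clip(y + offsets[:, 1], 0.0, phantom.width_mm)
    best = 0.0
    best_inc: Inclusion | None = None
    for inc in phantom.inclusions:
        cx, cy, _ = inc.center_mm
        d2 = np.min((px - cx) ** 2 + (py - cy) ** 2)
        chord = 2.0 * math.sqrt(max(0.0, inc.radius_mm**2 - d2))
        if chord > best:
            best = chord
            best_inc = inc
    return best, best_inc


def local_stiffness(
    phantom: Phantom,
    x: float,
    y: float,
    footprint_diameter_mm: float = 3.0,
) -> float:
    """Effective indentation stiffness (N/mm) at surface point (x, y).

    Series-spring homogenization along the indentation axis: with phantom
    thickness T, maximum inclusion chord t under the probe footprint, matrix
    stiffness k_m and inclusion stiffness k_i,

        k_eff = 1 / ((T - t) / (T k_m) + t / (T k_i)).

    This recovers both pure-material limits exactly (t = 0 gives k_m, t = T
    gives k_i), increases strictly with the chord when k_i > k_m, and stays
    bounded by the two pure stiffness values.
    """
    t, inc = max_footprint_chord(phantom, x, y, footprint_diameter_mm)
    k_m = phantom.matrix_material.stiffness_n_mm
    if inc is None or t == 0.0:
        return k_m
    k_i = inc.material.stiffness_n_mm
    T = phantom.thickness_mm
    return 1.0 / ((T - t) / (T * k_m) + t / (T * k_i))


# --- reference phantom builder ------------------------------------------------

# Fixed layout used when randomize_positions=False: two rows of four,
# largest inclusions first along x.  Satisfies >= 10 mm surface-to-surface
# planar separation and >= 5 mm lateral clearance.
_FIXED_LAYOUT_XY = {
    12.0: [(14.0, 16.0), (14.0, 44.0)],
    9.0: [(38.0, 15.0), (38.0, 45.0)],
    6.0: [(62.0, 15.0), (62.0, 45.0)],
    3.0: [(85.0, 15.0), (85.0, 45.0)],
}

_MIN_SURFACE_SEP_MM = 10.0
_LATERAL_CLEARANCE_MM = 5.0


def _inclusion_depth(diameter: float, thickness: float, deep_small: bool) -> float:
    """Center depth: mid-thickness, or deeper for the small (3, 6 mm) spheres."""
    if deep_small and diameter <= 6.0:
        return 10.0
    return thickness / 2.0


def make_reference_phantom(
    seed: int = 0,
    randomize_positions: bool = True,
    deep_small: bool = False,
    matrix_material: MaterialProps = HEALTHY_TISSUE,
    inclusion_material: MaterialProps = TUMOR_TISSUE,
) -> Phantom:
    """Build the 100 x 60 x 15 mm reference phantom with 8 inclusions.

    Two inclusions per diameter in {3, 6, 9, 12} mm, placed with pairwise
    planar surface separation >= 10 mm and >= 5 mm clearance from lateral
    faces.  Placement is deterministic given ``seed``.  Centers sit at
    mid-thickness (z = 7.5 mm); with ``deep_small=True`` the 3 and 6 mm
    spheres are buried deeper (center z = 10 mm), which is what makes small
    nodules hard to feel through the soft matrix.

    With ``randomize_positions=False`` a fixed deterministic layout is used.
    """
    length, width, thickness = 100.0, 60.0, 15.0
    diameters = sorted(REFERENCE_DIAMETERS_MM * 2, reverse=True)

    if not randomize_positions:
        inclusions = [
            Inclusion(
                center_mm=(x, y, _inclusion_depth(d, thickness, deep_small)),
                diameter_mm=d,
                material=inclusion_material,
            )
            for d, positions in _FIXED_LAYOUT_XY.items()
            for (x, y) in positions
        ]
        return Phantom(length, width, thickness, matrix_material, inclusions)

    rng = np.random.default_rng(seed)
    for _restart in range(100):
        placed: list[tuple[float, float, float]] = []  # (x, y, r)
        ok = True
        for d in diameters:
            r = d / 2.0
            lo_x, hi_x = r + _LATERAL_CLEARANCE_MM, length - r - _LATERAL_CLEARANCE_MM
            lo_y, hi_y = r + _LATERAL_CLEARANCE_MM, width - r - _LATERAL_CLEARANCE_MM
            for _trial in range(500):
                x = rng.uniform(lo_x, hi_x)
                y = rng.uniform(lo_y, hi_y)
                if all(
                    math.hypot(x - px, y - py) >= r + pr + _MIN_SURFACE_SEP_MM
                    for px, py, pr in placed
                ):
                    placed.append((x, y, r))
                    break
            else:
                ok = False
                break
        if ok:
            inclusions = [
                Inclusion(
                    center_mm=(x, y, _inclusion_depth(2 * r, thickness, deep_small)),
                    diameter_mm=2 * r,
                    material=inclusion_material,
                )
                for (x, y, r) in placed
            ]
            return Phantom(length, width, thickness, matrix_material, inclusions)
    raise GeometryError("could not place the 8 reference inclusions")  # pragma: no cover


# --- serialization ------------------------------------------------------------


def _material_to_dict(m: MaterialProps) -> dict:
    return dataclasses.asdict(m)


def phantom_to_dict(phantom: Phantom) -> dict:
    return {
        "length_mm": phantom.length_mm,
        "width_mm": phantom.width_mm,
        "thickness_mm": phantom.thickness_mm,
        "matrix_material": _material_to_dict(phantom.matrix_material),
        "inclusions": [
            {
                "center_mm": list(inc.center_mm),
                "diameter_mm": inc.diameter_mm,
                "material": _material_to_dict(inc.material),
                "has_air_bubble": inc.has_air_bubble,
                "bubble_fraction": inc.bubble_fraction,
            }
            for inc in phantom.inclusions
        ],
    }


def phantom_from_dict(data: dict) -> Phantom:
    return Phantom(
        length_mm=float(data["length_mm"]),
        width_mm=float(data["width_mm"]),
        thickness_mm=float(data["thickness_mm"]),
        matrix_material=MaterialProps(**data["matrix_material"]),
        inclusions=[
            Inclusion(
                center_mm=tuple(inc["center_mm"]),
                diameter_mm=float(inc["diameter_mm"]),
                material=MaterialProps(**inc["material"]),
                has_air_bubble=bool(inc.get("has_air_bubble", False)),
                bubble_fraction=float(inc.get("bubble_fraction", 0.0)),
            )
            for inc in data.get("inclusions", [])
        ],
    )


def save_phantom(phantom: Phantom, path) -> None:
    """Write the phantom description as a YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(phantom_to_dict(phantom), fh, sort_keys=False)


def load_phantom(path) -> Phantom:
    with open(path) as fh:
        return phantom_from_dict(yaml.safe_load(fh))
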
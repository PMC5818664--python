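"""Channel coordinate system, pore regions and filter-site geometry.

The analyses share a cylindrical channel frame: an axis (the membrane
normal, pointing extracellular), an origin on that axis, and an ordered
stack of half-open axial intervals naming the pore regions
(intracellular bulk, cavity, selectivity filter, vestibule, extracellular
bulk).  Radial cutoffs split the filter/vestibule levels into the axial
pore, the off-axis side-portal band, and the surrounding membrane.

Site planes (S1-S4 cage midpoints and the B23/B34 carbonyl planes of V64
and T63) are axial coordinates in the same frame; the off-axis S_side
binding site is described by per-subunit atom selectors (D66 and F69
backbone carbonyl oxygens plus a serine/aspartate side-chain oxygen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "RegionLabel",
    "AtomSelector",
    "ChannelGeometry",
    "ChannelSystem",
    "build_geometry",
    "assign_region",
    "assign_regions",
    "default_geometry_mapping",
    "default_system",
    "SUBUNITS",
    "SUBUNIT_ANGLES_DEG",
    "NEIGHBOR_SUBUNIT",
]


class GeometryError(ValueError):
    """Raised when a geometry description violates its invariants."""


class RegionLabel(IntEnum):
    INTRACELLULAR_BULK = 0
    CAVITY = 1
    SF = 2
    VESTIBULE = 3
    EXTRACELLULAR_BULK = 4
    SIDE_PORTAL = 5
    MEMBRANE_OTHER = 6


#: canonical region order from intracellular to extracellular
REGION_ORDER = (
    "intracellular_bulk",
    "cavity",
    "sf",
    "vestibule",
    "extracellular_bulk",
)

_REGION_TO_LABEL = {
    "intracellular_bulk": RegionLabel.INTRACELLULAR_BULK,
    "cavity": RegionLabel.CAVITY,
    "sf": RegionLabel.SF,
    "vestibule": RegionLabel.VESTIBULE,
    "extracellular_bulk": RegionLabel.EXTRACELLULAR_BULK,
}

#: tetramer chains; azimuthal placement makes (A,B) and (C,D) opposing pairs
SUBUNITS = ("A", "B", "C", "D")
SUBUNIT_ANGLES_DEG = {"A": 0.0, "B": 180.0, "C": 90.0, "D": 270.0}
#: spatially adjacent neighbor (next chain counter-clockwise)
NEIGHBOR_SUBUNIT = {"A": "C", "C": "B", "B": "D", "D": "A"}


class AtomSelector(NamedTuple):
    """Selects one protein atom by chain, residue number and atom name."""

    subunit: str
    residue_number: int
    atom_name: str


def default_s_side_atoms() -> dict[str, list[AtomSelector]]:
    """Per-subunit S_side coordination set.

    Two backbone carbonyl oxygens (D66, F69) and the side-chain oxygen of
    either S70 of the same subunit or D66 of the neighboring subunit.
    """
    out: dict[str, list[AtomSelector]] = {}
    for su in SUBUNITS:
        out[su] = [
            AtomSelector(su, 66, "O"),
            AtomSelector(su, 69, "O"),
            AtomSelector(su, 70, "OG"),
            AtomSelector(NEIGHBOR_SUBUNIT[su], 66, "OD1"),
        ]
    return out


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry of one channel copy in a fixed laboratory frame.

    ``region_bounds`` maps region name -> half-open axial interval
    ``[lo, hi)`` in the channel-local axial coordinate
    ``s = (x - axis_origin) . axis`` (A, +s extracellular).
    """

    axis: np.ndarray
    axis_origin: np.ndarray
    region_bounds: dict[str, tuple[float, float]]
    sf_radius: float = 4.5
    side_portal_width: float = 5.5
    cavity_radius: float = 8.0
    site_planes: dict[str, float] = field(default_factory=dict)
    s_side_atoms: dict[str, list[AtomSelector]] = field(
        default_factory=default_s_side_atoms
    )

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if not np.isfinite(n) or n == 0:
            raise GeometryError("axis must be a nonzero finite vector")
        object.__setattr__(self, "axis", axis / n)
        object.__setattr__(
            self, "axis_origin", np.asarray(self.axis_origin, dtype=float).reshape(3)
        )
        if self.sf_radius <= 0 or self.side_portal_width <= 0 or self.cavity_radius <= 0:
            raise GeometryError("radii must be positive")
        missing = [r for r in REGION_ORDER if r not in self.region_bounds]
        if missing:
            raise GeometryError(f"region_bounds missing {missing}")
        prev_hi = None
        for name in REGION_ORDER:
            lo, hi = (float(v) for v in self.region_bounds[name])
            if not lo < hi:
                raise GeometryError(f"region {name!r} interval empty: [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise GeometryError(
                    f"region intervals must be contiguous; gap/overlap before {name!r}"
                )
            prev_hi = hi
        planes = self.site_planes
        if "B23" in planes and "B34" in planes and not planes["B34"] < planes["B23"]:
            raise GeometryError("site plane B34 must lie below B23 (closer to cavity)")

    @property
    def s_range(self) -> tuple[float, float]:
        return (
            float(self.region_bounds[REGION_ORDER[0]][0]),
            float(self.region_bounds[REGION_ORDER[-1]][1]),
        )

    @property
    def portal_outer_radius(self) -> float:
        return self.sf_radius + self.side_portal_width

    def local_coords(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate s and radial distance r for positions (..., 3)."""
        pos = np.asarray(positions, dtype=float)
        d = pos - self.axis_origin
        s = d @ self.axis
        radial_vec = d - s[..., None] * self.axis
        r = np.linalg.norm(radial_vec, axis=-1)
        return s, r

    def to_global(self, s, r=0.0, azimuth_deg=0.0) -> np.ndarray:
        """Map channel-local (s, r, azimuth) to laboratory coordinates.

        The azimuth is measured in the plane perpendicular to the axis from
        an axis-dependent reference direction (x for a z axis).
        """
        ez = self.axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ ez) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        ex = ref - (ref @ ez) * ez
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        a = np.deg2rad(azimuth_deg)
        s = np.asarray(s, dtype=float)
        r = np.asarray(r, dtype=float)
        return (
            self.axis_origin
            + s[..., None] * ez
            + (r * np.cos(a))[..., None] * ex
            + (r * np.sin(a))[..., None] * ey
        )


def assign_regions(positions: np.ndarray, geometry: ChannelGeometry) -> np.ndarray:
    """Vectorized region labelling; returns an int array of RegionLabel values.

    Axial intervals are half-open ``[lo, hi)``.  Within the SF axial span the
    on-axis core (r <= sf_radius) is SF and the annulus out to the portal
    outer radius is SIDE_PORTAL; the vestibule level splits the same way into
    VESTIBULE / SIDE_PORTAL.  The cavity level is CAVITY within
    cavity_radius.  Everything else at membrane level is MEMBRANE_OTHER.
    """
    pos = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions contain non-finite values")
    s, r = geometry.local_coords(pos)
    labels = np.full(s.shape, int(RegionLabel.MEMBRANE_OTHER), dtype=np.int8)

    def _in(name: str) -> np.ndarray:
        lo, hi = geometry.region_bounds[name]
        return (s >= lo) & (s < hi)

    labels[_in("intracellular_bulk")] = int(RegionLabel.INTRACELLULAR_BULK)
    labels[_in("extracellular_bulk")] = int(RegionLabel.EXTRACELLULAR_BULK)

    m = _in("cavity")
    labels[m & (r <= geometry.cavity_radius)] = int(RegionLabel.CAVITY)

    core = r <= geometry.sf_radius
    portal = (r > geometry.sf_radius) & (r <= geometry.portal_outer_radius)
    m = _in("sf")
    labels[m & core] = int(RegionLabel.SF)
    labels[m & portal] = int(RegionLabel.SIDE_PORTAL)
    m = _in("vestibule")
    labels[m & core] = int(RegionLabel.VESTIBULE)
    labels[m & portal] = int(RegionLabel.SIDE_PORTAL)
    return labels


def assign_region(position: Sequence[float], geometry: ChannelGeometry) -> RegionLabel:
    """Region label of a single position (see :func:`assign_regions`)."""
    lab = assign_regions(np.asarray(position, dtype=float).reshape(1, 3), geometry)
    return RegionLabel(int(lab[0]))


def build_geometry(config: Mapping) -> ChannelGeometry:
    """Validate a structured mapping (parsed YAML/JSON) into a geometry.

    Required keys: ``axis``, ``axis_origin``, ``region_bounds``.  Optional:
    ``sf_radius``, ``side_portal_width``, ``cavity_radius``, ``site_planes``,
    ``s_side_atoms`` (per-subunit lists of ``[subunit, residue, atom]``).
    """
    try:
        bounds = {
            str(k): (float(v[0]), float(v[1]))
            for k, v in dict(config["region_bounds"]).items()
        }
        kwargs = dict(
            axis=config["axis"],
            axis_origin=config["axis_origin"],
            region_bounds=bounds,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise GeometryError(f"invalid geometry config: {exc}") from exc
    for key in ("sf_radius", "side_portal_width", "cavity_radius"):
        if key in config:
            kwargs[key] = float(config[key])
    if "site_planes" in config:
        kwargs["site_planes"] = {
            str(k): float(v) for k, v in dict(config["site_planes"]).items()
        }
    if "s_side_atoms" in config:
        kwargs["s_side_atoms"] = {
            str(su): [AtomSelector(str(a[0]), int(a[1]), str(a[2])) for a in sel]
            for su, sel in dict(config["s_side_atoms"]).items()
        }
    return ChannelGeometry(**kwargs)


DEFAULT_BOX = (40.0, 40.0, 160.0)
#: membrane midplanes of the default double-membrane layout (z, A)
DEFAULT_MIDPLANES = (40.0, 120.0)

_DEFAULT_BOUNDS = {
    "intracellular_bulk": (-41.0, -15.0),
    "cavity": (-15.0, -5.0),
    "sf": (-5.0, 5.0),
    "vestibule": (5.0, 12.0),
    "extracellular_bulk": (12.0, 41.0),
}

_DEFAULT_SITE_PLANES = {
    # carbonyl planes: B34 at the T63 plane, B23 at the V64 plane
    "B34": -1.2,
    "B23": 1.0,
    # cage midpoints adjacent to those planes
    "S4": -2.3,
    "S3": -0.1,
    "S2": 2.1,
    "S1": 4.3,
}


def default_geometry_mapping(channel: str = "lower") -> dict:
    """Plain-dict geometry for one copy of the default two-membrane system.

    The lower channel sits at z = 40 A pointing +z (extracellular up into
    the central compartment); the upper channel sits at z = 120 A pointing
    -z, so both channels face compartment (a) with their extracellular side.
    """
    if channel == "lower":
        axis, origin = [0.0, 0.0, 1.0], [20.0, 20.0, DEFAULT_MIDPLANES[0]]
    elif channel == "upper":
        axis, origin = [0.0, 0.0, -1.0], [20.0, 20.0, DEFAULT_MIDPLANES[1]]
    else:
        raise ValueError("channel must be 'lower' or 'upper'")
    return {
        "axis": axis,
        "axis_origin": origin,
        "region_bounds": {k: list(v) for k, v in _DEFAULT_BOUNDS.items()},
        "sf_radius": 4.5,
        "side_portal_width": 5.5,
        "cavity_radius": 8.0,
        "site_planes": dict(_DEFAULT_SITE_PLANES),
    }


@dataclass
class ChannelSystem:
    """Two channel copies of the double-membrane setup.

    Region assignment for arbitrary points picks the copy whose local axial
    coordinate is smaller in magnitude, which partitions the periodic box
    cleanly between the two copies.
    """

    channels: dict[str, ChannelGeometry]

    def region_labels(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus owning-channel index for positions (..., 3).

        Returns ``(labels, owner)`` with ``owner`` indexing
        ``list(self.channels)``.
        """
        names = list(self.channels)
        pos = np.asarray(positions, dtype=float)
        s_abs = np.stack(
            [np.abs(self.channels[n].local_coords(pos)[0]) for n in names], axis=0
        )
        owner = np.argmin(s_abs, axis=0)
        labels = np.full(pos.shape[:-1], int(RegionLabel.MEMBRANE_OTHER), dtype=np.int8)
        for i, n in enumerate(names):
            lab = assign_regions(pos, self.channels[n])
            labels = np.where(owner == i, lab, labels)
        return labels, owner

    @property
    def names(self) -> list[str]:
        return list(self.channels)


def default_system() -> ChannelSystem:
    return ChannelSystem(
        channels={
            "lower": build_geometry(default_geometry_mapping("lower")),
            "upper": build_geometry(default_geometry_mapping("upper")),
        }
    )
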
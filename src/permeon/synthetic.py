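"""Synthetic desk-scale stand-ins for double-membrane permeation runs.

Three generators:

* :func:`gen_trajectory` — a kinetic-hopping trajectory of a two-membrane,
  two-compartment box with one channel per membrane.  Ions sit in bulk
  anchors and, as a Poisson process at configurable per-species rates,
  traverse the scripted region sequence bulk -> (vestibule | side portal)
  -> selectivity filter -> opposite side, with exponential filter dwell
  times; distractor excursions enter the filter and return to the same
  side.  Hydration shells ride along with their ion and can be shed inside
  the filter.  Backbone-carbonyl pseudo-atoms for T62/T63/V64/G65 are
  emitted per subunit, with the T62 carbonyl rotated ~180 deg (and the
  T63/V64 carbonyls displaced outward) during scheduled flip intervals.
  The planted ground truth (crossings, pathways, flip windows) is returned
  alongside the trajectory.

* :func:`gen_sf_scaffold` — an idealized fourfold backbone scaffold of the
  filter region (residues 59-70) in either the crystal or the
  T62-carbonyl-flipped conformation, with the hydrogen-bond and
  amide-contact geometry characteristic of each state built in.

* :func:`gen_charge_density` — analytic axial charge-density profiles
  (zero, parallel-plate capacitor, gaussian dipole) for exercising the
  Poisson integrator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .channel import (
    ChannelSystem,
    SUBUNITS,
    SUBUNIT_ANGLES_DEG,
    default_system,
    DEFAULT_BOX,
)
from .electrostatics import ChargeDensityProfile
from .trajectory import Species, Trajectory, make_particles

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_trajectory",
    "gen_sf_scaffold",
    "gen_charge_density",
    "CARBONYL_S",
    "CARBONYL_C_RADIUS",
    "CO_LENGTH",
]

#: axial heights (channel-local s, A) of the emitted carbonyl pseudo-atoms;
#: T63 sits at the B34 plane and V64 at the B23 plane of the default geometry
CARBONYL_S = {62: -3.4, 63: -1.2, 64: 1.0, 65: 3.2}
#: radial position of the carbonyl C pseudo-atom and the C=O bond length, A
CARBONYL_C_RADIUS = 4.2
CO_LENGTH = 1.23

#: S_side pseudo-atoms: (residue, atom name) -> (s, r) in the channel frame
S_SIDE_SITES = {
    (66, "O"): (5.5, 7.0),
    (69, "O"): (6.5, 7.5),
    (70, "OG"): (7.5, 7.0),
    (66, "OD1"): (5.5, 8.0),
}

_RES_NAMES = {
    59: "VAL", 60: "THR", 61: "LEU", 62: "THR", 63: "THR", 64: "VAL",
    65: "GLY", 66: "ASP", 67: "GLY", 68: "ASN", 69: "PHE", 70: "SER",
}


@dataclass
class SynthConfig:
    """Study conditions for the kinetic-hopping generator.

    Defaults emulate the double-membrane permeation setup: a maintained
    imbalance of two permeant ions between the compartments and complete
    crossings arriving as a Poisson process at per-species rates matching
    the simulated K+ event rates (1.8 inward / 1.9 outward per us over the
    system).  Durations are desk-scale; rates, fractions and schedules are
    per-run conditions, not fit parameters.
    """

    seed: int = 0
    duration_ns: float = 1000.0
    frame_interval_ps: float = 100.0
    n_ions: dict = field(default_factory=lambda: {"K": 16, "CL": 16})
    n_waters: int = 40  # bulk waters, in addition to hydration shells
    crossing_rate_inward: dict = field(default_factory=lambda: {"K": 1.8})
    crossing_rate_outward: dict = field(default_factory=lambda: {"K": 1.9})
    side_entry_fraction: float = 0.0
    partial_entry_rate: dict = field(default_factory=dict)  # events/us
    hydration_waters: int = 4
    hydration_radius: float = 2.4
    shed_shell_in_sf: bool = True
    sf_dwell_mean_ns: float = 0.5
    waypoint_dwell_ps: float = 300.0
    flip_schedule: dict = field(default_factory=dict)  # subunit -> [(ns, ns)]
    flip_widen: float = 1.0
    jitter_sd: float = 0.3
    compartment_imbalance: int = 2
    imbalance_species: str = "K"
    sf_residents: int = 0
    box: tuple = DEFAULT_BOX

    def validate(self) -> None:
        if self.duration_ns <= 0 or self.frame_interval_ps <= 0:
            raise ValueError("duration and frame interval must be positive")
        if not 0.0 <= self.side_entry_fraction <= 1.0:
            raise ValueError("side_entry_fraction must be in [0, 1]")
        for rates in (
            self.crossing_rate_inward,
            self.crossing_rate_outward,
            self.partial_entry_rate,
        ):
            if any(v < 0 for v in rates.values()):
                raise ValueError("rates must be >= 0")
        if self.hydration_waters < 0 or self.n_waters < 0:
            raise ValueError("water counts must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for su in self.flip_schedule:
            if su not in SUBUNITS:
                raise ValueError(f"unknown subunit in flip_schedule: {su!r}")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic trajectory.

    ``events`` columns: kind (crossing|partial), ion_id, species, direction
    (inward|outward, empty for partials), pathway (axial|side), channel
    (lower|upper), t_start_ps, t_sf_entry_ps, t_sf_exit_ps, t_end_ps.
    ``flips`` columns: subunit, start_ps, end_ps.
    """

    events: pd.DataFrame
    flips: pd.DataFrame
    seed: int
    n_dropped: int = 0

    def crossings(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "crossing"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trajectory generator


def _bulk_point(rng: np.random.Generator, compartment: str, box) -> np.ndarray:
    # slabs keep a >2 A buffer from region boundaries so positional jitter
    # cannot push a resting ion across one
    x, y = rng.uniform(8.0, box[0] - 8.0), rng.uniform(8.0, box[1] - 8.0)
    if compartment == "a":
        z = rng.uniform(57.0, 103.0)
    else:
        z = rng.uniform(7.0, 23.0) if rng.random() < 0.5 else rng.uniform(137.0, 153.0)
    return np.array([x, y, z])


_SHELL_DIRS = np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 1], [-1, -1, 1], [1, -1, -1], [-1, 1, -1], [1, 1, -1], [-1, -1, -1],
    ],
    dtype=float,
)
_SHELL_DIRS /= np.linalg.norm(_SHELL_DIRS, axis=1, keepdims=True)


def _plan_events(cfg: SynthConfig, rng: np.random.Generator, n_frames: int, dt: float):
    """Draw the Poisson event schedule (not yet assigned to ions)."""
    duration_us = cfg.duration_ns / 1000.0
    plans = []
    specs = []
    for species, rate in cfg.crossing_rate_inward.items():
        specs.append((species, rate, "inward", "crossing"))
    for species, rate in cfg.crossing_rate_outward.items():
        specs.append((species, rate, "outward", "crossing"))
    for species, rate in cfg.partial_entry_rate.items():
        specs.append((species, rate, "", "partial"))
    for species, rate, direction, kind in specs:
        n = rng.poisson(rate * duration_us)
        for _ in range(n):
            t0 = rng.uniform(0.02, 0.80) * cfg.duration_ns * 1000.0
            plans.append(
                dict(
                    kind=kind,
                    species=species,
                    direction=direction
                    or ("inward" if rng.random() < 0.5 else "outward"),
                    is_partial=kind == "partial",
                    pathway="side"
                    if rng.random() < cfg.side_entry_fraction
                    else "axial",
                    channel="lower" if rng.random() < 0.5 else "upper",
                    azimuth=rng.uniform(0.0, 360.0),
                    t0=t0,
                    sf_dwell=max(
                        2.0 * dt, rng.exponential(cfg.sf_dwell_mean_ns * 1000.0)
                    ),
                )
            )
    plans.sort(key=lambda p: p["t0"])
    return plans


def _event_segments(plan: dict, cfg: SynthConfig, dt: float) -> list[dict]:
    """Waypoint segments (frame counts and channel-local coordinates)."""
    wd = cfg.waypoint_dwell_ps
    portal_r = 8.0
    r1 = portal_r if plan["pathway"] == "side" else 0.0
    ext = [(16.0, 3.0, wd), (8.0, r1, wd)]
    intr = [(-10.0, 0.0, wd), (-20.0, 3.0, wd)]
    sf = [(0.0, 0.0, plan["sf_dwell"])]
    if plan["is_partial"]:
        if plan["direction"] == "inward":  # excursion from the extracellular side
            way = ext + sf + ext[::-1]
        else:
            way = intr[::-1] + sf + intr
    elif plan["direction"] == "inward":
        way = ext + sf + intr
    else:
        way = intr[::-1] + sf + [(8.0, r1, wd), (16.0, 3.0, wd)]
    segs = []
    f = int(round(plan["t0"] / dt))
    for s, r, dwell in way:
        n = max(1, int(round(dwell / dt)))
        segs.append(dict(f0=f, f1=f + n, s=s, r=r, sf=(s == 0.0 and r == 0.0)))
        f += n
    return segs


def gen_trajectory(
    config: SynthConfig, system: ChannelSystem | None = None
) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory and its planted ground truth.

    Deterministic for a fixed ``config.seed``.  Crossing events that find
    no idle ion in the origin compartment are dropped (counted in
    ``GroundTruth.n_dropped``) and never appear in the sidecar.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    system = system or default_system()
    dt = cfg.frame_interval_ps
    n_frames = max(2, int(round(cfg.duration_ns * 1000.0 / dt)))
    times = np.arange(n_frames) * dt
    box = np.asarray(cfg.box, dtype=float)

    # --- particle table -----------------------------------------------------
    rows = []
    next_id = 0
    ion_ids: dict[str, list[int]] = {}
    for species, n in cfg.n_ions.items():
        ion_ids[species] = list(range(next_id, next_id + n))
        for _ in range(n):
            rows.append(dict(id=next_id, species=species))
            next_id += 1

    resident_ids: list[int] = []
    if cfg.sf_residents:
        pool = ion_ids.get(cfg.imbalance_species, [])
        resident_ids = pool[: cfg.sf_residents]

    hydrated_ids = [
        i
        for sp, ids in ion_ids.items()
        if sp != Species.CL.value
        for i in ids
        if i not in resident_ids
    ]
    shell_owner: list[tuple[int, int]] = []  # (water row id, owner ion id)
    if cfg.hydration_waters > 0:
        for ion in hydrated_ids:
            for k in range(cfg.hydration_waters):
                rows.append(dict(id=next_id, species=Species.WATER_O.value))
                shell_owner.append((next_id, ion))
                next_id += 1
    bulk_water_ids = list(range(next_id, next_id + cfg.n_waters))
    for _ in range(cfg.n_waters):
        rows.append(dict(id=next_id, species=Species.WATER_O.value))
        next_id += 1

    protein_rows = []  # (id, channel, subunit, resnum, atom, s, r_crystal)
    for ch_name in system.names:
        for su in SUBUNITS:
            for resnum, s in CARBONYL_S.items():
                for atom, r in (
                    ("C", CARBONYL_C_RADIUS),
                    ("O", CARBONYL_C_RADIUS - CO_LENGTH),
                ):
                    rows.append(
                        dict(
                            id=next_id,
                            species=Species.PROTEIN_ATOM.value,
                            subunit=su,
                            residue_number=resnum,
                            atom_name=atom,
                            channel=ch_name,
                        )
                    )
                    protein_rows.append((next_id, ch_name, su, resnum, atom, s, r))
                    next_id += 1
            for (resnum, atom), (s, r) in S_SIDE_SITES.items():
                rows.append(
                    dict(
                        id=next_id,
                        species=Species.PROTEIN_ATOM.value,
                        subunit=su,
                        residue_number=resnum,
                        atom_name=atom,
                        channel=ch_name,
                    )
                )
                protein_rows.append((next_id, ch_name, su, resnum, atom, s, r))
                next_id += 1

    particles = make_particles(rows)
    n_particles = len(particles)
    positions = np.empty((n_frames, n_particles, 3))

    # --- initial compartments (imbalance on the permeant species) ----------
    compartment: dict[int, str] = {}
    for species, ids in ion_ids.items():
        n = len(ids)
        if species == cfg.imbalance_species:
            n_a = (n + cfg.compartment_imbalance) // 2
        else:
            n_a = n // 2
        for j, ion in enumerate(ids):
            compartment[ion] = "a" if j < n_a else "b"

    # --- event schedule assigned to ions ------------------------------------
    plans = _plan_events(cfg, rng, n_frames, dt)
    busy_until = {i: -1 for ids in ion_ids.values() for i in ids}
    for i in resident_ids:
        busy_until[i] = n_frames + 1
    margin = 2
    kept: list[tuple[dict, list[dict], int]] = []
    n_dropped = 0
    for plan in plans:
        segs = _event_segments(plan, cfg, dt)
        if segs[-1]["f1"] >= n_frames - 1:
            n_dropped += 1
            continue
        origin = "a" if plan["direction"] == "inward" else "b"
        cands = [
            i
            for i in ion_ids.get(plan["species"], [])
            if busy_until[i] + margin < segs[0]["f0"] and compartment[i] == origin
        ]
        if not cands:
            n_dropped += 1
            continue
        ion = int(rng.choice(cands))
        busy_until[ion] = segs[-1]["f1"]
        if not plan["is_partial"]:
            compartment[ion] = "b" if origin == "a" else "a"
        kept.append((plan, segs, ion))

    # --- ion base positions: piecewise anchors + event overrides ------------
    anchor_changes: dict[int, list[tuple[int, np.ndarray]]] = {}
    for species, ids in ion_ids.items():
        n = len(ids)
        n_a = (
            (n + cfg.compartment_imbalance) // 2
            if species == cfg.imbalance_species
            else n // 2
        )
        for j, ion in enumerate(ids):
            comp0 = "a" if j < n_a else "b"
            anchor_changes[ion] = [(0, _bulk_point(rng, comp0, box))]
    site_planes = system.channels["lower"].site_planes
    for j, ion in enumerate(resident_ids):
        s_site = site_planes["S3"] if j % 2 == 0 else site_planes["S4"]
        anchor_changes[ion] = [
            (0, system.channels["lower"].to_global(np.array(s_site), 0.0))
        ]
    for plan, segs, ion in kept:
        if not plan["is_partial"]:
            dest = "b" if plan["direction"] == "inward" else "a"
            # note: both channels face compartment a with their extracellular
            # side, so inward (extra -> intra) always moves a -> b
            anchor_changes[ion].append((segs[-1]["f1"], _bulk_point(rng, dest, box)))

    for ids in ion_ids.values():
        for i in ids:
            row = particles.index[particles["id"] == i][0]
            changes = sorted(anchor_changes[i], key=lambda c: c[0])
            for k, (f0, anchor) in enumerate(changes):
                f1 = changes[k + 1][0] if k + 1 < len(changes) else n_frames
                positions[f0:f1, row] = anchor

    id_to_row = {int(pid): r for r, pid in enumerate(particles["id"].to_numpy())}
    sf_intervals: dict[int, list[tuple[int, int]]] = {}
    truth_rows = []
    for plan, segs, ion in kept:
        geom = system.channels[plan["channel"]]
        row = id_to_row[ion]
        for seg in segs:
            p = geom.to_global(np.array(seg["s"]), seg["r"], plan["azimuth"])
            positions[seg["f0"] : seg["f1"], row] = p
        sf_seg = next(s for s in segs if s["sf"])
        sf_intervals.setdefault(ion, []).append((sf_seg["f0"], sf_seg["f1"]))
        truth_rows.append(
            dict(
                kind=plan["kind"],
                ion_id=ion,
                species=plan["species"],
                direction="" if plan["is_partial"] else plan["direction"],
                pathway=plan["pathway"],
                channel=plan["channel"],
                t_start_ps=segs[0]["f0"] * dt,
                t_sf_entry_ps=sf_seg["f0"] * dt,
                t_sf_exit_ps=(sf_seg["f1"] - 1) * dt,
                t_end_ps=(segs[-1]["f1"] - 1) * dt,
            )
        )

    # --- waters --------------------------------------------------------------
    if shell_owner:
        offsets = {}
        for k, (wid, ion) in enumerate(shell_owner):
            offsets[wid] = _SHELL_DIRS[k % len(_SHELL_DIRS)] * cfg.hydration_radius
        for wid, ion in shell_owner:
            wrow, irow = id_to_row[wid], id_to_row[ion]
            positions[:, wrow] = positions[:, irow] + offsets[wid]
            if cfg.shed_shell_in_sf:
                for f0, f1 in sf_intervals.get(ion, []):
                    if f0 > 0:
                        positions[f0:f1, wrow] = positions[f0 - 1, wrow]
    for wid in bulk_water_ids:
        comp = "a" if rng.random() < 0.5 else "b"
        positions[:, id_to_row[wid]] = _bulk_point(rng, comp, box)

    # --- protein pseudo-atoms ------------------------------------------------
    flip_frames: dict[str, np.ndarray] = {}
    flip_truth = []
    for su in SUBUNITS:
        mask = np.zeros(n_frames, dtype=bool)
        for start_ns, end_ns in cfg.flip_schedule.get(su, []):
            f0 = max(0, int(round(start_ns * 1000.0 / dt)))
            f1 = min(n_frames, int(round(end_ns * 1000.0 / dt)))
            mask[f0:f1] = True
            flip_truth.append(dict(subunit=su, start_ps=f0 * dt, end_ps=f1 * dt))
        flip_frames[su] = mask

    for pid, ch_name, su, resnum, atom, s, r_crystal in protein_rows:
        geom = system.channels[ch_name]
        ang = SUBUNIT_ANGLES_DEG[su]
        r_t = np.full(n_frames, r_crystal)
        flip = flip_frames[su]
        if resnum == 62 and atom == "O":
            # ~180 deg flip about the backbone: the O swings to the far side
            r_t[flip] = CARBONYL_C_RADIUS + CO_LENGTH
        if resnum in (63, 64) and atom in ("C", "O"):
            # asymmetric deformation accompanying the flip
            r_t[flip] = r_crystal + cfg.flip_widen
        positions[:, id_to_row[pid]] = geom.to_global(
            np.full(n_frames, s), r_t, ang
        )

    if cfg.jitter_sd > 0:
        positions += rng.normal(0.0, cfg.jitter_sd, positions.shape)
    positions = np.mod(positions, box)

    truth = GroundTruth(
        events=pd.DataFrame(
            truth_rows,
            columns=[
                "kind", "ion_id", "species", "direction", "pathway", "channel",
                "t_start_ps", "t_sf_entry_ps", "t_sf_exit_ps", "t_end_ps",
            ],
        ),
        flips=pd.DataFrame(flip_truth, columns=["subunit", "start_ps", "end_ps"]),
        seed=cfg.seed,
        n_dropped=n_dropped,
    )
    traj = Trajectory(
        particles=particles, times=times, box=box, positions=positions,
        ground_truth=truth,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# idealized filter scaffolds


def _scaffold_chain(conformer: str, widen: float) -> list[dict]:
    """Local-frame atoms of one subunit (x = radial out, z = axial)."""
    R = 6.0
    rise = 2.9
    z = {i: rise * (i - 59) for i in range(59, 71)}
    atoms: dict[tuple[int, str], np.ndarray] = {}
    for i in range(59, 71):
        atoms[(i, "N")] = np.array([R, 0.0, z[i]])
        atoms[(i, "H")] = np.array([R - 1.0, 0.0, z[i]])
        atoms[(i, "CA")] = np.array([R + 0.5, 1.2, z[i] + 0.5])
        if 62 <= i <= 65:
            # pore-lining carbonyls point straight at the axis so opposing
            # O-O separations lie along the widening direction
            atoms[(i, "C")] = np.array([R, 0.0, z[i] + 1.45])
            atoms[(i, "O")] = atoms[(i, "C")] + np.array([-CO_LENGTH, 0.0, 0.0])
        else:
            atoms[(i, "C")] = np.array([R, 0.8, z[i] + 1.45])
            atoms[(i, "O")] = atoms[(i, "C")] + np.array([0.0, CO_LENGTH, 0.0])
    atoms[(70, "OG")] = np.array([R + 1.0, 1.5, z[70] + 0.5])
    atoms[(66, "OD1")] = np.array([R + 1.0, -1.5, z[66] + 0.5])

    def accept(donor_i: int, acceptor_i: int) -> None:
        """Park acceptor_i's carbonyl O on the donor's N-H axis (1.9 A)."""
        n, h = atoms[(donor_i, "N")], atoms[(donor_i, "H")]
        u = (h - n) / np.linalg.norm(h - n)
        atoms[(acceptor_i, "O")] = h + 1.9 * u
        atoms[(acceptor_i, "C")] = atoms[(acceptor_i, "O")] + np.array(
            [0.0, 1.0, -0.7]
        )

    if conformer == "crystal":
        accept(63, 60)  # T63 NH ... T60 CO
        accept(64, 59)  # V64 NH ... V59 CO
    elif conformer == "flipped_T62":
        # the T62/T63 amide pair opens to 4.5 A and the flipped T62 carbonyl
        # accepts from V64 NH; the two crystal bonds are left broken
        atoms[(62, "H")] = np.array([R - 1.0, 0.0, z[63] - 4.5])
        atoms[(62, "N")] = atoms[(62, "H")] + np.array([1.0, 0.0, 0.0])
        accept(64, 62)
    else:
        raise ValueError(f"unknown conformer: {conformer!r}")

    if widen:
        for i in (63, 64):
            for a in ("C", "O"):
                atoms[(i, a)] = atoms[(i, a)] + np.array([widen / 2.0, 0.0, 0.0])

    return [
        dict(res_id=i, atom_name=a, coord=xyz) for (i, a), xyz in sorted(atoms.items())
    ]


def gen_sf_scaffold(conformer: str = "crystal", widen: float = 0.0) -> struc.AtomArray:
    """Idealized fourfold filter scaffold as a biotite AtomArray.

    Chains A-D are placed at azimuths 0/180/90/270 deg so that (A,B) and
    (C,D) are geometrically opposing pairs.  ``widen`` increases the
    opposing T63/V64 carbonyl O-O separations by the given amount (A).
    """
    chain_atoms = _scaffold_chain(conformer, widen)
    n = len(chain_atoms) * len(SUBUNITS)
    arr = struc.AtomArray(n)
    k = 0
    for su in SUBUNITS:
        theta = np.deg2rad(SUBUNIT_ANGLES_DEG[su])
        c, s = np.cos(theta), np.sin(theta)
        for a in chain_atoms:
            x, y, z = a["coord"]
            arr.coord[k] = [x * c - y * s, x * s + y * c, z]
            arr.chain_id[k] = su
            arr.res_id[k] = a["res_id"]
            arr.res_name[k] = _RES_NAMES[a["res_id"]]
            arr.atom_name[k] = a["atom_name"]
            arr.element[k] = a["atom_name"][0]
            k += 1
    arr.hetero[:] = False
    return arr


# ---------------------------------------------------------------------------
# analytic charge densities


def gen_charge_density(
    profile: str,
    n_bins: int = 1000,
    z_range: tuple[float, float] = (0.0, 160.0),
    **params,
) -> ChargeDensityProfile:
    """Analytic axial charge-density profiles on a declared grid.

    ``zero``            — all bins zero.
    ``capacitor``       — two opposite sheets (surface density ``sigma``
                          e/A^2, separation ``separation`` A, centered at
                          ``center``), each deposited in a single bin.
    ``gaussian_dipole`` — antisymmetric pair of gaussians (``amplitude``
                          e/A^3, width ``width`` A, separation
                          ``separation`` A) integrating to zero.
    """
    edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h = edges[1] - edges[0]
    rho = np.zeros(n_bins)
    if profile == "zero":
        pass
    elif profile == "capacitor":
        sigma = float(params.get("sigma", 1e-4))
        d = float(params.get("separation", 30.0))
        center = float(params.get("center", 0.5 * (z_range[0] + z_range[1])))
        i1 = int(np.argmin(np.abs(centers - (center - d / 2))))
        i2 = int(np.argmin(np.abs(centers - (center + d / 2))))
        if i1 == i2:
            raise ValueError("capacitor sheets collapse onto one bin; refine grid")
        rho[i1] += sigma / h
        rho[i2] -= sigma / h
    elif profile == "gaussian_dipole":
        amp = float(params.get("amplitude", 1e-5))
        w = float(params.get("width", 5.0))
        d = float(params.get("separation", 40.0))
        center = float(params.get("center", 0.5 * (z_range[0] + z_range[1])))
        z1, z2 = center - d / 2, center + d / 2
        rho = amp * (
            np.exp(-0.5 * ((centers - z1) / w) ** 2)
            - np.exp(-0.5 * ((centers - z2) / w) ** 2)
        )
    else:
        raise ValueError(f"unknown profile: {profile!r}")
    return ChargeDensityProfile(bin_edges=edges, rho=rho)


def capacitor_sheet_positions(
    n_bins: int, z_range: tuple[float, float], separation: float, center: float | None = None
) -> tuple[float, float]:
    """Bin-center positions the capacitor sheets actually occupy."""
    edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if center is None:
        center = 0.5 * (z_range[0] + z_range[1])
    i1 = int(np.argmin(np.abs(centers - (center - separation / 2))))
    i2 = int(np.argmin(np.abs(centers - (center + separation / 2))))
    return float(centers[i1]), float(centers[i2])
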
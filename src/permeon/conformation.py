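"""Carbonyl-flip classification, opposing-carbonyl distances, H-bond and
amide-contact diagnostics of the two selectivity-filter states.

A per-subunit carbonyl orientation is labelled against the crystal
reference direction of that C=O group: crystal below 60 deg, flipped above
120 deg, 'other' in between, with optional temporal hysteresis to suppress
flicker.  Opposing-carbonyl distances d1 (T63) and d2 (V64) report filter
widening and asymmetry.  Hydrogen bonds use the geometric criterion
H...O <= 2.5 A with an N-H...O angle >= 150 deg; amide contact maps list
amide-proton pairs below a distance cutoff (the solid-state NMR proxy:
only pairs below ~4 A give strong cross-peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc

from .channel import ChannelGeometry, SUBUNITS, SUBUNIT_ANGLES_DEG
from .trajectory import Trajectory

__all__ = [
    "HBond",
    "classify_flip",
    "flip_timeline",
    "crystal_reference_direction",
    "opposing_distances",
    "distance_timeline",
    "detect_hbonds",
    "amide_contact_map",
    "DEFAULT_PAIRING",
]

#: default opposing-pair convention; the diagonal alternative is
#: (("A", "C"), ("B", "D"))
DEFAULT_PAIRING = (("A", "B"), ("C", "D"))

FLIP_CRYSTAL_MAX_DEG = 60.0
FLIP_FLIPPED_MIN_DEG = 120.0


class HBond(NamedTuple):
    """A backbone N-H...O=C contact satisfying the geometric criterion."""

    chain: str
    donor_res: int
    acceptor_res: int
    acceptor_chain: str
    h_to_acceptor: float
    angle: float


def crystal_reference_direction(
    geometry: ChannelGeometry, subunit: str
) -> np.ndarray:
    """Crystal-state C=O direction of a pore-lining carbonyl: the unit
    vector pointing from the subunit toward the pore axis."""
    ang = SUBUNIT_ANGLES_DEG[subunit]
    outward = geometry.to_global(np.array(0.0), 1.0, ang) - geometry.axis_origin
    outward /= np.linalg.norm(outward)
    return -outward


def _co_vectors(
    trajectory: Trajectory, subunit: str, residue: int, channel: str
) -> np.ndarray:
    c_row = trajectory.select_atoms(
        subunit=subunit, residue_number=residue, atom_name="C", channel=channel
    )
    o_row = trajectory.select_atoms(
        subunit=subunit, residue_number=residue, atom_name="O", channel=channel
    )
    if c_row.size != 1 or o_row.size != 1:
        raise KeyError(
            f"carbonyl C/O of {subunit}{residue} (channel {channel!r}) not found"
        )
    return trajectory.positions[:, o_row[0]] - trajectory.positions[:, c_row[0]]


def _label_from_angle(angle_deg: float) -> str:
    if angle_deg < FLIP_CRYSTAL_MAX_DEG:
        return "crystal"
    if angle_deg > FLIP_FLIPPED_MIN_DEG:
        return "flipped_T62"
    return "other"


def classify_flip(
    trajectory: Trajectory,
    frame: int,
    subunit: str,
    residue: int = 62,
    reference_direction: np.ndarray | None = None,
    geometry: ChannelGeometry | None = None,
    channel: str = "lower",
) -> tuple[str, float]:
    """Label one subunit's carbonyl orientation at one frame.

    Returns ``(label, flip_angle_deg)`` where the angle is measured between
    the instantaneous C=O vector and the crystal reference direction.
    """
    if reference_direction is None:
        if geometry is None:
            raise ValueError("need reference_direction or geometry")
        reference_direction = crystal_reference_direction(geometry, subunit)
    ref = np.asarray(reference_direction, dtype=float)
    ref = ref / np.linalg.norm(ref)
    v = _co_vectors(trajectory, subunit, residue, channel)[frame]
    cosang = float(np.clip(v @ ref / np.linalg.norm(v), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return _label_from_angle(angle), angle


def _dehysterize(labels: list[str], min_run: int) -> list[str]:
    """Reassign runs shorter than min_run to the preceding stable label."""
    if min_run <= 1 or not labels:
        return labels
    out = list(labels)
    i = 0
    prev_label = None
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        if j - i < min_run and prev_label is not None:
            for k in range(i, j):
                out[k] = prev_label
        else:
            prev_label = out[i]
        i = j
    return out


def flip_timeline(
    trajectory: Trajectory,
    geometry: ChannelGeometry,
    subunits: Sequence[str] = SUBUNITS,
    residue: int = 62,
    channel: str = "lower",
    hysteresis_frames: int = 3,
) -> pd.DataFrame:
    """Per-frame, per-subunit conformer labels and flip angles.

    Columns: ``label_<su>`` and ``angle_<su>`` per subunit, indexed by
    frame time (ps).  Label runs shorter than ``hysteresis_frames`` are
    merged into the preceding stable label.
    """
    data: dict[str, list] = {}
    for su in subunits:
        ref = crystal_reference_direction(geometry, su)
        v = _co_vectors(trajectory, su, residue, channel)
        cosang = np.clip(
            (v @ ref) / np.linalg.norm(v, axis=1), -1.0, 1.0
        )
        angles = np.degrees(np.arccos(cosang))
        labels = [_label_from_angle(a) for a in angles]
        data[f"label_{su}"] = _dehysterize(labels, hysteresis_frames)
        data[f"angle_{su}"] = angles
    return pd.DataFrame(data, index=pd.Index(trajectory.times, name="time_ps"))


def _carbonyl_o_position(
    trajectory: Trajectory, frame: int, subunit: str, residue: int, channel: str
) -> np.ndarray:
    row = trajectory.select_atoms(
        subunit=subunit, residue_number=residue, atom_name="O", channel=channel
    )
    if row.size != 1:
        raise KeyError(f"carbonyl O of {subunit}{residue} not found")
    return trajectory.positions[frame, row[0]]


def opposing_distances(
    trajectory: Trajectory,
    frame: int,
    pairing: tuple = DEFAULT_PAIRING,
    channel: str = "lower",
) -> dict[str, dict[tuple, float]]:
    """d1 (T63 O-O) and d2 (V64 O-O) for each subunit pair of the pairing."""
    out: dict[str, dict[tuple, float]] = {"d1": {}, "d2": {}}
    for name, residue in (("d1", 63), ("d2", 64)):
        for pair in pairing:
            p = _carbonyl_o_position(trajectory, frame, pair[0], residue, channel)
            q = _carbonyl_o_position(trajectory, frame, pair[1], residue, channel)
            out[name][tuple(pair)] = float(np.linalg.norm(p - q))
    return out


def distance_timeline(
    trajectory: Trajectory,
    pairing: tuple = DEFAULT_PAIRING,
    channel: str = "lower",
) -> pd.DataFrame:
    """d1/d2 per frame for both pairs; columns like ``d1_AB``."""
    cols = {}
    for name, residue in (("d1", 63), ("d2", 64)):
        for pair in pairing:
            rows = [
                trajectory.select_atoms(
                    subunit=su, residue_number=residue, atom_name="O", channel=channel
                )[0]
                for su in pair
            ]
            d = np.linalg.norm(
                trajectory.positions[:, rows[0]] - trajectory.positions[:, rows[1]],
                axis=1,
            )
            cols[f"{name}_{pair[0]}{pair[1]}"] = d
    return pd.DataFrame(cols, index=pd.Index(trajectory.times, name="time_ps"))


# ---------------------------------------------------------------------------
# structure-based diagnostics (biotite AtomArray input)


def _atom_coord(structure, chain, res, name) -> np.ndarray | None:
    m = (
        (structure.chain_id == chain)
        & (structure.res_id == res)
        & (structure.atom_name == name)
    )
    if not m.any():
        return None
    return structure.coord[np.flatnonzero(m)[0]]


def _amide_hydrogens(structure) -> dict[tuple[str, int], np.ndarray]:
    """Amide H per (chain, residue); reconstructed from N, CA, C(prev) when
    the structure carries no protons (crystal structures usually don't)."""
    out: dict[tuple[str, int], np.ndarray] = {}
    for chain in np.unique(structure.chain_id):
        res_ids = np.unique(structure.res_id[structure.chain_id == chain])
        for res in res_ids:
            h = _atom_coord(structure, chain, int(res), "H")
            if h is not None:
                out[(str(chain), int(res))] = h
                continue
            n = _atom_coord(structure, chain, int(res), "N")
            ca = _atom_coord(structure, chain, int(res), "CA")
            c_prev = _atom_coord(structure, chain, int(res) - 1, "C")
            if n is None or ca is None or c_prev is None:
                continue
            u = n - ca
            v = n - c_prev
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            d = u + v
            d /= np.linalg.norm(d)
            out[(str(chain), int(res))] = n + d  # 1.0 A N-H
    return out


def detect_hbonds(
    structure: struc.AtomArray,
    h_o_max: float = 2.5,
    angle_min: float = 150.0,
) -> list[HBond]:
    """Backbone N-H...O=C contacts satisfying the geometric criterion.

    Donors and acceptors separated by one residue on the same chain are
    skipped (covalent neighbors).
    """
    hydrogens = _amide_hydrogens(structure)
    is_o = structure.atom_name == "O"
    acceptors = [
        (str(structure.chain_id[i]), int(structure.res_id[i]), structure.coord[i])
        for i in np.flatnonzero(is_o)
    ]
    bonds: list[HBond] = []
    for (chain, res), h in hydrogens.items():
        n = _atom_coord(structure, chain, res, "N")
        if n is None:
            continue
        for acc_chain, acc_res, o in acceptors:
            if acc_chain == chain and abs(acc_res - res) <= 1:
                continue
            d = float(np.linalg.norm(o - h))
            if d > h_o_max:
                continue
            u = n - h
            v = o - h
            cosang = float(
                np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
            )
            angle = float(np.degrees(np.arccos(cosang)))
            if angle >= angle_min:
                bonds.append(HBond(chain, res, acc_res, acc_chain, d, angle))
    return bonds


def amide_contact_map(
    structure: struc.AtomArray, cutoff: float = 4.0
) -> set[tuple[str, int, int]]:
    """Amide-proton pairs (chain, res_i, res_j), i < j, closer than cutoff.

    Per subunit: both vicinal and longer-range pairs are reported.  The
    map is monotone in the cutoff.
    """
    hydrogens = _amide_hydrogens(structure)
    out: set[tuple[str, int, int]] = set()
    keys = sorted(hydrogens)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            (c1, r1), (c2, r2) = keys[a], keys[b]
            if c1 != c2:
                continue
            if np.linalg.norm(hydrogens[keys[a]] - hydrogens[keys[b]]) < cutoff:
                out.add((c1, min(r1, r2), max(r1, r2)))
    return out
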
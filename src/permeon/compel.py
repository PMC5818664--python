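"""Two-compartment bookkeeping for the computational-electrophysiology setup.

A double-membrane box splits into compartment (a), the axial slab between
the two membrane midplanes, and compartment (b), the complementary
(periodic) slab.  A small, maintained imbalance in permeant-ion counts
between the compartments sustains a transmembrane voltage; this module
audits the per-compartment counts and produces the ion<->water position
swaps that restore a target imbalance after permeation events have moved
charge across a membrane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trajectory import Frame, ION_SPECIES, Species

__all__ = [
    "CompelError",
    "CompartmentState",
    "Swap",
    "assign_compartments",
    "compartment_state",
    "maintain_imbalance",
    "apply_swaps",
]


class CompelError(ValueError):
    pass


class Swap(NamedTuple):
    """Exchange the positions of one ion and one water (by particle id)."""

    ion_id: int
    water_id: int


@dataclass
class CompartmentState:
    """Per-species ion counts in the two compartments at one frame."""

    frame_time: float
    counts: pd.DataFrame  # index: species, columns: a, b
    delta_n: dict[str, int]  # a minus b
    delta_q: float  # net charge difference (a minus b), e


def _compartment_of(z: np.ndarray, midplanes: tuple[float, float]) -> np.ndarray:
    z1, z2 = midplanes
    if z1 == z2:
        raise CompelError("membrane midplanes must be distinct")
    z1, z2 = sorted((float(z1), float(z2)))
    return np.where((z >= z1) & (z < z2), "a", "b")


def assign_compartments(frame: Frame, midplanes: tuple[float, float]) -> np.ndarray:
    """Compartment label ('a' or 'b') for every particle of the frame.

    Compartment a is the half-open slab [z1, z2); b is the complementary
    periodic slab.  Coordinates are wrapped into the box first.
    """
    z = np.mod(frame.positions[:, 2], frame.box[2])
    return _compartment_of(z, midplanes)


def compartment_state(
    frame: Frame,
    midplanes: tuple[float, float],
    species: Sequence[str] | None = None,
) -> CompartmentState:
    labels = assign_compartments(frame, midplanes)
    sp = frame.particles["species"].to_numpy()
    charge = frame.particles["charge"].to_numpy(dtype=float)
    wanted = list(species) if species is not None else [
        s for s in ION_SPECIES if (sp == s).any()
    ]
    rows = {}
    for s in wanted:
        in_s = sp == s
        rows[s] = {
            "a": int((in_s & (labels == "a")).sum()),
            "b": int((in_s & (labels == "b")).sum()),
        }
    counts = pd.DataFrame(rows).T.astype(int) if rows else pd.DataFrame(columns=["a", "b"])
    delta_n = {s: int(rows[s]["a"] - rows[s]["b"]) for s in rows}
    ion_mask = np.isin(sp, ION_SPECIES)
    delta_q = float(
        charge[ion_mask & (labels == "a")].sum() - charge[ion_mask & (labels == "b")].sum()
    )
    return CompartmentState(
        frame_time=frame.time, counts=counts, delta_n=delta_n, delta_q=delta_q
    )


def _axial_distance(z: np.ndarray, center: float, box_z: float) -> np.ndarray:
    d = np.abs(z - center)
    return np.minimum(d, box_z - d)


def maintain_imbalance(
    frame: Frame,
    target_delta_n: int,
    species: str | Species = Species.K,
    midplanes: tuple[float, float] = (40.0, 120.0),
) -> list[Swap]:
    """Swaps that restore the target per-species count imbalance a-b.

    Each swap exchanges the positions of one permeant ion in the surplus
    compartment with one water in the deficit compartment, changing
    delta_n by exactly 2; the minimal number of swaps is |current-target|/2.
    Candidates are the surplus-compartment ion closest to its bulk center
    and the deficit-compartment water closest to its bulk center (axial
    periodic distance); ties break on the lowest particle id.
    """
    s = species.value if isinstance(species, Species) else str(species)
    labels = assign_compartments(frame, midplanes)
    sp = frame.particles["species"].to_numpy()
    ids = frame.particles["id"].to_numpy()
    z = np.mod(frame.positions[:, 2], frame.box[2])
    box_z = float(frame.box[2])

    current = int((labels[sp == s] == "a").sum() - (labels[sp == s] == "b").sum())
    diff = int(target_delta_n) - current
    if diff == 0:
        return []
    if diff % 2 != 0:
        raise CompelError(
            f"delta_n parity mismatch: current {current}, target {target_delta_n}; "
            "a single ion/water swap changes delta_n by 2"
        )
    n_swaps = abs(diff) // 2
    surplus, deficit = ("b", "a") if diff > 0 else ("a", "b")

    z1, z2 = sorted(midplanes)
    center_a = 0.5 * (z1 + z2)
    center_b = np.mod(0.5 * (z2 + z1 + box_z), box_z)
    centers = {"a": center_a, "b": center_b}

    def ranked(mask: np.ndarray, center: float) -> list[int]:
        idx = np.flatnonzero(mask)
        dist = _axial_distance(z[idx], center, box_z)
        order = np.lexsort((ids[idx], dist))
        return [int(i) for i in idx[order]]

    ion_pool = ranked((sp == s) & (labels == surplus), centers[surplus])
    water_pool = ranked(
        (sp == Species.WATER_O.value) & (labels == deficit), centers[deficit]
    )
    if len(ion_pool) < n_swaps:
        raise CompelError(
            f"not enough {s} ions in compartment {surplus}: need {n_swaps}, "
            f"have {len(ion_pool)}"
        )
    if len(water_pool) < n_swaps:
        raise CompelError(
            f"not enough waters in compartment {deficit}: need {n_swaps}, "
            f"have {len(water_pool)}"
        )
    return [
        Swap(int(ids[i]), int(ids[w]))
        for i, w in zip(ion_pool[:n_swaps], water_pool[:n_swaps])
    ]


def apply_swaps(frame: Frame, swaps: Sequence[Swap]) -> Frame:
    """Return a frame copy with each swap's ion/water positions exchanged."""
    pos = frame.positions.copy()
    ids = frame.particles["id"].to_numpy()
    for sw in swaps:
        i = int(np.flatnonzero(ids == sw.ion_id)[0])
        w = int(np.flatnonzero(ids == sw.water_id)[0])
        pos[[i, w]] = pos[[w, i]]
    return Frame(
        time=frame.time, box=frame.box, positions=pos, particles=frame.particles
    )
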
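"""Particle/frame containers for reduced ion-channel trajectories.

A :class:`Trajectory` holds a static particle table (identity, species,
charge, optional protein labelling) plus per-frame positions for every
particle.  Coordinates are in Angstrom, times in ps.  The particle table is
a pandas DataFrame so that downstream selections (by species, subunit,
residue, atom name, channel copy) stay expressive and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "ION_SPECIES",
    "SPECIES_CHARGE",
    "Frame",
    "Trajectory",
    "make_particles",
    "minimum_image",
]


class Species(str, Enum):
    """Particle species of the reduced model."""

    K = "K"
    NA = "NA"
    RB = "RB"
    CL = "CL"
    WATER_O = "WATER_O"
    PROTEIN_ATOM = "PROTEIN_ATOM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: cation/anion species that take part in permeation bookkeeping
ION_SPECIES = (Species.K.value, Species.NA.value, Species.RB.value, Species.CL.value)

#: formal charges of the reduced model (PROTEIN_ATOM defaults to 0)
SPECIES_CHARGE = {
    Species.K.value: 1.0,
    Species.NA.value: 1.0,
    Species.RB.value: 1.0,
    Species.CL.value: -1.0,
    Species.WATER_O.value: 0.0,
    Species.PROTEIN_ATOM.value: 0.0,
}

PARTICLE_COLUMNS = [
    "id",
    "species",
    "charge",
    "subunit",
    "residue_number",
    "atom_name",
    "channel",
]


def make_particles(rows: list[dict]) -> pd.DataFrame:
    """Build a validated particle table from row dicts.

    Missing optional fields default to empty strings / zero.  Charges are
    filled from :data:`SPECIES_CHARGE` when not given explicitly.
    """
    df = pd.DataFrame(rows)
    if "id" not in df.columns or "species" not in df.columns:
        raise ValueError("particle rows need at least 'id' and 'species'")
    if "charge" not in df.columns:
        df["charge"] = [SPECIES_CHARGE[s] for s in df["species"]]
    else:
        df["charge"] = df["charge"].fillna(df["species"].map(SPECIES_CHARGE))
    for col, default in (("subunit", ""), ("atom_name", ""), ("channel", "")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default).astype(str)
    if "residue_number" not in df.columns:
        df["residue_number"] = 0
    df["residue_number"] = df["residue_number"].fillna(0).astype(int)
    df = df[PARTICLE_COLUMNS].reset_index(drop=True)
    if df["id"].duplicated().any():
        raise ValueError("particle ids must be unique")
    bad = set(df["species"]) - set(SPECIES_CHARGE)
    if bad:
        raise ValueError(f"unknown species: {sorted(bad)}")
    return df


@dataclass
class Frame:
    """A single-frame view into a trajectory (positions are not copied)."""

    time: float
    box: np.ndarray
    positions: np.ndarray
    particles: pd.DataFrame


@dataclass
class Trajectory:
    """Positions of ``n_particles`` particles over ``n_frames`` frames.

    Attributes
    ----------
    particles:
        Static table with columns ``id, species, charge, subunit,
        residue_number, atom_name, channel`` (row order defines the particle
        axis of ``positions``).
    times:
        Frame times, ps, shape ``(n_frames,)``.
    box:
        Orthorhombic box edges, A, shape ``(3,)`` (constant over the run).
    positions:
        Coordinates, A, shape ``(n_frames, n_particles, 3)``.
    """

    particles: pd.DataFrame
    times: np.ndarray
    box: np.ndarray
    positions: np.ndarray
    ground_truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != len(self.particles):
            raise ValueError("particle table and positions disagree on particle count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def wrap(self) -> "Trajectory":
        """Wrap all coordinates into [0, box) per axis (in place)."""
        self.positions = np.mod(self.positions, self.box[None, None, :])
        return self

    def frame(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            box=self.box,
            positions=self.positions[i],
            particles=self.particles,
        )

    def index_of_id(self, particle_id: int) -> int:
        hits = np.flatnonzero(self.particles["id"].to_numpy() == particle_id)
        if hits.size != 1:
            raise KeyError(f"particle id {particle_id} not found")
        return int(hits[0])

    def species_indices(self, species: str | Species) -> np.ndarray:
        s = species.value if isinstance(species, Species) else species
        return np.flatnonzero(self.particles["species"].to_numpy() == s)

    def select_atoms(
        self,
        subunit: str | None = None,
        residue_number: int | None = None,
        atom_name: str | None = None,
        channel: str | None = None,
    ) -> np.ndarray:
        """Row indices of protein atoms matching the given selectors."""
        mask = np.ones(len(self.particles), dtype=bool)
        p = self.particles
        if subunit is not None:
            mask &= p["subunit"].to_numpy() == subunit
        if residue_number is not None:
            mask &= p["residue_number"].to_numpy() == residue_number
        if atom_name is not None:
            mask &= p["atom_name"].to_numpy() == atom_name
        if channel is not None:
            mask &= p["channel"].to_numpy() == channel
        return np.flatnonzero(mask)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    return delta - box * np.round(delta / box)
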
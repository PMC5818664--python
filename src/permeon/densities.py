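"""Ion occupancy, PMF by Boltzmann inversion, hydration and coordination.

Occupancy is histogrammed over the channel-local axial/radial plane
(z along the pore axis, r the distance from it).  The 2D potential of
mean force follows by Boltzmann inversion,

    w(z, r) = -kB T ln( p(z, r) / p_ref ),

with p the normalized occupancy and p_ref the maximum-density bin, so
reported barriers are positive and the minimum of w over populated bins is
zero.  Zero-count bins are masked, never imputed.  Energies are in
kJ/mol at the simulation temperature (default 300 K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelGeometry, ChannelSystem
from .constants import KB_KJ_MOL
from .trajectory import Species, Trajectory, minimum_image

__all__ = [
    "PmfGrid",
    "CoordinationState",
    "occupancy_histogram",
    "pmf_from_counts",
    "pmf_from_occupancy",
    "site_occupancy",
    "hydration_number",
    "coordination_state",
    "HYDRATION_CUTOFF",
]

#: first-minimum ion-oxygen cutoffs for hydration counting, A
HYDRATION_CUTOFF = {"NA": 3.1, "K": 3.5, "RB": 3.7}

DEFAULT_TEMPERATURE = 300.0


@dataclass
class PmfGrid:
    """Occupancy histogram and free-energy surface over (z, r)."""

    z_edges: np.ndarray
    r_edges: np.ndarray
    counts: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    w: np.ndarray | None = None
    mask: np.ndarray | None = None  # True where counts == 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.z_edges) - 1, len(self.r_edges) - 1):
            raise ValueError("counts shape must match (n_z, n_r) bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CoordinationState:
    """Protein-oxygen / water-oxygen coordination signature of one ion."""

    frame_time: float
    ion_id: int
    n_protein_o: int
    n_water_o: int
    contributing_atoms: list = field(default_factory=list)


def occupancy_histogram(
    trajectory: Trajectory,
    system: ChannelSystem | ChannelGeometry,
    species: str | Species = Species.K,
    bins: tuple[int, int] = (60, 30),
    z_range: tuple[float, float] = (-15.0, 12.0),
    r_max: float = 12.0,
) -> PmfGrid:
    """Histogram ion positions in the channel frame over (z, r).

    For a two-copy system each ion-frame contributes in its owning copy's
    local coordinates.
    """
    s = species.value if isinstance(species, Species) else str(species)
    rows = trajectory.species_indices(s)
    pos = np.mod(trajectory.positions[:, rows, :], trajectory.box)
    if isinstance(system, ChannelGeometry):
        geoms = [system]
        owner = np.zeros(pos.shape[:-1], dtype=int)
    else:
        geoms = [system.channels[n] for n in system.names]
        _, owner = system.region_labels(pos)
    z_edges = np.linspace(z_range[0], z_range[1], bins[0] + 1)
    r_edges = np.linspace(0.0, r_max, bins[1] + 1)
    counts = np.zeros((bins[0], bins[1]))
    for gi, geom in enumerate(geoms):
        sel = owner == gi
        if not sel.any():
            continue
        sloc, rloc = geom.local_coords(pos[sel])
        counts += np.histogram2d(sloc, rloc, bins=(z_edges, r_edges))[0]
    return PmfGrid(z_edges=z_edges, r_edges=r_edges, counts=counts)


def pmf_from_counts(
    counts: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann inversion of a histogram: w = -kT ln(p/p_max), masked zeros.

    Returns ``(w, mask)``; ``w`` is NaN and ``mask`` True where the
    histogram is empty.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty; PMF undefined")
    mask = counts == 0
    p = counts / total
    p_ref = p.max()
    w = np.full(counts.shape, np.nan)
    w[~mask] = -KB_KJ_MOL * temperature * np.log(p[~mask] / p_ref)
    return w, mask


def pmf_from_occupancy(
    grid: PmfGrid, temperature: float = DEFAULT_TEMPERATURE
) -> PmfGrid:
    """Fill in the free-energy surface of an occupancy grid (new object)."""
    w, mask = pmf_from_counts(grid.counts, temperature)
    return PmfGrid(
        z_edges=grid.z_edges,
        r_edges=grid.r_edges,
        counts=grid.counts,
        temperature=temperature,
        w=w,
        mask=mask,
    )


def site_occupancy(
    trajectory: Trajectory,
    system: ChannelSystem,
    species: str | Species,
    sites: list[str],
    half_width: float = 1.1,
    channel: str = "lower",
) -> float:
    """Mean number of ions simultaneously inside the named filter sites.

    A site window is |z - z_site| <= half_width and r <= sf_radius in the
    given copy's channel frame; occupancy is averaged over frames.
    """
    s = species.value if isinstance(species, Species) else str(species)
    rows = trajectory.species_indices(s)
    geom = system.channels[channel]
    pos = np.mod(trajectory.positions[:, rows, :], trajectory.box)
    sloc, rloc = geom.local_coords(pos)
    inside = np.zeros(sloc.shape, dtype=bool)
    for site in sites:
        z_site = geom.site_planes[site]
        inside |= (np.abs(sloc - z_site) <= half_width) & (rloc <= geom.sf_radius)
    return float(inside.sum(axis=1).mean())


def _neighbor_distances(
    trajectory: Trajectory, ion_row: int, other_rows: np.ndarray, frame: int
) -> np.ndarray:
    d = trajectory.positions[frame, other_rows] - trajectory.positions[frame, ion_row]
    return np.linalg.norm(minimum_image(d, trajectory.box), axis=-1)


def hydration_number(
    trajectory: Trajectory,
    ion_id: int,
    frame: int,
    cutoff: float | None = None,
) -> int:
    """Number of water oxygens within the species' first-shell cutoff."""
    row = trajectory.index_of_id(ion_id)
    if cutoff is None:
        sp = str(trajectory.particles["species"].iloc[row])
        cutoff = HYDRATION_CUTOFF.get(sp, 3.5)
    waters = trajectory.species_indices(Species.WATER_O)
    if waters.size == 0:
        return 0
    d = _neighbor_distances(trajectory, row, waters, frame)
    return int((d <= cutoff).sum())


def coordination_state(
    trajectory: Trajectory,
    ion_id: int,
    frame: int,
    system: ChannelSystem,
    channel: str | None = None,
    protein_cutoff: float | None = None,
    water_cutoff: float | None = None,
) -> CoordinationState:
    """S_side coordination signature (protein O count, water O count).

    Protein oxygens are drawn from the geometry's per-subunit S_side atom
    selectors of the relevant channel copy; distinct signatures
    (n_protein_o, n_water_o) distinguish coordination states, and
    ``contributing_atoms`` records which selectors are engaged.
    """
    row = trajectory.index_of_id(ion_id)
    sp = str(trajectory.particles["species"].iloc[row])
    if protein_cutoff is None:
        protein_cutoff = {"NA": 3.2, "K": 3.6}.get(sp, 3.6)
    if water_cutoff is None:
        water_cutoff = HYDRATION_CUTOFF.get(sp, 3.5)
    if channel is None:
        pos = np.mod(trajectory.positions[frame, row], trajectory.box)
        _, owner = system.region_labels(pos.reshape(1, 3))
        channel = system.names[int(owner[0])]
    geom = system.channels[channel]
    contributing = []
    n_protein = 0
    for selectors in geom.s_side_atoms.values():
        for sel in selectors:
            rows = trajectory.select_atoms(
                subunit=sel.subunit,
                residue_number=sel.residue_number,
                atom_name=sel.atom_name,
                channel=channel if (trajectory.particles["channel"] != "").any() else None,
            )
            if rows.size == 0:
                continue
            d = _neighbor_distances(trajectory, row, rows, frame)
            if d.min() <= protein_cutoff:
                n_protein += 1
                contributing.append(sel)
    n_water = hydration_number(trajectory, ion_id, frame, cutoff=water_cutoff)
    return CoordinationState(
        frame_time=float(trajectory.times[frame]),
        ion_id=int(ion_id),
        n_protein_o=n_protein,
        n_water_o=n_water,
        contributing_atoms=contributing,
    )
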
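"""Membrane potential from binned charge density via the Poisson equation.

The electrostatic potential along the membrane normal follows from the
one-dimensional Poisson equation, d^2 phi / dz^2 = -rho(z)/eps0, solved by
double integration of the laterally averaged charge density with
phi(z_ref) = 0 and dphi/dz(z_ref) = 0 at a declared reference point.  The
binned density is treated as piecewise constant, for which the double
integral has a closed form (phi is quadratic within each bin), so the
integration introduces no quadrature error beyond the binning itself.

Charge density is carried in e/A^3; potentials are reported in mV.  Vacuum
permittivity is used throughout (no dielectric profile): the profile is the
bare double integral of the simulated charge distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import PHI_V_PER_E_PER_ANG
from .trajectory import Trajectory

__all__ = [
    "ChargeDensityProfile",
    "PotentialProfile",
    "bin_charge_density",
    "potential_from_density",
    "transmembrane_voltage",
    "voltage_timeseries",
    "default_plateau_windows",
]


@dataclass
class ChargeDensityProfile:
    """Charge density rho(z) on a uniform axial grid (e/A^3)."""

    bin_edges: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.rho.size + 1:
            raise ValueError("bin_edges must have len(rho)+1 entries")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("charge-density grid must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_charge(self, area: float) -> float:
        """Integral of rho over the box, e (slab volume = bin_width * area)."""
        return float(self.rho.sum() * self.bin_width * area)


@dataclass
class PotentialProfile:
    """Electrostatic potential phi(z) in mV with phi(reference_z) = 0."""

    z: np.ndarray
    phi: np.ndarray
    reference_z: float


def bin_charge_density(
    trajectory: Trajectory,
    n_bins: int,
    frames: slice | Sequence[int] | None = None,
) -> ChargeDensityProfile:
    """Time-averaged axial charge density of a trajectory.

    Coordinates are wrapped into the box before binning; the grid spans
    [0, box_z).  The sum of rho * slab_volume over bins equals the total
    system charge.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    idx = np.arange(trajectory.n_frames)[frames] if frames is not None else np.arange(
        trajectory.n_frames
    )
    if idx.size == 0:
        raise ValueError("no frames selected")
    box = trajectory.box
    charges = trajectory.particles["charge"].to_numpy(dtype=float)
    edges = np.linspace(0.0, box[2], n_bins + 1)
    z = np.mod(trajectory.positions[idx, :, 2], box[2])
    hist = np.zeros(n_bins)
    for zi in z:  # frame loop keeps memory flat
        hist += np.histogram(zi, bins=edges, weights=charges)[0]
    slab_volume = (edges[1] - edges[0]) * box[0] * box[1]
    rho = hist / (idx.size * slab_volume)
    return ChargeDensityProfile(bin_edges=edges, rho=rho)


def _solve_piecewise(rho: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Potential/field at bin edges for piecewise-constant rho, zero initial
    conditions at the left edge.  Reduced units: phi'' = -rho."""
    n = rho.size
    e_edges = np.concatenate(([0.0], np.cumsum(rho) * h))  # E' = rho
    phi_edges = np.zeros(n + 1)
    # phi(z) within bin k: phi_k - E_k (z-z_k) - rho_k (z-z_k)^2 / 2
    phi_edges[1:] = -np.cumsum(e_edges[:-1] * h + 0.5 * rho * h * h)
    return phi_edges, e_edges


def potential_from_density(
    rho: ChargeDensityProfile, reference_z: float | None = None
) -> PotentialProfile:
    """Double integration of the charge density (Poisson equation).

    Returns phi at bin centers in mV with phi(reference_z) = 0 and zero
    field at the reference (default: the left grid edge).
    """
    h = rho.bin_width
    z0 = float(rho.bin_edges[0])
    if reference_z is None:
        reference_z = z0
    if not (rho.bin_edges[0] <= reference_z <= rho.bin_edges[-1]):
        raise ValueError("reference_z outside the grid")
    phi_e, e_e = _solve_piecewise(rho.rho, h)

    def _eval(zq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = np.clip(((zq - z0) // h).astype(int), 0, rho.rho.size - 1)
        dz = zq - (z0 + k * h)
        phi = phi_e[k] - e_e[k] * dz - 0.5 * rho.rho[k] * dz * dz
        e = e_e[k] + rho.rho[k] * dz
        return phi, e

    phi_c, _ = _eval(rho.centers)
    phi_ref, e_ref = _eval(np.asarray([reference_z], dtype=float))
    # subtract the affine piece so phi(ref) = 0 and phi'(ref) = 0
    phi = phi_c - phi_ref[0] + e_ref[0] * (rho.centers - reference_z)
    phi_mv = phi * PHI_V_PER_E_PER_ANG * 1e3
    return PotentialProfile(z=rho.centers, phi=phi_mv, reference_z=float(reference_z))


def default_plateau_windows(
    midplanes: tuple[float, float], box_z: float, fraction: float = 0.5
) -> list[tuple[float, float]]:
    """Central-``fraction`` plateau windows (b-low, a, b-high) of the two
    bulk compartments delimited by the membrane midplanes."""
    z1, z2 = sorted(midplanes)

    def central(lo: float, hi: float) -> tuple[float, float]:
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * fraction
        return (mid - half, mid + half)

    return [central(0.0, z1), central(z1, z2), central(z2, box_z)]


def transmembrane_voltage(
    profile: PotentialProfile,
    windows: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Per-membrane voltage differences from three plateau windows.

    ``windows`` are (b-low, a, b-high) axial intervals.  The lower membrane
    separates b-low from a, the upper separates a from b-high:

        dV_lower = <phi>_a   - <phi>_b_low
        dV_upper = <phi>_b_high - <phi>_a

    For an antisymmetric double-membrane profile the two come out with
    opposite signs.  Values in mV.
    """
    if len(windows) != 3:
        raise ValueError("need three plateau windows: (b_low, a, b_high)")
    means = []
    for lo, hi in windows:
        m = (profile.z >= lo) & (profile.z < hi)
        if not m.any():
            raise ValueError(f"plateau window [{lo}, {hi}) contains no grid points")
        means.append(float(profile.phi[m].mean()))
    b_low, a, b_high = means
    return (a - b_low, b_high - a)


def voltage_timeseries(
    trajectory: Trajectory,
    n_bins: int,
    windows: Sequence[tuple[float, float]],
    stride: int = 1,
    window_frames: int = 1,
) -> np.ndarray:
    """Per-window (dV_lower, dV_upper) over the run; shape (n_windows, 2).

    Frames are grouped in blocks of ``window_frames`` (after striding) and
    each block is binned and integrated independently, giving a frame-wise
    spread for the transmembrane voltage.
    """
    idx = np.arange(0, trajectory.n_frames, stride)
    out = []
    for start in range(0, idx.size, window_frames):
        block = idx[start : start + window_frames]
        rho = bin_charge_density(trajectory, n_bins, frames=block)
        phi = potential_from_density(rho)
        out.append(transmembrane_voltage(phi, windows))
    return np.asarray(out)
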
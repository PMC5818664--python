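"""Charge binning and the Poisson double-integration solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from permeon.constants import PHI_V_PER_E_PER_ANG
from permeon.electrostatics import (
    ChargeDensityProfile,
    bin_charge_density,
    default_plateau_windows,
    potential_from_density,
    transmembrane_voltage,
)
from permeon.synthetic import capacitor_sheet_positions, gen_charge_density


def test_binned_integral_matches_total_charge(make_traj):
    rng = np.random.default_rng(0)
    rows = [dict(id=i, species=s) for i, s in enumerate(["K"] * 7 + ["CL"] * 4 + ["WATER_O"] * 5)]
    pos = rng.uniform(0, [40, 40, 160], size=(3, 16, 3))
    traj = make_traj(rows, pos)
    rho = bin_charge_density(traj, 80)
    assert rho.total_charge(40.0 * 40.0) == pytest.approx(3.0, abs=1e-12)
    # brute-force per-bin check on one frame
    rho1 = bin_charge_density(traj, 40, frames=[1])
    charges = traj.particles["charge"].to_numpy()
    z = np.mod(pos[1, :, 2], 160.0)
    expect = np.histogram(z, bins=rho1.bin_edges, weights=charges)[0] / (
        (160.0 / 40) * 1600.0
    )
    assert np.allclose(rho1.rho, expect)


def test_zero_density_zero_potential():
    phi = potential_from_density(gen_charge_density("zero", n_bins=64))
    assert np.allclose(phi.phi, 0.0)


def test_capacitor_matches_parallel_plate_closed_form():
    sigma, sep, n_bins = 2e-4, 30.0, 1000
    rho = gen_charge_density("capacitor", n_bins=n_bins, sigma=sigma, separation=sep)
    phi = potential_from_density(rho)
    z1, z2 = capacitor_sheet_positions(n_bins, (0.0, 160.0), sep)
    expected = sigma * (z2 - z1) * PHI_V_PER_E_PER_ANG * 1e3  # sigma d / eps0, mV
    # +sigma sheet at z1: the plateau before z1 sits above the one beyond z2
    drop = phi.phi[phi.z < z1 - 2].mean() - phi.phi[phi.z > z2 + 2].mean()
    assert abs(drop - expected) / expected < 0.005


def test_agrees_with_independent_ode_solver():
    rho = gen_charge_density("gaussian_dipole", n_bins=500, amplitude=1e-5)
    phi = potential_from_density(rho)
    z0, h = rho.bin_edges[0], rho.bin_width

    def rho_step(z):
        k = min(int((z - z0) // h), rho.rho.size - 1)
        return rho.rho[max(k, 0)]

    def rhs(z, y):  # y = (phi, dphi/dz)
        return [y[1], -rho_step(z)]

    sol = solve_ivp(
        rhs,
        (rho.bin_edges[0], rho.bin_edges[-1]),
        [0.0, 0.0],
        t_eval=rho.centers,
        max_step=h / 2,
        rtol=1e-10,
        atol=1e-14,
    )
    oracle_mv = sol.y[0] * PHI_V_PER_E_PER_ANG * 1e3
    scale = np.abs(oracle_mv).max()
    assert np.max(np.abs(phi.phi - oracle_mv)) / scale < 1e-6


def test_superposition():
    r1 = gen_charge_density("gaussian_dipole", n_bins=200, amplitude=1e-5)
    r2 = gen_charge_density("capacitor", n_bins=200, sigma=1e-4)
    a, b = 0.7, -1.3
    combo = ChargeDensityProfile(r1.bin_edges, a * r1.rho + b * r2.rho)
    phi = potential_from_density(combo).phi
    phi12 = a * potential_from_density(r1).phi + b * potential_from_density(r2).phi
    assert np.allclose(phi, phi12, atol=1e-9)


def test_transmembrane_voltage_signs_and_zero():
    windows = default_plateau_windows((40.0, 120.0), 160.0)
    flat = potential_from_density(gen_charge_density("zero", n_bins=160))
    assert transmembrane_voltage(flat, windows) == (0.0, 0.0)

    # antisymmetric double capacitor: one sheet pair per membrane
    n = 1600
    edges = np.linspace(0.0, 160.0, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h = edges[1] - edges[0]
    rho = np.zeros(n)
    for z_plus, z_minus in ((35.0, 45.0), (125.0, 115.0)):
        rho[np.argmin(np.abs(centers - z_plus))] += 1e-4 / h
        rho[np.argmin(np.abs(centers - z_minus))] -= 1e-4 / h
    phi = potential_from_density(ChargeDensityProfile(edges, rho))
    dv_lower, dv_upper = transmembrane_voltage(phi, windows)
    assert dv_lower == pytest.approx(-dv_upper, rel=1e-9)
    assert abs(dv_lower) > 0


def test_grid_refinement_convergence():
    windows = default_plateau_windows((40.0, 120.0), 160.0)
    dvs = []
    for n_bins in (250, 500):
        rho = gen_charge_density("gaussian_dipole", n_bins=n_bins, width=8.0,
                                 separation=80.0, amplitude=1e-5)
        dvs.append(transmembrane_voltage(potential_from_density(rho), windows)[0])
    assert abs(dvs[1] - dvs[0]) / abs(dvs[1]) < 0.01


def test_non_uniform_grid_rejected():
    edges = np.array([0.0, 1.0, 2.5, 3.0])
    with pytest.raises(ValueError):
        ChargeDensityProfile(edges, np.zeros(3))
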
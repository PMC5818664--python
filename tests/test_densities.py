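"""Occupancy, Boltzmann inversion, hydration and coordination."""

import numpy as np
import pytest

from permeon.constants import KB_KJ_MOL
from permeon.densities import (
    coordination_state,
    hydration_number,
    occupancy_histogram,
    pmf_from_counts,
    site_occupancy,
)
from permeon.synthetic import SynthConfig, gen_trajectory

KT300 = KB_KJ_MOL * 300.0


def test_single_static_ion_fills_one_bin(make_traj, system):
    geom = system.channels["lower"]
    p = geom.to_global(np.array(-0.6), 1.3, 45.0)
    traj = make_traj([dict(id=0, species="K")], np.tile(p, (5, 1, 1)))
    grid = occupancy_histogram(traj, geom, "K", bins=(10, 5), z_range=(-15, 12), r_max=10)
    assert grid.counts.sum() == 5
    assert (grid.counts > 0).sum() == 1


def test_uniform_histogram_multinomial_and_mass(make_traj, system):
    rng = np.random.default_rng(11)
    geom = system.channels["lower"]
    n = 20_000
    s = rng.uniform(-15, 12, n)
    r = rng.uniform(0, 10, n)
    az = rng.uniform(0, 360, n)
    pos = geom.to_global(s, r, az)
    traj = make_traj([dict(id=0, species="K")], pos.reshape(n, 1, 3), times=np.arange(n) * 1.0)
    grid = occupancy_histogram(traj, geom, "K", bins=(10, 5), z_range=(-15, 12), r_max=10)
    assert grid.counts.sum() == n  # mass conservation inside the domain
    p = 1.0 / 50
    sigma = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(grid.counts - n * p) < 4 * sigma)


def test_pmf_uniform_is_flat_and_zero_bins_masked():
    counts = np.full((6, 4), 25.0)
    w, mask = pmf_from_counts(counts)
    assert np.allclose(w, 0.0)
    counts[2, 2] = 0.0
    w, mask = pmf_from_counts(counts)
    assert mask[2, 2] and np.isnan(w[2, 2])
    with pytest.raises(ValueError):
        pmf_from_counts(np.zeros((3, 3)))


def test_pmf_recovers_harmonic_well():
    # Boltzmann-sampled 1D harmonic well: w(z) = k z^2 / 2
    k = 2.0  # kJ/mol/A^2
    sigma = np.sqrt(KT300 / k)
    rng = np.random.default_rng(202)
    z = rng.normal(0.0, sigma, size=100_000)
    edges = np.linspace(-3.5 * sigma, 3.5 * sigma, 71)
    counts = np.histogram(z, bins=edges)[0].astype(float).reshape(-1, 1)
    w, mask = pmf_from_counts(counts, temperature=300.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ref = centers[np.nanargmin(np.where(mask[:, 0], np.nan, w[:, 0]))]
    expect = 0.5 * k * centers**2 - 0.5 * k * ref**2
    sel = (np.abs(centers) <= 2 * sigma) & ~mask[:, 0]
    rmse = np.sqrt(np.mean((w[sel, 0] - expect[sel]) ** 2))
    assert rmse < 0.2


def test_pmf_consistent_when_sample_size_doubles():
    rng = np.random.default_rng(7)
    sigma = 1.0
    edges = np.linspace(-2.5, 2.5, 26)
    z1 = rng.normal(0, sigma, 50_000)
    z2 = rng.normal(0, sigma, 100_000)
    w1, _ = pmf_from_counts(np.histogram(z1, bins=edges)[0].reshape(-1, 1).astype(float))
    w2, _ = pmf_from_counts(np.histogram(z2, bins=edges)[0].reshape(-1, 1).astype(float))
    centers = 0.5 * (edges[:-1] + edges[1:])
    core = np.abs(centers) <= 2.0  # well-populated bins
    assert np.nanmax(np.abs(w1[core, 0] - w2[core, 0])) < 0.25  # sampling error


def test_pmf_shift_invariance_of_differences():
    counts = np.array([[40.0, 20.0], [10.0, 5.0]])
    w, _ = pmf_from_counts(counts)
    w2, _ = pmf_from_counts(counts * 7.0)  # scaling counts shifts log-densities
    d = w - w2
    assert np.allclose(d - d[0, 0], 0.0, atol=1e-12)


def test_two_filter_residents_occupy_s3_s4(system):
    cfg = SynthConfig(
        seed=5,
        duration_ns=100.0,
        frame_interval_ps=100.0,
        n_ions={"K": 10},
        n_waters=0,
        hydration_waters=0,
        crossing_rate_inward={},
        crossing_rate_outward={},
        sf_residents=2,
    )
    traj, _ = gen_trajectory(cfg)
    occ = site_occupancy(traj, system, "K", ["S3", "S4"])
    assert occ == pytest.approx(2.0, abs=0.1)


def test_hydration_number_fixture(make_traj):
    rows = [dict(id=0, species="NA")] + [dict(id=i, species="WATER_O") for i in range(1, 9)]
    pos = np.zeros((1, 9, 3))
    pos[0, 0] = [20, 20, 80]
    for i in range(1, 7):  # 6 waters at 2.4 A
        d = np.zeros(3)
        d[i % 3] = 2.4 * (1 if i < 4 else -1)
        pos[0, i] = pos[0, 0] + d
    pos[0, 7] = [5, 5, 5]
    pos[0, 8] = [35, 35, 150]
    traj = make_traj(rows, pos)
    assert hydration_number(traj, 0, 0) == 6
    assert hydration_number(traj, 0, 0, cutoff=2.0) == 0  # non-increasing in cutoff


def test_no_waters_zero_hydration(make_traj):
    traj = make_traj([dict(id=0, species="K")], np.zeros((1, 1, 3)) + 20.0)
    assert hydration_number(traj, 0, 0) == 0


def test_shed_shell_lowers_hydration_in_filter(system):
    cfg = SynthConfig(
        seed=31,
        duration_ns=200.0,
        frame_interval_ps=100.0,
        n_ions={"K": 8},
        n_waters=0,
        hydration_waters=4,
        crossing_rate_inward={"K": 20.0},
        crossing_rate_outward={},
        sf_dwell_mean_ns=1.0,
        shed_shell_in_sf=True,
    )
    traj, truth = gen_trajectory(cfg)
    cross = truth.crossings().iloc[0]
    dt = cfg.frame_interval_ps
    f_in_sf = int(cross.t_sf_entry_ps / dt) + 1
    f_bulk = max(0, int(cross.t_start_ps / dt) - 10)
    ion = int(cross.ion_id)
    assert hydration_number(traj, ion, f_bulk) == 4
    assert hydration_number(traj, ion, f_in_sf) < 4


def coordination_fixture(make_traj, system, with_neighbor_od1):
    geom = system.channels["lower"]
    ion_pos = geom.to_global(np.array(6.0), 7.2, 0.0)  # in the side-portal band
    rows = [dict(id=0, species="NA")]
    pos = [ion_pos]
    sels = [("A", 66, "O"), ("A", 69, "O")]
    sels.append(("C", 66, "OD1") if with_neighbor_od1 else ("A", 70, "OG"))
    offs = np.array([[2.5, 0, 0], [0, 2.5, 0], [0, 0, 2.5]])
    for k, (su, res, name) in enumerate(sels):
        rows.append(
            dict(id=k + 1, species="PROTEIN_ATOM", subunit=su, residue_number=res,
                 atom_name=name, channel="lower")
        )
        pos.append(ion_pos + offs[k])
    # a distant water for contrast
    rows.append(dict(id=9, species="WATER_O"))
    pos.append(ion_pos + [0, 0, 30.0])
    return make_traj(rows, np.asarray(pos)[None, :, :])


@pytest.mark.parametrize("with_neighbor_od1", [False, True])
def test_s_side_coordination_states(make_traj, system, with_neighbor_od1):
    traj = coordination_fixture(make_traj, system, with_neighbor_od1)
    st = coordination_state(traj, 0, 0, system)
    assert st.n_protein_o == 3
    assert st.n_water_o == 0
    names = {(s.subunit, s.residue_number, s.atom_name) for s in st.contributing_atoms}
    if with_neighbor_od1:
        assert ("C", 66, "OD1") in names
    else:
        assert ("A", 70, "OG") in names


def test_ion_far_from_channel_sees_only_bulk_water(make_traj, system):
    rows = [dict(id=0, species="NA")] + [dict(id=i, species="WATER_O") for i in range(1, 6)]
    center = np.array([20.0, 20.0, 80.0])
    pos = [center] + [center + d for d in 2.6 * np.eye(3)] + [center - 2.6 * np.eye(3)[0], center - 2.6 * np.eye(3)[1]]
    traj = make_traj(rows, np.asarray(pos)[None, :, :])
    st = coordination_state(traj, 0, 0, system)
    assert st.n_protein_o == 0
    assert st.n_water_o == 5
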
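"""Carbonyl-flip classification, d1/d2 distances, H-bonds and contacts."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from permeon.conformation import (
    amide_contact_map,
    classify_flip,
    crystal_reference_direction,
    detect_hbonds,
    distance_timeline,
    flip_timeline,
    opposing_distances,
)
from permeon.synthetic import SynthConfig, gen_sf_scaffold, gen_trajectory


def carbonyl_traj(make_traj, angle_deg, system):
    """Single T62 carbonyl of subunit A rotated by angle about the axis-local
    backbone direction (crystal reference points at the pore axis)."""
    geom = system.channels["lower"]
    ref = crystal_reference_direction(geom, "A")
    c = geom.to_global(np.array(-3.4), 4.2, 0.0)
    # rotate the C=O vector in the plane spanned by ref and the axis
    a = np.deg2rad(angle_deg)
    v = 1.23 * (np.cos(a) * ref + np.sin(a) * geom.axis)
    rows = [
        dict(id=0, species="PROTEIN_ATOM", subunit="A", residue_number=62,
             atom_name="C", channel="lower"),
        dict(id=1, species="PROTEIN_ATOM", subunit="A", residue_number=62,
             atom_name="O", channel="lower"),
    ]
    return make_traj(rows, np.array([c, c + v])[None, :, :])


@pytest.mark.parametrize(
    "angle,label", [(0.0, "crystal"), (180.0, "flipped_T62"), (90.0, "other")]
)
def test_classify_flip_reference_and_flipped(make_traj, system, angle, label):
    traj = carbonyl_traj(make_traj, angle, system)
    got_label, got_angle = classify_flip(
        traj, 0, "A", geometry=system.channels["lower"]
    )
    assert got_label == label
    assert got_angle == pytest.approx(angle, abs=1e-6)


def test_classify_flip_rigid_rotation_invariance(make_traj, system):
    traj = carbonyl_traj(make_traj, 0.0, system)
    theta = np.deg2rad(33.0)
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    geom = system.channels["lower"]
    rotated = traj.positions[0] @ R.T
    traj.positions[0] = rotated
    ref = crystal_reference_direction(geom, "A") @ R.T
    label, angle = classify_flip(traj, 0, "A", reference_direction=ref)
    assert label == "crystal" and abs(angle) < 1e-6


def flip_run(seed=13):
    cfg = SynthConfig(
        seed=seed,
        duration_ns=200.0,
        frame_interval_ps=100.0,
        n_ions={"K": 4},
        n_waters=0,
        hydration_waters=0,
        crossing_rate_inward={},
        crossing_rate_outward={},
        flip_schedule={"A": [(40.0, 120.0)], "C": [(0.0, 60.0)]},
    )
    return gen_trajectory(cfg)


def test_flip_timeline_matches_planted_schedule(system):
    traj, truth = flip_run()
    tl = flip_timeline(traj, system.channels["lower"])
    dt = 100.0
    for su in "ABCD":
        planted = np.zeros(traj.n_frames, dtype=bool)
        for r in truth.flips[truth.flips["subunit"] == su].itertuples():
            planted[int(r.start_ps / dt) : int(r.end_ps / dt) + 1] = True
        got = (tl[f"label_{su}"] == "flipped_T62").to_numpy()
        assert (got == planted).mean() >= 0.99


def test_fourfold_scaffold_pairings_agree(make_traj, system):
    cfg = SynthConfig(
        seed=1, duration_ns=1.0, frame_interval_ps=100.0, n_ions={"K": 2},
        n_waters=0, hydration_waters=0, crossing_rate_inward={},
        crossing_rate_outward={}, jitter_sd=0.0,
    )
    traj, _ = gen_trajectory(cfg)
    d = opposing_distances(traj, 0)
    (ab, cd) = d["d1"][("A", "B")], d["d1"][("C", "D")]
    assert ab == pytest.approx(cd, abs=1e-9)
    # symmetric in pair order
    d_rev = opposing_distances(traj, 0, pairing=(("B", "A"), ("D", "C")))
    assert d_rev["d1"][("B", "A")] == pytest.approx(ab, abs=1e-12)
    assert d["d2"][("A", "B")] > 0


def test_planted_asymmetry_separates_pairing_distributions():
    cfg = SynthConfig(
        seed=8,
        duration_ns=100.0,
        frame_interval_ps=100.0,
        n_ions={"K": 2},
        n_waters=0,
        hydration_waters=0,
        crossing_rate_inward={},
        crossing_rate_outward={},
        flip_schedule={"A": [(0.0, 100.0)]},  # one subunit flipped throughout
    )
    traj, _ = gen_trajectory(cfg)
    dt = distance_timeline(traj)
    assert len(dt) == 1000
    stat = mannwhitneyu(dt["d1_AB"], dt["d1_CD"])
    assert stat.pvalue < 0.01


def chain_bonds(structure, chain="A"):
    return {
        (b.donor_res, b.acceptor_res)
        for b in detect_hbonds(structure)
        if b.chain == chain and b.acceptor_chain == chain
    }


def test_hbond_network_differs_between_conformers():
    cry = chain_bonds(gen_sf_scaffold("crystal"))
    fl = chain_bonds(gen_sf_scaffold("flipped_T62"))
    assert cry - fl == {(63, 60), (64, 59)}  # T63NH-T60CO, V64NH-V59CO
    assert fl - cry == {(64, 62)}  # V64NH-T62CO
    assert (64, 62) not in cry


def test_distant_pair_is_not_a_bond(make_traj):
    fl = gen_sf_scaffold("flipped_T62")
    bonds = detect_hbonds(fl, h_o_max=0.5)
    assert bonds == []


def test_amide_contact_maps():
    vicinal = {(i, i + 1) for i in range(61, 65)}
    cry = {(i, j) for c, i, j in amide_contact_map(gen_sf_scaffold("crystal")) if c == "A"}
    assert vicinal <= cry
    fl = {(i, j) for c, i, j in amide_contact_map(gen_sf_scaffold("flipped_T62")) if c == "A"}
    assert vicinal - fl == {(62, 63)}
    assert amide_contact_map(gen_sf_scaffold("crystal"), cutoff=0.0) == set()
    # monotone in cutoff
    small = amide_contact_map(gen_sf_scaffold("crystal"), cutoff=3.0)
    assert small <= amide_contact_map(gen_sf_scaffold("crystal"), cutoff=4.0)


def test_hydrogens_reconstructed_when_absent():
    import biotite.structure as struc

    from permeon.conformation import _amide_hydrogens

    arr = struc.AtomArray(4)
    coords = {
        (1, "C"): np.array([0.5, -1.2, 0.0]),
        (2, "N"): np.array([0.0, 0.0, 0.0]),
        (2, "CA"): np.array([1.45, 0.0, 0.0]),
        (2, "O"): np.array([9.0, 9.0, 9.0]),
    }
    for k, ((res, name), xyz) in enumerate(coords.items()):
        arr.coord[k] = xyz
        arr.chain_id[k] = "A"
        arr.res_id[k] = res
        arr.res_name[k] = "GLY"
        arr.atom_name[k] = name
        arr.element[k] = name[0]
    h = _amide_hydrogens(arr)[("A", 2)]
    # H sits 1 A from N along the bisector of the N-CA and N-C(prev) bonds
    u = np.array([-1.0, 0.0, 0.0])
    v = -coords[(1, "C")] / np.linalg.norm(coords[(1, "C")])
    d = (u + v) / np.linalg.norm(u + v)
    assert np.linalg.norm(h) == pytest.approx(1.0, abs=1e-6)
    assert np.allclose(h, d, atol=1e-6)
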
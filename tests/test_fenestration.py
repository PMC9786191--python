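"""Fenestration distances, state comparison and lipid-facing census."""

import numpy as np
import pytest

from poremcm.fenestration import (
    CensusParams,
    DistancePair,
    classify_interface,
    compare_states,
    pair_distance,
)
from poremcm.structio import AtomRecord, ChannelStructure, Transform
from poremcm.synthetic import (
    SyntheticChannelSpec,
    make_toy_channel,
    toy_anchor_table,
    toy_resnum,
)


def _two_residue_structure(xyz_a, xyz_b, resnames=("LEU", "LEU")):
    atoms = [
        AtomRecord(1, "CB", "C", resnames[0], 1, "A"),
        AtomRecord(2, "CB", "C", resnames[1], 2, "A"),
    ]
    return ChannelStructure(atoms, np.array([xyz_a, xyz_b], float))


def test_pair_distance_simple():
    st = _two_residue_structure([0, 0, 0], [3, 4, 0])
    assert pair_distance(st, DistancePair(1, 2)) == pytest.approx(5.0)


def test_pair_distance_glycine_uses_ca():
    atoms = [
        AtomRecord(1, "CA", "C", "GLY", 1, "A"),
        AtomRecord(2, "CB", "C", "LEU", 2, "A"),
        AtomRecord(3, "CA", "C", "LEU", 2, "A"),
    ]
    st = ChannelStructure(atoms, np.array([[0, 0, 0], [0, 0, 7.0], [1, 1, 1]], float))
    assert pair_distance(st, DistancePair(1, 2)) == pytest.approx(7.0)


def test_pair_distance_accepts_labels(toy_channel):
    anchors = toy_anchor_table()
    d_label = pair_distance(toy_channel, DistancePair("3i6", "4i9"), anchors)
    d_num = pair_distance(
        toy_channel, DistancePair(toy_resnum(3, "i", 6), toy_resnum(4, "i", 9))
    )
    assert d_label == pytest.approx(d_num)


def test_pair_distance_rigid_invariance(toy_channel, rng):
    from scipy.spatial.transform import Rotation

    pair = DistancePair(toy_resnum(3, "i", 6), toy_resnum(4, "i", 9))
    d0 = pair_distance(toy_channel, pair)
    moved = toy_channel.transformed(
        Transform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3) * 10)
    )
    assert pair_distance(moved, pair) == pytest.approx(d0, abs=1e-9)


def test_pair_distance_brute_force_oracle(toy_channel, rng):
    from poremcm.structio import cbeta_coord

    residues = [r for r in toy_channel.annotations if toy_channel.has_atom(r, "CA")]
    for _ in range(10):
        a, b = rng.choice(residues, 2, replace=False)
        expected = float(
            np.sqrt(((cbeta_coord(toy_channel, a) - cbeta_coord(toy_channel, b)) ** 2).sum())
        )
        assert pair_distance(toy_channel, DistancePair(int(a), int(b))) == pytest.approx(
            expected, abs=1e-9
        )


def test_pair_requires_distinct_members():
    with pytest.raises(ValueError):
        DistancePair(5, 5)


# -- compare_states --------------------------------------------------------


def test_compare_identical_structures(toy_channel):
    pairs = [DistancePair(toy_resnum(r, "i", 6), toy_resnum(r % 4 + 1, "i", 9)) for r in (1, 2, 3)]
    table = compare_states(toy_channel, toy_channel, pairs)
    assert np.allclose(table["delta"], 0.0)


def test_compare_planted_widths():
    wide = make_toy_channel(SyntheticChannelSpec(fenestration_width=12.0))
    narrow = make_toy_channel(SyntheticChannelSpec(fenestration_width=10.0))
    pair = DistancePair(toy_resnum(3, "i", 6), toy_resnum(4, "i", 9), "III/IV")
    table = compare_states(wide, narrow, [pair])
    assert table.loc[0, "delta"] == pytest.approx(2.0, abs=0.1)


def test_compare_antisymmetric():
    a = make_toy_channel(SyntheticChannelSpec(fenestration_width=12.0))
    b = make_toy_channel(SyntheticChannelSpec(fenestration_width=9.0))
    pair = DistancePair(toy_resnum(3, "i", 6), toy_resnum(4, "i", 9))
    t_ab = compare_states(a, b, [pair])
    t_ba = compare_states(b, a, [pair])
    assert t_ab.loc[0, "delta"] == pytest.approx(-t_ba.loc[0, "delta"])


def test_compare_missing_pair_flagged(toy_channel):
    table = compare_states(
        toy_channel, toy_channel, [DistancePair(99999, 99998)]
    )
    assert table.loc[0, "flag"] != ""
    assert np.isnan(table.loc[0, "delta"])


# -- census ----------------------------------------------------------------


def test_census_counts_planted(toy_channel):
    for iface in ("I/II", "II/III", "III/IV", "IV/I"):
        census = classify_interface(toy_channel, iface)
        assert census.counts == (3, 2)


def test_census_counts_follow_spec():
    ch = make_toy_channel(SyntheticChannelSpec(interface_aromatics=4, interface_polars=3))
    assert classify_interface(ch, "III/IV").counts == (4, 3)


def test_census_empty_when_nothing_planted():
    ch = make_toy_channel(SyntheticChannelSpec(interface_aromatics=0, interface_polars=0))
    census = classify_interface(ch, (2, 3))
    assert census.counts == (0, 0)


def test_census_monotone_in_facing_angle(toy_channel):
    counts = []
    for angle in (80.0, 60.0, 40.0, 20.0, 5.0):
        census = classify_interface(
            toy_channel, "III/IV", CensusParams(facing_angle_deg=angle)
        )
        counts.append(sum(census.counts))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_census_deterministic(toy_channel):
    a = classify_interface(toy_channel, "III/IV")
    b = classify_interface(toy_channel, "III/IV")
    assert (a.aromatic, a.polar) == (b.aromatic, b.polar)


def test_census_rejects_nonadjacent_interface(toy_channel):
    with pytest.raises(ValueError):
        classify_interface(toy_channel, (1, 3))


def test_census_special_attractors():
    """A planted glycine backbone O / proline N / cysteine S on the
    interface is reported as a special attractor atom."""
    ch = make_toy_channel()
    # graft a lipid-facing GLY with a backbone O and a CYS with SG onto the
    # III/IV interface side of the structure
    atoms = list(ch.atoms)
    coords = [ch.coords]
    phi = np.deg2rad(225.0)
    base = np.array([11.0 * np.cos(phi), 11.0 * np.sin(phi), -6.0])
    serial = max(a.serial for a in atoms)
    extra = [
        ("GLY", "CA", base),
        ("GLY", "O", base + [0.3, 0.3, 1.0]),
        ("CYS", "CA", base + [2.0, 0.0, 3.0]),
        ("CYS", "SG", base + [2.3, 0.3, 4.2]),
    ]
    annotations = dict(ch.annotations)
    resnum = 8000
    for resname, name, pos in extra:
        if name == "CA":
            resnum += 1
            annotations[resnum] = (3, "i") if resname == "GLY" else (4, "i")
        serial += 1
        atoms.append(AtomRecord(serial, name, name[0], resname, resnum, "C"))
        coords.append(np.asarray(pos, float)[None, :])
    st = ChannelStructure(atoms, np.vstack(coords), annotations, ch.pore_axis)
    census = classify_interface(st, "III/IV")
    kinds = {(resname, atom) for _, resname, atom in census.special}
    assert ("GLY", "O") in kinds
    assert ("CYS", "SG") in kinds
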
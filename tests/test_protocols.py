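"""Deactivation and egress protocols: schedule arithmetic, enforcement,
chaining, profile analysis."""

import numpy as np
import pytest

from poremcm.fenestration import DistancePair, pair_distance
from poremcm.mcm import MCMConfig, SimulationSystem
from poremcm.protocols import (
    DeactivationSchedule,
    EgressSchedule,
    ProfileAnalysis,
    analyze_profile,
    deactivate_vsd,
    egress_barrier,
    egress_profile,
    path_barrier,
    tb_start_state,
)
from poremcm.synthetic import SyntheticChannelSpec, make_toy_channel, make_toy_ligand, toy_resnum

FAST = MCMConfig(max_minimizer_iter=60)


FAST_DEACT = MCMConfig(max_minimizer_iter=120, max_steps=4)


def fast_deact(repeat=3, n_steps=7, step_dz=1.5, patience=2, seed=0):
    """Desk-scale pulling schedule: same 10.5 A total displacement as the
    production default, coarser steps."""
    return DeactivationSchedule(
        repeat=repeat, n_steps=n_steps, step_dz=step_dz, patience=patience, seed=seed
    )


# -- schedule arithmetic ----------------------------------------------------


def test_default_deactivation_commands_10p5_angstrom():
    assert DeactivationSchedule(repeat=3).total_displacement == pytest.approx(10.5)


def test_default_egress_commands_32_angstrom():
    assert EgressSchedule().total_displacement == pytest.approx(32.0)


def test_schedule_validation():
    with pytest.raises(ValueError):
        DeactivationSchedule(repeat=3, n_steps=0)
    with pytest.raises(ValueError):
        EgressSchedule(step_dr=0)


# -- deactivation -----------------------------------------------------------


@pytest.fixture(scope="module")
def deactivated():
    ch = make_toy_channel()
    traj = deactivate_vsd(ch, fast_deact(), FAST_DEACT)
    return ch, traj


def test_deactivation_one_structure_per_step(deactivated):
    _, traj = deactivated
    assert len(traj) == 7


def test_pulled_atoms_reach_commanded_planes(deactivated):
    ch, traj = deactivated
    final = traj[-1]
    for n in range(1, 6):
        resnum = toy_resnum(3, "s4", n)
        z0 = ch.coords[ch.atom_index(resnum, "CA")][2]
        z1 = final.coords[final.atom_index(resnum, "CA")][2]
        assert z1 == pytest.approx(z0 - 10.5, abs=0.05)


def test_pinned_atoms_stay_near_templates(deactivated):
    ch, traj = deactivated
    final = traj[-1]
    pulled = {toy_resnum(3, "s4", n) for n in range(1, 6)}
    drift = np.linalg.norm(final.coords - ch.coords, axis=1)
    for i, a in enumerate(ch.atoms):
        if a.name == "CA" and a.resnum not in pulled:
            # flat bottom 1 A + elastic slack under the pull
            assert drift[i] < 4.0


def test_single_step_trajectory():
    ch = make_toy_channel()
    traj = deactivate_vsd(ch, fast_deact(n_steps=1, step_dz=0.5), FAST_DEACT)
    assert len(traj) == 1
    resnum = toy_resnum(3, "s4", 1)
    z0 = ch.coords[ch.atom_index(resnum, "CA")][2]
    z1 = traj[0].coords[traj[0].atom_index(resnum, "CA")][2]
    assert z1 == pytest.approx(z0 - 0.5, abs=0.05)


def test_missing_pulled_residue_errors():
    ch = make_toy_channel()
    schedule = DeactivationSchedule(repeat=3, pulled_residues=[99999])
    with pytest.raises(KeyError):
        deactivate_vsd(ch, schedule, FAST)


def test_deactivation_narrows_own_interface(deactivated):
    """Pulling down S4 of repeat III narrows the III/IV fenestration
    (the linker drags the neighbouring S6 inward)."""
    ch, traj = deactivated
    pair = DistancePair(toy_resnum(3, "i", 6), toy_resnum(4, "i", 9))
    before = pair_distance(ch, pair)
    after = pair_distance(traj[-1], pair)
    assert after < before


def test_deactivation_locality(deactivated):
    """The interface opposite the pulled sensor moves far less than the
    sensor's own neighbourhood."""
    ch, traj = deactivated
    far_pair = DistancePair(toy_resnum(1, "i", 6), toy_resnum(2, "i", 9))
    before = pair_distance(ch, far_pair)
    after = pair_distance(traj[-1], far_pair)
    assert abs(after - before) < 0.5


# -- egress -----------------------------------------------------------------


@pytest.fixture(scope="module")
def short_egress():
    ch = make_toy_channel()
    lig = make_toy_ligand()
    tb = tb_start_state(ch, lig, mcm_config=FAST)
    schedule = EgressSchedule(n_steps=12, step_dr=0.4, patience=4, seed=5)
    return egress_profile(ch, lig, tb, schedule, mcm_config=FAST)


def test_egress_zero_steps_returns_start_only():
    ch = make_toy_channel()
    lig = make_toy_ligand()
    tb = tb_start_state(ch, lig, mcm_config=FAST)
    prof = egress_profile(ch, lig, tb, EgressSchedule(n_steps=0), mcm_config=FAST)
    assert len(prof.steps) == 1


def test_egress_radii_progress_outward(short_egress):
    r = short_egress.radii()
    assert r[-1] > r[0] + 3.0
    # achieved radii track the commanded ladder within the relaxation slack
    targets = np.array([s["target_radius"] for s in short_egress.steps])
    assert np.all(np.abs(r - targets) < 1.2)


def test_egress_records_contacts(short_egress):
    assert all("contacts" in s for s in short_egress.steps)
    assert short_egress.steps[0]["contacts"], "bound pose should touch residues"


def test_egress_matches_brute_force_on_analytic_landscape():
    """With a rigid channel reduced to a single radial attractor, the
    recorded profile must match a dense brute-force scan of the same
    landscape."""
    from poremcm.energy import NonbondedModel, EnergyParams, Topology, COULOMB
    from poremcm.structio import AtomRecord, ChannelStructure
    from poremcm.ligand import LigandAtom, LigandModel, LigandPose

    # channel: one negative bead on the x axis; ligand: a single cation,
    # which is also its own para-carbon
    ch = ChannelStructure(
        [AtomRecord(1, "CA", "C", "ATT", 1, "A")], np.array([[6.0, 0.0, 0.0]])
    )
    ch.topology = Topology(["O"], np.array([-0.5]), np.array([False]), np.empty((0, 4)))
    lig = LigandModel(
        [LigandAtom("N1", "N+", "N", charge=1.0, ionized=True)],
        np.zeros((1, 3)),
        anchors={"ammonium": 0, "para_carbon": 0},
    )
    start = (LigandPose(np.array([1.0, 0.0, 0.0])), np.zeros(0))
    schedule = EgressSchedule(n_steps=20, step_dr=0.4, patience=3, seed=1, two_stage=False)
    prof = egress_profile(ch, lig, start, schedule, mcm_config=FAST)
    from poremcm.energy import pair_elec, pair_vdw

    params = EnergyParams()
    for step in prof.steps:
        rho = step["achieved_radius"]
        # brute-force scan over the circle the constraint allows (any
        # azimuth at radius rho, z free but optimal at 0): dense grid of
        # the ion-attractor distance, full pair energy
        angles = np.linspace(0, 2 * np.pi, 4000)
        d = np.sqrt((rho * np.cos(angles) - 6.0) ** 2 + (rho * np.sin(angles)) ** 2)
        d = np.maximum(d, 0.5)
        e = np.array(
            [
                pair_elec(1.0, -0.5, float(x), params, ionized=True)
                + pair_vdw(float(x), "N+", "O", params)
                for x in d
            ]
        )
        assert step["interaction_energy"] == pytest.approx(float(e.min()), abs=0.1)


def test_egress_escape_truncation():
    """A start far outside everything escapes immediately once the target
    ladder exceeds the escape factor."""
    ch = make_toy_channel()
    lig = make_toy_ligand()
    from poremcm.ligand import LigandPose

    start = (LigandPose(np.array([40.0, 0.0, 0.0])), np.zeros(len(lig.torsions)))
    schedule = EgressSchedule(n_steps=4, step_dr=0.4, patience=2, escape_factor=0.2, seed=0)
    with pytest.warns(UserWarning):
        prof = egress_profile(ch, lig, start, schedule, mcm_config=FAST)
    assert prof.truncated


# -- profile analysis -------------------------------------------------------


def test_analyze_constructed_profile():
    analysis = analyze_profile(np.array([0.0, 3.0, -2.0, 4.0, 1.0]))
    assert analysis.minima == [2]
    assert path_barrier([0.0, 3.0, -2.0, 4.0, 1.0], 2, 4) == pytest.approx(6.0)
    assert analysis.start_energy == 0.0 and analysis.end_energy == 1.0


def test_analyze_monotone_profile_has_no_interior_minima():
    analysis = analyze_profile(np.linspace(-5, 5, 20))
    assert analysis.minima == []


def test_analyze_plateau_tiebreak():
    e = np.array([5.0, 1.0, 1.0, 1.0, 6.0, 2.0])
    analysis = analyze_profile(e)
    assert analysis.minima == [1]  # first step of the plateau


def test_analyze_requires_two_steps():
    with pytest.raises(ValueError):
        analyze_profile(np.array([1.0]))


def test_egress_barrier_simple_cases():
    # monotone rise out of the well: barrier equals total rise
    e = np.array([-10.0, -8.0, -6.0, -4.0])
    assert egress_barrier(e) == pytest.approx(6.0)
    # bump then interim minimum: barrier measured to the bump top
    e = np.array([-10.0, -4.0, -8.0, -2.0])
    assert egress_barrier(e, interim_separation=1.0) == pytest.approx(6.0)
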
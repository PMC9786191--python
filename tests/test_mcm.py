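"""MCM engine: perturbation determinism, minimizer descent, termination,
pose-stack clustering invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poremcm.energy import Topology
from poremcm.ligand import LigandPose
from poremcm.mcm import (
    MCMConfig,
    PoseStack,
    SimulationSystem,
    StackRecord,
    mcm_run,
    minimize_state,
    perturb,
    stack_update,
)
from poremcm.restraints import PinRestraint
from poremcm.structio import AtomRecord, ChannelStructure


def bead_system(n=1, coords=None, pins=()):
    atoms = [AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A") for i in range(n)]
    coords = np.zeros((n, 3)) if coords is None else np.asarray(coords, float)
    st_ = ChannelStructure(atoms, coords)
    topo = Topology(["BB"] * n, np.zeros(n), np.zeros(n, bool), np.empty((0, 4)))
    return SimulationSystem(st_, topo, restraints=list(pins), mobile_atoms=range(n))


def ligand_system(toy_channel, mex):
    return SimulationSystem(toy_channel, toy_channel.topology, mex)


# -- perturb ---------------------------------------------------------------


def test_perturb_deterministic(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    state = system.initial_state(LigandPose(np.array([0, 0, -6.0])))
    cfg = MCMConfig()
    c1 = perturb(state, system, cfg, np.random.default_rng(77))
    c2 = perturb(state, system, cfg, np.random.default_rng(77))
    np.testing.assert_array_equal(c1.pose.translation, c2.pose.translation)
    np.testing.assert_array_equal(c1.pose.quaternion, c2.pose.quaternion)
    np.testing.assert_array_equal(c1.ligand_torsions, c2.ligand_torsions)


def test_perturb_zero_amplitude_is_identity(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    state = system.initial_state(LigandPose(np.array([0, 0, -6.0])))
    cfg = MCMConfig(
        translation_amplitude=0.0,
        rotation_amplitude=0.0,
        torsion_amplitude=0.0,
        cartesian_amplitude=0.0,
    )
    cand = perturb(state, system, cfg, np.random.default_rng(1))
    np.testing.assert_allclose(cand.pose.translation, state.pose.translation)
    np.testing.assert_allclose(cand.pose.quaternion, state.pose.quaternion)


def test_perturb_spans_translation_amplitude(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    state = system.initial_state(LigandPose(np.array([0, 0, -6.0])))
    cfg = MCMConfig(translation_amplitude=1.0)
    rng = np.random.default_rng(5)
    steps = [
        np.linalg.norm(
            perturb(state, system, cfg, rng).pose.translation - state.pose.translation
        )
        for _ in range(300)
    ]
    assert max(steps) > 0.9  # the configured amplitude is actually explored
    assert min(steps) < 0.2


# -- minimization ----------------------------------------------------------


def test_minimize_quadratic_recovers_optimum():
    """Single bead in a pure harmonic (pin with zero flat bottom): the
    minimizer must land on the analytic optimum."""
    pin = PinRestraint(0, np.array([2.0, -1.0, 3.0]), free_radius=0.0, force_constant=5.0)
    system = bead_system(coords=[[8.0, 4.0, -2.0]], pins=[pin])
    state = system.initial_state()
    out = minimize_state(state, system, MCMConfig(max_minimizer_iter=200))
    np.testing.assert_allclose(out.channel_coords[0], pin.template, atol=1e-4)


def test_minimize_descent_property(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    rng = np.random.default_rng(0)
    cfg = MCMConfig(max_minimizer_iter=40)
    for _ in range(20):
        pose = LigandPose(rng.uniform(-4, 4, 3) + [0, 0, -5.0])
        state = system.initial_state(pose, rng.uniform(-np.pi, np.pi, len(mex.torsions)))
        if not np.isfinite(state.energy):
            continue
        out = minimize_state(state, system, cfg)
        assert out.energy <= state.energy + 1e-9


def test_minimize_already_at_minimum_stays():
    pin = PinRestraint(0, np.zeros(3), free_radius=0.0, force_constant=5.0)
    system = bead_system(coords=[[0.0, 0.0, 0.0]], pins=[pin])
    state = system.initial_state()
    out = minimize_state(state, system, MCMConfig())
    np.testing.assert_allclose(out.channel_coords[0], np.zeros(3), atol=1e-6)


# -- full runs -------------------------------------------------------------


def test_patience_one_flat_landscape_terminates_immediately():
    system = bead_system()  # no forces at all: perfectly flat
    state = system.initial_state()
    _, traj, _ = mcm_run(state, system, MCMConfig(patience=1, seed=0))
    assert len(traj.steps) == 1


def test_best_energy_monotone_nonincreasing(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    state = system.initial_state(LigandPose(np.array([0, 0, -6.0])))
    _, traj, _ = mcm_run(
        state, system, MCMConfig(patience=15, seed=4, max_minimizer_iter=40)
    )
    best = traj.best_energies()
    assert np.all(np.diff(best) <= 1e-9)


def test_full_run_determinism(toy_channel, mex):
    system = ligand_system(toy_channel, mex)
    cfg = MCMConfig(patience=8, seed=123, max_minimizer_iter=40)
    outs = []
    for _ in range(2):
        state = system.initial_state(LigandPose(np.array([0, 0, -6.0])))
        best, traj, _ = mcm_run(state, system, cfg)
        outs.append((best.energy, tuple(s["candidate_energy"] for s in traj.steps)))
    assert outs[0] == outs[1]


def test_double_well_finds_global_minimum():
    """Two pinned wells of different depths; MCM must find the deeper one
    (the landscape is enumerable: the global optimum is the deep well's
    centre)."""
    deep = PinRestraint(0, np.array([3.0, 0.0, 0.0]), free_radius=0.0, force_constant=1.0)
    found = 0
    for seed in range(10):
        system = bead_system(coords=[[-3.0, 0.0, 0.0]])

        def wells_energy(coords, axis=None, _deep=deep):
            # double well along x: f(x) = min(k(x+3)^2 + 2, k(x-3)^2)
            x = coords[0]
            e1 = 1.0 * ((x[0] + 3.0) ** 2 + x[1] ** 2 + x[2] ** 2) + 2.0
            e2 = 1.0 * ((x[0] - 3.0) ** 2 + x[1] ** 2 + x[2] ** 2)
            if e1 < e2:
                g = {0: np.array([2.0 * (x[0] + 3.0), 2 * x[1], 2 * x[2]])}
                return e1, g
            g = {0: np.array([2.0 * (x[0] - 3.0), 2 * x[1], 2 * x[2]])}
            return e2, g

        system.restraints = [type("W", (), {"energy_and_gradient": staticmethod(wells_energy)})]
        state = system.initial_state()
        best, _, _ = mcm_run(
            state,
            system,
            MCMConfig(patience=40, seed=seed, cartesian_amplitude=2.5,
                      per_variable_probability=1.0),
        )
        if abs(best.channel_coords[0, 0] - 3.0) < 0.1:
            found += 1
    assert found >= 9


# -- pose stack ------------------------------------------------------------


def rec(energy, xyz):
    return StackRecord(energy=energy, ligand_coords=np.asarray(xyz, float).reshape(-1, 3))


def test_stack_merges_identical_pose():
    stack = PoseStack()
    stack_update(stack, rec(0.0, [[0, 0, 0]]))
    stack_update(stack, rec(1.0, [[0.1, 0, 0]]))  # same cluster, worse energy
    assert len(stack) == 1
    assert stack.best.energy == 0.0


def test_stack_rejects_above_window():
    stack = PoseStack(window=7.0)
    stack_update(stack, rec(0.0, [[0, 0, 0]]))
    stack_update(stack, rec(8.0, [[30, 0, 0]]))
    assert len(stack) == 1


def test_new_best_reprunes_window():
    stack = PoseStack(window=7.0)
    stack_update(stack, rec(0.0, [[0, 0, 0]]))
    stack_update(stack, rec(5.0, [[30, 0, 0]]))
    assert len(stack) == 2
    stack_update(stack, rec(-10.0, [[60, 0, 0]]))
    assert len(stack) == 1
    assert stack.best.energy == -10.0


def test_stack_capacity_evicts_worst():
    stack = PoseStack(window=100.0, capacity=5, rmsd_threshold=0.5)
    for k in range(12):
        stack_update(stack, rec(float(k), [[10.0 * k, 0, 0]]))
    assert len(stack) == 5
    assert stack.energies().max() == 4.0


@settings(max_examples=40, deadline=None)
@given(
    energies=st.lists(st.floats(-20, 20), min_size=1, max_size=40),
    seed=st.integers(0, 1000),
)
def test_stack_invariants_random_streams(energies, seed):
    """Window, capacity and pairwise-dissimilarity invariants hold after
    every update of a random record stream."""
    rng = np.random.default_rng(seed)
    stack = PoseStack(window=7.0, capacity=10, rmsd_threshold=1.5)
    for e in energies:
        xyz = rng.uniform(-8, 8, size=(3, 3))
        stack_update(stack, rec(e, xyz))
        es = stack.energies()
        assert len(stack) <= 10
        assert es.max() - es.min() <= 7.0 + 1e-12
        for i in range(len(stack)):
            for j in range(i + 1, len(stack)):
                d = np.sqrt(np.mean(np.sum(
                    (stack.records[i].ligand_coords - stack.records[j].ligand_coords) ** 2,
                    axis=1)))
                assert d >= 1.5 - 1e-12


def test_stack_rejects_nonfinite():
    stack = PoseStack()
    with pytest.raises(ValueError):
        stack_update(stack, rec(np.nan, [[0, 0, 0]]))
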
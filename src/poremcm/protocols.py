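"""Stateful modelling protocols: in-silico voltage-sensor deactivation and
ligand egress profiling.

**Deactivation** pulls the Calpha atoms of the five S4 gating-charge
positions of one repeat down the pore axis through successive sets of planes
(default 21 steps of 0.5 A — a 10.5 A total downshift, matching the S4
displacement between up and down sensor conformations).  Within each step
the pulled atoms may move freely in their planes but not leave them, all
other Calpha atoms are pinned (flat-bottom, penalty-free within 1 A of the
starting structure), and the energy is MC-minimized until a patience of
consecutive non-improving minimizations is reached; each step starts from
the previous step's minimized structure.

**Egress** pulls a bound ligand out of the pore through a fenestration by
stepping the constrained distance between the ligand's para-carbon and the
pore axis (default 80 steps of 0.4 A = 32 A).  Each step runs two MCM
stages: first with the channel backbone fixed and the radius constrained,
then fully unconstrained; the recorded point is the relaxed structure, and
the next step starts from it.  The resulting profile of ligand-channel
interaction energy against radius is analyzed for interior minima (interim
binding sites) and the barriers separating them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import Topology, default_channel_topology
from .ligand import LigandModel, LigandPose
from .mcm import MCMConfig, MCMState, SimulationSystem, mcm_run
from .restraints import AxialDistanceRestraint, PinRestraint, PlaneRestraint
from .structio import ChannelStructure

__all__ = [
    "DeactivationSchedule",
    "EgressSchedule",
    "EgressProfile",
    "ProfileAnalysis",
    "deactivate_vsd",
    "egress_profile",
    "analyze_profile",
    "egress_barrier",
    "build_state_models",
]


@dataclass
class DeactivationSchedule:
    """S4 pulling schedule for one repeat.

    ``pulled_residues`` are the residue numbers of the 5 gating-charge
    positions; if omitted, the toy-channel S4-stub convention is used.
    Total commanded displacement is ``n_steps * step_dz`` (10.5 A with the
    defaults).
    """

    repeat: int
    pulled_residues: list[int] | None = None
    n_steps: int = 21
    step_dz: float = 0.5
    patience: int = 200
    pin_free_radius: float = 1.0
    pin_force_constant: float = 10.0
    mobile_radius: float = 12.0
    mobile_hops: int = 16  # bonded-graph reach of the drag chain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.step_dz <= 0:
            raise ValueError("n_steps >= 1 and step_dz > 0 required")

    @property
    def total_displacement(self) -> float:
        return self.n_steps * self.step_dz

    def resolve_pulled(self, structure: ChannelStructure) -> list[int]:
        if self.pulled_residues is not None:
            return list(self.pulled_residues)
        from .synthetic import toy_resnum

        residues = [toy_resnum(self.repeat, "s4", n) for n in range(1, 6)]
        missing = [r for r in residues if not structure.has_atom(r, "CA")]
        if missing:
            raise ValueError(
                f"S4 gating-charge residues {missing} not found; supply "
                "pulled_residues explicitly"
            )
        return residues


def _mobile_set(
    structure: ChannelStructure,
    topology: Topology,
    pulled_idx: list[int],
    total_dz: float,
    radius: float,
    hops: int = 16,
) -> np.ndarray:
    """Atoms free to move: anything within ``radius`` of the commanded path
    of a pulled atom, plus everything within ``hops`` bonds of the pulled
    atoms (the drag chain: S4 -> linker -> contacted helices), plus the
    bond partners of all of those."""
    u = structure.pore_axis[1]
    path_pts = []
    for i in pulled_idx:
        p0 = structure.coords[i]
        for f in np.linspace(0.0, 1.0, 6):
            path_pts.append(p0 - u * total_dz * f)
    path = np.array(path_pts)
    d = np.linalg.norm(structure.coords[:, None, :] - path[None, :, :], axis=-1)
    mobile = set(np.nonzero(d.min(axis=1) <= radius)[0].tolist())
    mobile.update(pulled_idx)
    adj: dict[int, set[int]] = {}
    for i, j, _, _ in topology.bonds:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    frontier = set(pulled_idx)
    seen = set(pulled_idx)
    for _ in range(hops):
        frontier = set().union(*(adj.get(i, set()) for i in frontier)) - seen
        if not frontier:
            break
        seen |= frontier
    mobile |= seen
    for i in list(mobile):
        mobile.update(adj.get(i, ()))
    return np.asarray(sorted(mobile), int)


def deactivate_vsd(
    structure: ChannelStructure,
    schedule: DeactivationSchedule,
    mcm_config: MCMConfig | None = None,
) -> list[ChannelStructure]:
    """Stepwise S4 downshift; returns one MC-minimized structure per step
    (step k chained from step k-1)."""
    pulled_res = schedule.resolve_pulled(structure)
    pulled_idx = [structure.atom_index(r, "CA") for r in pulled_res]
    topo = getattr(structure, "topology", None) or default_channel_topology(structure)
    u = structure.pore_axis[1]
    p0 = structure.pore_axis[0]
    z0 = {i: float((structure.coords[i] - p0) @ u) for i in pulled_idx}
    templates = structure.coords.copy()
    mobile = _mobile_set(
        structure, topo, pulled_idx, schedule.total_displacement,
        schedule.mobile_radius, schedule.mobile_hops,
    )
    base_cfg = mcm_config or MCMConfig()
    rng = np.random.default_rng(schedule.seed)
    trajectory: list[ChannelStructure] = []
    current = structure
    for step in range(1, schedule.n_steps + 1):
        planes = [
            PlaneRestraint(i, z0[i] - step * schedule.step_dz) for i in pulled_idx
        ]
        pins = [
            PinRestraint(
                int(i),
                templates[int(i)],
                schedule.pin_free_radius,
                schedule.pin_force_constant,
            )
            for i in mobile
            if int(i) not in pulled_idx and structure.atoms[int(i)].name == "CA"
        ]
        cfg = MCMConfig(
            patience=schedule.patience,
            kT=base_cfg.kT,
            cartesian_amplitude=base_cfg.cartesian_amplitude,
            per_variable_probability=base_cfg.per_variable_probability,
            max_minimizer_iter=base_cfg.max_minimizer_iter,
            max_steps=base_cfg.max_steps,
        )
        system = SimulationSystem(
            current, topo, restraints=planes + pins, mobile_atoms=mobile
        )
        state = system.initial_state()
        best, _, _ = mcm_run(state, system, cfg, rng=rng)
        system.project_constraints(best)
        snapshot = current.copy()
        snapshot.coords = best.channel_coords.copy()
        snapshot.name = f"{structure.name}-deact{schedule.repeat}-step{step}"
        trajectory.append(snapshot)
        current = snapshot
    return trajectory


def build_state_models(
    structure: ChannelStructure,
    which: set[int],
    schedules: dict[int, DeactivationSchedule] | None = None,
    mcm_config: MCMConfig | None = None,
) -> ChannelStructure:
    """Deactivate the voltage sensors of the listed repeats sequentially
    (order I, II, III, IV) and return the final minimized structure.

    ``which = {1,2,3,4}`` yields a resting-sensor (RRRR-like) model;
    ``which = {1,2,4}`` leaves repeat III activated (RRAR-like)."""
    current = structure
    for repeat in sorted(which):
        schedule = (schedules or {}).get(repeat) or DeactivationSchedule(repeat=repeat)
        if schedule.repeat != repeat:
            raise ValueError("schedule repeat mismatch")
        traj = deactivate_vsd(current, schedule, mcm_config)
        current = traj[-1]
    return current


def tb_start_state(
    structure: ChannelStructure,
    ligand: LigandModel,
    interface=(3, 4),
    para_radius: float = 6.0,
    patience: int = 30,
    seed: int = 0,
    mcm_config: MCMConfig | None = None,
):
    """Construct a tonic-block-like bound state: ammonium head at the
    outer-pore carbonyl site, aromatic ring reaching into the given
    interface's fenestration.

    The ligand is placed by geometry (head on the axis at the attractor-ring
    height, para-carbon toward the interface), then relaxed by a short MCM
    with the para-carbon held at ``para_radius``; the restraint is removed
    before returning.  Use the result (an :class:`~poremcm.mcm.MCMState`)
    as the egress starting point, or replace it with a docked pose.
    """
    from scipy.spatial.transform import Rotation

    from .fenestration import _parse_interface

    r1, r2 = _parse_interface(interface)
    topo = getattr(structure, "topology", None) or default_channel_topology(structure)
    system = SimulationSystem(structure, topo, ligand)
    # head near the cation-attractive site under the filter, long axis
    # threaded through the fenestration window centre
    charged = np.nonzero(topo.charge[: system.n_channel] < 0)[0]
    z_site = float(structure.coords[charged, 2].mean()) if len(charged) else 3.0
    phi = np.deg2rad(90.0 * (r1 - 1) + 45.0)
    n_pos = np.array([1.5 * np.cos(phi), 1.5 * np.sin(phi), z_site - 0.5])
    window = np.array(
        [para_radius * np.cos(phi), para_radius * np.sin(phi), 0.25]
    )
    direction = window - n_pos
    direction /= np.linalg.norm(direction)
    rot, _ = Rotation.align_vectors(direction[None, :], np.array([[1.0, 0.0, 0.0]]))
    pose = LigandPose(n_pos, rot.as_quat())
    state = system.initial_state(pose, np.zeros(len(ligand.torsions)))
    para = system.n_channel + ligand.anchor_index("para_carbon")
    system.restraints = [AxialDistanceRestraint(para, para_radius)]
    system.project_constraints(state)
    system.evaluate(state)
    from .mcm import minimize_state

    cfg = mcm_config or MCMConfig()
    # trust-bounded relaxations only: the tonic-block pose is metastable
    # (the vertical inner-pore pose is a deeper competing basin) and must
    # not wander out of its window basin while it relaxes
    relax = MCMConfig(
        patience=1,
        max_minimizer_iter=cfg.max_minimizer_iter,
        minimizer_bound=0.3,
    )
    best = state
    for _ in range(max(2, min(patience, 6))):
        system.project_constraints(best)
        system.evaluate(best)
        best = minimize_state(best, system, relax)
    system.restraints = []
    system.evaluate(best)
    best = minimize_state(best, system, relax)
    return best


# ---------------------------------------------------------------------------
# egress

@dataclass
class EgressSchedule:
    """Radial pulling schedule for the ligand para-carbon.

    With the defaults the para-carbon is stepped 80 x 0.4 A = 32 A away
    from the pore axis.  Each step runs a constrained MCM (stage 1, channel
    backbone fixed) followed by an unconstrained one (stage 2) when
    ``two_stage`` is set.
    """

    n_steps: int = 80
    step_dr: float = 0.4
    patience: int = 100
    two_stage: bool = True
    relax_bound: float = 0.3  # trust bound (A/rad) of the stage-2 relaxation
    contact_cutoff: float = 4.0
    escape_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 0 or self.step_dr <= 0:
            raise ValueError("n_steps >= 0 and step_dr > 0 required")

    @property
    def total_displacement(self) -> float:
        return self.n_steps * self.step_dr


@dataclass
class EgressProfile:
    """Per-step record of an egress scan, ordered by target radius."""

    steps: list[dict] = field(default_factory=list)
    truncated: bool = False  # early exit: ligand escaped mid-scan

    def energies(self) -> np.ndarray:
        return np.array([s["interaction_energy"] for s in self.steps])

    def radii(self) -> np.ndarray:
        return np.array([s["achieved_radius"] for s in self.steps])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def egress_profile(
    structure: ChannelStructure,
    ligand: LigandModel,
    start: MCMState | tuple[LigandPose, np.ndarray],
    schedule: EgressSchedule | None = None,
    mcm_config: MCMConfig | None = None,
) -> EgressProfile:
    """Pull the ligand para-carbon radially outward and record the
    MC-minimized interaction-energy profile.

    ``start`` is the bound state (e.g. the tonic-block pose from docking):
    an :class:`~poremcm.mcm.MCMState` or a (pose, torsion_angles) pair.
    The recorded radius of each step is the achieved one after the final
    (unconstrained) stage, and the next step starts from that state.
    """
    schedule = schedule or EgressSchedule()
    cfg = mcm_config or MCMConfig(patience=schedule.patience)
    topo = getattr(structure, "topology", None) or default_channel_topology(structure)
    system = SimulationSystem(structure, topo, ligand)
    para_local = ligand.anchor_index("para_carbon")
    para_global = system.n_channel + para_local
    axis = structure.pore_axis

    if isinstance(start, MCMState):
        state = start.copy()
        system.evaluate(state)
    else:
        pose, torsions = start
        state = system.initial_state(pose, torsions)

    def record(step: int, target: float, st: MCMState) -> dict:
        from .docking import contact_residues

        lig_xyz = system.ligand_coords(st)
        rho = AxialDistanceRestraint(para_local, max(target, 0.0)).radius(lig_xyz, axis)
        return {
            "step": step,
            "target_radius": target,
            "achieved_radius": rho,
            "interaction_energy": system.interaction_energy(st),
            "total_energy": st.energy,
            "contacts": contact_residues(structure, lig_xyz, schedule.contact_cutoff),
        }

    rho0 = AxialDistanceRestraint(para_local, 0.0).radius(
        system.ligand_coords(state), axis
    )
    profile = EgressProfile(steps=[record(0, rho0, state)])
    if schedule.n_steps == 0:
        return profile
    final_radius = rho0 + schedule.total_displacement
    # quasi-static scan: per-step moves stay small compared to the step
    # size so the chained states trace one continuous path
    stage_cfg = MCMConfig(
        patience=schedule.patience,
        kT=cfg.kT,
        torsion_amplitude=0.6,
        translation_amplitude=0.4,
        rotation_amplitude=0.3,
        per_variable_probability=cfg.per_variable_probability,
        max_minimizer_iter=cfg.max_minimizer_iter,
        minimizer_bound=0.8,
    )
    relax_cfg = MCMConfig(
        patience=1,
        kT=cfg.kT,
        max_minimizer_iter=cfg.max_minimizer_iter,
        minimizer_bound=schedule.relax_bound,
    )
    rng = np.random.default_rng(schedule.seed)
    for step in range(1, schedule.n_steps + 1):
        target = rho0 + step * schedule.step_dr  # commanded ladder
        # stage 1: radius constrained (backbone is rigid in this system)
        system.restraints = [AxialDistanceRestraint(para_global, target)]
        system.project_constraints(state)
        system.evaluate(state)
        state, _, _ = mcm_run(state, system, stage_cfg, rng=rng)
        system.project_constraints(state)
        system.evaluate(state)
        if schedule.two_stage:
            # stage 2: constraint removed; a trust-bounded local relaxation
            # (a smooth coarse landscape cannot localize an unrestrained
            # search the way a rugged all-atom one does)
            from .mcm import minimize_state

            system.restraints = []
            system.evaluate(state)
            state = minimize_state(state, system, relax_cfg)
        profile.steps.append(record(step, target, state))
        achieved = profile.steps[-1]["achieved_radius"]
        if achieved > schedule.escape_factor * final_radius:
            profile.truncated = True
            warnings.warn(
                f"ligand escaped at step {step} (radius {achieved:.1f} A); "
                "profile truncated"
            )
            break
    return profile


# ---------------------------------------------------------------------------
# profile analysis

@dataclass
class ProfileAnalysis:
    minima: list[int]  # interior minima (step indices)
    barriers: list[dict]  # {"from": i, "to": j, "height": kcal/mol}
    start_energy: float
    end_energy: float
    contacts: dict[int, list[str]]


def _interior_minima(e: np.ndarray) -> list[int]:
    """Strict interior minima with plateau tie-break (first step of a
    plateau lower than both flanking values)."""
    runs: list[tuple[int, float]] = []  # (start index, value)
    for i, v in enumerate(e):
        if not runs or v != runs[-1][1]:
            runs.append((i, float(v)))
    minima = []
    for k in range(1, len(runs) - 1):
        if runs[k][1] < runs[k - 1][1] and runs[k][1] < runs[k + 1][1]:
            minima.append(runs[k][0])
    return minima


def path_barrier(energies, i: int, j: int) -> float:
    """Barrier going from point i toward point j: the highest energy on the
    path minus the energy at i (>= 0)."""
    e = np.asarray(energies, float)
    lo, hi = (i, j) if i <= j else (j, i)
    return float(e[lo : hi + 1].max() - e[i])


def analyze_profile(profile: EgressProfile | np.ndarray) -> ProfileAnalysis:
    """Interior minima, barriers between successive stationary points
    (start, interior minima, end), endpoint energies and contact tables."""
    if isinstance(profile, EgressProfile):
        e = profile.energies()
        contacts = {s["step"]: s["contacts"] for s in profile.steps}
    else:
        e = np.asarray(profile, float)
        contacts = {}
    if len(e) < 2:
        raise ValueError("profile needs at least 2 steps")
    minima = _interior_minima(e)
    nodes = [0] + minima + [len(e) - 1]
    barriers = []
    for a, b in zip(nodes, nodes[1:]):
        if a == b:
            continue
        barriers.append({"from": a, "to": b, "height": path_barrier(e, a, b)})
        barriers.append({"from": b, "to": a, "height": path_barrier(e, b, a)})
    return ProfileAnalysis(minima, barriers, float(e[0]), float(e[-1]), contacts)


def egress_barrier(
    profile: EgressProfile | np.ndarray,
    basin_extent: float = 2.5,
    interim_separation: float = 4.0,
) -> float:
    """Barrier for leaving the bound site.

    The bound-site energy is the lowest point within ``basin_extent`` A of
    the starting radius (the chained scan may keep relaxing inside the
    basin over the first steps).  The exit target is the deepest interior
    minimum at least ``interim_separation`` A further out (the interim
    site), or the profile end when there is none; the barrier is the
    highest energy on the path between them, minus the bound-site energy.
    """
    if isinstance(profile, EgressProfile):
        e = profile.energies()
        r = profile.radii()
    else:
        e = np.asarray(profile, float)
        r = np.arange(len(e), dtype=float)
    in_basin = np.nonzero(r <= r[0] + basin_extent)[0]
    i0 = int(in_basin[np.argmin(e[in_basin])])
    minima = [
        j for j in _interior_minima(e)
        if j > i0 and r[j] >= r[i0] + interim_separation
    ]
    j = min(minima, key=lambda k: e[k]) if minima else len(e) - 1
    return path_barrier(e, i0, j)
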
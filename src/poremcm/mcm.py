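"""Monte-Carlo-minimization engine over internal (generalized) coordinates.

Each MCM step randomly perturbs a subset of the degrees of freedom —
channel side-chain torsions, ligand rigid-body position/orientation and
ligand torsions, plus (for the pulling protocols) Cartesian coordinates of
a selected mobile-atom set — then locally minimizes the energy and applies
a Metropolis test at temperature kT.  A trajectory terminates when a given
number of consecutive minimizations (the *patience*) fails to improve the
apparent global minimum.

Low-energy ligand-channel complexes are clustered into a :class:`PoseStack`:
records within a fixed energy window of the best one, merged when the ligand
heavy-atom RMSD is below a similarity threshold, capped in count.

The local minimizer is L-BFGS with analytic gradients: Cartesian forces are
chained through the rigid-body Jacobian (SO(3) exponential map) and the
torsion-axis formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .energy import (
    EnergyBreakdown,
    EnergyParams,
    NonbondedModel,
    Topology,
    combine_topologies,
    ligand_topology,
)
from .ligand import LigandModel, LigandPose, ligand_rmsd
from .restraints import AxialDistanceRestraint, PlaneRestraint
from .structio import ChannelStructure

__all__ = [
    "MCMConfig",
    "MCMState",
    "SidechainTorsion",
    "SimulationSystem",
    "PoseStack",
    "StackRecord",
    "stack_update",
    "perturb",
    "minimize_state",
    "mcm_run",
    "select_flexible_sidechains",
]

_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class MCMConfig:
    """Sampling parameters.

    ``patience`` counts consecutive non-improving minimizations before
    termination (1000 in the production docking protocol).  ``kT`` is the
    Metropolis acceptance temperature in kcal/mol.
    """

    patience: int = 1000
    kT: float = 0.6
    seed: int = 0
    torsion_amplitude: float = np.pi
    translation_amplitude: float = 1.0
    rotation_amplitude: float = 0.6
    cartesian_amplitude: float = 0.3
    per_variable_probability: float = 0.3
    max_minimizer_iter: int = 120
    minimizer_bound: float | None = None  # trust bound per scalar DOF (A / rad)
    max_steps: int | None = None  # hard cap on MC steps per trajectory
    flex_radius: float = 10.0  # side chains within this of the ligand are flexible

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        for amp in (
            self.torsion_amplitude,
            self.translation_amplitude,
            self.rotation_amplitude,
            self.cartesian_amplitude,
        ):
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")


@dataclass
class SidechainTorsion:
    """A chi-like rotation: ``moving`` atoms rotate about the axis from
    ``axis_a`` (CA) to ``axis_b`` (CB); channel atom indices."""

    resnum: int
    axis_a: int
    axis_b: int
    moving: tuple[int, ...]


@dataclass
class MCMState:
    """Current point of an MCM trajectory.

    Channel coordinates are stored in full; ligand placement as pose +
    torsion angles (wrapped to (-pi, pi]).
    """

    channel_coords: np.ndarray
    pose: LigandPose | None = None
    ligand_torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    energy: float | None = None
    breakdown: EnergyBreakdown | None = None

    def copy(self) -> "MCMState":
        return MCMState(
            self.channel_coords.copy(),
            self.pose.copy() if self.pose is not None else None,
            np.asarray(self.ligand_torsions, float).copy(),
            self.energy,
            self.breakdown,
        )


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    return -((-np.asarray(a, float) + np.pi) % (2 * np.pi) - np.pi)


def select_flexible_sidechains(
    structure: ChannelStructure,
    focus_coords: np.ndarray,
    radius: float = 10.0,
) -> list[SidechainTorsion]:
    """Side chains with any atom within ``radius`` of the focus coordinates
    (typically the ligand or the moving restrained atoms); residues without
    atoms beyond CB have no rotatable side-chain and are skipped."""
    focus = np.asarray(focus_coords, float).reshape(-1, 3)
    out: list[SidechainTorsion] = []
    for resnum in structure.residue_numbers():
        idx = structure.residue_atoms(resnum)
        names = {structure.atoms[i].name: i for i in idx}
        if "CA" not in names or "CB" not in names:
            continue
        moving = tuple(
            i for i in idx if structure.atoms[i].name not in (_BACKBONE | {"CB"})
        )
        if not moving:
            continue
        d = np.linalg.norm(
            structure.coords[list(idx)][:, None, :] - focus[None, :, :], axis=-1
        )
        if d.min() <= radius:
            out.append(SidechainTorsion(resnum, names["CA"], names["CB"], moving))
    return out


# ---------------------------------------------------------------------------
# pose stack

@dataclass
class StackRecord:
    energy: float
    ligand_coords: np.ndarray
    pose: LigandPose | None = None
    ligand_torsions: np.ndarray | None = None
    interaction_energy: float | None = None
    channel_coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


class PoseStack:
    """Clustered low-energy complexes.

    Invariants maintained after every update: every record within ``window``
    kcal/mol of the best; at most ``capacity`` records; no two records with
    ligand heavy-atom RMSD below ``rmsd_threshold`` (the lower-energy
    representative of a cluster is kept).
    """

    def __init__(
        self,
        window: float = 7.0,
        capacity: int = 100,
        rmsd_threshold: float = 1.5,
    ) -> None:
        if window < 0 or capacity < 1 or rmsd_threshold < 0:
            raise ValueError("invalid stack parameters")
        self.window = window
        self.capacity = capacity
        self.rmsd_threshold = rmsd_threshold
        self.records: list[StackRecord] = []

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best(self) -> StackRecord | None:
        return self.records[0] if self.records else None

    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    def update(self, record: StackRecord) -> None:
        if not np.isfinite(record.energy):
            raise ValueError("record energy must be finite")
        if self.records and record.energy > self.records[0].energy + self.window:
            return
        # merge into an existing cluster if geometrically similar
        for k, existing in enumerate(self.records):
            if (
                ligand_rmsd(existing.ligand_coords, record.ligand_coords)
                < self.rmsd_threshold
            ):
                if record.energy < existing.energy:
                    self.records[k] = record
                    self.records.sort(key=lambda r: r.energy)
                    self._prune()
                return
        self.records.append(record)
        self.records.sort(key=lambda r: r.energy)
        self._prune()

    def _prune(self) -> None:
        best = self.records[0].energy
        self.records = [r for r in self.records if r.energy <= best + self.window]
        del self.records[self.capacity:]


def stack_update(stack: PoseStack, record: StackRecord) -> PoseStack:
    """Functional-style wrapper around :meth:`PoseStack.update`."""
    stack.update(record)
    return stack


# ---------------------------------------------------------------------------
# simulation system

class SimulationSystem:
    """Binds a channel (+ topology), an optional ligand, the energy model,
    restraints and the degree-of-freedom layout for MCM runs."""

    def __init__(
        self,
        channel: ChannelStructure,
        channel_topology: Topology,
        ligand: LigandModel | None = None,
        params: EnergyParams | None = None,
        restraints: Sequence = (),
        mobile_atoms: Sequence[int] = (),
        sidechains: Sequence[SidechainTorsion] = (),
    ) -> None:
        self.channel = channel
        self.ligand = ligand
        self.params = params or EnergyParams()
        self.restraints = list(restraints)
        self.mobile_atoms = np.asarray(sorted(set(int(i) for i in mobile_atoms)), int)
        self.sidechains = list(sidechains)
        self.n_channel = len(channel.atoms)
        if ligand is not None:
            topo = combine_topologies(channel_topology, ligand_topology(ligand))
        else:
            topo = channel_topology
        self.topology = topo
        self.nb = NonbondedModel(topo, self.params)
        self._moving = self._moving_indices()
        self._static_cache: float | None = None

    # -- degrees of freedom ---------------------------------------------

    def _moving_indices(self) -> np.ndarray:
        moving = set(self.mobile_atoms.tolist())
        for sc in self.sidechains:
            moving.update(sc.moving)
        if self.ligand is not None:
            moving.update(range(self.n_channel, self.n_channel + len(self.ligand)))
        return np.asarray(sorted(moving), int)

    @property
    def moving_atoms(self) -> np.ndarray:
        return self._moving

    def initial_state(
        self,
        pose: LigandPose | None = None,
        ligand_torsions: Sequence[float] | None = None,
    ) -> MCMState:
        nt = len(self.ligand.torsions) if self.ligand is not None else 0
        ang = np.zeros(nt) if ligand_torsions is None else np.asarray(ligand_torsions, float)
        if self.ligand is not None and pose is None:
            pose = LigandPose()
        state = MCMState(self.channel.coords.copy(), pose, _wrap_angles(ang))
        self.evaluate(state)
        return state

    # -- coordinates and energy ----------------------------------------

    def full_coords(self, state: MCMState) -> np.ndarray:
        if self.ligand is None:
            return state.channel_coords
        lig = self.ligand.coords(state.pose, state.ligand_torsions)
        return np.vstack([state.channel_coords, lig])

    def ligand_coords(self, state: MCMState) -> np.ndarray:
        if self.ligand is None:
            raise ValueError("system has no ligand")
        return self.ligand.coords(state.pose, state.ligand_torsions)

    def _torsion_potential(self, angles: np.ndarray) -> float:
        p = self.params
        if not p.use_torsion or p.torsion_barrier <= 0.0 or not len(angles):
            return 0.0
        return float((0.5 * p.torsion_barrier * (1.0 + np.cos(3.0 * angles))).sum())

    def _static_energy(self, coords: np.ndarray) -> float:
        if self._static_cache is None:
            full = self.nb.full_energy(coords)
            v, e, b = self.nb.subset_energy(coords, self._moving)
            self._static_cache = full.vdw + full.elec + full.bonds - (v + e + b)
        return self._static_cache

    def invalidate_static(self) -> None:
        self._static_cache = None

    def restraint_energy(self, coords: np.ndarray) -> float:
        total = 0.0
        for r in self.restraints:
            e, _ = r.energy_and_gradient(coords, self.channel.pore_axis)
            total += e
        return total

    def evaluate(self, state: MCMState) -> float:
        """Objective energy (nonbonded + bonds + torsion potential +
        restraint penalties); caches it on the state."""
        coords = self.full_coords(state)
        v, e, b = self.nb.subset_energy(coords, self._moving)
        total = (
            self._static_energy(coords)
            + v + e + b
            + self._torsion_potential(state.ligand_torsions)
            + self.restraint_energy(coords)
        )
        state.energy = float(total)
        return state.energy

    def breakdown(self, state: MCMState) -> EnergyBreakdown:
        coords = self.full_coords(state)
        bd = self.nb.full_energy(coords, self.n_channel if self.ligand is not None else None)
        bd.torsion = self._torsion_potential(state.ligand_torsions)
        bd.restraints = self.restraint_energy(coords)
        state.breakdown = bd
        return bd

    def interaction_energy(self, state: MCMState) -> float:
        if self.ligand is None:
            return 0.0
        return self.nb.interaction_energy(self.full_coords(state), self.n_channel)

    # -- constraint projections -----------------------------------------

    def project_constraints(self, state: MCMState) -> None:
        """Snap plane-restrained atoms into their planes and translate the
        ligand to the exact axial-distance target (in place)."""
        axis = self.channel.pore_axis
        for r in self.restraints:
            if isinstance(r, PlaneRestraint):
                r.project(state.channel_coords, axis)
            elif isinstance(r, AxialDistanceRestraint) and self.ligand is not None:
                lig = self.ligand.coords(state.pose, state.ligand_torsions)
                local_idx = r.atom_index - self.n_channel
                proxy = AxialDistanceRestraint(local_idx, r.target_radius)
                state.pose.translation = state.pose.translation + proxy.radial_correction(
                    lig, axis
                )


# ---------------------------------------------------------------------------
# perturbation

def perturb(state: MCMState, system: SimulationSystem, config: MCMConfig, rng: np.random.Generator) -> MCMState:
    """Random move: ligand rigid body always perturbed (when present); each
    ligand torsion, side-chain and mobile atom with probability
    ``per_variable_probability``.  Constrained coordinates are re-projected.
    Deterministic given the generator state."""
    cand = state.copy()
    cand.energy = None
    p = config.per_variable_probability
    if system.ligand is not None and cand.pose is not None:
        if config.translation_amplitude > 0:
            vec = rng.normal(size=3)
            vec /= max(np.linalg.norm(vec), 1e-12)
            cand.pose.translation = cand.pose.translation + vec * rng.uniform(
                0, config.translation_amplitude
            )
        if config.rotation_amplitude > 0:
            axis = rng.normal(size=3)
            axis /= max(np.linalg.norm(axis), 1e-12)
            angle = rng.uniform(-config.rotation_amplitude, config.rotation_amplitude)
            rot = Rotation.from_rotvec(axis * angle)
            cand.pose.quaternion = (rot * Rotation.from_quat(cand.pose.quaternion)).as_quat()
        if len(cand.ligand_torsions) and config.torsion_amplitude > 0:
            pick = rng.random(len(cand.ligand_torsions)) < p
            delta = rng.uniform(
                -config.torsion_amplitude, config.torsion_amplitude, len(cand.ligand_torsions)
            )
            cand.ligand_torsions = _wrap_angles(cand.ligand_torsions + pick * delta)
    if system.sidechains and config.torsion_amplitude > 0:
        for sc in system.sidechains:
            if rng.random() >= p:
                continue
            angle = rng.uniform(-config.torsion_amplitude, config.torsion_amplitude)
            a, b = cand.channel_coords[sc.axis_a], cand.channel_coords[sc.axis_b]
            u = b - a
            u /= max(np.linalg.norm(u), 1e-12)
            rot = Rotation.from_rotvec(u * angle)
            idx = list(sc.moving)
            cand.channel_coords[idx] = rot.apply(cand.channel_coords[idx] - b) + b
    if len(system.mobile_atoms) and config.cartesian_amplitude > 0:
        pick = rng.random(len(system.mobile_atoms)) < p
        step = rng.normal(scale=config.cartesian_amplitude, size=(len(system.mobile_atoms), 3))
        cand.channel_coords[system.mobile_atoms] += pick[:, None] * step
    system.project_constraints(cand)
    system.evaluate(cand)
    return cand


# ---------------------------------------------------------------------------
# local minimization

def _so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    W = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + 0.5 * W + W @ W / 6.0
    return (
        np.eye(3)
        + ((1 - np.cos(theta)) / theta**2) * W
        + ((theta - np.sin(theta)) / theta**3) * (W @ W)
    )


class _DOFLayout:
    """Mapping between the minimizer's flat increment vector and system
    coordinates; gradients are chained analytically."""

    def __init__(self, system: SimulationSystem, state: MCMState) -> None:
        self.system = system
        self.state0 = state
        self.n_cart = len(system.mobile_atoms)
        self.n_sc = len(system.sidechains)
        self.has_ligand = system.ligand is not None
        self.n_tor = len(state.ligand_torsions) if self.has_ligand else 0
        if self.has_ligand:
            lig0 = system.ligand.coords(state.pose, state.ligand_torsions)
            self.center0 = system.ligand.mass_center(lig0)
        self.size = 3 * self.n_cart + self.n_sc + (6 + self.n_tor if self.has_ligand else 0)

    def build_state(self, x: np.ndarray) -> MCMState:
        sys_, s0 = self.system, self.state0
        state = s0.copy()
        state.energy = None
        off = 0
        if self.n_cart:
            state.channel_coords[sys_.mobile_atoms] += x[: 3 * self.n_cart].reshape(-1, 3)
            off = 3 * self.n_cart
        for k, sc in enumerate(sys_.sidechains):
            angle = x[off + k]
            if angle != 0.0:
                a, b = state.channel_coords[sc.axis_a], state.channel_coords[sc.axis_b]
                u = b - a
                u /= max(np.linalg.norm(u), 1e-12)
                rot = Rotation.from_rotvec(u * angle)
                idx = list(sc.moving)
                state.channel_coords[idx] = rot.apply(state.channel_coords[idx] - b) + b
        off += self.n_sc
        if self.has_ligand:
            dt = x[off : off + 3]
            w = x[off + 3 : off + 6]
            dtor = x[off + 6 : off + 6 + self.n_tor]
            state.ligand_torsions = _wrap_angles(s0.ligand_torsions + dtor)
            rot_w = Rotation.from_rotvec(w)
            q_new = rot_w * s0.pose.rotation()
            t_new = rot_w.apply(s0.pose.translation - self.center0) + self.center0 + dt
            state.pose = LigandPose(t_new, q_new.as_quat())
        return state

    def energy_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        sys_ = self.system
        state = self.build_state(x)
        coords = sys_.full_coords(state)
        moving = sys_.moving_atoms
        energy, grad_mov = sys_.nb.subset_gradient(coords, moving)
        energy += sys_._static_energy(coords)
        # restraints
        for r in sys_.restraints:
            e, grads = r.energy_and_gradient(coords, sys_.channel.pore_axis)
            energy += e
            for idx, g in grads.items():
                k = np.searchsorted(moving, idx)
                if k < len(moving) and moving[k] == idx:
                    grad_mov[k] += g
        # torsion potential
        p = sys_.params
        if self.has_ligand and p.use_torsion and p.torsion_barrier > 0.0 and self.n_tor:
            ang = state.ligand_torsions
            energy += float((0.5 * p.torsion_barrier * (1 + np.cos(3 * ang))).sum())
            dtor_pot = -1.5 * p.torsion_barrier * np.sin(3 * ang)
        else:
            dtor_pot = np.zeros(self.n_tor)
        # scatter per-atom gradient into full array for chaining
        grad_atoms = np.zeros_like(coords)
        grad_atoms[moving] = grad_mov
        gx = np.zeros(self.size)
        off = 0
        if self.n_cart:
            gx[: 3 * self.n_cart] = grad_atoms[sys_.mobile_atoms].ravel()
            off = 3 * self.n_cart
        for k, sc in enumerate(sys_.sidechains):
            a, b = coords[sc.axis_a], coords[sc.axis_b]
            u = b - a
            u /= max(np.linalg.norm(u), 1e-12)
            idx = list(sc.moving)
            tau = np.cross(coords[idx] - b, grad_atoms[idx]).sum(axis=0)
            gx[off + k] = u @ tau
        off += self.n_sc
        if self.has_ligand:
            lig_idx = np.arange(sys_.n_channel, sys_.n_channel + len(sys_.ligand))
            g_lig = grad_atoms[lig_idx]
            x_lig = coords[lig_idx]
            gx[off : off + 3] = g_lig.sum(axis=0)
            w = x[off + 3 : off + 6]
            center = self.center0 + x[off : off + 3]
            tau = np.cross(x_lig - center, g_lig).sum(axis=0)
            gx[off + 3 : off + 6] = _so3_left_jacobian(w).T @ tau
            # ligand torsions: world-frame axis formula
            for k, tor in enumerate(sys_.ligand.torsions):
                a_w = x_lig[tor.axis_a]
                b_w = x_lig[tor.axis_b]
                u = b_w - a_w
                u /= max(np.linalg.norm(u), 1e-12)
                idx = list(tor.moving)
                tau_t = np.cross(x_lig[idx] - b_w, g_lig[idx]).sum(axis=0)
                gx[off + 6 + k] = u @ tau_t + dtor_pot[k]
        return float(energy), gx


def minimize_state(
    state: MCMState, system: SimulationSystem, config: MCMConfig | None = None
) -> MCMState:
    """Local energy minimization from ``state``; never returns a state with
    higher energy than the input (descent contract)."""
    config = config or MCMConfig()
    if state.energy is None:
        system.evaluate(state)
    layout = _DOFLayout(system, state)
    if layout.size == 0:
        return state
    if not np.isfinite(state.energy):
        raise FloatingPointError(_describe_clash(system, state))
    bounds = None
    if config.minimizer_bound is not None:
        b = float(config.minimizer_bound)
        bounds = [(-b, b)] * layout.size
    res = _scipy_minimize(
        layout.energy_and_gradient,
        np.zeros(layout.size),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_minimizer_iter, "ftol": 1e-8, "gtol": 1e-5},
    )
    new = layout.build_state(res.x)
    system.project_constraints(new)
    system.evaluate(new)
    if not np.isfinite(new.energy):
        raise FloatingPointError(_describe_clash(system, new))
    return new if new.energy <= state.energy else state


def _describe_clash(system: SimulationSystem, state: MCMState) -> str:
    coords = system.full_coords(state)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return (
        f"non-finite energy; closest pair: atoms {i} and {j} at {d[i, j]:.2e} A"
    )


# ---------------------------------------------------------------------------
# full MCM trajectory

@dataclass
class MCMTrajectory:
    steps: list[dict] = field(default_factory=list)

    def best_energies(self) -> np.ndarray:
        return np.array([s["best_energy"] for s in self.steps])


def mcm_run(
    state: MCMState,
    system: SimulationSystem,
    config: MCMConfig,
    stack: PoseStack | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MCMState, MCMTrajectory, PoseStack | None]:
    """Run one MCM trajectory until ``patience`` consecutive minimizations
    fail to improve the apparent global minimum.

    Returns (best state, trajectory log, stack).  Fully deterministic given
    the seed/generator.
    """
    rng = rng or np.random.default_rng(config.seed)
    current = minimize_state(state, system, config)
    best = current
    traj = MCMTrajectory()
    if stack is not None and system.ligand is not None:
        stack.update(_record(system, current))
    fails = 0
    step = 0
    while fails < config.patience:
        if config.max_steps is not None and step >= config.max_steps:
            break
        cand = perturb(current, system, config, rng)
        cand = minimize_state(cand, system, config)
        improved = cand.energy < best.energy - 1e-9
        if improved:
            best = cand
            fails = 0
        else:
            fails += 1
        delta = cand.energy - current.energy
        accept = delta <= 0 or rng.random() < np.exp(-delta / max(config.kT, 1e-9))
        if accept:
            current = cand
        if stack is not None and system.ligand is not None:
            stack.update(_record(system, cand))
        step += 1
        traj.steps.append(
            {
                "step": step,
                "candidate_energy": cand.energy,
                "best_energy": best.energy,
                "accepted": bool(accept),
            }
        )
    return best, traj, stack


def _record(system: SimulationSystem, state: MCMState) -> StackRecord:
    return StackRecord(
        energy=state.energy,
        ligand_coords=system.ligand_coords(state),
        pose=state.pose.copy() if state.pose is not None else None,
        ligand_torsions=np.asarray(state.ligand_torsions).copy(),
        interaction_energy=system.interaction_energy(state),
        channel_coords=None,
    )
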
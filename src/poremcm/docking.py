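"""Random-start ligand docking into the inner-pore region.

Protocol: hundreds of random positions, orientations and conformations of
the ligand are generated with the mass centre inside a sphere (radius 8 A by
default) centred at the focus of the P1 helices; each start is refined by a
fixed count of MC-minimizations without ligand-channel constraints; the
energetically best complexes are then refined in full MCM trajectories with
patience-based termination, and all low-energy complexes are clustered into
a pose stack.

Reported poses are filtered by the ligand-channel *interaction* energy
window (10 kcal/mol by default), annotated with contact residues (heavy
atoms within 4 A) and classified geometrically: a pose whose aromatic-ring
centroid lies beyond a radial boundary from the pore axis reaches into a
fenestration (tonic-block-like, "TB"); otherwise the ring extends in the
inner pore (use-dependent-block-like, "UDB").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .energy import default_channel_topology
from .labels import SegmentAnchorTable, ResidueLabel
from .ligand import LigandModel, LigandPose
from .mcm import (
    MCMConfig,
    MCMState,
    PoseStack,
    SimulationSystem,
    mcm_run,
    minimize_state,
    perturb,
    select_flexible_sidechains,
)
from .restraints import cylindrical_radius
from .structio import ChannelStructure

__all__ = [
    "DockingConfig",
    "generate_starts",
    "dock",
    "report_poses",
    "classify_pose",
    "p1_focus",
]


@dataclass
class DockingConfig:
    """Start generation + two-stage refinement parameters.

    Production defaults follow the docking protocol (8 A start sphere,
    hundreds of starts, 100 coarse MC-minimizations each, the best 100
    refined at patience 1000); scale ``n_starts``/``coarse_minimizations``/
    ``n_refine``/``refine_patience`` down for desk-scale runs.
    """

    sphere_center: np.ndarray | None = None  # default: focus of P1 helices
    sphere_radius: float = 8.0
    n_starts: int = 400
    coarse_minimizations: int = 100
    n_refine: int = 100
    refine_patience: int = 1000
    report_window: float = 10.0
    stack_window: float = 7.0
    stack_capacity: int = 100
    stack_rmsd: float = 1.5
    tb_boundary: float = 8.0  # ring-centroid radius separating TB/UDB poses
    seed: int = 0
    mcm: MCMConfig = field(default_factory=MCMConfig)

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.n_refine > self.n_starts:
            raise ValueError("n_refine cannot exceed n_starts")


def p1_focus(structure: ChannelStructure) -> np.ndarray:
    """Focus of the P1 helices: the least-squares point of closest approach
    of the four membrane-descending P-helix axes.  The axes converge in the
    central cavity under the selectivity filter, which makes this point the
    natural docking sphere centre."""
    by_repeat: dict[int, list[np.ndarray]] = {}
    for resnum, (repeat, seg) in sorted(structure.annotations.items()):
        if seg == "p" and structure.has_atom(resnum, "CA"):
            by_repeat.setdefault(repeat, []).append(structure.ca_coord(resnum))
    if not by_repeat:
        raise ValueError("structure has no annotated p-segment residues")
    A = np.zeros((3, 3))
    rhs = np.zeros(3)
    for pts in by_repeat.values():
        pts = np.asarray(pts)
        if len(pts) < 2:
            continue
        center = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - center)
        u = vt[0]
        proj = np.eye(3) - np.outer(u, u)
        A += proj
        rhs += proj @ center
    if np.linalg.matrix_rank(A) < 3:
        return np.mean([p for pts in by_repeat.values() for p in pts], axis=0)
    return np.linalg.solve(A, rhs)


def generate_starts(
    config: DockingConfig,
    ligand: LigandModel,
    rng: np.random.Generator,
    center: np.ndarray | None = None,
) -> list[tuple[LigandPose, np.ndarray]]:
    """Random starting placements: mass centre uniform in the sphere,
    orientation uniform over rotations, torsions uniform in (-pi, pi]."""
    center = np.asarray(
        config.sphere_center if center is None else center, float
    )
    starts = []
    for _ in range(config.n_starts):
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        radius = config.sphere_radius * rng.random() ** (1.0 / 3.0)
        target = center + direction * radius
        rot = Rotation.random(random_state=rng)
        torsions = rng.uniform(-np.pi, np.pi, size=len(ligand.torsions))
        local_mc = ligand.mass_center(ligand.conformer(torsions))
        translation = target - rot.apply(local_mc)
        starts.append((LigandPose(translation, rot.as_quat()), torsions))
    return starts


def _coarse_refine(system, state, n, config: MCMConfig, rng) -> MCMState:
    """Fixed-count MC-minimization refinement of one start."""
    current = minimize_state(state, system, config)
    best = current
    for _ in range(n - 1):
        cand = perturb(current, system, config, rng)
        cand = minimize_state(cand, system, config)
        if cand.energy < best.energy:
            best = cand
        delta = cand.energy - current.energy
        if delta <= 0 or rng.random() < np.exp(-delta / max(config.kT, 1e-9)):
            current = cand
    return best


def dock(
    structure: ChannelStructure,
    ligand: LigandModel,
    config: DockingConfig | None = None,
    flexible_sidechains: bool = True,
) -> PoseStack:
    """Run the full docking pipeline; returns the merged pose stack."""
    config = config or DockingConfig()
    rng = np.random.default_rng(config.seed)
    center = (
        np.asarray(config.sphere_center, float)
        if config.sphere_center is not None
        else p1_focus(structure)
    )
    topo = getattr(structure, "topology", None) or default_channel_topology(structure)
    sidechains = (
        select_flexible_sidechains(structure, center[None, :],
                                   config.mcm.flex_radius + config.sphere_radius)
        if flexible_sidechains
        else []
    )
    system = SimulationSystem(
        structure, topo, ligand, sidechains=sidechains
    )
    starts = generate_starts(config, ligand, rng, center)
    coarse_cfg = config.mcm
    refined: list[MCMState] = []
    for pose, torsions in starts:
        state = system.initial_state(pose, torsions)
        if not np.isfinite(state.energy):
            continue  # start embedded in the protein wall; discard
        refined.append(
            _coarse_refine(system, state, config.coarse_minimizations, coarse_cfg, rng)
        )
    refined.sort(key=lambda s: s.energy)  # rank by total system energy
    stack = PoseStack(config.stack_window, config.stack_capacity, config.stack_rmsd)
    full_cfg = MCMConfig(
        patience=config.refine_patience,
        kT=coarse_cfg.kT,
        torsion_amplitude=coarse_cfg.torsion_amplitude,
        translation_amplitude=coarse_cfg.translation_amplitude,
        rotation_amplitude=coarse_cfg.rotation_amplitude,
        per_variable_probability=coarse_cfg.per_variable_probability,
        max_minimizer_iter=coarse_cfg.max_minimizer_iter,
    )
    for state in refined[: config.n_refine]:
        _, _, stack = mcm_run(state, system, full_cfg, stack=stack, rng=rng)
    return stack


def classify_pose(
    ligand: LigandModel,
    ligand_coords: np.ndarray,
    axis,
    boundary: float = 8.0,
) -> str:
    """"TB" when the aromatic-ring centroid sits beyond ``boundary`` (A)
    from the pore axis (ring reaching into a fenestration), else "UDB"."""
    ring = [i for i, a in enumerate(ligand.atoms) if a.type == "CA"]
    if not ring:
        raise ValueError("ligand has no aromatic (type CA) atoms to classify")
    centroid = np.asarray(ligand_coords, float)[ring].mean(axis=0)
    return "TB" if cylindrical_radius(centroid, axis) >= boundary else "UDB"


def report_poses(
    stack: PoseStack,
    window: float = 10.0,
    structure: ChannelStructure | None = None,
    ligand: LigandModel | None = None,
    anchors: SegmentAnchorTable | None = None,
    contact_cutoff: float = 4.0,
    tb_boundary: float = 8.0,
) -> pd.DataFrame:
    """Ranked table of stack poses within the interaction-energy window.

    Columns: rank, energy, interaction_energy, pose class (if the ligand is
    given), contact residues within ``contact_cutoff`` A (labelled when the
    structure carries annotations; an anchor table adds universal labels).
    """
    if not len(stack):
        warnings.warn("empty pose stack; returning empty table")
        return pd.DataFrame(
            columns=["rank", "energy", "interaction_energy", "class", "contacts"]
        )
    inter = np.array(
        [
            r.interaction_energy if r.interaction_energy is not None else r.energy
            for r in stack.records
        ]
    )
    best = inter.min()
    keep = [
        (r, ie) for r, ie in zip(stack.records, inter) if ie <= best + window
    ]
    keep.sort(key=lambda t: t[1])
    rows = []
    for rank, (rec, ie) in enumerate(keep, start=1):
        contacts: list[str] = []
        if structure is not None:
            contacts = contact_residues(
                structure, rec.ligand_coords, contact_cutoff, anchors
            )
        klass = (
            classify_pose(ligand, rec.ligand_coords, structure.pore_axis, tb_boundary)
            if (ligand is not None and structure is not None)
            else ""
        )
        rows.append(
            {
                "rank": rank,
                "energy": rec.energy,
                "interaction_energy": ie,
                "class": klass,
                "contacts": contacts,
            }
        )
    return pd.DataFrame(rows)


def contact_residues(
    structure: ChannelStructure,
    ligand_coords: np.ndarray,
    cutoff: float = 4.0,
    anchors: SegmentAnchorTable | None = None,
) -> list[str]:
    """Residues with any heavy atom within ``cutoff`` A of any ligand heavy
    atom, as universal labels where annotated (else plain residue numbers)."""
    lig = np.asarray(ligand_coords, float)
    d = np.linalg.norm(structure.coords[:, None, :] - lig[None, :, :], axis=-1)
    near = d.min(axis=1) <= cutoff
    resnums: dict[int, None] = {}
    for i in np.nonzero(near)[0]:
        a = structure.atoms[int(i)]
        if a.element != "H":
            resnums.setdefault(a.resnum, None)
    out = []
    for resnum in resnums:
        ann = structure.annotations.get(resnum)
        if ann is not None and anchors is not None:
            repeat, seg = ann
            anchor_relpos, anchor_resnum = anchors.anchor(repeat, seg)
            out.append(str(ResidueLabel(repeat, seg, anchor_relpos + resnum - anchor_resnum)))
        else:
            out.append(str(resnum))
    return out
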
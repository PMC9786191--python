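"""Reduced nonbonded energy model for desk-scale channel/ligand systems.

The model preserves the structural contracts of force-field calculations on
P-loop channels without reproducing any particular force field:

* Lennard-Jones 12-6 van der Waals with a ~10-entry united-atom type table;
* Coulomb electrostatics with the distance-dependent dielectric
  ``eps(r) = eps0 * r`` (so the pair energy falls off as 1/r^2);
* a 9 A distance cutoff with a shifting function that takes both the energy
  and its first derivative exactly to zero at the cutoff — except for pairs
  involving an atom of an ionized group, which are computed without cutoff;
* 1-2 and 1-3 bonded pairs excluded, 1-4 pairs scaled by 0.5;
* optional harmonic bond terms (used by the coarse synthetic channels to
  keep helices coherent while they are dragged by the protocols).

Quantitative kcal/mol values are therefore model-internal: orderings and
contracts (signs, cutoff behaviour, brute-force equivalence) are meaningful,
absolute magnitudes are not comparable to all-atom force fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ligand import LigandModel, LigandPose
from .structio import ChannelStructure

__all__ = [
    "AtomType",
    "DEFAULT_TYPE_TABLE",
    "EnergyParams",
    "EnergyBreakdown",
    "Topology",
    "NonbondedModel",
    "pair_vdw",
    "pair_elec",
    "total_energy",
    "default_channel_topology",
    "combine_topologies",
    "ligand_topology",
]

COULOMB = 332.06  # kcal * A / (mol * e^2)


@dataclass(frozen=True)
class AtomType:
    rmin_half: float  # A, half the LJ minimum-energy distance of the homopair
    eps: float  # kcal/mol well depth


# United-atom table; hydrogens are normally absorbed into heavy atoms.
DEFAULT_TYPE_TABLE: dict[str, AtomType] = {
    "C": AtomType(2.00, 0.105),   # aliphatic carbon (united CHn)
    "CA": AtomType(1.95, 0.080),  # aromatic carbon
    "N": AtomType(1.85, 0.170),
    "N+": AtomType(1.85, 0.170),  # ammonium / guanidinium nitrogen (ionized)
    "O": AtomType(1.60, 0.210),
    "O-": AtomType(1.60, 0.210),  # carboxylate oxygen (ionized)
    "S": AtomType(2.00, 0.250),
    "H": AtomType(0.80, 0.010),
    "BB": AtomType(2.30, 0.060),  # coarse backbone bead of synthetic channels
    "FL": AtomType(3.00, 0.350),  # united bulky aromatic side chain (fenestration flank)
    "PK": AtomType(2.10, 2.500),  # planted pocket bead (deep well)
}


@dataclass
class EnergyParams:
    """Tunable knobs of the reduced model (defaults follow the modelling
    protocol: 9 A cutoff + shift, eps(r) = 4r)."""

    cutoff: float = 9.0
    eps0: float = 4.0  # dimensionless prefactor of the r-linear dielectric
    scale14: float = 0.5
    use_vdw: bool = True
    use_elec: bool = True
    use_torsion: bool = True
    torsion_barrier: float = 0.0  # kcal/mol 3-fold barrier on ligand torsions
    type_table: dict[str, AtomType] = field(default_factory=lambda: dict(DEFAULT_TYPE_TABLE))

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.eps0 <= 0:
            raise ValueError("eps0 must be positive")
        for name, t in self.type_table.items():
            if t.eps < 0:
                raise ValueError(f"negative well depth for type {name!r}")

    def lookup(self, type_name: str) -> AtomType:
        try:
            return self.type_table[type_name]
        except KeyError:
            raise KeyError(f"unknown atom type {type_name!r}") from None


@dataclass
class EnergyBreakdown:
    vdw: float = 0.0
    elec: float = 0.0
    bonds: float = 0.0
    torsion: float = 0.0
    restraints: float = 0.0
    ligand_channel_interaction: float = 0.0  # cross vdw+elec pairs only

    @property
    def total(self) -> float:
        return self.vdw + self.elec + self.bonds + self.torsion + self.restraints

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.vdw + other.vdw,
            self.elec + other.elec,
            self.bonds + other.bonds,
            self.torsion + other.torsion,
            self.restraints + other.restraints,
            self.ligand_channel_interaction + other.ligand_channel_interaction,
        )


# ---------------------------------------------------------------------------
# closed-form pair terms (scalar; the vectorized engine mirrors these)

def _lj(r, rmin, eps):
    sr6 = (rmin / r) ** 6
    return eps * (sr6 * sr6 - 2.0 * sr6)


def _lj_deriv(r, rmin, eps):
    sr6 = (rmin / r) ** 6
    return eps * (-12.0 * sr6 * sr6 + 12.0 * sr6) / r


def _coul(r, qq, eps0):
    return COULOMB * qq / (eps0 * r * r)


def _coul_deriv(r, qq, eps0):
    return -2.0 * COULOMB * qq / (eps0 * r**3)


def pair_vdw(r: float, type_a: str, type_b: str, params: EnergyParams) -> float:
    """Shifted Lennard-Jones 12-6 energy of one pair (kcal/mol)."""
    if r <= 0:
        raise ValueError("r must be positive")
    ta, tb = params.lookup(type_a), params.lookup(type_b)
    rmin = ta.rmin_half + tb.rmin_half
    eps = np.sqrt(ta.eps * tb.eps)
    if r >= params.cutoff:
        return 0.0
    return float(
        _lj(r, rmin, eps)
        - _lj(params.cutoff, rmin, eps)
        - (r - params.cutoff) * _lj_deriv(params.cutoff, rmin, eps)
    )


def pair_elec(
    qi: float, qj: float, r: float, params: EnergyParams, ionized: bool = False
) -> float:
    """Coulomb energy with eps(r) = eps0*r (kcal/mol).

    Non-ionized pairs are shifted to zero energy and slope at the cutoff;
    pairs where either atom belongs to an ionized group are computed without
    any cutoff.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    qq = qi * qj
    if ionized:
        return float(_coul(r, qq, params.eps0))
    if r >= params.cutoff:
        return 0.0
    return float(
        _coul(r, qq, params.eps0)
        - _coul(params.cutoff, qq, params.eps0)
        - (r - params.cutoff) * _coul_deriv(params.cutoff, qq, params.eps0)
    )


# ---------------------------------------------------------------------------
# topologies

@dataclass
class Topology:
    """Per-atom nonbonded parameters and bonded terms of one molecule or of
    a combined channel+ligand system.

    ``bonds`` rows are (i, j, r0, k): harmonic springs k*(r-r0)^2; k may be 0
    for connectivity that only defines nonbonded exclusions (e.g. ligand
    bonds, whose geometry is maintained by internal coordinates).
    """

    type_names: list[str]
    charge: np.ndarray
    ionized: np.ndarray
    bonds: np.ndarray  # (M, 4) float: i, j, r0, k

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, float)
        self.ionized = np.asarray(self.ionized, bool)
        self.bonds = np.asarray(self.bonds, float).reshape(-1, 4)
        n = len(self.type_names)
        if self.charge.shape != (n,) or self.ionized.shape != (n,):
            raise ValueError("charge/ionized length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.type_names)


def ligand_topology(ligand: LigandModel) -> Topology:
    return Topology(
        [a.type for a in ligand.atoms],
        np.array([a.charge for a in ligand.atoms]),
        np.array([a.ionized for a in ligand.atoms]),
        np.array([[i, j, 0.0, 0.0] for i, j in ligand.bonds], float).reshape(-1, 4),
    )


_IONIZED_CHANNEL_ATOMS = {
    ("LYS", "NZ"): ("N+", 1.0),
    ("ARG", "NH1"): ("N+", 0.5),
    ("ARG", "NH2"): ("N+", 0.5),
    ("ASP", "OD1"): ("O-", -0.5),
    ("ASP", "OD2"): ("O-", -0.5),
    ("GLU", "OE1"): ("O-", -0.5),
    ("GLU", "OE2"): ("O-", -0.5),
}


def default_channel_topology(structure: ChannelStructure) -> Topology:
    """Element-based typing for channel atoms; partial charges only on the
    standard ionized side-chain groups and backbone carbonyl oxygens.

    Synthetic channels carry their own explicit topology; this default is
    for quick scoring of experimental structures (no bond inference, so
    bonded exclusions are empty — fine for rigid-channel interaction
    energies, not for minimizing the channel itself).
    """
    element_map = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H"}
    names, charges, ionized = [], [], []
    untyped = []
    for a in structure.atoms:
        key = (a.resname, a.name)
        if key in _IONIZED_CHANNEL_ATOMS:
            t, q = _IONIZED_CHANNEL_ATOMS[key]
            names.append(t)
            charges.append(q)
            ionized.append(True)
        else:
            t = element_map.get(a.element)
            if t is None:
                untyped.append(f"{a.resname}{a.resnum}:{a.name}")
                t = "C"
            names.append(t)
            charges.append(-0.4 if a.name == "O" else 0.0)
            ionized.append(False)
    if untyped:
        raise KeyError(f"untyped atoms (unknown element): {untyped[:10]}")
    return Topology(names, np.array(charges), np.array(ionized), np.empty((0, 4)))


def combine_topologies(channel: Topology, lig: Topology) -> Topology:
    """Stack channel atoms first, ligand atoms after (the convention used by
    the whole package)."""
    off = channel.n_atoms
    lig_bonds = lig.bonds.copy()
    if len(lig_bonds):
        lig_bonds[:, :2] += off
    return Topology(
        channel.type_names + lig.type_names,
        np.concatenate([channel.charge, lig.charge]),
        np.concatenate([channel.ionized, lig.ionized]),
        np.vstack([channel.bonds, lig_bonds]),
    )


# ---------------------------------------------------------------------------
# vectorized engine

class NonbondedModel:
    """Precomputed pair-parameter matrices for fast repeated evaluation.

    Intended for desk-scale systems (up to a few thousand atoms); the pair
    matrices are dense.  ``subset_energy``/``subset_gradient`` evaluate only
    pairs touching a moving-atom set, which the sampling engine combines
    with a cached static-static term.
    """

    def __init__(self, topology: Topology, params: EnergyParams) -> None:
        self.topology = topology
        self.params = params
        n = topology.n_atoms
        rmin_half = np.array([params.lookup(t).rmin_half for t in topology.type_names])
        eps = np.array([params.lookup(t).eps for t in topology.type_names])
        self.rmin = rmin_half[:, None] + rmin_half[None, :]
        self.eps = np.sqrt(eps[:, None] * eps[None, :])
        self.qq = topology.charge[:, None] * topology.charge[None, :]
        self.ionized_pair = topology.ionized[:, None] | topology.ionized[None, :]
        self.scale = self._exclusion_matrix(n, topology.bonds, params.scale14)
        np.fill_diagonal(self.scale, 0.0)

    @staticmethod
    def _exclusion_matrix(n: int, bonds: np.ndarray, scale14: float) -> np.ndarray:
        scale = np.ones((n, n))
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j, _, _ in bonds:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        for i in range(n):
            one = adj[i]
            two = set().union(*(adj[j] for j in one)) if one else set()
            three = set().union(*(adj[j] for j in two)) if two else set()
            for j in three - two - one - {i}:
                scale[i, j] = min(scale[i, j], scale14)  # 1-4
            for j in (one | two) - {i}:
                scale[i, j] = 0.0  # 1-2 and 1-3
        return scale

    # -- pair blocks ----------------------------------------------------

    def _pair_terms(self, coords, rows, cols, want_grad):
        """Energies (and optionally forces) of the pair block rows x cols."""
        p = self.params
        d = coords[rows][:, None, :] - coords[cols][None, :, :]
        r = np.sqrt(np.maximum((d**2).sum(axis=-1), 1e-12))
        sub = np.ix_(rows, cols)
        scale = self.scale[sub]
        rmin, eps, qq = self.rmin[sub], self.eps[sub], self.qq[sub]
        ion = self.ionized_pair[sub]
        inside = r < p.cutoff
        e_vdw = np.zeros_like(r)
        e_el = np.zeros_like(r)
        de = np.zeros_like(r)  # dE/dr
        if p.use_vdw:
            lj = _lj(r, rmin, eps) - _lj(p.cutoff, rmin, eps) \
                - (r - p.cutoff) * _lj_deriv(p.cutoff, rmin, eps)
            e_vdw = np.where(inside, lj, 0.0) * scale
            if want_grad:
                de += np.where(
                    inside, _lj_deriv(r, rmin, eps) - _lj_deriv(p.cutoff, rmin, eps), 0.0
                ) * scale
        if p.use_elec:
            coul = _coul(r, qq, p.eps0)
            shifted = coul - _coul(p.cutoff, qq, p.eps0) \
                - (r - p.cutoff) * _coul_deriv(p.cutoff, qq, p.eps0)
            e_el = np.where(ion, coul, np.where(inside, shifted, 0.0)) * scale
            if want_grad:
                dcoul = _coul_deriv(r, qq, p.eps0)
                de += np.where(
                    ion, dcoul,
                    np.where(inside, dcoul - _coul_deriv(p.cutoff, qq, p.eps0), 0.0),
                ) * scale
        if not want_grad:
            return e_vdw, e_el, None, None, None
        return e_vdw, e_el, de, d, r

    def subset_energy(
        self, coords: np.ndarray, moving: np.ndarray
    ) -> tuple[float, float, float]:
        """(vdw, elec, bond) energy of all pairs with >= 1 moving atom."""
        n = self.topology.n_atoms
        moving = np.asarray(moving, int)
        mask = np.zeros(n, bool)
        mask[moving] = True
        static = np.nonzero(~mask)[0]
        e_vdw = e_el = 0.0
        if len(moving):
            v, e, *_ = self._pair_terms(coords, moving, static, False)
            e_vdw += float(v.sum())
            e_el += float(e.sum())
            v, e, *_ = self._pair_terms(coords, moving, moving, False)
            e_vdw += 0.5 * float(v.sum())
            e_el += 0.5 * float(e.sum())
        e_bond = self._bond_energy(coords, mask)
        return e_vdw, e_el, e_bond

    def _bond_energy(self, coords, moving_mask=None) -> float:
        b = self.topology.bonds
        if not len(b):
            return 0.0
        i, j = b[:, 0].astype(int), b[:, 1].astype(int)
        if moving_mask is not None:
            sel = moving_mask[i] | moving_mask[j]
            if not sel.any():
                return 0.0
            i, j, b = i[sel], j[sel], b[sel]
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        return float((b[:, 3] * (r - b[:, 2]) ** 2).sum())

    def subset_gradient(
        self, coords: np.ndarray, moving: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Energy of pairs touching the moving set, and dE/dxyz for the
        moving atoms (shape (len(moving), 3)).  Includes bond terms."""
        n = self.topology.n_atoms
        moving = np.asarray(moving, int)
        mask = np.zeros(n, bool)
        mask[moving] = True
        static = np.nonzero(~mask)[0]
        grad = np.zeros((len(moving), 3))
        energy = 0.0
        if len(moving):
            v, e, de, d, r = self._pair_terms(coords, moving, static, True)
            energy += float(v.sum() + e.sum())
            grad += ((de / r)[:, :, None] * d).sum(axis=1)
            v, e, de, d, r = self._pair_terms(coords, moving, moving, True)
            energy += 0.5 * float(v.sum() + e.sum())
            grad += ((de / r)[:, :, None] * d).sum(axis=1)
        # bonds
        b = self.topology.bonds
        if len(b):
            i, j = b[:, 0].astype(int), b[:, 1].astype(int)
            sel = mask[i] | mask[j]
            if sel.any():
                i, j, bb = i[sel], j[sel], b[sel]
                d = coords[i] - coords[j]
                r = np.linalg.norm(d, axis=1)
                energy += float((bb[:, 3] * (r - bb[:, 2]) ** 2).sum())
                f = (2.0 * bb[:, 3] * (r - bb[:, 2]) / np.maximum(r, 1e-12))[:, None] * d
                pos = {a: k for k, a in enumerate(moving)}
                for row, (ii, jj) in enumerate(zip(i, j)):
                    if ii in pos:
                        grad[pos[ii]] += f[row]
                    if jj in pos:
                        grad[pos[jj]] -= f[row]
        return energy, grad

    def full_energy(self, coords: np.ndarray, n_channel: int | None = None) -> EnergyBreakdown:
        """Breakdown over all pairs; if ``n_channel`` is given, atoms
        [n_channel:] are the ligand and the cross vdw+elec sum is reported
        as the ligand-channel interaction energy."""
        n = self.topology.n_atoms
        idx = np.arange(n)
        v, e, *_ = self._pair_terms(coords, idx, idx, False)
        breakdown = EnergyBreakdown(
            vdw=0.5 * float(v.sum()),
            elec=0.5 * float(e.sum()),
            bonds=self._bond_energy(coords),
        )
        if n_channel is not None and n_channel < n:
            breakdown.ligand_channel_interaction = float(
                v[:n_channel, n_channel:].sum() + e[:n_channel, n_channel:].sum()
            )
        return breakdown

    def interaction_energy(self, coords: np.ndarray, n_channel: int) -> float:
        """Ligand-channel cross vdw+elec sum only."""
        ch = np.arange(n_channel)
        lig = np.arange(n_channel, self.topology.n_atoms)
        v, e, *_ = self._pair_terms(coords, lig, ch, False)
        return float(v.sum() + e.sum())


def total_energy(
    structure: ChannelStructure,
    ligand: LigandModel | None = None,
    params: EnergyParams | None = None,
    *,
    channel_topology: Topology | None = None,
    pose: LigandPose | None = None,
    torsion_angles: Sequence[float] | None = None,
) -> EnergyBreakdown:
    """Total nonbonded + bond energy of a channel (optionally with a posed
    ligand), equal to the brute-force double loop over all atom pairs with
    the standard exclusion rules."""
    params = params or EnergyParams()
    if channel_topology is None:
        channel_topology = default_channel_topology(structure)
    if ligand is None:
        topo = channel_topology
        coords = structure.coords
        n_channel = None
    else:
        topo = combine_topologies(channel_topology, ligand_topology(ligand))
        coords = np.vstack([structure.coords, ligand.coords(pose, torsion_angles)])
        n_channel = channel_topology.n_atoms
    model = NonbondedModel(topo, params)
    breakdown = model.full_energy(coords, n_channel)
    if ligand is not None and params.use_torsion and params.torsion_barrier > 0.0:
        ang = np.zeros(len(ligand.torsions)) if torsion_angles is None else np.asarray(torsion_angles)
        breakdown.torsion = float(
            (0.5 * params.torsion_barrier * (1.0 + np.cos(3.0 * ang))).sum()
        )
    return breakdown
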
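"""Synthetic four-repeat pseudo-channels and blocker-like toy ligands.

The generator builds a coarse (one-to-two beads per residue) pore domain
with the architecture the analysis protocols assume:

* four repeats in pseudo-4-fold arrangement around the z (pore) axis, each
  contributing an outer helix (S5 / segment ``o``), a P-loop (``p``), an
  inner helix (S6 / segment ``i``), an S4-S5 linker (``k``) and a 5-bead S4
  stub of "gating charge" positions for the deactivation protocol;
* a cation-attractive ring of carbonyl-like oxygen beads at the outer-pore
  bottom (one per repeat, at the p48-equivalent position);
* lateral fenestrations between adjacent repeats whose width (the planted
  inter-repeat S6-S6 gap at mid-membrane) is a direct parameter;
* mild electronegative "interim site" attractors midway along each
  repeat-interface, emulating the polar/aromatic lipid-facing residues that
  can host a cationic ligand on its way in or out;
* planted lipid-facing aromatic/polar side chains per interface so the
  census operations have a known ground truth.

Segment chains are held together by harmonic bonds, and the repeat-r linker
is bonded to the bottom of the neighbouring repeat's S5/S6 (the domain-swap
contact), so pulling S4 down deforms the neighbour interface the way the
deactivation protocol expects.

Toy ligands: ``mex_like`` (ammonium bead + short linker + 6-ring with a
named para-carbon, net charge +1) and ``thio_like`` (same pharmacophore
with a longer sulfur-containing linker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import Topology
from .ligand import LigandAtom, LigandModel, LigandPose, Torsion
from .structio import AtomRecord, ChannelStructure

__all__ = [
    "SyntheticChannelSpec",
    "SyntheticLigandSpec",
    "make_toy_channel",
    "make_toy_ligand",
    "plant_pocket",
    "toy_anchor_table",
    "toy_segment_ranges",
    "PlantedPocket",
]

_REPEAT_BASE = {1: 1000, 2: 2000, 3: 3000, 4: 4000}
_SEG_OFFSET = {"k": 1, "o": 11, "p": 31, "i": 51, "s4": 81}
_N_SEG = {"k": 5, "o": 14, "p": 15, "i": 19, "s4": 5}
_P_RELPOS0 = 36  # p-segment beads run p36..p50; p50 is the filter position


def _deg(a: float) -> float:
    return np.deg2rad(a)


@dataclass
class SyntheticChannelSpec:
    """Geometry and interaction knobs of the toy channel.

    ``fenestration_width`` is the planted gap (A) between the mid-membrane
    S6 beads of adjacent repeats; the S6 ring radius follows from it.
    ``attractor_strength`` is the partial-charge magnitude (e) on the four
    outer-pore carbonyl beads.
    """

    fenestration_width: float = 12.0
    attractor_strength: float = 0.45
    interface_attractor_charge: float = 0.9
    s6_radius: float = 9.9  # S6 helix-axis ring radius (width-independent)
    s5_offset: float = 5.0  # S5 ring sits this much outside the S6 ring
    helix_spacing: float = 1.5  # A rise per bead
    interface_aromatics: int = 3
    interface_polars: int = 2
    chain_bond_k: float = 5.0
    contact_bond_k: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fenestration_width <= 0:
            raise ValueError("fenestration_width must be positive")
        chord = self.s6_radius * np.sqrt(2.0)
        if not (6.0 <= self.fenestration_width <= chord - 0.5):
            raise ValueError(
                f"fenestration_width must be in [6.0, {chord - 0.5:.1f}] A "
                "for the flank side chains to fit"
            )
        if self.interface_aromatics + self.interface_polars > 7:
            raise ValueError("too many planted interface residues (max 7)")


@dataclass
class SyntheticLigandSpec:
    kind: str = "mex_like"  # or "thio_like"
    ammonium_charge: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("mex_like", "thio_like"):
            raise ValueError(f"unknown ligand kind {self.kind!r}")


def toy_resnum(repeat: int, segment: str, relpos: int) -> int:
    """Residue number of a toy-channel bead; p-segment relpos is the
    universal p-numbering (p36..p54)."""
    base = _REPEAT_BASE[repeat] + _SEG_OFFSET[segment]
    if segment == "p":
        return base + (relpos - _P_RELPOS0)
    return base + (relpos - 1)


def toy_anchor_table():
    """Anchor table matching the generated annotations (labels module)."""
    from .labels import SegmentAnchorTable

    entries = []
    for r in (1, 2, 3, 4):
        entries.append((r, "k", 1, toy_resnum(r, "k", 1)))
        entries.append((r, "o", 1, toy_resnum(r, "o", 1)))
        entries.append((r, "p", 50, toy_resnum(r, "p", 50)))
        entries.append((r, "i", 1, toy_resnum(r, "i", 1)))
    return SegmentAnchorTable(entries, channel="toy")


def toy_segment_ranges() -> dict[tuple[int, str], tuple[int, int]]:
    out = {}
    for r in (1, 2, 3, 4):
        for seg in ("k", "o", "p", "i"):
            lo = _REPEAT_BASE[r] + _SEG_OFFSET[seg]
            out[(r, seg)] = (lo, lo + _N_SEG[seg] - 1)
    return out


def _cyl(rho: float, phi: float, z: float) -> np.ndarray:
    return np.array([rho * np.cos(phi), rho * np.sin(phi), z])


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[AtomRecord] = []
        self.xyz: list[np.ndarray] = []
        self.types: list[str] = []
        self.charges: list[float] = []
        self.ionized: list[bool] = []
        self.bonds: list[tuple[int, int, float]] = []  # i, j, k_spring
        self.serial = 0

    def add(self, name, element, resname, resnum, chain, pos, type_, charge=0.0,
            ionized=False, het=False) -> int:
        self.serial += 1
        self.atoms.append(
            AtomRecord(self.serial, name, element, resname, resnum, chain, het)
        )
        self.xyz.append(np.asarray(pos, float))
        self.types.append(type_)
        self.charges.append(charge)
        self.ionized.append(ionized)
        return self.serial - 1

    def bond(self, i: int, j: int, k: float) -> None:
        self.bonds.append((i, j, k))

    def finish(self, annotations, name) -> tuple[ChannelStructure, Topology]:
        coords = np.array(self.xyz)
        structure = ChannelStructure(self.atoms, coords, annotations, name=name)
        rows = [
            [i, j, float(np.linalg.norm(coords[i] - coords[j])), k]
            for i, j, k in self.bonds
        ]
        topo = Topology(
            self.types,
            np.array(self.charges),
            np.array(self.ionized, bool),
            np.array(rows, float).reshape(-1, 4),
        )
        structure.topology = topo
        return structure, topo


def make_toy_channel(spec: SyntheticChannelSpec | None = None) -> ChannelStructure:
    """Build a toy four-repeat pore domain.

    The returned structure carries its explicit nonbonded topology (types,
    charges, bonds) in ``structure.topology``.  Pore axis is +z through the
    origin, extracellular side up.  Construction is deterministic.
    """
    spec = spec or SyntheticChannelSpec()
    w = spec.fenestration_width
    r6 = spec.s6_radius
    r5 = r6 + spec.s5_offset
    dz = spec.helix_spacing
    b = _Builder()
    chain_names = {1: "A", 2: "B", 3: "C", 4: "D"}
    annotations: dict[int, tuple[int, str]] = {}
    seg_atoms: dict[tuple[int, str], list[int]] = {}

    planted = _planted_interface_residues(spec)

    # fenestration flanks: bulky united side chains (one per window side,
    # residues i6 of repeat r and i9 of repeat r+1) protrude along the
    # S6-to-S6 chord; their separation IS the fenestration width
    flank_z = {6: 10.0 - 5 * dz, 9: 10.0 - 8 * dz}
    d_xy = np.sqrt(w**2 - (flank_z[6] - flank_z[9]) ** 2)
    chord_xy = r6 * np.sqrt(2.0)
    protrusion = (chord_xy - d_xy) / 2.0

    for r in (1, 2, 3, 4):
        phi = _deg(90.0 * (r - 1))
        chain = chain_names[r]

        # S6 (i): vertical bead column; flank side chains on i6 (toward the
        # forward interface r/(r+1)) and i9 (toward the backward interface)
        idx_i = []
        for n in range(1, _N_SEG["i"] + 1):
            resnum = toy_resnum(r, "i", n)
            z = 10.0 - (n - 1) * dz
            pos = _cyl(r6, phi, z)
            if n in (6, 7, 8, 9):
                resname, cb_dir = "PHE", None
            else:
                resname, cb_dir = _residue_identity(planted, r, "i", n)
            ia = b.add("CA", "C", resname, resnum, chain, pos, "BB")
            idx_i.append(ia)
            annotations[resnum] = (r, "i")
            if n in (6, 7, 8, 9):
                # four bulky flank side chains line the window: i6/i8 reach
                # toward the forward interface, i7/i9 toward the backward
                # one; the beads are bonded in a packed aromatic cluster
                other_phi = phi + _deg(90.0) if n in (6, 8) else phi - _deg(90.0)
                u_chord = _cyl(r6, other_phi, z) - pos
                u_chord /= np.linalg.norm(u_chord)
                cb = pos + protrusion * u_chord
                ib = b.add("CB", "C", resname, resnum, chain, cb, "FL")
                b.bond(ia, ib, 10.0)
                if n > 6:
                    b.bond(prev_flank_cb, ib, spec.chain_bond_k)
                prev_flank_cb = ib
            elif cb_dir is not None:
                cb = pos + 1.5 * cb_dir(phi, pos)
                ib = b.add("CB", "C", resname, resnum, chain, cb, "C")
                b.bond(ia, ib, 10.0)
        seg_atoms[(r, "i")] = idx_i

        # S5 (o): outer helix, azimuthally behind its own S6 (keeps the
        # r/(r+1) interface window open for egress)
        idx_o = []
        phi_o = phi - _deg(10.0)
        for n in range(1, _N_SEG["o"] + 1):
            resnum = toy_resnum(r, "o", n)
            z = -11.5 + (n - 1) * dz  # ordered bottom-up (N-term at linker)
            pos = _cyl(r5, phi_o, z)
            resname, cb_dir = _residue_identity(planted, r, "o", n)
            ia = b.add("CA", "C", resname, resnum, chain, pos, "BB")
            idx_o.append(ia)
            annotations[resnum] = (r, "o")
            if cb_dir is not None:
                cb = pos + 1.5 * cb_dir(phi_o, pos)
                ib = b.add("CB", "C", resname, resnum, chain, cb, "C")
                b.bond(ia, ib, 10.0)
        seg_atoms[(r, "o")] = idx_o

        # P-loop (p): membrane-descending helix from the outer rim to the
        # selectivity-filter position p50 at the outer-pore bottom
        idx_p = []
        phi_p = phi + _deg(25.0)
        for relpos in range(_P_RELPOS0, _P_RELPOS0 + _N_SEG["p"]):
            resnum = toy_resnum(r, "p", relpos)
            f = (relpos - _P_RELPOS0) / (50 - _P_RELPOS0)
            rho = 13.0 - f * (13.0 - 3.2)
            z = 18.0 - f * (18.0 - 3.0)
            pos = _cyl(rho, phi_p, z)
            # the p48 bead carries the carbonyl charge: the four of them
            # form the cation-attractive ring at the outer-pore bottom
            charge = -spec.attractor_strength if relpos == 48 else 0.0
            ia = b.add(
                "CA", "C", "GLY" if relpos == 50 else "THR", resnum, chain,
                pos, "BB", charge=charge,
            )
            idx_p.append(ia)
            annotations[resnum] = (r, "p")
        seg_atoms[(r, "p")] = idx_p

        # S4-S5 linker (k): low arc under the gate, inward of the S6 ring,
        # sweeping from beneath the next repeat's S6 toward its own S5
        idx_k = []
        for n in range(1, _N_SEG["k"] + 1):
            resnum = toy_resnum(r, "k", n)
            frac = (n - 1) / (_N_SEG["k"] - 1)
            phi_k = phi + _deg(80.0 - 60.0 * frac)
            pos = _cyl(6.5, phi_k, -18.5)
            ia = b.add("CA", "C", "LEU", resnum, chain, pos, "BB")
            idx_k.append(ia)
            annotations[resnum] = (r, "k")
        seg_atoms[(r, "k")] = idx_k

        # S4 stub: 5 pullable gating-charge beads in the VSD position
        idx_s4 = []
        for n in range(1, _N_SEG["s4"] + 1):
            resnum = toy_resnum(r, "s4", n)
            pos = _cyl(20.0, phi + _deg(60.0), -4.0 - (n - 1) * 3.0)
            ia = b.add("CA", "C", "ARG", resnum, chain, pos, "BB")
            idx_s4.append(ia)
        seg_atoms[(r, "s4")] = idx_s4

        # interim-site attractor: an electronegative spot just outside the
        # fenestration throat, standing in for the polar/aromatic cluster
        # of the lipid-facing interface
        att_resnum = _REPEAT_BASE[r] + 91
        apos = _cyl(13.5, phi + _deg(45.0), 3.0)
        b.add(
            "O", "O", "ATT", att_resnum, chain, apos, "O",
            charge=-spec.interface_attractor_charge, het=True,
        )


    # containment lattices (bonded bead curtains standing in for the packed
    # protein that surrounds a real fenestration): a cylindrical curtain
    # seals each interface above the window and a wall in the inter-column
    # chord plane seals it below, so the flanked window is the only lateral
    # exit.  Beads overlapping protein built above are skipped.
    existing = np.array(b.xyz)

    def lattice(positions, tag, base_resnum, chain):
        grid: dict[tuple[int, int], int] = {}
        for (gi, gj), pos in positions:
            if np.linalg.norm(existing - pos, axis=1).min() < 3.2:
                continue
            idx = b.add(
                "CA", "C", tag, base_resnum + 10 * gi + gj, chain, pos, "C"
            )
            grid[(gi, gj)] = idx
        for (gi, gj), idx in grid.items():
            for ni, nj in ((gi + 1, gj), (gi, gj + 1)):
                if (ni, nj) in grid:
                    b.bond(idx, grid[(ni, nj)], spec.chain_bond_k)

    for r in (1, 2, 3, 4):
        phi = _deg(90.0 * (r - 1))
        chain = chain_names[r]
        curtain = []
        for gi, az in enumerate(np.linspace(12.0, 78.0, 6)):
            for gj, zc in enumerate((4.0, 7.0, 10.0, 13.0, 16.0, 19.0)):
                curtain.append(((gi, gj), _cyl(11.0, phi + _deg(az), zc)))
        lattice(curtain, "TUR", _REPEAT_BASE[r] + 300, chain)

        chord_a = _cyl(r6, phi, 0.0)
        chord_b = _cyl(r6, phi + _deg(90.0), 0.0)
        wall = []
        for gi, s_frac in enumerate((0.3, 0.5, 0.7)):
            base_xy = chord_a + s_frac * (chord_b - chord_a)
            for gj, zc in enumerate(
                (-16.5, -13.5, -10.5, -7.5, -4.5, 5.5, 8.5, 11.5, 14.5, 17.5)
            ):
                wall.append(((gi, gj), base_xy + np.array([0.0, 0.0, zc])))
        lattice(wall, "WAL", _REPEAT_BASE[r] + 400, chain)

    # intra-segment chain bonds and junctions
    for r in (1, 2, 3, 4):
        for seg in ("i", "o", "p", "k", "s4"):
            idx = seg_atoms[(r, seg)]
            for a, c in zip(idx, idx[1:]):
                b.bond(a, c, spec.chain_bond_k)
        b.bond(seg_atoms[(r, "s4")][-1], seg_atoms[(r, "k")][0], spec.chain_bond_k)
        b.bond(seg_atoms[(r, "k")][-1], seg_atoms[(r, "o")][0], spec.chain_bond_k)
        b.bond(seg_atoms[(r, "o")][-1], seg_atoms[(r, "p")][0], spec.chain_bond_k)
        b.bond(seg_atoms[(r, "p")][-1], seg_atoms[(r, "i")][0], spec.chain_bond_k)

    # domain-swap contacts that carry the deactivation motion: the repeat-r
    # linker runs beneath the next repeat's S6; the repeat-r S4 packs
    # against the next repeat's S5; and each S5 packs against its own S6.
    # Pulling S4_r down therefore drags S5_{r+1} down and toward repeat r,
    # which squeezes S6_{r+1} and narrows the r/(r+1) fenestration.
    coords_now = np.array(b.xyz)

    def contact(src_atoms, tgt_atoms, max_dist):
        for ia in src_atoms:
            d = np.linalg.norm(coords_now[tgt_atoms] - coords_now[ia], axis=1)
            j = int(np.argmin(d))
            if d[j] < max_dist:
                b.bond(ia, tgt_atoms[j], spec.contact_bond_k)

    for r in (1, 2, 3, 4):
        r_next = r % 4 + 1
        contact(seg_atoms[(r, "k")], seg_atoms[(r_next, "i")], 6.0)
        contact(seg_atoms[(r, "s4")], seg_atoms[(r_next, "o")], 8.5)
        contact(seg_atoms[(r, "o")], seg_atoms[(r, "i")], 6.5)

    structure, _ = b.finish(annotations, name=f"toy-channel-w{w:g}")
    return structure


def _residue_identity(planted, repeat, seg, n):
    """(resname, CB-direction function) for an o/i bead.  Default residues
    are united pore-lining leucine beads without an explicit side-chain
    bead; planted lipid-facing residues carry a CB pointing outward,
    tilted toward their interface."""
    key = (repeat, seg, n)
    if key in planted:
        resname, tilt = planted[key]

        def outward(phi_helix, pos, _tilt=tilt):
            return np.array(
                [np.cos(phi_helix + _tilt), np.sin(phi_helix + _tilt), 0.0]
            )

        return resname, outward
    return "LEU", None


def _planted_interface_residues(spec: SyntheticChannelSpec):
    """Assign lipid-facing aromatic (PHE) and polar (SER) residues to each
    interface r/(r+1): drawn alternately from S6 of repeat r (CB tilted
    toward the interface) and S6 of repeat r+1 (tilted back toward it)."""
    planted: dict[tuple[int, str, int], tuple[str, float]] = {}
    kinds = ["PHE"] * spec.interface_aromatics + ["SER"] * spec.interface_polars
    for r in (1, 2, 3, 4):
        r_next = r % 4 + 1
        # own S6 lower half faces forward (toward +45 deg), next repeat's S6
        # top faces backward; slots are spaced two apart so planted side
        # chains never sit on adjacent residues, and avoid the i6/i9 flanks
        own = [(r, "i", n, _deg(35.0)) for n in (11, 13, 15, 17, 19)]
        nxt = [(r_next, "i", n, -_deg(35.0)) for n in (2, 4)]
        order = [own[0], nxt[0], own[1], nxt[1], own[2], own[3], own[4]]
        for kind, (rr, seg, n, tilt) in zip(kinds, order):
            planted[(rr, seg, n)] = (kind, tilt)
    return planted


# ---------------------------------------------------------------------------
# ligands

def make_toy_ligand(spec: SyntheticLigandSpec | None = None) -> LigandModel:
    """Build a blocker-like toy ligand: protonated amine head, linker,
    aromatic 6-ring with the para-carbon named.  ``thio_like`` inserts a
    sulfur-containing extension so the amine-to-ring distance is longer."""
    spec = spec or SyntheticLigandSpec()
    atoms: list[LigandAtom] = [
        LigandAtom("N1", "N+", "N", charge=spec.ammonium_charge, ionized=True)
    ]
    xyz = [np.zeros(3)]
    bonds: list[tuple[int, int]] = []
    chain = ["C1"]
    if spec.kind == "thio_like":
        chain += ["S1", "C2"]
    x = 0.0
    prev = 0
    for nm in chain:
        x += 1.55
        atoms.append(
            LigandAtom(nm, "S" if nm.startswith("S") else "C", nm[0], charge=0.0)
        )
        xyz.append(np.array([x, 0.0, 0.0]))
        bonds.append((prev, len(atoms) - 1))
        prev = len(atoms) - 1
    # aromatic ring in the xy plane; CR1 bonded to the last chain atom
    ring_start = len(atoms)
    cr1_x = x + 1.5
    center = np.array([cr1_x + 1.4, 0.0, 0.0])
    for k in range(6):
        ang = np.pi + k * np.pi / 3.0  # CR1 at the near side
        atoms.append(LigandAtom(f"CR{k+1}", "CA", "C"))
        xyz.append(center + 1.4 * np.array([np.cos(ang), np.sin(ang), 0.0]))
    bonds.append((prev, ring_start))
    for k in range(6):
        bonds.append((ring_start + k, ring_start + (k + 1) % 6))
    torsions = [
        Torsion(prev, ring_start, tuple(range(ring_start + 1, ring_start + 6)))
    ]
    if spec.kind == "thio_like":
        # extra rotatable bond in the elongated linker
        torsions.append(Torsion(1, 2, tuple(range(3, len(atoms)))))
    coords = np.array(xyz)
    n_idx = 0
    ring_idx = list(range(ring_start, ring_start + 6))
    d_from_n = np.linalg.norm(coords[ring_idx] - coords[n_idx], axis=1)
    para = ring_idx[int(np.argmax(d_from_n))]
    # ring-flip automorphism: rotating the ring 180 deg about the linker
    # axis maps equivalent carbons onto each other
    flip = list(range(len(atoms)))
    flip[ring_start + 1], flip[ring_start + 5] = flip[ring_start + 5], flip[ring_start + 1]
    flip[ring_start + 2], flip[ring_start + 4] = flip[ring_start + 4], flip[ring_start + 2]
    lig = LigandModel(
        atoms,
        coords,
        bonds,
        torsions,
        anchors={"ammonium": n_idx, "para_carbon": para},
        name=spec.kind,
        symmetries=[tuple(flip)],
    )
    assert abs(lig.net_charge - spec.ammonium_charge) < 1e-12
    return lig


# ---------------------------------------------------------------------------
# pocket planting

@dataclass
class PlantedPocket:
    """Record of a planted binding site: the channel with added pocket
    beads and the pose that is the local energy optimum."""

    channel: ChannelStructure
    pose: LigandPose
    torsion_angles: np.ndarray
    ligand_coords: np.ndarray


def plant_pocket(
    channel: ChannelStructure,
    ligand: LigandModel,
    pose: LigandPose,
    torsion_angles=None,
    strength: float = 1.0,
) -> PlantedPocket:
    """Add complementary beads around the posed ligand so the pose becomes
    a deep local optimum of the interaction energy.

    For each ligand heavy atom, a pocket bead is placed at the pair's LJ
    minimum distance, on the side away from the ligand centroid; the bead
    facing the ammonium nitrogen additionally carries a negative charge.
    ``strength`` scales well depths and charges; 0 returns the channel
    unchanged.  A clashing pose (ligand atom within 70% of contact distance
    of a channel atom) is an error.
    """
    from .energy import DEFAULT_TYPE_TABLE

    topo = getattr(channel, "topology", None)
    if topo is None:
        raise ValueError("channel must carry an explicit topology (toy channel)")
    torsion_angles = (
        np.zeros(len(ligand.torsions)) if torsion_angles is None
        else np.asarray(torsion_angles, float)
    )
    lig_xyz = ligand.coords(pose, torsion_angles)
    # clash check against existing channel atoms
    d = np.linalg.norm(channel.coords[:, None, :] - lig_xyz[None, :, :], axis=-1)
    if float(d.min()) < 2.2:
        raise ValueError(f"pose clashes with channel (min distance {d.min():.2f} A)")
    if strength == 0.0:
        return PlantedPocket(channel, pose.copy(), torsion_angles.copy(), lig_xyz)

    new = channel.copy()
    centroid = lig_xyz.mean(axis=0)
    pk = DEFAULT_TYPE_TABLE["PK"]
    atoms = list(new.atoms)
    coords = [new.coords]
    types = list(topo.type_names)
    charges = list(topo.charge)
    ionized = list(topo.ionized)
    serial = max(a.serial for a in atoms)
    resnum = 9000
    placed: list[np.ndarray] = []
    rmin_lig = np.array([DEFAULT_TYPE_TABLE[a.type].rmin_half for a in ligand.atoms])
    for i, a in enumerate(ligand.atoms):
        t = DEFAULT_TYPE_TABLE[a.type]
        direction = lig_xyz[i] - centroid
        nrm = np.linalg.norm(direction)
        candidates = []
        if nrm > 1e-9:
            candidates.append(direction / nrm)
        candidates += [
            np.array([0.0, 0.0, 1.0]),
            np.array([0.0, 0.0, -1.0]),
            np.array([1.0, 0.0, 0.0]),
            np.array([-1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([0.0, -1.0, 0.0]),
        ]
        bead_pos = None
        for d in candidates:
            cand = lig_xyz[i] + d * (t.rmin_half + pk.rmin_half)
            # the bead must touch only its own atom: no clash with the rest
            # of the ligand, previously placed beads, or the channel
            d_lig = np.linalg.norm(lig_xyz - cand, axis=1)
            ok_lig = all(
                d_lig[j] >= rmin_lig[j] + pk.rmin_half - 0.1
                for j in range(len(ligand.atoms))
                if j != i
            )
            ok_prev = all(
                np.linalg.norm(p - cand) >= 2.0 * pk.rmin_half - 0.6 for p in placed
            )
            ok_chan = np.linalg.norm(channel.coords - cand, axis=1).min() >= 3.2
            if ok_lig and ok_prev and ok_chan:
                bead_pos = cand
                break
        if bead_pos is None:
            continue
        placed.append(bead_pos)
        serial += 1
        resnum += 1
        atoms.append(AtomRecord(serial, "PK", "C", "PKT", resnum, "Z", het=True))
        coords.append(bead_pos[None, :])
        types.append("PK")
        charges.append(-1.0 * strength if a.ionized else -0.15 * strength)
        ionized.append(False)
    if not placed:
        raise ValueError("no valid pocket bead positions around this pose")
    out = ChannelStructure(
        atoms, np.vstack(coords), dict(new.annotations), new.pore_axis, new.name + "+pocket"
    )
    out.topology = Topology(
        types, np.array(charges), np.array(ionized, bool), topo.bonds.copy()
    )
    return PlantedPocket(out, pose.copy(), torsion_angles.copy(), lig_xyz)
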
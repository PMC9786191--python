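"""Structure I/O and rigid superposition.

Structures are held in a light :class:`ChannelStructure` container: a flat
atom table (numpy coordinates + per-atom metadata), optional pore-domain
segment annotations (residue number -> (repeat, segment letter)), and a pore
axis convention.  After alignment the pore axis is +z with the extracellular
side at positive z; coordinates are in Angstrom, residue numbering 1-based.

Reading and writing standard formats (PDB, mmCIF, multi-model PDB
trajectories) is delegated to gemmi.  Superposition is a Kabsch fit of
Calpha atoms over a residue selection — by convention the P1 pore helices,
the most 3D-conserved segment of P-loop channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ChannelStructure",
    "Transform",
    "read_structure",
    "write_structure",
    "write_trajectory",
    "superpose",
    "cbeta_coord",
]

_SOLVENT = {"HOH", "WAT", "DOD"}


@dataclass
class AtomRecord:
    """Metadata of one atom; coordinates live in the owning structure."""

    serial: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    het: bool = False
    occupancy: float = 1.0
    bfactor: float = 0.0


class ChannelStructure:
    """Atom table + coordinates + pore-domain annotations.

    ``annotations`` maps residue number -> (repeat, segment letter) for
    pore-domain residues; residues absent from it (voltage sensors, ligands)
    are unlabelled.  ``pore_axis`` is (point, unit direction), by default the
    z axis through the origin.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        coords: np.ndarray,
        annotations: Mapping[int, tuple[int, str]] | None = None,
        pore_axis: tuple[np.ndarray, np.ndarray] | None = None,
        name: str = "",
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(atoms)}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.atoms = list(atoms)
        self.coords = coords
        self.annotations = dict(annotations or {})
        if pore_axis is None:
            pore_axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
        point, direction = (np.asarray(pore_axis[0], float), np.asarray(pore_axis[1], float))
        n = np.linalg.norm(direction)
        if not np.isclose(n, 1.0, atol=1e-8):
            direction = direction / n
        self.pore_axis = (point, direction)
        self.name = name
        # explicit nonbonded topology (types/charges/bonds), attached by the
        # synthetic generator; None means "derive a default when scoring"
        self.topology = None
        self._index: dict[tuple[int, str], int] | None = None

    # -- lookup ---------------------------------------------------------

    def _build_index(self) -> dict[tuple[int, str], int]:
        if self._index is None:
            self._index = {}
            for i, a in enumerate(self.atoms):
                self._index.setdefault((a.resnum, a.name), i)
        return self._index

    def atom_index(self, resnum: int, name: str) -> int:
        idx = self._build_index().get((resnum, name))
        if idx is None:
            raise KeyError(f"no atom {name!r} in residue {resnum}")
        return idx

    def has_atom(self, resnum: int, name: str) -> bool:
        return (resnum, name) in self._build_index()

    def residue_atoms(self, resnum: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.resnum == resnum]

    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.resnum, None)
        return list(seen)

    def resname(self, resnum: int) -> str:
        i = self.residue_atoms(resnum)
        if not i:
            raise KeyError(f"no residue {resnum}")
        return self.atoms[i[0]].resname

    def ca_coord(self, resnum: int) -> np.ndarray:
        return self.coords[self.atom_index(resnum, "CA")]

    def validate_annotations(self) -> list[str]:
        """Warnings for annotated residues without a Calpha atom."""
        warnings = []
        for resnum in self.annotations:
            if not self.has_atom(resnum, "CA"):
                warnings.append(f"annotated residue {resnum} has no CA atom")
        return warnings

    # -- copies / motion ------------------------------------------------

    def copy(self) -> "ChannelStructure":
        new = ChannelStructure(
            [AtomRecord(**vars(a)) for a in self.atoms],
            self.coords.copy(),
            dict(self.annotations),
            (self.pore_axis[0].copy(), self.pore_axis[1].copy()),
            self.name,
        )
        new.topology = self.topology
        return new

    def transformed(self, transform: "Transform") -> "ChannelStructure":
        new = self.copy()
        new.coords = transform.apply(self.coords)
        new.pore_axis = (
            transform.apply(self.pore_axis[0][None, :])[0],
            self.pore_axis[1] @ transform.rotation.T,
        )
        return new


@dataclass
class Transform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# reading / writing

def _detect_format(path: Path, format: str | None) -> gemmi.CoorFormat:
    if format is not None:
        return {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[format]
    return gemmi.CoorFormat.Detect


def read_structure(
    path,
    format: str | None = None,
    keep_solvent: bool = False,
) -> ChannelStructure:
    """Read a PDB or mmCIF file into a :class:`ChannelStructure`.

    Heteroatoms (ligands, ions) are retained and flagged ``het``; solvent
    is dropped by default.  Alternate conformers are reduced to the
    highest-occupancy one (ties broken by altloc identifier).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    return _from_gemmi_model(st[0], name=st.name or path.stem, keep_solvent=keep_solvent)


def _from_gemmi_model(model: gemmi.Model, name: str, keep_solvent: bool) -> ChannelStructure:
    atoms: list[AtomRecord] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            if not keep_solvent and res.name in _SOLVENT:
                continue
            het = res.het_flag == "H"
            # highest-occupancy altloc wins; tie-break by altloc letter
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ + 1e-12
                    or (abs(atom.occ - prev.occ) <= 1e-12 and atom.altloc < prev.altloc)
                ):
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        resname=res.name,
                        resnum=res.seqid.num,
                        chain=chain.name,
                        het=het,
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                    )
                )
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    return ChannelStructure(atoms, np.array(xyz, float).reshape(len(atoms), 3), name=name)


def _to_gemmi(structures: Sequence[ChannelStructure], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for imodel, s in enumerate(structures, start=1):
        model = gemmi.Model(imodel)
        # group atoms by chain, then by residue, building each gemmi object
        # completely before adding it (gemmi's add_* methods copy)
        chains: dict[str, dict[tuple[int, str, bool], list[tuple[AtomRecord, np.ndarray]]]] = {}
        for a, pos in zip(s.atoms, s.coords):
            chains.setdefault(a.chain or "A", {}).setdefault(
                (a.resnum, a.resname, a.het), []
            ).append((a, pos))
        for chain_name, residues in chains.items():
            chain = gemmi.Chain(chain_name)
            for (resnum, resname, het), members in residues.items():
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "H" if het else "A"
                for a, pos in members:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.occ = a.occupancy
                    atom.b_iso = a.bfactor
                    atom.pos = gemmi.Position(*pos)
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: ChannelStructure, path) -> None:
    """Write a single structure as PDB (coordinates to 0.001 A)."""
    _to_gemmi([structure], structure.name or "model").write_pdb(str(path))


def write_trajectory(structures: Sequence[ChannelStructure], path) -> None:
    """Write an ordered list of conformations as a multi-model PDB.

    All structures must share the atom ordering of the first (same atoms,
    different coordinates), as produced by the sampling protocols.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("empty trajectory")
    n0 = len(structures[0].atoms)
    for k, s in enumerate(structures[1:], start=2):
        if len(s.atoms) != n0:
            raise ValueError(f"model {k} has {len(s.atoms)} atoms, expected {n0}")
    _to_gemmi(structures, structures[0].name or "trajectory").write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition

def superpose(
    mobile: ChannelStructure,
    reference: ChannelStructure,
    selection: Iterable[int],
    atom: str = "CA",
) -> tuple[Transform, float]:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto
    ``reference`` over ``atom`` atoms of the residues in ``selection``.

    Residues missing the atom in either structure are skipped; at least 3
    paired atoms are required.  Returns the proper-rotation transform and
    the RMSD (A) after applying it.
    """
    pairs = [
        r for r in selection
        if mobile.has_atom(r, atom) and reference.has_atom(r, atom)
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired {atom} atoms, got {len(pairs)}")
    P = np.array([mobile.coords[mobile.atom_index(r, atom)] for r in pairs])
    Q = np.array([reference.coords[reference.atom_index(r, atom)] for r in pairs])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def cbeta_coord(structure: ChannelStructure, resnum: int) -> np.ndarray:
    """Cbeta coordinates of a residue; Calpha for glycine (or any residue
    lacking a Cbeta).  Raises if the residue has neither atom."""
    if structure.has_atom(resnum, "CB") and structure.resname(resnum) != "GLY":
        return structure.coords[structure.atom_index(resnum, "CB")]
    if structure.has_atom(resnum, "CA"):
        return structure.coords[structure.atom_index(resnum, "CA")]
    raise KeyError(f"residue {resnum} has neither CB nor CA")
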
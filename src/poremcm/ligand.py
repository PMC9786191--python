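"""Ligand representation: atoms, charges, rotatable torsions, rigid pose.

A ligand is a small molecule described at united-atom resolution: each atom
has a nonbonded type, a partial charge and an ``ionized`` flag (atoms of
permanently charged groups such as an ammonium nitrogen).  Internal geometry
is a reference conformer in a local frame plus named rotatable torsions;
world coordinates are obtained by applying torsion angles, then a rigid-body
pose (translation + unit quaternion).

Named anchor atoms identify pharmacophore points used by the protocols: the
``ammonium`` nitrogen (the cationic group attracted to the outer-pore
carbonyl site) and the ``para_carbon`` of the aromatic ring (the atom pulled
in egress scans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = ["LigandAtom", "LigandPose", "Torsion", "LigandModel", "ligand_rmsd"]

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "X": 12.0}


@dataclass
class LigandAtom:
    name: str
    type: str
    element: str
    charge: float = 0.0
    ionized: bool = False


@dataclass
class LigandPose:
    """Rigid-body placement: local coordinates are rotated by ``quaternion``
    (scipy scalar-last convention) and shifted by ``translation``."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quaternion: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float)
        q = np.asarray(self.quaternion, float)
        self.quaternion = q / np.linalg.norm(q)

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    def copy(self) -> "LigandPose":
        return LigandPose(self.translation.copy(), self.quaternion.copy())


@dataclass
class Torsion:
    """Rotatable bond: atoms in ``moving`` rotate about the axis from atom
    ``axis_a`` to atom ``axis_b`` (indices into the atom list)."""

    axis_a: int
    axis_b: int
    moving: tuple[int, ...]


class LigandModel:
    def __init__(
        self,
        atoms: Sequence[LigandAtom],
        ref_coords: np.ndarray,
        bonds: Iterable[tuple[int, int]] = (),
        torsions: Iterable[Torsion] = (),
        anchors: dict[str, int] | None = None,
        name: str = "ligand",
        symmetries: Iterable[Sequence[int]] = (),
    ) -> None:
        self.atoms = list(atoms)
        self.ref_coords = np.asarray(ref_coords, float)
        if self.ref_coords.shape != (len(self.atoms), 3):
            raise ValueError("ref_coords shape mismatch")
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in bonds]
        self.torsions = list(torsions)
        self.anchors = dict(anchors or {})
        self.name = name
        # topological automorphisms mapping the molecule onto itself
        # (e.g. the flip of a symmetric aromatic ring); used for
        # symmetry-corrected RMSD.  The identity is implicit.
        self.symmetries = [tuple(int(i) for i in p) for p in symmetries]

    # -- basic queries --------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def atom_index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise KeyError(f"no ligand atom named {name!r}")

    def anchor_index(self, role: str) -> int:
        if role not in self.anchors:
            raise KeyError(f"ligand {self.name!r} has no {role!r} anchor atom")
        return self.anchors[role]

    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(a.element, 12.0) for a in self.atoms])

    # -- geometry -------------------------------------------------------

    def conformer(self, torsion_angles: Sequence[float] | None = None) -> np.ndarray:
        """Local-frame coordinates after applying torsion angles (radians)."""
        xyz = self.ref_coords.copy()
        if torsion_angles is None:
            return xyz
        if len(torsion_angles) != len(self.torsions):
            raise ValueError("torsion angle count mismatch")
        for tor, angle in zip(self.torsions, torsion_angles):
            if angle == 0.0:
                continue
            a, b = xyz[tor.axis_a], xyz[tor.axis_b]
            axis = b - a
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(axis * angle)
            idx = list(tor.moving)
            xyz[idx] = rot.apply(xyz[idx] - b) + b
        return xyz

    def coords(
        self,
        pose: LigandPose | None = None,
        torsion_angles: Sequence[float] | None = None,
    ) -> np.ndarray:
        """World coordinates for a pose and torsion-angle vector."""
        xyz = self.conformer(torsion_angles)
        if pose is None:
            return xyz
        return pose.rotation().apply(xyz) + pose.translation

    def mass_center(self, coords: np.ndarray | None = None) -> np.ndarray:
        xyz = self.ref_coords if coords is None else coords
        m = self.masses()
        return (xyz * m[:, None]).sum(axis=0) / m.sum()

    # -- serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "atoms": [
                {
                    "name": a.name,
                    "type": a.type,
                    "element": a.element,
                    "charge": float(a.charge),
                    "ionized": bool(a.ionized),
                    "xyz": [float(v) for v in self.ref_coords[i]],
                }
                for i, a in enumerate(self.atoms)
            ],
            "bonds": [[self.atoms[i].name, self.atoms[j].name] for i, j in self.bonds],
            "torsions": [
                {
                    "axis": [self.atoms[t.axis_a].name, self.atoms[t.axis_b].name],
                    "moving": [self.atoms[m].name for m in t.moving],
                }
                for t in self.torsions
            ],
            "anchors": {role: self.atoms[i].name for role, i in self.anchors.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LigandModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        atoms = [
            LigandAtom(
                name=a["name"],
                type=a["type"],
                element=a.get("element", a["name"][0]),
                charge=float(a.get("charge", 0.0)),
                ionized=bool(a.get("ionized", False)),
            )
            for a in doc["atoms"]
        ]
        coords = np.array([a["xyz"] for a in doc["atoms"]], float)
        names = {a.name: i for i, a in enumerate(atoms)}
        bonds = [(names[i], names[j]) for i, j in doc.get("bonds", [])]
        torsions = [
            Torsion(
                names[t["axis"][0]],
                names[t["axis"][1]],
                tuple(names[m] for m in t["moving"]),
            )
            for t in doc.get("torsions", [])
        ]
        anchors = {role: names[n] for role, n in doc.get("anchors", {}).items()}
        return cls(atoms, coords, bonds, torsions, anchors, name=doc.get("name", "ligand"))


def ligand_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Heavy-atom RMSD between two coordinate sets in a common frame
    (no superposition — poses live in the channel frame)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate shape mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def symmetric_rmsd(ligand: LigandModel, coords_a, coords_b) -> float:
    """RMSD minimized over the ligand's topological symmetries (e.g. an
    aromatic-ring flip relabels equivalent carbons without changing the
    physical pose)."""
    a = np.asarray(coords_a, float)
    best = ligand_rmsd(a, coords_b)
    for perm in ligand.symmetries:
        best = min(best, ligand_rmsd(a[list(perm)], coords_b))
    return best
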
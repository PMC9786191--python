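"""Restraints used by the sampling protocols.

Three families:

* **Pin** — flat-bottom parabolic positional restraint on a Calpha atom:
  penalty-free within ``free_radius`` (1 A) of the template position,
  harmonic with ``force_constant`` (10 kcal/mol/A^2) beyond.  Used to
  preserve the channel fold during all protocols.
* **Plane** — holds an atom in a plane normal to the pore axis at a target
  z; the atom is free to move within the plane but not to leave it.  Used
  to pull S4 gating-charge Calpha atoms down during in-silico voltage-sensor
  deactivation.
* **Axial distance** — holds an atom (the ligand para-carbon) at a target
  cylindrical radius from the pore axis; azimuth and z are unrestricted,
  which is equivalent to a sphere of fixed radius whose centre slides along
  the axis.  Used to pull the ligand out through a fenestration.

"Not to leave the plane/radius" is realized as projection of the constrained
coordinate after each random perturbation plus a stiff harmonic
(k = 1000 kcal/mol/A^2) during minimization; after an accepted step the
violation is within ``tolerance`` (0.05 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PinRestraint",
    "PlaneRestraint",
    "AxialDistanceRestraint",
    "pin_energy",
    "plane_violation",
    "axial_distance",
    "cylindrical_radius",
]

STIFF_K = 1000.0  # kcal/mol/A^2, enforcement harmonic for plane/axial
ENFORCE_TOL = 0.05  # A


def _axis(axis):
    point, direction = axis
    return np.asarray(point, float), np.asarray(direction, float)


def cylindrical_radius(xyz: np.ndarray, axis) -> float:
    """Distance of a point from the (infinite) pore axis."""
    p, u = _axis(axis)
    d = np.asarray(xyz, float) - p
    return float(np.linalg.norm(d - (d @ u) * u))


@dataclass
class PinRestraint:
    """Flat-bottom positional pin on one atom."""

    atom_index: int
    template: np.ndarray
    free_radius: float = 1.0
    force_constant: float = 10.0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, float)
        if self.free_radius < 0 or self.force_constant < 0:
            raise ValueError("free_radius and force_constant must be >= 0")

    def energy_and_gradient(self, coords: np.ndarray, axis=None):
        d_vec = coords[self.atom_index] - self.template
        d = float(np.linalg.norm(d_vec))
        if d <= self.free_radius:
            return 0.0, {}
        excess = d - self.free_radius
        e = self.force_constant * excess**2
        g = 2.0 * self.force_constant * excess * d_vec / max(d, 1e-12)
        return e, {self.atom_index: g}


def pin_energy(deviation: float, pin: PinRestraint) -> float:
    """Closed-form pin penalty at a given deviation (A) from the template:
    0 inside the flat bottom, k*(d - free_radius)^2 beyond."""
    if deviation < 0:
        raise ValueError("deviation must be >= 0")
    excess = deviation - pin.free_radius
    return 0.0 if excess <= 0 else pin.force_constant * excess**2


@dataclass
class PlaneRestraint:
    """Constrain an atom to the plane normal to the pore axis at ``target_z``
    (z measured along the axis from the axis point)."""

    atom_index: int
    target_z: float
    force_constant: float = STIFF_K
    tolerance: float = ENFORCE_TOL

    def signed_violation(self, coords: np.ndarray, axis) -> float:
        p, u = _axis(axis)
        return float((coords[self.atom_index] - p) @ u) - self.target_z

    def energy_and_gradient(self, coords: np.ndarray, axis):
        p, u = _axis(axis)
        dz = self.signed_violation(coords, axis)
        return self.force_constant * dz**2, {
            self.atom_index: 2.0 * self.force_constant * dz * u
        }

    def project(self, coords: np.ndarray, axis) -> None:
        """Snap the atom back into the plane (in place)."""
        p, u = _axis(axis)
        dz = self.signed_violation(coords, axis)
        coords[self.atom_index] -= dz * u


def plane_violation(structure, restraint: PlaneRestraint) -> float:
    """|z_atom - target_z| along the structure's pore axis (A)."""
    coords = structure.coords if hasattr(structure, "coords") else np.asarray(structure)
    axis = structure.pore_axis if hasattr(structure, "pore_axis") else (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    return abs(restraint.signed_violation(coords, axis))


@dataclass
class AxialDistanceRestraint:
    """Constrain an atom to a target cylindrical radius about the pore axis
    (azimuth and axial position fully free)."""

    atom_index: int
    target_radius: float
    force_constant: float = STIFF_K
    tolerance: float = ENFORCE_TOL

    def __post_init__(self) -> None:
        if self.target_radius < 0:
            raise ValueError("target radius must be >= 0")

    def radius(self, coords: np.ndarray, axis) -> float:
        return cylindrical_radius(coords[self.atom_index], axis)

    def energy_and_gradient(self, coords: np.ndarray, axis):
        p, u = _axis(axis)
        d = coords[self.atom_index] - p
        radial = d - (d @ u) * u
        rho = float(np.linalg.norm(radial))
        drho = rho - self.target_radius
        if rho < 1e-9:
            return self.force_constant * drho**2, {}
        g = 2.0 * self.force_constant * drho * radial / rho
        return self.force_constant * drho**2, {self.atom_index: g}

    def radial_correction(self, coords: np.ndarray, axis) -> np.ndarray:
        """Translation that, applied rigidly to the ligand, puts the
        restrained atom exactly at the target radius."""
        p, u = _axis(axis)
        d = coords[self.atom_index] - p
        radial = d - (d @ u) * u
        rho = float(np.linalg.norm(radial))
        if rho < 1e-9:
            # atom on the axis: pick an arbitrary radial direction
            radial = np.array([1.0, 0.0, 0.0]) - u[0] * u
            rho = float(np.linalg.norm(radial))
        return (self.target_radius - rho) * radial / rho


def axial_distance(structure, ligand_coords: np.ndarray, restraint: AxialDistanceRestraint) -> float:
    """Cylindrical radius (A) of the restrained ligand atom about the pore
    axis of ``structure``.  ``restraint.atom_index`` indexes ``ligand_coords``."""
    return cylindrical_radius(ligand_coords[restraint.atom_index], structure.pore_axis)
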
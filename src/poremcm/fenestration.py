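"""Fenestration geometry and the lipid-facing residue census.

Fenestration widths are compared through Cbeta-Cbeta distances of residue
pairs lining the lateral windows (Calpha for glycine).  The lipid-facing
census classifies, for one repeat-repeat interface, the outward-pointing
aromatic (F/W/Y) and polar (S/T/N/Q) residues that could offer interim
binding sites to a cationic ligand travelling along the membrane-channel
interface, plus special backbone/side-chain attractor atoms (glycine
backbone O, proline N, cysteine S).

"Lipid-facing" is an operational definition: a residue counts when its
side-chain centroid points away from the pore axis (within a facing-angle
threshold of the radial direction, 60 deg by default) and falls in the
azimuthal wedge of the interface.  The thresholds are explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import SegmentAnchorTable, parse_label, resolve
from .structio import ChannelStructure, cbeta_coord

__all__ = [
    "DistancePair",
    "InterfaceCensus",
    "CensusParams",
    "pair_distance",
    "compare_states",
    "classify_interface",
]

_BACKBONE = {"N", "CA", "C", "O"}
AROMATIC = {"PHE", "TRP", "TYR"}
POLAR = {"SER", "THR", "ASN", "GLN"}

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass(frozen=True)
class DistancePair:
    """Two residues whose Cbeta separation measures a fenestration width;
    members may be residue numbers or universal labels (resolved through an
    anchor table)."""

    a: int | str
    b: int | str
    interface: str = ""

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("pair members must differ")


def _resolve_member(member: int | str, anchors: SegmentAnchorTable | None) -> int:
    if isinstance(member, (int, np.integer)):
        return int(member)
    if anchors is None:
        raise ValueError(f"label {member!r} needs an anchor table to resolve")
    return resolve(parse_label(member), anchors)


def pair_distance(
    structure: ChannelStructure,
    pair: DistancePair,
    anchors: SegmentAnchorTable | None = None,
) -> float:
    """Euclidean Cbeta-Cbeta distance (A) of the pair (Calpha for glycine)."""
    ra = _resolve_member(pair.a, anchors)
    rb = _resolve_member(pair.b, anchors)
    return float(np.linalg.norm(cbeta_coord(structure, ra) - cbeta_coord(structure, rb)))


def compare_states(
    struct_a: ChannelStructure,
    struct_b: ChannelStructure,
    pairs: list[DistancePair],
    anchors: SegmentAnchorTable | None = None,
) -> pd.DataFrame:
    """Per-pair distance table for two conformational states: columns
    pair, interface, d_a, d_b, delta (= d_a - d_b).  A pair missing in
    either structure is flagged, not fatal."""
    rows = []
    for pair in pairs:
        row = {
            "pair": f"{pair.a}-{pair.b}",
            "interface": pair.interface,
            "d_a": np.nan,
            "d_b": np.nan,
            "delta": np.nan,
            "flag": "",
        }
        try:
            row["d_a"] = pair_distance(struct_a, pair, anchors)
            row["d_b"] = pair_distance(struct_b, pair, anchors)
            row["delta"] = row["d_a"] - row["d_b"]
        except (KeyError, ValueError) as exc:
            row["flag"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CensusParams:
    facing_angle_deg: float = 60.0  # max angle between radial and side-chain
    wedge_halfwidth_deg: float = 50.0  # azimuthal extent of one interface
    min_outward_extension: float = 0.0  # A, centroid radius minus CA radius
    aromatic: frozenset = frozenset(AROMATIC)
    polar: frozenset = frozenset(POLAR)
    segments: tuple = ("o", "p", "i")


@dataclass
class InterfaceCensus:
    interface: str
    aromatic: list[int] = field(default_factory=list)
    polar: list[int] = field(default_factory=list)
    special: list[tuple[int, str, str]] = field(default_factory=list)  # resnum, resname, atom

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.aromatic), len(self.polar)


def _parse_interface(interface) -> tuple[int, int]:
    if isinstance(interface, (tuple, list)):
        r1, r2 = int(interface[0]), int(interface[1])
    else:
        p1, p2 = str(interface).split("/")
        r1 = _ROMAN.get(p1, None) or int(p1)
        r2 = _ROMAN.get(p2, None) or int(p2)
    if r2 != r1 % 4 + 1:
        raise ValueError(f"interface must pair adjacent repeats, got {r1}/{r2}")
    return r1, r2


def _azimuth(v: np.ndarray) -> float:
    return float(np.arctan2(v[1], v[0]))


def _ang_dist(a: float, b: float) -> float:
    return abs((a - b + np.pi) % (2 * np.pi) - np.pi)


def classify_interface(
    structure: ChannelStructure,
    interface,
    params: CensusParams | None = None,
) -> InterfaceCensus:
    """Census of lipid-facing residues of one repeat interface (e.g.
    ``"III/IV"`` or ``(3, 4)``).  Requires segment annotations and a
    defined pore axis."""
    params = params or CensusParams()
    r1, r2 = _parse_interface(interface)
    if not structure.annotations:
        raise ValueError("structure has no segment annotations")
    p0, u = structure.pore_axis

    def radial_xy(x: np.ndarray) -> np.ndarray:
        d = x - p0
        return d - (d @ u) * u

    # interface bisector azimuth from the two repeats' CA centroids
    centers = {}
    for r in (r1, r2):
        pts = [
            structure.ca_coord(resnum)
            for resnum, (rep, seg) in structure.annotations.items()
            if rep == r and seg in params.segments and structure.has_atom(resnum, "CA")
        ]
        if not pts:
            raise ValueError(f"no annotated pore-domain residues for repeat {r}")
        centers[r] = radial_xy(np.mean(pts, axis=0))
    bis = centers[r1] / np.linalg.norm(centers[r1]) + centers[r2] / np.linalg.norm(centers[r2])
    bisector = _azimuth(bis)

    census = InterfaceCensus(interface=f"{r1}/{r2}")
    cos_facing = np.cos(np.deg2rad(params.facing_angle_deg))
    for resnum, (rep, seg) in sorted(structure.annotations.items()):
        if rep not in (r1, r2) or seg not in params.segments:
            continue
        idx = structure.residue_atoms(resnum)
        names = {structure.atoms[i].name: i for i in idx}
        resname = structure.atoms[idx[0]].resname
        if "CA" not in names:
            continue
        ca = structure.coords[names["CA"]]
        # special attractor atoms are positional features, not side chains
        if resname == "GLY" and "O" in names:
            if _ang_dist(_azimuth(radial_xy(ca)), bisector) <= np.deg2rad(params.wedge_halfwidth_deg):
                census.special.append((resnum, resname, "O"))
        if resname == "PRO" and "N" in names:
            if _ang_dist(_azimuth(radial_xy(ca)), bisector) <= np.deg2rad(params.wedge_halfwidth_deg):
                census.special.append((resnum, resname, "N"))
        if resname == "CYS":
            s_atom = "SG" if "SG" in names else ("S" if "S" in names else None)
            if s_atom and _ang_dist(_azimuth(radial_xy(ca)), bisector) <= np.deg2rad(params.wedge_halfwidth_deg):
                census.special.append((resnum, resname, s_atom))
        side = [i for i in idx if structure.atoms[i].name not in _BACKBONE]
        if not side:
            continue
        centroid = structure.coords[side].mean(axis=0)
        direction = centroid - ca
        d_xy = direction - (direction @ u) * u
        nd = np.linalg.norm(d_xy)
        if nd < 1e-6:
            continue
        rad = radial_xy(ca)
        nr = np.linalg.norm(rad)
        if nr < 1e-6:
            continue
        # outward-facing test
        if (d_xy @ rad) / (nd * nr) < cos_facing:
            continue
        # outward-extension proxy
        ext = np.linalg.norm(radial_xy(centroid)) - nr
        if ext < params.min_outward_extension:
            continue
        # azimuthal wedge membership by side-chain direction
        if _ang_dist(_azimuth(d_xy), bisector) > np.deg2rad(params.wedge_halfwidth_deg):
            continue
        if resname in params.aromatic:
            census.aromatic.append(resnum)
        elif resname in params.polar:
            census.polar.append(resnum)
    return census
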
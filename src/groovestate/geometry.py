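"""Geometric primitives for binding-groove analysis.

Distances, side-chain dihedral angles, rotamer-regime classification,
distance-based hydrogen-bond calls and B-factor averages.  All angles are
degrees; all distances are angstroms; B-factors are Å².

Hydrogen bonds are called on heavy-atom donor--acceptor distance alone
(default cutoff 3.5 Å, inclusive), with no angular term: the survey this
package supports is built on crystal structures without hydrogen positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "GeometryError",
    "HBondCriterion",
    "RotamerBins",
    "GAMMA_ATOMS",
    "wrap_angle",
    "min_distance",
    "dihedral",
    "chi1",
    "classify_rotamer",
    "hbond_present",
    "mean_bfactor",
]


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


def wrap_angle(angle):
    """Wrap an angle (degrees) into the periodic interval (-180, 180].

    Works elementwise on arrays.  180 maps to 180, -180 maps to 180.
    """
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def _as_coords(atoms) -> np.ndarray:
    """Coerce an atom collection (AtomRecords or raw 3-vectors) to (n, 3)."""
    if hasattr(atoms, "coords"):  # ResidueView-like
        arr = np.asarray(atoms.coords, dtype=float)
    else:
        seq = list(atoms) if isinstance(atoms, Iterable) else [atoms]
        rows = []
        for item in seq:
            if hasattr(item, "position"):
                rows.append(np.asarray(item.position, dtype=float))
            else:
                rows.append(np.asarray(item, dtype=float))
        arr = np.asarray(rows, dtype=float)
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise GeometryError(f"expected 3-D coordinates, got shape {arr.shape}")
    return arr


def min_distance(atoms_a, atoms_b) -> float:
    """Minimum Euclidean distance (Å) over all cross pairs of two atom sets.

    Accepts AtomRecord collections, residue views, or raw coordinate arrays.
    Symmetric in its arguments.
    """
    a = _as_coords(atoms_a)
    b = _as_coords(atoms_b)
    if a.size == 0 or b.size == 0:
        raise GeometryError("min_distance requires two non-empty atom sets")
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees, in (-180, 180]) defined by four points.

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of the p1 plane onto the p4 plane is positive.  The angle is invariant
    under rigid-body motion and satisfies
    ``dihedral(p4, p3, p2, p1) == dihedral(p1, p2, p3, p4)``.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise GeometryError("central bond is degenerate (p2 == p3)")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points give an undefined dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


#: γ-position atom that closes the χ1 torsion N-CA-CB-γ, by residue type.
GAMMA_ATOMS = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "THR": "OG1", "SER": "OG", "CYS": "SG",
}


def chi1(residue_view) -> float:
    """χ1 side-chain dihedral (degrees) of a residue: N-CA-CB-γ.

    The γ atom is looked up from the residue type (CG for most residues,
    CG1 for Val/Ile, OG/OG1/SG for Ser/Thr/Cys).  Gly and Ala have no χ1.
    """
    name = residue_view.residue_name
    gamma = GAMMA_ATOMS.get(name)
    if gamma is None:
        raise GeometryError(f"residue type {name!r} has no χ1 dihedral")
    try:
        pts = [residue_view.atom(a).position for a in ("N", "CA", "CB", gamma)]
    except KeyError as exc:
        raise GeometryError(
            f"missing atom for χ1 of {name} {residue_view.residue_number}: {exc}"
        ) from None
    return dihedral(*pts)


@dataclass(frozen=True)
class RotamerBins:
    """±60° regimes about the three canonical χ1 rotamers.

    Regimes are half-open toward increasing angle, so the circle is
    partitioned exactly: trans = [120°, 240°), gauche− = [−120°, 0°),
    gauche+ = [0°, 120°) (all after wrapping into (−180°, 180°]).
    """

    trans_center: float = 180.0
    gauche_minus_center: float = -60.0
    gauche_plus_center: float = 60.0
    half_width: float = 60.0


def classify_rotamer(chi: float, bins: RotamerBins | None = None) -> str:
    """Assign a χ angle (degrees) to ``trans``/``gauche_minus``/``gauche_plus``.

    Exactly one regime fires for every finite angle; the result is invariant
    under adding multiples of 360°.
    """
    if not np.isfinite(chi):
        raise GeometryError("χ must be finite")
    bins = bins or RotamerBins()
    w = wrap_angle(chi)
    lo_gm = wrap_angle(bins.gauche_minus_center - bins.half_width)  # -120
    lo_gp = wrap_angle(bins.gauche_plus_center - bins.half_width)   # 0
    hi_gp = wrap_angle(bins.gauche_plus_center + bins.half_width)   # 120
    if lo_gm <= w < lo_gp:
        return "gauche_minus"
    if lo_gp <= w < hi_gp:
        return "gauche_plus"
    return "trans"


@dataclass(frozen=True)
class HBondCriterion:
    """A distance-only hydrogen-bond test between two named atom sets.

    ``donor``/``acceptor`` are (residue_key, atom_names) pairs where
    residue_key names one of the mapped groove residues.  The call is
    symmetric in practice since only the minimum heavy-atom distance enters.
    """

    donor: tuple[str, tuple[str, ...]]
    acceptor: tuple[str, tuple[str, ...]]
    cutoff: float = 3.5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.donor[1] or not self.acceptor[1]:
            raise ValueError("donor and acceptor atom sets must be non-empty")


def hbond_present(donor_atoms, acceptor_atoms, cutoff: float = 3.5) -> tuple[bool, float]:
    """Distance-criterion H-bond call: (bonded, min distance Å).

    Bonded iff the minimum heavy-atom cross distance is ≤ cutoff
    (inclusive); the distance is returned either way so that surveys can
    re-tally under a different threshold.
    """
    d = min_distance(donor_atoms, acceptor_atoms)
    return d <= cutoff, d


def mean_bfactor(atoms) -> float:
    """Arithmetic mean isotropic B-factor (Å²) over an atom selection."""
    if hasattr(atoms, "atoms"):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise GeometryError("mean_bfactor of an empty selection")
    return float(np.mean([a.bfactor for a in atoms]))
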
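"""Locked / unlocked classification of the A and F pockets.

The MHC class I binding groove switches between a peptide-bound "locked"
geometry and a peptide-receptive "unlocked" geometry through two triads of
co-switching side chains:

* A pocket — Phe9 / His70 / Tyr99.  Locked: His70 imidazole within
  hydrogen-bond distance (≤ 3.5 Å) of the Tyr99 hydroxyl and Phe9 in its
  peptide-bound rotamer.  Unlocked: the His70-Tyr99 bond released
  (> 3.5 Å) and the Phe9 ring flipped perpendicular to its peptide-bound
  orientation.
* F pocket — Arg97 / His114 / Tyr116 (with His74 and Asp77 as locking
  partners on the α1 helix).  Unlocked: Tyr116 χ1 in the gauche− regime
  with an H-bond to His114.  Partially unlocked: Tyr116 bonded to Arg97
  but not to His114.  Locked: Tyr116 χ1 trans with an H-bond to His74 or
  Asp77.

Mixed evidence yields ``indeterminate`` rather than a forced call; when
several F-pocket patterns fire simultaneously the precedence is
unlocked > partially_unlocked > locked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from . import structure_io as sio
from .geometry import (RotamerBins, chi1, classify_rotamer, hbond_present,
                       mean_bfactor, wrap_angle)

__all__ = [
    "PocketState",
    "MeasurementError",
    "TriadMeasurement",
    "LigandReport",
    "GrooveReport",
    "HBOND_ATOM_SETS",
    "HBOND_CUTOFF",
    "PHE9_LOCKED_CHI1_REF",
    "measure_groove",
    "classify_a_pocket",
    "classify_f_pocket",
]


class PocketState(str, Enum):
    LOCKED = "locked"
    PARTIALLY_UNLOCKED = "partially_unlocked"
    UNLOCKED = "unlocked"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


class MeasurementError(ValueError):
    """A groove residue or atom required for measurement is missing."""


#: Heavy-atom sets of the named hydrogen bonds (closest-partner rule).
HBOND_ATOM_SETS: dict[str, tuple[tuple[str, tuple[str, ...]],
                                 tuple[str, tuple[str, ...]]]] = {
    "his70_tyr99": (("tyr99", ("OH",)), ("his70", ("ND1", "NE2"))),
    "arg97_tyr116": (("arg97", ("NE", "NH1", "NH2")), ("tyr116", ("OH",))),
    "his114_tyr116": (("his114", ("ND1", "NE2")), ("tyr116", ("OH",))),
    "tyr116_his74": (("tyr116", ("OH",)), ("his74", ("ND1", "NE2"))),
    "tyr116_asp77": (("tyr116", ("OH",)), ("asp77", ("OD1", "OD2"))),
}

#: Distance cutoff (Å, inclusive) for every H-bond call.
HBOND_CUTOFF = 3.5

#: Peptide-bound (locked) reference χ1 of Phe9, degrees.  The unlocked
#: "perpendicular" conformation is operationalized as |Δχ1| > 60° from it.
PHE9_LOCKED_CHI1_REF = -60.0
PHE9_FLIP_THRESHOLD = 60.0


@dataclass
class TriadMeasurement:
    """Raw geometric observables of one pocket triad in one molecule."""

    pocket: str                          # "A" or "F"
    molecule_label: str = ""
    # A pocket
    his70_tyr99_distance: float | None = None
    phe9_chi1: float | None = None
    phe9_regime: str | None = None
    phe9_unlocked_conformation: bool | None = None
    # F pocket
    tyr116_chi1: float | None = None
    tyr116_regime: str | None = None
    arg97_tyr116_bonded: bool | None = None
    his114_tyr116_bonded: bool | None = None
    tyr116_his74_bonded: bool | None = None
    tyr116_asp77_bonded: bool | None = None
    distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.pocket not in ("A", "F"):
            raise ValueError("pocket must be 'A' or 'F'")
        for key, value in self.distances.items():
            if value < 0:
                raise ValueError(f"negative distance for {key}")


@dataclass
class LigandReport:
    """A hetero group in the groove with its mobility summary."""

    residue_name: str
    chain_id: str
    residue_number: int
    pocket: str                           # "A", "F" or "?" if unassignable
    mean_bfactor: float
    n_atoms: int


@dataclass
class GrooveReport:
    """All measurements and state calls for one structure entry."""

    entry_id: str
    measurements: dict[str, dict[str, TriadMeasurement]]   # molecule -> pocket
    states: dict[str, dict[str, PocketState]]              # molecule -> pocket
    ligands: list[LigandReport] = field(default_factory=list)

    @property
    def molecules(self) -> list[str]:
        return list(self.measurements)


def _residue(model: sio.StructureModel, mapping: sio.ResidueMapping,
             key: str) -> sio.ResidueView:
    number = mapping.residues[key]
    try:
        return sio.select_residue(model, mapping.heavy_chain, number)
    except sio.LookupError_:
        raise MeasurementError(
            f"{model.entry_id} molecule {mapping.molecule_label}: groove "
            f"residue {key} (number {number}) not found in chain "
            f"{mapping.heavy_chain}") from None


def _atom_set(view: sio.ResidueView, names: tuple[str, ...], key: str):
    atoms = view.atom_set(names)
    if not atoms:
        raise MeasurementError(
            f"residue {key} ({view.residue_name} {view.residue_number}) has "
            f"none of the atoms {names}")
    return atoms


def _hbond(model, mapping, bond_key: str) -> tuple[bool, float]:
    (key_a, names_a), (key_b, names_b) = HBOND_ATOM_SETS[bond_key]
    set_a = _atom_set(_residue(model, mapping, key_a), names_a, key_a)
    set_b = _atom_set(_residue(model, mapping, key_b), names_b, key_b)
    return hbond_present(set_a, set_b, cutoff=HBOND_CUTOFF)


def measure_molecule(model: sio.StructureModel, mapping: sio.ResidueMapping,
                     bins: RotamerBins | None = None,
                     phe9_reference: float = PHE9_LOCKED_CHI1_REF,
                     ) -> dict[str, TriadMeasurement]:
    """A- and F-pocket triad measurements for one asymmetric-unit molecule."""
    bins = bins or RotamerBins()
    label = mapping.molecule_label

    bonded_hy, d_hy = _hbond(model, mapping, "his70_tyr99")
    phe9 = _residue(model, mapping, "phe9")
    try:
        phe9_x1 = chi1(phe9)
    except Exception as exc:
        raise MeasurementError(f"cannot measure Phe9 χ1: {exc}") from exc
    flipped = abs(wrap_angle(phe9_x1 - phe9_reference)) > PHE9_FLIP_THRESHOLD

    a = TriadMeasurement(
        pocket="A", molecule_label=label,
        his70_tyr99_distance=d_hy,
        phe9_chi1=phe9_x1,
        phe9_regime=classify_rotamer(phe9_x1, bins),
        phe9_unlocked_conformation=flipped,
        distances={"his70_tyr99": d_hy},
    )

    tyr116 = _residue(model, mapping, "tyr116")
    try:
        t116_x1 = chi1(tyr116)
    except Exception as exc:
        raise MeasurementError(f"cannot measure Tyr116 χ1: {exc}") from exc
    f_bonds = {}
    f_dists = {}
    for bond_key in ("arg97_tyr116", "his114_tyr116", "tyr116_his74",
                     "tyr116_asp77"):
        bonded, dist = _hbond(model, mapping, bond_key)
        f_bonds[bond_key] = bonded
        f_dists[bond_key] = dist

    f = TriadMeasurement(
        pocket="F", molecule_label=label,
        tyr116_chi1=t116_x1,
        tyr116_regime=classify_rotamer(t116_x1, bins),
        arg97_tyr116_bonded=f_bonds["arg97_tyr116"],
        his114_tyr116_bonded=f_bonds["his114_tyr116"],
        tyr116_his74_bonded=f_bonds["tyr116_his74"],
        tyr116_asp77_bonded=f_bonds["tyr116_asp77"],
        distances=f_dists,
    )
    return {"A": a, "F": f}


def classify_a_pocket(m: TriadMeasurement) -> PocketState:
    """State of the A pocket from the Phe9-His70-Tyr99 triad.

    Locked: His70-Tyr99 within the 3.5 Å hydrogen-bond cutoff and Phe9 in
    its peptide-bound rotamer.  Unlocked: the bond released and Phe9
    flipped.  Any mixed pattern is indeterminate.
    """
    if m.pocket != "A":
        raise ValueError("classify_a_pocket expects an A-pocket measurement")
    bonded = m.his70_tyr99_distance <= HBOND_CUTOFF
    flipped = bool(m.phe9_unlocked_conformation)
    if bonded and not flipped:
        return PocketState.LOCKED
    if not bonded and flipped:
        return PocketState.UNLOCKED
    return PocketState.INDETERMINATE


def classify_f_pocket(m: TriadMeasurement) -> PocketState:
    """State of the F pocket from the Arg97-His114-Tyr116 triad.

    Precedence when several patterns fire: unlocked > partially_unlocked >
    locked.  The locked state accepts a Tyr116 hydroxyl bond to either
    His74 or Asp77 (both appear as locking partners on the α1 helix).
    """
    if m.pocket != "F":
        raise ValueError("classify_f_pocket expects an F-pocket measurement")
    unlocked = (m.tyr116_regime == "gauche_minus" and
                bool(m.his114_tyr116_bonded))
    partial = bool(m.arg97_tyr116_bonded) and not bool(m.his114_tyr116_bonded)
    locked = (m.tyr116_regime == "trans" and
              (bool(m.tyr116_his74_bonded) or bool(m.tyr116_asp77_bonded)))
    if unlocked:
        return PocketState.UNLOCKED
    if partial:
        return PocketState.PARTIALLY_UNLOCKED
    if locked:
        return PocketState.LOCKED
    return PocketState.INDETERMINATE


def _assign_ligand_pockets(model: sio.StructureModel,
                           mappings: Mapping[str, sio.ResidueMapping],
                           ) -> list[LigandReport]:
    """Groove hetero groups with per-ligand mean B; pocket by proximity.

    A ligand belongs to the A pocket if its centroid is nearer the Phe9 Cβ
    than the Tyr116 Cβ of the closest molecule, else to the F pocket.
    Waters are excluded.
    """
    anchors = {}
    for label, mapping in mappings.items():
        try:
            phe9 = _residue(model, mapping, "phe9").atom("CB").position
            t116 = _residue(model, mapping, "tyr116").atom("CB").position
        except (MeasurementError, sio.LookupError_):
            continue
        anchors[label] = (np.asarray(phe9), np.asarray(t116))

    out = []
    for view in model.hetero_residues():
        centroid = view.coords.mean(axis=0)
        pocket = "?"
        best = np.inf
        for phe9_cb, t116_cb in anchors.values():
            d_a = float(np.linalg.norm(centroid - phe9_cb))
            d_f = float(np.linalg.norm(centroid - t116_cb))
            if min(d_a, d_f) < best:
                best = min(d_a, d_f)
                pocket = "A" if d_a <= d_f else "F"
        out.append(LigandReport(residue_name=view.residue_name,
                                chain_id=view.chain_id,
                                residue_number=view.residue_number,
                                pocket=pocket,
                                mean_bfactor=mean_bfactor(view),
                                n_atoms=len(view.atoms)))
    return out


def measure_groove(model: sio.StructureModel,
                   mappings: Mapping[str, sio.ResidueMapping] | None = None,
                   config: Mapping | None = None,
                   bins: RotamerBins | None = None,
                   phe9_reference: float = PHE9_LOCKED_CHI1_REF,
                   ) -> GrooveReport:
    """Measure and classify both pockets for every molecule of a structure.

    ``mappings`` may be precomputed; otherwise they are resolved from
    ``config`` (or the auto heuristic).  Raises
    :class:`MeasurementError` naming the residue if a groove residue is
    missing.
    """
    if mappings is None:
        try:
            mappings = sio.resolve_chain_mapping(model, config)
        except sio.MissingResidueError as exc:
            raise MeasurementError(str(exc)) from exc
    measurements: dict[str, dict[str, TriadMeasurement]] = {}
    states: dict[str, dict[str, PocketState]] = {}
    for label, mapping in mappings.items():
        per_pocket = measure_molecule(model, mapping, bins=bins,
                                      phe9_reference=phe9_reference)
        measurements[label] = per_pocket
        states[label] = {
            "A": classify_a_pocket(per_pocket["A"]),
            "F": classify_f_pocket(per_pocket["F"]),
        }
    ligands = _assign_ligand_pockets(model, mappings)
    return GrooveReport(entry_id=model.entry_id, measurements=measurements,
                        states=states, ligands=ligands)
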
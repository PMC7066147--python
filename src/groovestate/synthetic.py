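"""Synthetic inputs for every analysis stage.

Three generators, all deterministic under a fixed seed:

* :func:`make_fixture_structure` — toy binding-groove structures.  The
  eight groove residues (Phe9, His70, His74, Asp77, Arg97, Tyr99, His114,
  Tyr116) are built from ideal amino-acid internal coordinates, side
  chains rotated to prescribed χ1 values, and rigidly placed so the named
  inter-residue distances (His70-Tyr99, the four Tyr116 partners) hit
  prescribed values exactly (to 1e-3 Å before optional coordinate noise).
  Optional dipeptide-like ligands with prescribed B-factors and polyglycine
  padding (for heavy-chain-length heuristics) are supported.  These are
  synthetic stand-ins: they reproduce prescribed groove geometry, not any
  deposited structure's full coordinates.
* :func:`sample_window` — Metropolis samples from a known periodic 1-D
  potential under the quadratic umbrella bias, the stand-in for the MD
  engine; :func:`analytic_reference_pmf` is the matching exact oracle.
* :func:`make_melt_curve` — multi-transition logistic F350/F330 curves
  with a linear baseline and homoscedastic Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import wrap_angle
from .melt import MeltCurve
from .pocket_state import (PHE9_LOCKED_CHI1_REF, PocketState, TriadMeasurement,
                           classify_a_pocket, classify_f_pocket)
from .structure_io import AtomRecord, StructureModel
from .wham import KB_KCAL, PMFProfile, UmbrellaWindowSeries, bias_energy

__all__ = [
    "FixtureValidationError",
    "LigandSpec",
    "FixtureSpec",
    "make_fixture_structure",
    "make_fixture_model",
    "PotentialSpec",
    "default_double_well",
    "analytic_reference_pmf",
    "sample_window",
    "sample_protocol",
    "make_melt_curve",
    "make_concentration_series",
]


class FixtureValidationError(ValueError):
    """Requested pocket states are inconsistent with the requested geometry."""


# ---------------------------------------------------------------------------
# Internal-coordinate residue construction


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees, package sign convention)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone() -> dict[str, np.ndarray]:
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([-math.cos(math.radians(111.0)),
                               math.sin(math.radians(111.0)), 0.0])
    o = _place_atom(n, ca, c, 1.231, 120.5, 180.0)
    cb = _place_atom(n, c, ca, 1.530, 110.5, 122.5)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _build_residue(resname: str, chi_1: float | None = None,
                   chi_2: float = 90.0) -> dict[str, np.ndarray]:
    """Ideal-geometry heavy atoms of one residue, side chain at χ1/χ2."""
    bb = _backbone()
    if resname == "GLY":
        return {k: bb[k] for k in ("N", "CA", "C", "O")}
    if resname == "ALA":
        return bb
    if chi_1 is None:
        raise ValueError(f"{resname} requires a χ1 value")
    atoms = dict(bb)
    n, ca, cb = bb["N"], bb["CA"], bb["CB"]
    cg = _place_atom(n, ca, cb, 1.52, 114.0, chi_1)
    atoms["CG"] = cg
    if resname in ("PHE", "TYR"):
        cd1 = _place_atom(ca, cb, cg, 1.39, 120.0, chi_2)
        cd2 = _place_atom(ca, cb, cg, 1.39, 120.0, chi_2 - 180.0)
        ce1 = _place_atom(cb, cg, cd1, 1.39, 120.0, 180.0)
        ce2 = _place_atom(cb, cg, cd2, 1.39, 120.0, 180.0)
        cz = _place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
        atoms.update(CD1=cd1, CD2=cd2, CE1=ce1, CE2=ce2, CZ=cz)
        if resname == "TYR":
            atoms["OH"] = _place_atom(cd1, ce1, cz, 1.38, 120.0, 180.0)
    elif resname == "HIS":
        nd1 = _place_atom(ca, cb, cg, 1.38, 122.0, chi_2)
        cd2 = _place_atom(ca, cb, cg, 1.36, 131.0, chi_2 - 180.0)
        ce1 = _place_atom(cb, cg, nd1, 1.32, 109.0, 180.0)
        ne2 = _place_atom(cg, nd1, ce1, 1.32, 108.0, 0.0)
        atoms.update(ND1=nd1, CD2=cd2, CE1=ce1, NE2=ne2)
    elif resname == "ASP":
        od1 = _place_atom(ca, cb, cg, 1.25, 118.5, chi_2)
        od2 = _place_atom(ca, cb, cg, 1.25, 118.5, chi_2 - 180.0)
        atoms.update(OD1=od1, OD2=od2)
    elif resname == "ARG":
        cd = _place_atom(ca, cb, cg, 1.52, 111.5, 180.0)
        ne = _place_atom(cb, cg, cd, 1.46, 112.0, 180.0)
        cz = _place_atom(cg, cd, ne, 1.33, 124.5, 180.0)
        nh1 = _place_atom(cd, ne, cz, 1.33, 120.0, 0.0)
        nh2 = _place_atom(cd, ne, cz, 1.33, 120.0, 180.0)
        atoms.update(CD=cd, NE=ne, CZ=cz, NH1=nh1, NH2=nh2)
    else:
        raise ValueError(f"no template for residue type {resname!r}")
    return atoms


def _rotation_between(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto unit vector u (Rodrigues)."""
    v = v / np.linalg.norm(v)
    u = u / np.linalg.norm(u)
    cross = np.cross(v, u)
    s = np.linalg.norm(cross)
    c = float(np.dot(v, u))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    k = cross / s
    kmat = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)


def _orient_contact(atoms: dict[str, np.ndarray], contact: str,
                    anchor: np.ndarray, direction, distance: float,
                    ) -> dict[str, np.ndarray]:
    """Rigidly place a residue so ``contact`` sits ``distance`` Å from
    ``anchor`` along ``direction``, with the residue body pointing away."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    target = np.asarray(anchor, dtype=float) + distance * u
    pivot = atoms[contact]
    centroid = np.mean(list(atoms.values()), axis=0)
    away = centroid - pivot
    if np.linalg.norm(away) < 1e-9:
        rot = np.eye(3)
    else:
        rot = _rotation_between(away, u)
    return {name: rot @ (pos - pivot) + target for name, pos in atoms.items()}


def _translate(atoms: dict[str, np.ndarray], ref: str,
               point) -> dict[str, np.ndarray]:
    shift = np.asarray(point, dtype=float) - atoms[ref]
    return {name: pos + shift for name, pos in atoms.items()}


# ---------------------------------------------------------------------------
# Fixture specification


@dataclass(frozen=True)
class LigandSpec:
    """A groove ligand stand-in (dipeptide/cryo-solvent) for one pocket."""

    name: str = "GM"
    pocket: str = "F"                # "A" or "F"
    mean_bfactor: float = 30.0

    def __post_init__(self):
        if self.pocket not in ("A", "F"):
            raise ValueError("ligand pocket must be 'A' or 'F'")
        if self.mean_bfactor < 0:
            raise ValueError("mean B-factor must be non-negative")


#: (name, pocket-anchor offset index) heavy atoms of the dipeptide stand-in.
_LIGAND_ATOMS = ("N1", "CA1", "C1", "O1", "N2", "CA2", "CB2", "CG2", "SD2",
                 "CE2", "C2", "O2", "OXT")


@dataclass(frozen=True)
class FixtureSpec:
    """Prescribed groove geometry (and intended states) of one molecule."""

    a_state: str | None = None           # expected A-pocket state or None
    f_state: str | None = None           # expected F-pocket state or None
    his70_tyr99_distance: float = 2.9    # Å, Tyr99 OH to nearest His70 N
    phe9_chi1: float = PHE9_LOCKED_CHI1_REF
    tyr116_chi1: float = 180.0
    arg97_tyr116_bonded: bool = False
    his114_tyr116_bonded: bool = False
    tyr116_his74_bonded: bool = True
    tyr116_asp77_bonded: bool = False
    bonded_distance: float = 2.9         # Å used when a partner flag is True
    unbonded_distance: float = 6.0       # Å used when a partner flag is False
    bfactors: tuple[tuple[str, float], ...] = ()   # (groove key, Å²)
    default_bfactor: float = 20.0
    noise_sigma: float = 0.0             # Å, Gaussian, applied last
    seed: int = 0
    chain_id: str = "A"
    chain_length: int = 8                # >= 8; extra residues are Gly padding
    light_chain_length: int = 0          # Gly residues in a β2m-like chain
    ligands: tuple[LigandSpec, ...] = ()
    tyr116_altlocs: tuple[tuple[str, float, float], ...] = ()
    # optional Tyr116 altlocs: (altloc letter, χ1, occupancy); overrides
    # tyr116_chi1 when non-empty (first entry defines placement geometry)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.chain_length < 8:
            raise ValueError("chain_length must be at least 8")
        if self.bonded_distance > 3.5 or self.unbonded_distance <= 3.5:
            raise FixtureValidationError(
                "bonded_distance must be <= 3.5 Å and unbonded_distance > 3.5 Å")
        self.validate_states()

    # -- intended-state bookkeeping -------------------------------------
    def implied_states(self) -> tuple[PocketState, PocketState]:
        """States the classifiers must return for this geometry."""
        from .geometry import classify_rotamer
        a = TriadMeasurement(
            pocket="A",
            his70_tyr99_distance=self.his70_tyr99_distance,
            phe9_chi1=self.phe9_chi1,
            phe9_regime=classify_rotamer(self.phe9_chi1),
            phe9_unlocked_conformation=abs(
                wrap_angle(self.phe9_chi1 - PHE9_LOCKED_CHI1_REF)) > 60.0,
        )
        f = TriadMeasurement(
            pocket="F",
            tyr116_chi1=self.tyr116_chi1,
            tyr116_regime=classify_rotamer(self.tyr116_chi1),
            arg97_tyr116_bonded=self.arg97_tyr116_bonded,
            his114_tyr116_bonded=self.his114_tyr116_bonded,
            tyr116_his74_bonded=self.tyr116_his74_bonded,
            tyr116_asp77_bonded=self.tyr116_asp77_bonded,
        )
        return classify_a_pocket(a), classify_f_pocket(f)

    def validate_states(self) -> None:
        implied_a, implied_f = self.implied_states()
        if self.a_state is not None and PocketState(self.a_state) != implied_a:
            raise FixtureValidationError(
                f"requested A state {self.a_state!r} inconsistent with "
                f"geometry (distance {self.his70_tyr99_distance} Å, Phe9 χ1 "
                f"{self.phe9_chi1}°) which implies {implied_a.value!r}")
        if self.f_state is not None and PocketState(self.f_state) != implied_f:
            raise FixtureValidationError(
                f"requested F state {self.f_state!r} inconsistent with "
                f"geometry which implies {implied_f.value!r}")

    @classmethod
    def for_states(cls, a_state: str, f_state: str, seed: int = 0,
                   **overrides) -> "FixtureSpec":
        """Canonical geometry presets for each nominal state combination."""
        params: dict = {"a_state": a_state, "f_state": f_state, "seed": seed}
        if a_state == "locked":
            params.update(his70_tyr99_distance=2.9,
                          phe9_chi1=PHE9_LOCKED_CHI1_REF)
        elif a_state == "unlocked":
            params.update(his70_tyr99_distance=4.3, phe9_chi1=180.0)
        else:
            raise ValueError(f"no preset for A state {a_state!r}")
        if f_state == "locked":
            params.update(tyr116_chi1=180.0, tyr116_his74_bonded=True,
                          tyr116_asp77_bonded=False,
                          arg97_tyr116_bonded=False,
                          his114_tyr116_bonded=False)
        elif f_state == "unlocked":
            params.update(tyr116_chi1=-60.0, tyr116_his74_bonded=False,
                          tyr116_asp77_bonded=False,
                          arg97_tyr116_bonded=True,
                          his114_tyr116_bonded=True)
        elif f_state == "partially_unlocked":
            params.update(tyr116_chi1=180.0, tyr116_his74_bonded=False,
                          tyr116_asp77_bonded=False,
                          arg97_tyr116_bonded=True,
                          his114_tyr116_bonded=False)
        else:
            raise ValueError(f"no preset for F state {f_state!r}")
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        data = json.loads(__import__("pathlib").Path(path).read_text())
        if "ligands" in data:
            data["ligands"] = tuple(LigandSpec(**entry)
                                    for entry in data["ligands"])
        if "bfactors" in data:
            data["bfactors"] = tuple((k, float(v))
                                     for k, v in dict(data["bfactors"]).items())
        return cls(**data)


_GROOVE_NUMBERS = {"phe9": 9, "his70": 70, "his74": 74, "asp77": 77,
                   "arg97": 97, "tyr99": 99, "his114": 114, "tyr116": 116}
_GROOVE_TYPES = {"phe9": "PHE", "his70": "HIS", "his74": "HIS",
                 "asp77": "ASP", "arg97": "ARG", "tyr99": "TYR",
                 "his114": "HIS", "tyr116": "TYR"}


def _groove_coordinates(spec: FixtureSpec) -> dict[str, dict[str, np.ndarray]]:
    """Exact (pre-noise) placement of the eight groove residues."""
    def dist(flag: bool) -> float:
        return spec.bonded_distance if flag else spec.unbonded_distance

    placed: dict[str, dict[str, np.ndarray]] = {}
    tyr99 = _build_residue("TYR", chi_1=180.0)
    placed["tyr99"] = tyr99
    oh99 = tyr99["OH"]

    his70 = _build_residue("HIS", chi_1=-60.0)
    placed["his70"] = _orient_contact(his70, "ND1", oh99, (1.0, 0.35, 0.1),
                                      spec.his70_tyr99_distance)
    phe9 = _build_residue("PHE", chi_1=spec.phe9_chi1)
    placed["phe9"] = _translate(phe9, "CA", (-9.0, 5.0, 1.0))

    t116_chi = (spec.tyr116_altlocs[0][1] if spec.tyr116_altlocs
                else spec.tyr116_chi1)
    tyr116 = _build_residue("TYR", chi_1=t116_chi)
    tyr116 = _translate(tyr116, "CA", (18.0, 0.0, 0.0))
    placed["tyr116"] = tyr116
    oh116 = tyr116["OH"]

    placed["arg97"] = _orient_contact(_build_residue("ARG", chi_1=-60.0),
                                      "NH1", oh116, (0.1, 1.0, 0.25),
                                      dist(spec.arg97_tyr116_bonded))
    placed["his114"] = _orient_contact(_build_residue("HIS", chi_1=-60.0),
                                       "NE2", oh116, (0.1, -1.0, 0.25),
                                       dist(spec.his114_tyr116_bonded))
    placed["his74"] = _orient_contact(_build_residue("HIS", chi_1=180.0),
                                      "ND1", oh116, (0.25, 0.1, 1.0),
                                      dist(spec.tyr116_his74_bonded))
    placed["asp77"] = _orient_contact(_build_residue("ASP", chi_1=180.0),
                                      "OD1", oh116, (0.25, 0.1, -1.0),
                                      dist(spec.tyr116_asp77_bonded))
    return placed


def _ligand_coordinates(anchor: np.ndarray, offset) -> dict[str, np.ndarray]:
    """Zig-zag heavy-atom skeleton of the dipeptide stand-in near a pocket."""
    base = np.asarray(anchor, dtype=float) + np.asarray(offset, dtype=float)
    coords = {}
    for i, name in enumerate(_LIGAND_ATOMS):
        coords[name] = base + np.array([1.45 * i * 0.8,
                                        0.6 * (i % 2), 0.4 * ((i // 2) % 2)])
    return coords


def make_fixture_structure(spec: FixtureSpec) -> StructureModel:
    """Build one synthetic groove molecule as a :class:`StructureModel`.

    The model contains the eight groove residues at their HLA-A2 author
    numbers (plus Gly padding up to ``chain_length`` and an optional
    Gly light chain), with side chains at the prescribed χ1 values and the
    named inter-residue distances placed exactly (before noise).  Raises
    :class:`FixtureValidationError` when requested states contradict the
    requested geometry.
    """
    spec.validate_states()  # also run at construction; explicit for clarity
    rng = np.random.default_rng(spec.seed)
    bmap = dict(spec.bfactors)
    placed = _groove_coordinates(spec)

    records: list[AtomRecord] = []

    def add_residue(chain: str, number: int, resname: str,
                    coords: dict[str, np.ndarray], bfactor: float,
                    hetero: bool = False, altloc: str = "",
                    occupancy: float = 1.0) -> None:
        for atom_name, pos in coords.items():
            noisy = np.asarray(pos) + rng.normal(0.0, spec.noise_sigma, 3) \
                if spec.noise_sigma > 0 else np.asarray(pos)
            records.append(AtomRecord(
                chain_id=chain, residue_number=number, insertion_code="",
                residue_name=resname, atom_name=atom_name, altloc=altloc,
                occupancy=occupancy, bfactor=bfactor,
                position=tuple(float(x) for x in noisy), hetero=hetero))

    # groove residues in author-number order
    entries = sorted(_GROOVE_NUMBERS.items(), key=lambda kv: kv[1])
    pad_numbers = [n for n in range(1, spec.chain_length + 1)
                   if n not in _GROOVE_NUMBERS.values()]
    pad_numbers = pad_numbers[:spec.chain_length - 8]
    all_numbers = sorted(pad_numbers + [n for _, n in entries])

    for number in all_numbers:
        key = next((k for k, v in _GROOVE_NUMBERS.items() if v == number), None)
        if key is None:
            gly = _translate(_build_residue("GLY"), "CA",
                             (3.2 * number, -40.0, 0.0))
            add_residue(spec.chain_id, number, "GLY", gly,
                        spec.default_bfactor)
            continue
        b = bmap.get(key, spec.default_bfactor)
        if key == "tyr116" and spec.tyr116_altlocs:
            frame = placed["tyr116"]
            for letter, chi_val, occ in spec.tyr116_altlocs:
                variant = _translate(_build_residue("TYR", chi_1=chi_val),
                                     "CA", frame["CA"])
                add_residue(spec.chain_id, 116, "TYR", variant, b,
                            altloc=letter, occupancy=occ)
            continue
        add_residue(spec.chain_id, number, _GROOVE_TYPES[key], placed[key], b)

    for i, lig in enumerate(spec.ligands):
        anchor = (placed["phe9"]["CB"] if lig.pocket == "A"
                  else placed["tyr116"]["CB"])
        offset = (0.0, 3.5, 2.0)
        coords = _ligand_coordinates(anchor, offset)
        add_residue(spec.chain_id, 201 + i, lig.name, coords,
                    lig.mean_bfactor, hetero=True)

    for j in range(spec.light_chain_length):
        gly = _translate(_build_residue("GLY"), "CA",
                         (3.2 * j, 40.0, 0.0))
        add_residue("L", j + 1, "GLY", gly, spec.default_bfactor)

    model = StructureModel(entry_id=f"SYN-{spec.seed}", atoms=records,
                           molecule_groups={"1": [spec.chain_id]})
    return model


def make_fixture_model(specs: Sequence[FixtureSpec],
                       entry_id: str = "SYNTH") -> StructureModel:
    """Several molecules (chains A, B, ...) in one synthetic asymmetric unit."""
    if not specs:
        raise ValueError("need at least one molecule spec")
    chains = "ABCDEFGH"
    records: list[AtomRecord] = []
    groups: dict[str, list[str]] = {}
    for i, spec in enumerate(specs):
        chain = chains[i]
        single = make_fixture_structure(replace(spec, chain_id=chain,
                                                light_chain_length=0))
        shift = np.array([0.0, 0.0, 60.0 * i])
        for a in single.atoms:
            records.append(replace(a, position=tuple(np.asarray(a.position)
                                                     + shift)))
        groups[str(i + 1)] = [chain]
    return StructureModel(entry_id=entry_id, atoms=records,
                          molecule_groups=groups)


# ---------------------------------------------------------------------------
# Periodic potential, Metropolis umbrella sampler


@dataclass(frozen=True)
class PotentialSpec:
    """Periodic 1-D potential V(ξ) = Σ A_j (1 − cos(j (ξ − φ_j))).

    ``terms`` are (multiplicity j, amplitude A_j kcal/mol, phase φ_j deg).
    The period is 360°, and V is finite everywhere.
    """

    terms: tuple[tuple[int, float, float], ...] = ()

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        v = np.zeros_like(xi)
        for j, amp, phase in self.terms:
            v = v + amp * (1.0 - np.cos(np.radians(j * (xi - phase))))
        return float(v) if v.ndim == 0 else v

    def _scalar(self, xi: float) -> float:
        v = 0.0
        for j, amp, phase in self.terms:
            v += amp * (1.0 - math.cos(math.radians(j * (xi - phase))))
        return v


def default_double_well() -> PotentialSpec:
    """Two-well benchmark: minima near 180° (trans) and −60° (gauche−).

    The gauche− well lies ~0.7 kcal/mol below trans (the unlocked rotamer
    slightly more stable, as in the empty-groove landscape) and the
    barrier between them, through −120°, is ~2.9 kcal/mol — echoing the
    locked/unlocked Tyr116 picture without claiming to reproduce it.  The
    wells are deliberately non-degenerate: with exactly degenerate minima
    the min-normalization anchor of block-wise profiles flips
    stochastically between wells, which ruins block-error convergence."""
    return PotentialSpec(terms=((3, 1.45, 180.0), (1, 0.8, -90.0)))


def analytic_reference_pmf(potential: PotentialSpec, temperature: float = 300.0,
                           grid: np.ndarray | None = None) -> PMFProfile:
    """Exact PMF of a 1-D potential: V(ξ) − min V, evaluated pointwise.

    For a one-dimensional coordinate no marginalization is involved, so
    this is the exact oracle against which the WHAM reconstruction from
    biased samples is judged.
    """
    if grid is None:
        grid = -180.0 + 2.0 * (np.arange(180) + 0.5)
    grid = np.asarray(grid, dtype=float)
    v = potential(grid)
    return PMFProfile(grid=grid, free_energy=v - _potential_min(potential),
                      temperature=temperature)


def _potential_min(potential: PotentialSpec) -> float:
    """Global minimum of V, refined to machine precision.

    Using the true minimum (rather than the evaluation grid's) keeps the
    reference profile a pointwise function of the angle, independent of
    the grid it is evaluated on.
    """
    from scipy.optimize import minimize_scalar

    coarse = np.linspace(-180.0, 180.0, 3600, endpoint=False)
    v = potential(coarse)
    best = float(v.min())
    if float(v.max()) - best < 1e-12:
        return best
    local_min = np.flatnonzero((v <= np.roll(v, 1)) & (v <= np.roll(v, -1)))
    for i in local_min[:16]:
        lo, hi = coarse[i] - 0.1, coarse[i] + 0.1
        res = minimize_scalar(potential._scalar, bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-12})
        best = min(best, float(res.fun))
    return best


def sample_window(potential: PotentialSpec, center: float, k: float,
                  n_steps: int, step_size: float = 10.0, seed: int = 0,
                  temperature: float = 300.0, burn_in: int = 0,
                  ) -> UmbrellaWindowSeries:
    """Metropolis chain on V(ξ) + k·Δ² at the given temperature.

    Uniform proposals in ±``step_size``; the chain starts at the window
    center (wrapped) and records every post-move state after ``burn_in``
    discarded steps.  Deterministic under a fixed seed; the acceptance
    rate is recorded in the returned series label.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    rng = np.random.default_rng(seed)
    kt = KB_KCAL * temperature
    x = wrap_angle(center)
    e = potential._scalar(x) + bias_energy(x, center, k)
    total = burn_in + n_steps
    proposals = rng.uniform(-step_size, step_size, total)
    uniforms = rng.random(total)
    out = np.empty(n_steps)
    accepted = 0
    wrap = wrap_angle
    for i in range(total):
        x_new = wrap(x + proposals[i])
        e_new = potential._scalar(x_new) + bias_energy(x_new, center, k)
        if e_new <= e or uniforms[i] < math.exp(-(e_new - e) / kt):
            x, e = x_new, e_new
            accepted += 1
        if i >= burn_in:
            out[i - burn_in] = x
    rate = accepted / total
    return UmbrellaWindowSeries(center=center, force_constant=k, samples=out,
                                label=f"seed={seed} acceptance={rate:.3f}")


def sample_protocol(potential: PotentialSpec, centers: Sequence[float],
                    k: float = 0.015, n_steps: int = 50_000,
                    step_size: float = 10.0, seed: int = 0,
                    temperature: float = 300.0, burn_in: int = 1000,
                    ) -> list[UmbrellaWindowSeries]:
    """One sampled series per window center, seeds derived per window."""
    return [sample_window(potential, c, k, n_steps, step_size=step_size,
                          seed=seed + 1000 * i, temperature=temperature,
                          burn_in=burn_in)
            for i, c in enumerate(centers)]


# ---------------------------------------------------------------------------
# Melting curves


def make_melt_curve(midpoints: Sequence[float],
                    amplitudes: Sequence[float] | None = None,
                    widths: Sequence[float] | None = None,
                    noise_sigma: float = 0.002,
                    temperatures: np.ndarray | None = None,
                    baseline: tuple[float, float] = (0.85, -4e-4),
                    seed: int = 0, label: str = "") -> MeltCurve:
    """Sum-of-logistics F350/F330 curve with linear baseline and noise.

    ratio(T) = b0 + b1·T + Σ_i a_i / (1 + exp(−(T − m_i)/w_i)) + ε,
    ε ~ N(0, σ²) i.i.d.  Default grid 25-95 °C in 0.25 °C steps; default
    per-transition amplitude 0.1 and width 1.2 °C.  Deterministic under a
    fixed seed; midpoints must lie inside the grid.
    """
    if temperatures is None:
        temperatures = np.arange(25.0, 95.0 + 1e-9, 0.25)
    temperatures = np.asarray(temperatures, dtype=float)
    midpoints = list(midpoints)
    for m in midpoints:
        if not (temperatures[0] < m < temperatures[-1]):
            raise ValueError(f"midpoint {m} °C outside the temperature grid")
    if amplitudes is None:
        amplitudes = [0.1] * len(midpoints)
    if widths is None:
        widths = [1.2] * len(midpoints)
    if not (len(amplitudes) == len(widths) == len(midpoints)):
        raise ValueError("midpoints/amplitudes/widths lengths differ")
    b0, b1 = baseline
    ratio = b0 + b1 * temperatures
    for m, a, w in zip(midpoints, amplitudes, widths):
        ratio = ratio + a / (1.0 + np.exp(-(temperatures - m) / w))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sigma, temperatures.size)
    return MeltCurve(temperature=temperatures, ratio=ratio,
                     label=label or f"seed={seed}")


def make_concentration_series(
        concentrations_mm: Sequence[float] = (0.05, 0.1, 0.5, 1.0, 5.0,
                                              10.0, 50.0, 100.0),
        heavy_tm_base: float = 46.0, heavy_tm_per_decade: float = 2.5,
        beta2m_tm: float = 62.0, noise_sigma: float = 0.002,
        seed: int = 0, **kwargs) -> list[MeltCurve]:
    """A dipeptide-concentration series of two-transition curves.

    The heavy-chain midpoint rises logarithmically with dipeptide
    concentration (stabilization of the binding groove by the bound
    dipeptide); the β2m transition stays fixed at 62 °C.  Labels carry the
    concentration in mM.
    """
    curves = []
    ref = concentrations_mm[0]
    for i, conc in enumerate(concentrations_mm):
        tm_heavy = heavy_tm_base + heavy_tm_per_decade * math.log10(conc / ref)
        curves.append(make_melt_curve(
            midpoints=[tm_heavy, beta2m_tm], noise_sigma=noise_sigma,
            seed=seed + i, label=f"{conc:g}", **kwargs))
    return curves
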
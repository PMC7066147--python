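"""Coordinate-file ingestion and residue addressing.

Reads PDB and mmCIF files (via gemmi) into a flat, explicit
:class:`StructureModel`, with deterministic policies for alternate
locations and for identifying the MHC heavy chain(s) among the chains of
the asymmetric unit.  Author residue numbering is used throughout; groove
residues are addressed through a :class:`ResidueMapping` that defaults to
HLA-A2 mature-chain numbering (Phe9 ... Tyr116).

Only the first model of a file is read (crystal structures have one).
Hetero groups — dipeptide ligands, cryo-solvent (EDO, GOL), waters — are
retained and addressable by residue name.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "FormatError",
    "LookupError_",
    "MappingError",
    "AtomRecord",
    "ResidueView",
    "StructureModel",
    "ResidueMapping",
    "GROOVE_RESIDUES",
    "STANDARD_AA",
    "read_structure",
    "write_structure",
    "select_residue",
    "resolve_chain_mapping",
    "load_mapping_config",
]


class FormatError(ValueError):
    """File parsed but does not contain a usable structure."""


class LookupError_(KeyError):
    """Requested chain/residue/atom not present in the model."""


class MappingError(ValueError):
    """Heavy chain / groove residues could not be resolved."""


class MissingResidueError(MappingError):
    """A mapped groove residue is absent from the structure."""


STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Groove residues of the A- and F-pocket triads, HLA-A2 mature numbering.
GROOVE_RESIDUES: dict[str, tuple[str, int]] = {
    "phe9": ("PHE", 9),
    "his70": ("HIS", 70),
    "his74": ("HIS", 74),
    "asp77": ("ASP", 77),
    "arg97": ("ARG", 97),
    "tyr99": ("TYR", 99),
    "his114": ("HIS", 114),
    "tyr116": ("TYR", 116),
}

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a coordinate file, author numbering, explicit altloc."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    altloc: str
    occupancy: float
    bfactor: float
    position: tuple[float, float, float]
    hetero: bool = False

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.bfactor < 0:
            raise ValueError(f"negative B-factor {self.bfactor}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite atom position")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ResidueView:
    """Atoms of a single residue after altloc resolution (one per name)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atoms: list[AtomRecord]

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise LookupError_(
            f"atom {name!r} not found in {self.residue_name} "
            f"{self.chain_id}{self.residue_number}"
        )

    def atom_set(self, names: Sequence[str]) -> list[AtomRecord]:
        """Atoms of this residue whose names are in ``names`` (present ones)."""
        return [a for a in self.atoms if a.atom_name in names]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.position for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Flat atom list plus chain bookkeeping for one coordinate entry."""

    entry_id: str
    atoms: list[AtomRecord]
    molecule_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise FormatError(f"structure {self.entry_id!r} contains no atoms")
        self._index: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            self._index.setdefault(a.residue_key, []).append(a)

    # -- residue access -------------------------------------------------
    def residue_atoms(self, chain_id: str, residue_number: int,
                      insertion_code: str = "") -> list[AtomRecord]:
        key = (chain_id, residue_number, insertion_code)
        if key not in self._index:
            raise LookupError_(f"residue {key} not in structure {self.entry_id}")
        return self._index[key]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[tuple[int, str, str]]:
        """Ordered (residue_number, insertion_code, residue_name) of a chain."""
        seen: dict[tuple[int, str], str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault((a.residue_number, a.insertion_code), a.residue_name)
        return [(num, icode, name) for (num, icode), name in seen.items()]

    def protein_residue_count(self, chain_id: str) -> int:
        return sum(1 for _, _, name in self.chain_residues(chain_id)
                   if name in STANDARD_AA)

    def hetero_residues(self, include_water: bool = False) -> list[ResidueView]:
        """Hetero groups (ligands, cryo-solvent; waters optional) as views."""
        out = []
        seen = set()
        for a in self.atoms:
            if not a.hetero or a.residue_key in seen:
                continue
            if a.residue_name in _WATER_NAMES and not include_water:
                continue
            seen.add(a.residue_key)
            out.append(select_residue(self, a.chain_id, a.residue_number,
                                      a.insertion_code))
        return out


def _from_gemmi(st: gemmi.Structure, entry_id: str) -> StructureModel:
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise FormatError(f"{entry_id}: file has no models")
    model = st[0]  # first model only
    for chain in model:
        for res in chain:
            het = res.het_flag == "H" or res.name not in STANDARD_AA
            for atom in res:
                altloc = atom.altloc if atom.altloc not in ("\x00", " ") else ""
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    atom_name=atom.name,
                    altloc=altloc,
                    occupancy=float(np.clip(atom.occ, 0.0, 1.0)),
                    bfactor=max(float(atom.b_iso), 0.0),
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    hetero=het,
                ))
    return StructureModel(entry_id=entry_id, atoms=atoms)


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    ``format`` is ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from
    content/extension).  All ATOM and HETATM records of the first model are
    kept, including ligands and waters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such coordinate file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    entry_id = st.name.strip() or path.stem
    model = _from_gemmi(st, entry_id)
    if not model.atoms:
        raise FormatError(f"{path}: zero atoms")
    return model


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.entry_id
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, str, str] | None] = {}
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            gmodel.add_chain(ch)
            ch = gmodel[len(gmodel) - 1]
            chains[a.chain_id] = ch
            current[a.chain_id] = None
        key = a.residue_key
        if current[a.chain_id] != key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.hetero else "A"
            ch.add_residue(res)
            current[a.chain_id] = key
        res = ch[len(ch) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.altloc = a.altloc or "\x00"
        atom.occ = a.occupancy
        atom.b_iso = a.bfactor
        atom.pos = gemmi.Position(*a.position)
        atom.element = gemmi.Element(_guess_element(a.atom_name))
        res.add_atom(atom)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for el in ("CL", "BR", "ZN", "MG", "NA", "FE", "MN"):
        if stripped.upper() == el:
            return el.capitalize()
    for c in stripped:
        if c.isalpha():
            return c.upper()
    return "C"


def write_structure(model: StructureModel, path: str | os.PathLike,
                    format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (``auto``: chosen from the extension)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(model)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def select_residue(model: StructureModel, chain_id: str, residue_number: int,
                   insertion_code: str = "",
                   altloc_policy: str = "highest_occupancy",
                   altloc: str | None = None) -> ResidueView:
    """One residue with exactly one altloc variant per atom name.

    ``highest_occupancy`` keeps, per atom name, the variant with the largest
    occupancy (ties broken by altloc letter order, the blank altloc first);
    ``specific`` keeps atoms with the requested ``altloc`` (plus un-split
    atoms) and raises if that altloc does not occur on any split atom.
    """
    atoms = model.residue_atoms(chain_id, residue_number, insertion_code)
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.atom_name, []).append(a)

    chosen: list[AtomRecord] = []
    if altloc_policy == "highest_occupancy":
        for name, variants in by_name.items():
            chosen.append(min(variants, key=lambda a: (-a.occupancy, a.altloc)))
    elif altloc_policy == "specific":
        if altloc is None:
            raise ValueError("altloc_policy='specific' requires altloc=")
        present = {a.altloc for a in atoms if a.altloc}
        if present and altloc not in present:
            raise LookupError_(
                f"altloc {altloc!r} absent from residue "
                f"{chain_id}{residue_number} (has {sorted(present)})")
        for name, variants in by_name.items():
            matching = [a for a in variants if a.altloc in ("", altloc)]
            if matching:
                chosen.append(min(matching, key=lambda a: (-a.occupancy, a.altloc)))
    else:
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")

    first = atoms[0]
    return ResidueView(chain_id=chain_id, residue_number=residue_number,
                       insertion_code=insertion_code,
                       residue_name=first.residue_name, atoms=chosen)


@dataclass
class ResidueMapping:
    """Where the eight groove residues live in one molecule of a file."""

    allele: str
    molecule_label: str
    heavy_chain: str
    residues: dict[str, int]  # groove key -> author residue number

    def validate(self, model: StructureModel) -> None:
        """Check that mapped residues exist and have the expected type."""
        for key, number in self.residues.items():
            expected_name, _ = GROOVE_RESIDUES[key]
            try:
                atoms = model.residue_atoms(self.heavy_chain, number)
            except LookupError_:
                raise MissingResidueError(
                    f"{model.entry_id} molecule {self.molecule_label}: groove "
                    f"residue {key} ({expected_name} {number}) missing from "
                    f"chain {self.heavy_chain}") from None
            actual = atoms[0].residue_name
            if actual != expected_name:
                raise MappingError(
                    f"{model.entry_id} chain {self.heavy_chain} residue "
                    f"{number}: expected {expected_name} for {key}, found {actual}")


def load_mapping_config(path: str | os.PathLike) -> dict:
    """Parse a key-value mapping override file.

    Lines of the form ``heavy_chains = A,D`` or ``tyr116 = 116``;
    ``#`` comments and blank lines ignored.
    """
    config: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "heavy_chains":
            config[key] = [c.strip() for c in value.split(",") if c.strip()]
        elif key == "allele":
            config[key] = value
        elif key in GROOVE_RESIDUES:
            config.setdefault("residues", {})[key] = int(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return config


MIN_HEAVY_CHAIN_RESIDUES = 250  # β2m-like chains (~100 aa) fall well below


def resolve_chain_mapping(model: StructureModel, config: Mapping | None = None,
                          ) -> dict[str, ResidueMapping]:
    """Identify heavy chain(s) and groove-residue numbers per molecule.

    Auto mode maps every protein chain with at least
    ``MIN_HEAVY_CHAIN_RESIDUES`` residues as the heavy chain of one
    asymmetric-unit molecule (labelled "1", "2", ... in file order) and uses
    HLA-A2 mature-chain numbering for the groove residues.  An explicit
    ``config`` (``heavy_chains`` list, optional per-residue numbers) always
    wins over the heuristic.  The mapping is validated against the model.
    """
    config = dict(config or {})
    allele = config.get("allele", "HLA-A2")
    numbers = {key: GROOVE_RESIDUES[key][1] for key in GROOVE_RESIDUES}
    numbers.update(config.get("residues", {}))

    if "heavy_chains" in config:
        heavy = list(config["heavy_chains"])
        missing = [c for c in heavy if c not in model.chains()]
        if missing:
            raise MappingError(
                f"{model.entry_id}: configured chain(s) {missing} not present")
    else:
        heavy = [c for c in model.chains()
                 if model.protein_residue_count(c) >= MIN_HEAVY_CHAIN_RESIDUES]
        if not heavy:
            counts = {c: model.protein_residue_count(c) for c in model.chains()}
            raise MappingError(
                f"{model.entry_id}: no chain reaches "
                f"{MIN_HEAVY_CHAIN_RESIDUES} protein residues "
                f"(counts: {counts}); provide an explicit mapping config")

    mappings: dict[str, ResidueMapping] = {}
    for i, chain in enumerate(heavy, start=1):
        label = str(i)
        m = ResidueMapping(allele=allele, molecule_label=label,
                           heavy_chain=chain, residues=dict(numbers))
        m.validate(model)
        mappings[label] = m
    model.molecule_groups = {label: [m.heavy_chain]
                             for label, m in mappings.items()}
    return mappings
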
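"""Molecular structure I/O and 3D conformer generation.

Reads activity-annotated molecule tables (SMILES-CSV or SDF), normalizes
structures (neutralize protonation states, keep the largest fragment) and
embeds a single low-energy 3D conformer per molecule.  The 3D structures
round-trip through V2000 SDF so the rendering stage can be decoupled from
structure preparation.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "Molecule3D",
    "ParseError",
    "ParseResult",
    "parse_dataset",
    "normalize_structure",
    "embed_3d",
    "write_sdf",
    "read_sdf",
]

#: SDF property name that carries the continuous activity (maximum
#: fold-change of the reporter assay over the tested concentrations).
ACTIVITY_PROP = "MAX"


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule of the dataset: identifier, SMILES and activity.

    ``activity`` is the continuous assay readout (fold-change relative to
    vehicle control, dimensionless, > 0).  ``flags`` records non-fatal
    normalization events such as an uncharger failure.
    """

    id: str
    smiles: str
    activity: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if not math.isfinite(self.activity):
            raise ValueError(f"activity of {self.id!r} is not finite")


@dataclass
class Molecule3D:
    """Element-typed atoms with 3D coordinates and a bond list.

    ``elements`` is a list of element symbols, ``coords`` an (n_atoms, 3)
    float array in Angstrom, ``bonds`` a list of ``(i, j, order)`` tuples
    with order 1.0/1.5/2.0/3.0 (1.5 = aromatic).  ``props`` carries
    passthrough SDF properties (e.g. the activity field).
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]]
    props: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"molecule {self.id!r}: coords shape {self.coords.shape} "
                f"does not match {n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id!r} has non-finite coordinates")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: bond ({i},{j}) out of range")
        if n > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-6:
                raise ValueError(f"molecule {self.id!r}: two atoms coincide")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class ParseError:
    """A per-record parse failure: input position, offending id, message."""

    index: int
    id: str
    message: str


@dataclass
class ParseResult:
    """Outcome of a dataset parse: valid records plus reported failures.

    Iterating the result iterates the valid records, so it can be used
    directly wherever a record list is expected.  ``n_in == len(records)
    + len(errors)`` always holds (loss accounting).
    """

    records: list[MoleculeRecord]
    errors: list[ParseError]
    n_in: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _check_unique_ids(records: Sequence[MoleculeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate molecule id {r.id!r} in dataset")
        seen.add(r.id)


def parse_dataset(path: str | Path, format: str = "smiles-csv") -> ParseResult:
    """Read a molecule dataset from ``path``.

    ``format`` is ``"smiles-csv"`` (header ``id,smiles,activity``) or
    ``"sdf"`` (V2000, activity in the ``MAX`` property).  Input order is
    preserved; entries that fail to parse are reported in ``errors``
    rather than silently dropped.  An unreadable file raises.
    """
    path = Path(path)
    if format not in ("smiles-csv", "sdf"):
        raise ValueError(f"unknown dataset format {format!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))

    records: list[MoleculeRecord] = []
    errors: list[ParseError] = []
    n_in = 0

    if format == "smiles-csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                warnings.warn(f"{path}: empty dataset file", stacklevel=2)
                return ParseResult([], [], 0)
            missing = {"id", "smiles", "activity"} - set(reader.fieldnames)
            if missing:
                raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
            for idx, row in enumerate(reader):
                n_in += 1
                rid = (row.get("id") or f"row{idx}").strip()
                smi = (row.get("smiles") or "").strip()
                try:
                    act = float(row["activity"])
                except (TypeError, ValueError):
                    errors.append(ParseError(idx, rid, "activity not numeric"))
                    continue
                if Chem.MolFromSmiles(smi) is None:
                    errors.append(ParseError(idx, rid, f"unparseable SMILES {smi!r}"))
                    continue
                try:
                    records.append(MoleculeRecord(rid, smi, act))
                except ValueError as exc:
                    errors.append(ParseError(idx, rid, str(exc)))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for idx, mol in enumerate(supplier):
            n_in += 1
            if mol is None:
                errors.append(ParseError(idx, f"sdf{idx}", "unparseable SDF block"))
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{idx}"
            rid = rid.strip() or f"sdf{idx}"
            try:
                act = float(mol.GetProp(ACTIVITY_PROP))
            except (KeyError, ValueError):
                errors.append(ParseError(idx, rid, f"missing/invalid {ACTIVITY_PROP}"))
                continue
            records.append(MoleculeRecord(rid, Chem.MolToSmiles(mol), act))

    if n_in == 0:
        warnings.warn(f"{path}: empty dataset file", stacklevel=2)
    _check_unique_ids(records)
    return ParseResult(records, errors, n_in)


_UNCHARGER = rdMolStandardize.Uncharger()
_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def normalize_structure(record: MoleculeRecord) -> MoleculeRecord:
    """Neutralize protonation states and keep the largest fragment.

    Salts and solvent fragments are removed by heavy-atom count; charged
    sites are neutralized where chemically possible.  A residual net
    charge (e.g. a quaternary ammonium) is not an error: the record is
    passed through with an ``"uncharged_failed"`` flag.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"{record.id}: unparseable SMILES {record.smiles!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    flags = record.flags
    if Chem.GetFormalCharge(mol) != 0 and "uncharged_failed" not in flags:
        flags = flags + ("uncharged_failed",)
    return replace(record, smiles=Chem.MolToSmiles(mol), flags=flags)


def _mol_to_molecule3d(mol: Chem.Mol, rid: str) -> Molecule3D:
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    props = {
        k: mol.GetProp(k)
        for k in mol.GetPropNames()
        if not k.startswith("_")
    }
    return Molecule3D(rid, elements, coords, bonds, props)


def embed_3d(record: MoleculeRecord, seed: int) -> Molecule3D:
    """Embed a single low-energy 3D conformer, hydrogens explicit.

    Distance-geometry embedding (ETKDG) followed by MMFF relaxation (UFF
    fallback).  Deterministic for a fixed (structure, seed) pair.  Raises
    ``RuntimeError`` on embedding failure so the caller can skip the
    record and continue.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"{record.id}: unparseable SMILES {record.smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"{record.id}: 3D embedding failed")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # an unrelaxed DG conformer still satisfies the contract
    m3d = _mol_to_molecule3d(mol, record.id)
    m3d.props[ACTIVITY_PROP] = repr(record.activity)
    return m3d


_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def _molecule3d_to_mol(m: Molecule3D) -> Chem.Mol:
    rw = Chem.RWMol()
    for el in m.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in m.bonds:
        rw.AddBond(int(i), int(j), _BOND_TYPES.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(m.elements))
    for i, (x, y, z) in enumerate(m.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    Chem.SanitizeMol(
        mol,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        catchErrors=True,
    )
    mol.SetProp("_Name", m.id)
    for k, v in m.props.items():
        mol.SetProp(k, v)
    return mol


def write_sdf(molecules: Iterable[Molecule3D], path: str | Path) -> None:
    """Write molecules to a V2000 SDF file (empty input gives a valid empty file)."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for m in molecules:
            writer.write(_molecule3d_to_mol(m))
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Molecule3D]:
    """Read a V2000 SDF written by :func:`write_sdf` back into ``Molecule3D``.

    ``read_sdf(write_sdf(x))`` preserves ids, elements, bonds and
    coordinates to the precision of the text format (1e-4 Angstrom).
    Malformed blocks raise with the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.stat().st_size == 0:
        return []  # an empty molecule list round-trips through an empty file
    out: list[Molecule3D] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: malformed SDF block at record {idx}")
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{idx}"
        out.append(_mol_to_molecule3d(mol, rid.strip() or f"sdf{idx}"))
    return out
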
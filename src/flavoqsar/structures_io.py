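"""Molecular structure input/output and 3D embedding.

Structures enter the pipeline as SMILES lists or SDF/MOL V2000 blocks and
are exposed as :class:`Molecule3D`: an explicit-hydrogen molecular graph
with a single 3D conformer and per-atom property channels (filled later by
:mod:`flavoqsar.charges`).  RDKit does the parsing, hydrogen addition,
aromaticity perception and distance-geometry embedding; this module pins
the conventions the descriptor code relies on (explicit hydrogens, one
conformer, stable ids, deterministic embedding).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

#: bond order code for aromatic bonds in Molecule3D.bonds
AROMATIC = "aromatic"

_RDKIT_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_TO_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}


class StructureError(ValueError):
    """Unparsable or invalid structure input."""


@dataclass
class Molecule3D:
    """Explicit-hydrogen molecular graph with one 3D conformer.

    Attributes
    ----------
    id : str
        Molecule identifier (from input, or ``mol_%04d``).
    atoms : list of (str, int, (float, float, float))
        Per atom: element symbol, formal charge (e), xyz coordinates (Å).
    bonds : list of (int, int, order)
        ``order`` is 1, 2, 3 or ``"aromatic"``; ``i < j``; no duplicates.
    properties : dict[str, np.ndarray]
        Per-atom scalar channels (σ/π/total charge, lone-pair EN, ...).
    needs_embedding : bool
        True when the source had no 3D coordinates (e.g. SMILES).
    """

    id: str
    atoms: list
    bonds: list
    properties: dict = field(default_factory=dict)
    needs_embedding: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list:
        return [a[0] for a in self.atoms]

    @property
    def formal_charges(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=int)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in Å."""
        return np.array([a[2] for a in self.atoms], dtype=float)

    @property
    def net_charge(self) -> int:
        return int(self.formal_charges.sum())

    def validate(self) -> None:
        """Check the structural invariants; raise StructureError on failure."""
        n = self.n_atoms
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(
                    f"{self.id}: bond ({i},{j}) references missing atom")
            if i == j:
                raise StructureError(f"{self.id}: self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"{self.id}: duplicate bond {key}")
            seen.add(key)
            if order not in _TO_RDKIT_BOND:
                raise StructureError(f"{self.id}: bad bond order {order!r}")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"{self.id}: non-finite coordinates")

    # -- RDKit bridge ------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Build an RDKit molecule (explicit H, one conformer)."""
        em = Chem.RWMol()
        for sym, chg, _ in self.atoms:
            a = Chem.Atom(sym)
            a.SetFormalCharge(int(chg))
            a.SetNoImplicit(True)
            em.AddAtom(a)
        for i, j, order in self.bonds:
            em.AddBond(int(i), int(j), _TO_RDKIT_BOND[order])
        mol = em.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for idx, (_, _, xyz) in enumerate(self.atoms):
            conf.SetAtomPosition(idx, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
        Chem.SanitizeMol(mol)
        mol.SetProp("_Name", self.id)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str,
                   needs_embedding: bool = False) -> "Molecule3D":
        """Convert an RDKit molecule; hydrogens must already be explicit."""
        if mol.GetNumConformers():
            conf = mol.GetConformer()
            coords = [tuple(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        else:
            coords = [(0.0, 0.0, 0.0)] * mol.GetNumAtoms()
            needs_embedding = True
        atoms = [(a.GetSymbol(), a.GetFormalCharge(), coords[a.GetIdx()])
                 for a in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            bonds.append((min(i, j), max(i, j), _RDKIT_BOND_ORDERS[b.GetBondType()]))
        out = cls(id=mol_id, atoms=atoms, bonds=sorted(bonds),
                  needs_embedding=needs_embedding)
        out.validate()
        return out


# -- reading ---------------------------------------------------------------

_SDF_MARKER = re.compile(r"V2000|^\$\$\$\$", re.MULTILINE)


def _looks_like_sdf(text: str) -> bool:
    return bool(_SDF_MARKER.search(text))


def read_structures(source, fmt: str | None = None,
                    strict: bool = False) -> list:
    """Read molecules from a SMILES list or an SDF/MOL block.

    Parameters
    ----------
    source : str or path-like
        Path to a file, or the text itself.
    fmt : {"smiles", "sdf", None}
        Input format; ``None`` autodetects (V2000/``$$$$`` markers → SDF).
    strict : bool
        If True, the first unparsable record aborts; otherwise bad records
        are logged with their line/record number and the rest returned.

    Returns
    -------
    list of Molecule3D
        SMILES-derived molecules are flagged ``needs_embedding``;
        SDF coordinates are preserved as printed.
    """
    text = _read_text(source)
    if fmt is None:
        fmt = "sdf" if _looks_like_sdf(text) else "smiles"
    if fmt == "smiles":
        mols = _read_smiles(text, strict=strict)
    elif fmt == "sdf":
        mols = _read_sdf(text, strict=strict)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not mols:
        logger.warning("no molecules parsed from input")
    return mols


def _read_text(source) -> str:
    try:
        import os
        if os.path.exists(str(source)) and "\n" not in str(source):
            with open(source) as fh:
                return fh.read()
    except (OSError, TypeError):
        pass
    return str(source)


def _read_smiles(text: str, strict: bool) -> list:
    mols = []
    counter = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        counter += 1
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol_{counter:04d}"
        rdmol = Chem.MolFromSmiles(smi)
        if rdmol is None:
            msg = f"line {lineno}: unparsable SMILES {smi!r}"
            if strict:
                raise StructureError(msg)
            logger.error(msg)
            continue
        rdmol = Chem.AddHs(rdmol)
        mols.append(Molecule3D.from_rdkit(rdmol, mol_id, needs_embedding=True))
    return mols


def _read_sdf(text: str, strict: bool) -> list:
    mols = []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, removeHs=False, sanitize=True)
    for rec, rdmol in enumerate(supplier, start=1):
        if rdmol is None:
            msg = f"SDF record {rec}: unparsable"
            if strict:
                raise StructureError(msg)
            logger.error(msg)
            continue
        rdmol = Chem.AddHs(rdmol, addCoords=True)
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol_id = name.strip() or f"mol_{rec:04d}"
        mols.append(Molecule3D.from_rdkit(rdmol, mol_id))
    return mols


def write_sdf(mols, path) -> None:
    """Write molecules to an SDF (V2000) file."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for mol in mols:
        writer.write(mol.to_rdkit())
    writer.close()


# -- embedding -------------------------------------------------------------

def embed3d(mol: Molecule3D, seed: int = 0) -> Molecule3D:
    """Generate one deterministic 3D conformer (ETKDG + force-field cleanup).

    A pure function of (molecular graph, seed): the same inputs give
    bit-identical coordinates.  Molecules that already carry coordinates
    (``needs_embedding`` False) are returned unchanged; a single-atom
    molecule is placed at the origin.
    """
    if not mol.needs_embedding:
        return mol
    if mol.n_atoms == 1:
        sym, chg, _ = mol.atoms[0]
        return Molecule3D(id=mol.id, atoms=[(sym, chg, (0.0, 0.0, 0.0))],
                          bonds=[], properties=dict(mol.properties))
    rdmol = mol.to_rdkit()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.useRandomCoords = False
    params.enforceChirality = True
    conf_id = AllChem.EmbedMolecule(rdmol, params)
    if conf_id < 0:
        # fallback for hard cases: random-coordinate DG, still seeded
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(rdmol, params)
    if conf_id < 0:
        raise StructureError(f"3D embedding failed for molecule {mol.id!r}")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception:  # MMFF not parameterized: keep DG geometry
        logger.warning("force-field cleanup skipped for %s", mol.id)
    out = Molecule3D.from_rdkit(rdmol, mol.id)
    out.properties = dict(mol.properties)
    out.needs_embedding = False
    return out
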
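"""Reading and normalising small-molecule structures.

All inputs (SMILES strings, MDL MOL/SDF blocks, component-dictionary
tables) are reduced to a single internal representation: a
hydrogen-suppressed, heavy-atom labelled graph.  Hydrogens never appear
as atoms; 3D coordinates are ignored; multi-fragment inputs (salts,
counterions) are stripped to their largest connected component.

Markush (generic) structures are supported: atom symbols denoting an
R-group placeholder become atoms with ``element_kind == R_GROUP`` so the
scoring layer can instantiate them against a concrete bound ligand.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about valence issues in permissively-parsed blocks.
RDLogger.DisableLog("rdApp.*")

#: sentinel element kind for Markush attachment points
R_GROUP = "R_GROUP"

#: MOL-file atom symbols treated as R-group placeholders.  KEGG and other
#: sources vary ("R", "R#", "*", "A"); over-inclusive detection is safer
#: and each hit is logged.
R_GROUP_SYMBOLS = frozenset({"R", "R#", "*", "A"})


class MoleculeParseError(ValueError):
    """Raised when a structure input cannot be turned into a Molecule."""

    def __init__(self, message: str, *, id: str = "", source: str = ""):
        self.id = id
        self.source = source
        super().__init__(message)


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol (or the R_GROUP sentinel) and charge."""

    index: int
    element_kind: str
    formal_charge: int = 0

    @property
    def is_r_group(self) -> bool:
        return self.element_kind == R_GROUP


@dataclass(frozen=True)
class Molecule:
    """Hydrogen-suppressed molecular graph.

    ``bonds`` are ``(i, j, order)`` with ``i < j``; order is 1.0 / 1.5
    (aromatic) / 2.0 / 3.0.  Bond order is carried for round-tripping but
    the similarity layer ignores it entirely.
    """

    id: str
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.id}: bond ({i},{j}) indexes outside 0..{n-1}")
            if i == j:
                raise ValueError(f"{self.id}: self-bond on atom {i}")
            if i > j:
                raise ValueError(f"{self.id}: bond ({i},{j}) not normalised i<j")
            if (i, j) in seen:
                raise ValueError(f"{self.id}: duplicate bond ({i},{j})")
            seen.add((i, j))

    # -- basic graph views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def is_empty(self) -> bool:
        return not self.atoms

    @property
    def is_markush(self) -> bool:
        return any(a.is_r_group for a in self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element_kind for a in self.atoms)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def element_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element_kind] = out.get(a.element_kind, 0) + 1
        return out

    def with_id(self, new_id: str) -> "Molecule":
        return Molecule(new_id, self.atoms, self.bonds)

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit Mol (R-group atoms become dummy atoms)."""
        rw = Chem.RWMol()
        for a in self.atoms:
            if a.is_r_group:
                ra = Chem.Atom(0)
            else:
                ra = Chem.Atom(a.element_kind)
                ra.SetFormalCharge(a.formal_charge)
            ra.SetNoImplicit(False)
            rw.AddAtom(ra)
        order_map = {
            1.0: Chem.BondType.SINGLE,
            1.5: Chem.BondType.AROMATIC,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
        }
        for i, j, order in self.bonds:
            rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - permissive rebuild
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            )
        return mol


def _bond_order(bond: Chem.Bond) -> float:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return 1.5
    return float(bond.GetBondTypeAsDouble())


def _largest_fragment_indices(mol: Chem.Mol) -> set[int]:
    frags = Chem.GetMolFrags(mol)
    if len(frags) <= 1:
        return set(range(mol.GetNumAtoms()))
    best = max(frags, key=lambda f: (len(f), -min(f)))
    return set(best)


def _from_rdkit(mol: Chem.Mol, id: str, *, r_flags: Mapping[int, bool] | None = None) -> Molecule:
    """Convert an RDKit Mol to the internal heavy-atom graph.

    ``r_flags`` marks original atom indices that must become R_GROUP atoms
    (used by the MOL path where the symbol is known before sanitisation).
    """
    r_flags = r_flags or {}
    keep = _largest_fragment_indices(mol)
    dropped_fragments = mol.GetNumAtoms() and len(keep) < mol.GetNumAtoms()

    index_map: dict[int, int] = {}
    atoms: list[Atom] = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx not in keep:
            continue
        if atom.GetAtomicNum() == 1:  # suppress explicit hydrogens
            continue
        if atom.GetAtomicNum() == 0 or r_flags.get(idx) or atom.GetSymbol() in R_GROUP_SYMBOLS:
            kind = R_GROUP
            charge = 0
        else:
            kind = atom.GetSymbol()
            charge = atom.GetFormalCharge()
        index_map[idx] = len(atoms)
        atoms.append(Atom(index=len(atoms), element_kind=kind, formal_charge=charge))

    bonds: list[tuple[int, int, float]] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a not in index_map or b not in index_map:
            continue
        i, j = sorted((index_map[a], index_map[b]))
        bonds.append((i, j, _bond_order(bond)))
    bonds.sort()

    if dropped_fragments:
        logger.warning("%s: multi-fragment input, kept largest component (%d atoms)", id, len(atoms))

    result = Molecule(id=id, atoms=tuple(atoms), bonds=tuple(bonds))
    for atom in result.atoms:
        if atom.is_r_group:
            adj = result.adjacency()
            if not adj[atom.index]:
                logger.warning("%s: isolated R-group atom %d", id, atom.index)
            break
    return result


def parse_smiles(smiles: str, id: str) -> Molecule:
    """Parse a SMILES string into a normalised heavy-atom Molecule.

    Aromatic perception is RDKit's default model, shared with the MOL
    path, so the same compound from either source yields identical
    atom/bond multisets.  Dummy atoms (``*``) become R-group atoms.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES", id=id, source=smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # retry without sanitisation so hypervalent / odd-charge entries
        # (common in component dictionaries) still yield a graph
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is not None:
            try:
                Chem.SanitizeMol(
                    mol,
                    Chem.SanitizeFlags.SANITIZE_ALL
                    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                )
            except Exception:
                mol = None
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES for {id!r}: {smiles!r}", id=id, source=smiles)
    return _from_rdkit(mol, id)


def _molblock_r_flags(text: str) -> dict[int, bool]:
    """Scan a V2000 atom block for R-group placeholder symbols."""
    lines = text.splitlines()
    flags: dict[int, bool] = {}
    if len(lines) < 4:
        return flags
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
    except (ValueError, IndexError):
        return flags
    for i in range(n_atoms):
        line_no = 4 + i
        if line_no >= len(lines):
            break
        symbol = lines[line_no][31:34].strip()
        if symbol in R_GROUP_SYMBOLS:
            flags[i] = True
    return flags


def parse_molfile(text: str, id: str) -> Molecule:
    """Parse an MDL MOL (V2000) block; 3D coordinates are ignored.

    Atom symbols ``R``, ``R#``, ``*`` and ``A`` become R_GROUP atoms and
    flag the molecule as a Markush structure.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty MOL block", id=id)
    r_flags = _molblock_r_flags(text)
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if mol is not None:
            try:
                Chem.SanitizeMol(
                    mol,
                    Chem.SanitizeFlags.SANITIZE_ALL
                    ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
                    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                )
            except Exception:
                mol = None
    if mol is None:
        # locate the offending region for the error message
        lines = text.splitlines()
        hint = "counts line" if len(lines) >= 4 else f"only {len(lines)} lines"
        raise MoleculeParseError(
            f"malformed MOL block for {id!r} (near {hint}, line 4)", id=id
        )
    return _from_rdkit(mol, id, r_flags=r_flags)


def parse_sdf(text: str) -> Iterator[Molecule]:
    """Split an SDF into records and parse each; record name is the id."""
    record: list[str] = []
    k = 0
    for line in text.splitlines() + ["$$$$"]:
        if line.strip() == "$$$$":
            block = "\n".join(record)
            record = []
            if block.strip():
                name = block.splitlines()[0].strip() or f"SDF{k}"
                k += 1
                yield parse_molfile(block, name)
        else:
            record.append(line)


def write_smiles(molecule: Molecule) -> str:
    """Canonical SMILES for a Molecule (R-group atoms written as ``*``)."""
    return Chem.MolToSmiles(molecule.to_rdkit())


@dataclass
class ComponentTable:
    """Component ID -> Molecule lookup built from SMILES descriptors.

    Entries whose descriptor fails to parse, or parses to an empty graph
    (e.g. a bare proton), are excluded and counted in ``n_skipped``.
    """

    molecules: dict[str, Molecule] = field(default_factory=dict)
    n_skipped: int = 0
    skipped_ids: list[str] = field(default_factory=list)

    def __contains__(self, key: str) -> bool:
        return key in self.molecules

    def __getitem__(self, key: str) -> Molecule:
        return self.molecules[key]

    def __len__(self) -> int:
        return len(self.molecules)

    def get(self, key: str) -> Molecule | None:
        return self.molecules.get(key)

    def add(self, id: str, smiles: str) -> None:
        if id in self.molecules:
            raise ValueError(f"duplicate component ID {id!r}")
        try:
            mol = parse_smiles(smiles, id)
        except MoleculeParseError:
            logger.warning("component %s: unusable SMILES %r, skipped", id, smiles)
            self.n_skipped += 1
            self.skipped_ids.append(id)
            return
        if mol.is_empty:
            logger.warning("component %s: no heavy atoms (%r), skipped", id, smiles)
            self.n_skipped += 1
            self.skipped_ids.append(id)
            return
        self.molecules[id] = mol

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ComponentTable":
        table = cls()
        seen: set[str] = set()
        for id, smiles in pairs:
            if id in seen:
                raise ValueError(f"duplicate component ID {id!r}")
            seen.add(id)
            table.add(id, smiles)
        return table


def _iter_csv_components(path: Path) -> Iterator[tuple[str, str]]:
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise MoleculeParseError(
                    f"{path}: row {row!r} lacks an id,smiles pair", source=str(path)
                )
            id, smiles = row[0].strip(), row[1].strip()
            if id.lower() in {"id", "component_id"} and not Chem.MolFromSmiles(smiles):
                continue  # header row
            yield id, smiles


def _iter_cif_components(path: Path) -> Iterator[tuple[str, str]]:
    import gemmi.cif

    doc = gemmi.cif.read(str(path))
    for block in doc:
        comp_id = block.find_value("_chem_comp.id") or block.name
        table = block.find("_pdbx_chem_comp_descriptor.", ["comp_id", "type", "descriptor"])
        smiles = None
        for row in table:
            if row[1].upper().startswith("SMILES"):
                smiles = row[2].strip('"').strip("'")
                if row[1].upper() == "SMILES_CANONICAL":
                    break
        if comp_id and smiles:
            yield comp_id.strip(), smiles


def load_component_table(path: str | Path) -> ComponentTable:
    """Load a component dictionary from CSV(id,smiles) or mmCIF CCD.

    The dialect is sniffed from the content: files containing a
    ``data_`` block are read as mmCIF, otherwise as two-column CSV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_text(errors="replace")[:4096]
    if not head.strip():
        logger.warning("%s: empty component table", path)
        return ComponentTable()
    if any(line.startswith("data_") for line in head.splitlines()):
        pairs: Iterable[tuple[str, str]] = _iter_cif_components(path)
    elif "," in head:
        pairs = _iter_csv_components(path)
    else:
        raise MoleculeParseError(
            f"{path}: neither mmCIF nor CSV component dialect recognised",
            source=str(path),
        )
    table = ComponentTable.from_pairs(pairs)
    if table.n_skipped:
        logger.warning("%s: skipped %d unusable entries", path, table.n_skipped)
    return table
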
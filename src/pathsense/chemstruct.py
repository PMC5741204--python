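"""Parsing, validation and normalization of compound structures.

All downstream encoding works on a canonical heavy-atom molecular graph:
aromatic form, formal charges neutralized where chemically possible,
hydrogens implicit, stereochemistry retained on the stored structure (but
ignored by :func:`canonical_key`, which identifies constitutionally
identical compounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

from pathsense.errors import StructureParseError, NormalizationError

RDLogger.DisableLog("rdApp.*")

#: bond order labels used throughout the fragment encoding
BOND_SINGLE = 1
BOND_DOUBLE = 2
BOND_TRIPLE = 3
BOND_AROMATIC = "ar"

_RDKIT_BOND_TO_LABEL = {
    Chem.BondType.SINGLE: BOND_SINGLE,
    Chem.BondType.DOUBLE: BOND_DOUBLE,
    Chem.BondType.TRIPLE: BOND_TRIPLE,
    Chem.BondType.AROMATIC: BOND_AROMATIC,
}


@dataclass(frozen=True)
class RawStructure:
    """A structure string with an explicitly tagged dialect.

    The dialect is never guessed from ambiguous content; as a convenience
    :meth:`from_text` recognizes the unambiguous ``InChI=`` prefix.
    """

    text: str
    dialect: str  # "InChI" | "SMILES"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("structure text must be non-empty")
        if self.dialect not in ("InChI", "SMILES"):
            raise ValueError(f"unknown dialect {self.dialect!r} (use 'InChI' or 'SMILES')")

    @classmethod
    def from_text(cls, text: str) -> "RawStructure":
        dialect = "InChI" if text.startswith("InChI=") or text.startswith("InChi=") else "SMILES"
        return cls(text=text, dialect=dialect)


@dataclass(frozen=True)
class MolGraph:
    """Heavy-atom molecular graph.

    atoms
        tuple of (element symbol, aromatic flag, stereo descriptor or None),
        indexed densely from 0.
    bonds
        tuple of (i, j, order) with i < j, order in {1, 2, 3, "ar"}; undirected,
        no duplicates.
    provenance
        the RawStructure this graph came from.
    multi_fragment
        true when the parsed input had more than one connected component.
    normalized
        set by :func:`normalize`.
    """

    atoms: tuple[tuple[str, bool, Optional[str]], ...]
    bonds: tuple[tuple[int, int, object], ...]
    provenance: RawStructure
    multi_fragment: bool = False
    normalized: bool = False
    rdmol: Chem.Mol = field(compare=False, hash=False, repr=False, default=None)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[tuple[int, object]]:
        """(neighbor index, bond order) pairs of atom ``idx``."""
        out = []
        for i, j, order in self.bonds:
            if i == idx:
                out.append((j, order))
            elif j == idx:
                out.append((i, order))
        return out

    def adjacency(self) -> dict[int, list[tuple[int, object]]]:
        adj: dict[int, list[tuple[int, object]]] = {i: [] for i in range(self.num_atoms)}
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def atom_label(self, idx: int) -> str:
        """Fragment atom label: element symbol, lowercased when aromatic."""
        symbol, aromatic, _stereo = self.atoms[idx]
        return symbol.lower() if aromatic else symbol

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for symbol, _aromatic, _stereo in self.atoms:
            counts[symbol] = counts.get(symbol, 0) + 1
        return counts


def _mol_to_graph(mol: Chem.Mol, provenance: RawStructure, *, multi_fragment: bool,
                  normalized: bool) -> MolGraph:
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    if len(heavy) != mol.GetNumAtoms():
        # explicit hydrogens are never part of the graph representation
        mol = Chem.RemoveHs(mol, sanitize=False)
        Chem.SanitizeMol(mol)
    atoms = []
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        stereo = None if tag == Chem.ChiralType.CHI_UNSPECIFIED else tag.name
        atoms.append((atom.GetSymbol(), atom.GetIsAromatic(), stereo))
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        order = _RDKIT_BOND_TO_LABEL.get(bond.GetBondType())
        if order is None:
            raise NormalizationError(
                f"unsupported bond type {bond.GetBondType()} between atoms {i} and {j}",
                atom_indices=(i, j),
            )
        bonds.append((i, j, order))
    return MolGraph(
        atoms=tuple(atoms),
        bonds=tuple(sorted(bonds, key=lambda b: (b[0], b[1]))),
        provenance=provenance,
        multi_fragment=multi_fragment,
        normalized=normalized,
        rdmol=mol,
    )


def parse_structure(raw: RawStructure) -> MolGraph:
    """Parse a structure string into an un-normalized molecular graph.

    Raises :class:`StructureParseError` on unparsable text or an empty
    molecule.
    """
    if raw.dialect == "InChI":
        text = raw.text
        if text.startswith("InChi="):  # tolerate the frequent capitalization variant
            text = "InChI=" + text[len("InChi="):]
        mol = Chem.MolFromInchi(text, sanitize=True, treatWarningAsError=False)
    else:
        mol = Chem.MolFromSmiles(raw.text, sanitize=True)
    if mol is None:
        raise StructureParseError(raw.text, raw.dialect)
    if mol.GetNumHeavyAtoms() == 0:
        raise StructureParseError(raw.text, raw.dialect, reason="empty molecule")
    n_frags = len(Chem.GetMolFrags(mol))
    return _mol_to_graph(mol, raw, multi_fragment=n_frags > 1, normalized=False)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    # deterministic choice: most heavy atoms, ties broken by canonical SMILES
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Set formal charges to zero, adjusting hydrogen counts.

    Charge-separated pairs that cannot be neutralized without rewriting
    connectivity (e.g. nitro groups) are left untouched; fragment atom
    labels carry no charge so they cannot leak into the encoding anyway.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        has_opposite_neighbor = any(
            n.GetFormalCharge() * charge < 0 for n in atom.GetNeighbors()
        )
        if has_opposite_neighbor:
            continue
        h_count = atom.GetTotalNumHs()
        if charge < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(h_count - charge)
        elif h_count >= charge:
            atom.SetFormalCharge(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(h_count - charge)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def normalize(mol: MolGraph) -> MolGraph:
    """Normalize a molecular graph: aromatic form, charges neutralized,
    hydrogens implicit, stereo preserved, salts reduced to the largest
    connected component. Idempotent.
    """
    if mol.normalized:
        return mol
    if mol.rdmol is None:
        raise NormalizationError("MolGraph lacks its backing structure; re-parse first")
    rdmol = Chem.Mol(mol.rdmol)
    rdmol = _largest_fragment(rdmol)
    rdmol = _neutralize(rdmol)
    rdmol = Chem.RemoveHs(rdmol)
    try:
        Chem.SetAromaticity(rdmol)
    except Exception as exc:  # pragma: no cover - rdkit failure paths are opaque
        raise NormalizationError(f"aromatic perception failed: {exc}") from exc
    return _mol_to_graph(rdmol, mol.provenance, multi_fragment=False, normalized=True)


def canonical_key(mol: MolGraph) -> str:
    """Deterministic key identical for isomorphic normalized graphs.

    Stereochemistry is deliberately excluded, so stereoisomers and
    protonation states collapse to one key.
    """
    if not mol.normalized:
        raise ValueError("canonical_key requires a normalized MolGraph")
    return Chem.MolToSmiles(mol.rdmol, isomericSmiles=False, canonical=True)


def parse_and_normalize(text_or_raw) -> MolGraph:
    """Convenience: parse (auto-tagging dialect by InChI= prefix) and normalize."""
    raw = text_or_raw if isinstance(text_or_raw, RawStructure) else RawStructure.from_text(text_or_raw)
    return normalize(parse_structure(raw))
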
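"""Self-contained toy knowledge bases.

Two curated fixtures encode well-characterized detection routes:

* ``cocaine`` — cocaine ester hydrolysis to benzoate (detectable through
  benzoate-responsive regulators) plus distractor chemistry.
* ``parathion`` — phosphotriesterase hydrolysis to 4-nitrophenol
  (DmpR-detectable) followed by monooxygenation releasing nitrite
  (NarL-detectable).

``random`` produces seed-reproducible small molecules with synthetic
reactions whose fragment arithmetic is balanced by construction (reaction
signatures are derived from the recorded reactant lists themselves).

Reactions here are heavy-atom balanced; hydrogen/redox bookkeeping
(NAD(P)H, O2) is intentionally simplified since the fragment encoding never
sees hydrogens.
"""

from __future__ import annotations

import random
import tempfile
from pathlib import Path

from rdkit import Chem

COCAINE_INCHI = (
    "InChI=1S/C17H21NO4/c1-18-12-8-9-13(18)15(17(20)21-2)14(10-12)22-16(19)"
    "11-6-4-3-5-7-11/h3-7,12-15H,8-10H2,1-2H3/t12-,13+,14-,15+/m0/s1"
)
PARATHION_SMILES = "CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]"
NITROPHENOL_SMILES = "Oc1ccc(cc1)[N+](=O)[O-]"

# (id, structure, dialect, xrefs)
_COCAINE_COMPOUNDS = [
    ("cocaine", COCAINE_INCHI, "InChI", "CHEBI:60056"),
    ("water", "O", "SMILES", "CHEBI:15377"),
    ("benzoate", "OC(=O)c1ccccc1", "SMILES", "CHEBI:16150|CHEBI:30746"),
    ("ecgonine_methyl_ester", "COC(=O)C1C(O)CC2CCC1N2C", "SMILES", "CHEBI:3944"),
    ("ethanol", "CCO", "SMILES", "CHEBI:16236"),
    ("acetaldehyde", "CC=O", "SMILES", "CHEBI:15343"),
    ("acetate", "CC(=O)[O-]", "SMILES", "CHEBI:30089"),
    ("phenol", "Oc1ccccc1", "SMILES", "CHEBI:15882"),
    ("benzene", "c1ccccc1", "SMILES", "CHEBI:16716"),
    ("toluene", "Cc1ccccc1", "SMILES", "CHEBI:17578"),
    ("cyclohexane", "C1CCCCC1", "SMILES", "CHEBI:29005"),
]

# (id, substrates, products, reversible, xrefs)
_COCAINE_REACTIONS = [
    ("RXN_cocaine_esterase", "cocaine|water", "benzoate|ecgonine_methyl_ester",
     "true", "RHEA:28650|EC:3.1.1.84"),
    ("RXN_ethanol_dehydrogenase", "ethanol", "acetaldehyde", "true", "EC:1.1.1.1"),
    ("RXN_aldehyde_dehydrogenase", "acetaldehyde|water", "acetate", "true", "EC:1.2.1.3"),
    ("RXN_benzene_hydroxylase", "benzene|water", "phenol", "true", "EC:1.14.13.244"),
    ("RXN_toluene_oxidase", "toluene|water|water", "benzoate", "true", "EC:1.14.12.11"),
    ("RXN_benzene_reductase", "benzene", "cyclohexane", "true", "FIXTURE:hydrogenation"),
]

_COCAINE_DETECTABLES = [
    ("benzoate", "benzoate", "BenM|BenR|CbdS|PcaR|TcbR|CatR|BadR|XylS", "fixture"),
]

_COCAINE_COFACTORS = ["water"]

_PARATHION_COMPOUNDS = [
    ("parathion", PARATHION_SMILES, "SMILES", "CHEBI:27928"),
    ("water", "O", "SMILES", "CHEBI:15377"),
    ("4-nitrophenol", NITROPHENOL_SMILES, "SMILES", "CHEBI:16836"),
    ("diethyl_thiophosphate", "CCOP(=S)(O)OCC", "SMILES", "CHEBI:62951"),
    ("nitrite", "ON=O", "SMILES", "CHEBI:16301"),
    ("hydroquinone", "Oc1ccc(O)cc1", "SMILES", "CHEBI:17594"),
    ("phenol", "Oc1ccccc1", "SMILES", "CHEBI:15882"),
    ("catechol", "Oc1ccccc1O", "SMILES", "CHEBI:18135"),
    ("benzene", "c1ccccc1", "SMILES", "CHEBI:16716"),
    ("ethanol", "CCO", "SMILES", "CHEBI:16236"),
    ("acetaldehyde", "CC=O", "SMILES", "CHEBI:15343"),
    ("cyclohexane", "C1CCCCC1", "SMILES", "CHEBI:29005"),
]

_PARATHION_REACTIONS = [
    ("RXN_phosphotriesterase", "parathion|water", "4-nitrophenol|diethyl_thiophosphate",
     "true", "EC:3.1.8.1"),
    ("RXN_nitrophenol_monooxygenase", "4-nitrophenol|water", "hydroquinone|nitrite",
     "true", "EC:1.14.13.29"),
    ("RXN_benzene_hydroxylase", "benzene|water", "phenol", "true", "EC:1.14.13.244"),
    ("RXN_phenol_2_hydroxylase", "phenol|water", "catechol", "true", "EC:1.14.13.7"),
    ("RXN_ethanol_dehydrogenase", "ethanol", "acetaldehyde", "true", "EC:1.1.1.1"),
    ("RXN_benzene_reductase", "benzene", "cyclohexane", "true", "FIXTURE:hydrogenation"),
]

_PARATHION_DETECTABLES = [
    ("4-nitrophenol", "4-nitrophenol", "DmpR", "fixture"),
    ("nitrite", "nitrite", "NarL", "fixture"),
]

_PARATHION_COFACTORS = ["water"]


def _write_tsv(path: Path, header: tuple[str, ...], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(cell) for cell in row) + "\n")


def _write_kb(directory: Path, compounds, reactions, detectables, cofactors) -> Path:
    directory.mkdir(parents=True, exist_ok=True)
    _write_tsv(directory / "compounds.tsv", ("id", "structure", "dialect", "xrefs"), compounds)
    _write_tsv(directory / "reactions.tsv",
               ("id", "substrates", "products", "reversible", "xrefs"), reactions)
    _write_tsv(directory / "detectables.tsv",
               ("compound_id", "effector", "transcription_factors", "source"), detectables)
    _write_tsv(directory / "cofactors.tsv", ("compound_id",), [(c,) for c in cofactors])
    return directory


_ELEMENTS = ["C", "C", "C", "C", "C", "C", "C", "O", "O", "N"]
_MAX_VALENCE = {"C": 4, "O": 2, "N": 3}


def random_molecule(rng: random.Random, min_atoms: int = 3, max_atoms: int = 8) -> str:
    """Seed-reproducible random acyclic small molecule, as canonical SMILES."""
    n = rng.randint(min_atoms, max_atoms)
    mol = Chem.RWMol()
    symbols = []
    free = []  # remaining valence per atom
    first = rng.choice(_ELEMENTS)
    mol.AddAtom(Chem.Atom(first))
    symbols.append(first)
    free.append(_MAX_VALENCE[first])
    for _ in range(n - 1):
        anchors = [i for i, f in enumerate(free) if f >= 1]
        if not anchors:
            break
        anchor = rng.choice(anchors)
        symbol = rng.choice(_ELEMENTS)
        idx = mol.AddAtom(Chem.Atom(symbol))
        symbols.append(symbol)
        free.append(_MAX_VALENCE[symbol])
        order = Chem.BondType.SINGLE
        used = 1
        if free[anchor] >= 2 and free[idx] >= 2 and symbols[idx] != "O" and rng.random() < 0.2:
            order = Chem.BondType.DOUBLE
            used = 2
        mol.AddBond(anchor, idx, order)
        free[anchor] -= used
        free[idx] -= used
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _random_kb_rows(seed: int, n_compounds: int, n_reactions: int):
    rng = random.Random(seed)
    smiles_seen: dict[str, str] = {}
    compounds = []
    attempts = 0
    while len(compounds) < n_compounds and attempts < n_compounds * 50:
        attempts += 1
        smi = random_molecule(rng)
        if smi in smiles_seen.values():
            continue
        cid = f"RND_C{len(compounds):03d}"
        smiles_seen[cid] = smi
        compounds.append((cid, smi, "SMILES", ""))
    ids = [c[0] for c in compounds]
    reactions = []
    for k in range(n_reactions):
        n_sub = rng.randint(1, 2)
        n_prod = rng.randint(1, 2)
        substrates = rng.sample(ids, n_sub)
        products = rng.sample(ids, n_prod)
        reversible = "true" if rng.random() < 0.5 else "false"
        reactions.append((f"RND_RXN{k:03d}", "|".join(substrates), "|".join(products),
                          reversible, ""))
    detectables = [
        (cid, cid, "FixR", "fixture") for cid in sorted(rng.sample(ids, min(2, len(ids))))
    ]
    return compounds, reactions, detectables, []


def build_fixture_kb(name: str, seed: int = 0, out_dir: str | Path | None = None,
                     n_compounds: int = 12, n_reactions: int = 6) -> Path:
    """Write a named fixture knowledge base and return its directory.

    ``name`` is one of ``cocaine``, ``parathion``, ``random``; the size
    parameters apply to ``random`` only.  Identical arguments produce
    byte-identical directories.
    """
    if out_dir is None:
        out_dir = Path(tempfile.mkdtemp(prefix=f"pathsense_{name}_"))
    directory = Path(out_dir)
    if name == "cocaine":
        return _write_kb(directory, _COCAINE_COMPOUNDS, _COCAINE_REACTIONS,
                         _COCAINE_DETECTABLES, _COCAINE_COFACTORS)
    if name == "parathion":
        return _write_kb(directory, _PARATHION_COMPOUNDS, _PARATHION_REACTIONS,
                         _PARATHION_DETECTABLES, _PARATHION_COFACTORS)
    if name == "random":
        return _write_kb(directory, *_random_kb_rows(seed, n_compounds, n_reactions))
    raise ValueError(f"unknown fixture {name!r} (expected cocaine, parathion or random)")
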
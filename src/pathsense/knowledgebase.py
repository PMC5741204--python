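"""Tabular knowledge base: compounds, reactions, detectable compounds and
cofactors, with cached signatures and a fragment index.

Directory layout (UTF-8, tab-delimited, one header row):

* ``compounds.tsv``   — id, structure, dialect, xrefs (pipe-separated)
* ``reactions.tsv``   — id, substrates (pipe-separated, primary first),
  products, reversible (true/false), xrefs
* ``detectables.tsv`` — compound_id, effector, transcription_factors
  (pipe-separated), source
* ``cofactors.tsv``   — compound_id
* ``cache/signatures.tsv`` — optional: structure key, diameter, fragment, count

Compounds are deduplicated by canonical structure key with cross-references
unioned; rows that cannot be parsed, normalized or referentially resolved go
to a rejection report, never silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pathsense.chemstruct import MolGraph, RawStructure, normalize, parse_structure, canonical_key
from pathsense.config import RunConfig
from pathsense.errors import KnowledgeBaseError, PathsenseError
from pathsense.matching import FragmentIndex
from pathsense.signatures import (
    MolecularSignature,
    ReactionSignature,
    molecular_signature,
    reaction_signature,
)
from pathsense.similarity import Fingerprint, fingerprint

COMPOUNDS_FILE = "compounds.tsv"
REACTIONS_FILE = "reactions.tsv"
DETECTABLES_FILE = "detectables.tsv"
COFACTORS_FILE = "cofactors.tsv"
CACHE_DIR = "cache"
CACHE_FILE = "signatures.tsv"


@dataclass
class CompoundRecord:
    id: str
    raw: RawStructure
    mol: MolGraph
    key: str
    signature: MolecularSignature
    fingerprint: Fingerprint
    xrefs: tuple[str, ...] = ()


@dataclass
class ReactionRecord:
    id: str
    substrate_ids: tuple[str, ...]  # primary first
    product_ids: tuple[str, ...]
    reversible: bool
    xrefs: tuple[str, ...]
    forward_signature: ReactionSignature
    reverse_signature: ReactionSignature


@dataclass
class DetectableRecord:
    compound_id: str
    effector: str
    transcription_factors: tuple[str, ...]
    source: str = ""


@dataclass
class Rejection:
    file: str
    row_id: str
    reason: str


@dataclass
class KnowledgeBase:
    config: RunConfig
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)  # any id -> primary id
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    detectables: list[DetectableRecord] = field(default_factory=list)
    cofactor_ids: set[str] = field(default_factory=set)
    fragment_index: FragmentIndex = field(default_factory=FragmentIndex)
    rejections: list[Rejection] = field(default_factory=list)

    def resolve_id(self, compound_id: str) -> str:
        if compound_id not in self.aliases:
            raise KeyError(f"unknown compound id {compound_id!r}")
        return self.aliases[compound_id]

    def compound(self, compound_id: str) -> CompoundRecord:
        return self.compounds[self.resolve_id(compound_id)]

    def compound_by_key(self, key: str) -> Optional[CompoundRecord]:
        for record in self.compounds.values():
            if record.key == key:
                return record
        return None

    def is_cofactor(self, compound_id: str) -> bool:
        try:
            return self.resolve_id(compound_id) in self.cofactor_ids
        except KeyError:
            return False

    def detectables_for_key(self, key: str) -> list[DetectableRecord]:
        return [
            det for det in self.detectables
            if self.compound(det.compound_id).key == key
        ]

    # -- construction -----------------------------------------------------

    def add_compound(self, compound_id: str, raw: RawStructure,
                     xrefs: tuple[str, ...] = (),
                     cache: Optional[dict[tuple[str, int], MolecularSignature]] = None) -> CompoundRecord:
        """Parse, normalize, encode and register a compound, deduplicating
        by canonical structure key (cross-references are unioned)."""
        if compound_id in self.aliases:
            raise KnowledgeBaseError(f"duplicate compound id {compound_id!r}")
        mol = normalize(parse_structure(raw))
        key = canonical_key(mol)
        existing = self.compound_by_key(key)
        if existing is not None:
            existing.xrefs = tuple(sorted(set(existing.xrefs) | set(xrefs)))
            self.aliases[compound_id] = existing.id
            return existing
        diameter = self.config.diameter
        cached = (cache or {}).get((key, diameter))
        sig = cached if cached is not None else molecular_signature(mol, diameter)
        record = CompoundRecord(
            id=compound_id,
            raw=raw,
            mol=mol,
            key=key,
            signature=sig,
            fingerprint=fingerprint(mol, self.config.fingerprint_width),
            xrefs=tuple(sorted(set(xrefs))),
        )
        self.compounds[compound_id] = record
        self.aliases[compound_id] = compound_id
        self.fragment_index.add(compound_id, sig)
        return record

    def add_reaction(self, reaction_id: str, substrate_ids: tuple[str, ...],
                     product_ids: tuple[str, ...], reversible: bool,
                     xrefs: tuple[str, ...] = ()) -> ReactionRecord:
        if reaction_id in self.reactions:
            raise KnowledgeBaseError(f"duplicate reaction id {reaction_id!r}")
        for cid in (*substrate_ids, *product_ids):
            if cid not in self.aliases:
                raise KnowledgeBaseError(f"reaction {reaction_id!r} references unknown compound {cid!r}")
        sub_sigs = [self.compound(cid).signature for cid in substrate_ids]
        prod_sigs = [self.compound(cid).signature for cid in product_ids]
        forward = reaction_signature(sub_sigs, prod_sigs)
        record = ReactionRecord(
            id=reaction_id,
            substrate_ids=tuple(self.resolve_id(c) for c in substrate_ids),
            product_ids=tuple(self.resolve_id(c) for c in product_ids),
            reversible=reversible,
            xrefs=tuple(sorted(set(xrefs))),
            forward_signature=forward,
            reverse_signature=forward.reversed(),
        )
        self.reactions[reaction_id] = record
        return record

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Write the registries back to a knowledge-base directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        compound_rows = [
            (rec.id, rec.raw.text, rec.raw.dialect, "|".join(rec.xrefs))
            for rec in sorted(self.compounds.values(), key=lambda r: r.id)
        ]
        _write_tsv(directory / COMPOUNDS_FILE,
                   ("id", "structure", "dialect", "xrefs"), compound_rows)
        reaction_rows = [
            (rec.id, "|".join(rec.substrate_ids), "|".join(rec.product_ids),
             "true" if rec.reversible else "false", "|".join(rec.xrefs))
            for rec in sorted(self.reactions.values(), key=lambda r: r.id)
        ]
        _write_tsv(directory / REACTIONS_FILE,
                   ("id", "substrates", "products", "reversible", "xrefs"), reaction_rows)
        detectable_rows = [
            (det.compound_id, det.effector, "|".join(det.transcription_factors), det.source)
            for det in sorted(self.detectables, key=lambda d: (d.compound_id, d.effector))
        ]
        _write_tsv(directory / DETECTABLES_FILE,
                   ("compound_id", "effector", "transcription_factors", "source"), detectable_rows)
        _write_tsv(directory / COFACTORS_FILE, ("compound_id",),
                   [(cid,) for cid in sorted(self.cofactor_ids)])
        self.write_cache(directory)
        return directory

    def write_cache(self, directory: str | Path) -> Path:
        cache_path = Path(directory) / CACHE_DIR
        cache_path.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in sorted(self.compounds.values(), key=lambda r: r.key):
            for fragment, count in rec.signature.fragments.items():
                rows.append((rec.key, str(rec.signature.diameter), fragment, str(count)))
        _write_tsv(cache_path / CACHE_FILE, ("key", "diameter", "fragment", "count"), rows)
        return cache_path / CACHE_FILE


def _write_tsv(path: Path, header: tuple[str, ...], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(cell) for cell in row) + "\n")


def _read_tsv(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        raise KnowledgeBaseError(f"missing knowledge-base file: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [row for row in reader if any((v or "").strip() for v in row.values())]


def _split(value: str) -> tuple[str, ...]:
    return tuple(part for part in (value or "").split("|") if part)


def _read_cache(directory: Path) -> dict[tuple[str, int], MolecularSignature]:
    cache_file = directory / CACHE_DIR / CACHE_FILE
    if not cache_file.exists():
        return {}
    grouped: dict[tuple[str, int], dict[str, int]] = {}
    for row in _read_tsv(cache_file):
        key = (row["key"], int(row["diameter"]))
        grouped.setdefault(key, {})[row["fragment"]] = int(row["count"])
    return {
        (key, diameter): MolecularSignature(fragments, diameter)
        for (key, diameter), fragments in grouped.items()
    }


def load_kb(directory: str | Path, config: Optional[RunConfig] = None) -> KnowledgeBase:
    """Load and index a knowledge-base directory.

    Invalid rows (unparsable structures, dangling references) end up in
    ``kb.rejections`` with a reason; everything else is parsed, normalized,
    deduplicated and signature-encoded at ``config.diameter``.
    """
    directory = Path(directory)
    config = config or RunConfig()
    kb = KnowledgeBase(config=config)
    cache = _read_cache(directory)

    for row in _read_tsv(directory / COMPOUNDS_FILE):
        cid = (row.get("id") or "").strip()
        try:
            if not cid:
                raise KnowledgeBaseError("missing compound id")
            raw = RawStructure(text=row["structure"], dialect=row["dialect"])
            kb.add_compound(cid, raw, xrefs=_split(row.get("xrefs", "")), cache=cache)
        except (PathsenseError, ValueError, KeyError) as exc:
            kb.rejections.append(Rejection(COMPOUNDS_FILE, cid or "<blank>", str(exc)))

    for row in _read_tsv(directory / REACTIONS_FILE):
        rid = (row.get("id") or "").strip()
        try:
            if not rid:
                raise KnowledgeBaseError("missing reaction id")
            substrates = _split(row["substrates"])
            products = _split(row["products"])
            if not substrates or not products:
                raise KnowledgeBaseError("reaction needs at least one substrate and one product")
            reversible = (row.get("reversible", "true").strip().lower()
                          in ("true", "1", "yes"))
            kb.add_reaction(rid, substrates, products, reversible,
                            xrefs=_split(row.get("xrefs", "")))
        except (PathsenseError, ValueError, KeyError) as exc:
            kb.rejections.append(Rejection(REACTIONS_FILE, rid or "<blank>", str(exc)))

    for row in _read_tsv(directory / DETECTABLES_FILE):
        cid = (row.get("compound_id") or "").strip()
        try:
            kb.resolve_id(cid)
            kb.detectables.append(DetectableRecord(
                compound_id=cid,
                effector=row.get("effector", cid),
                transcription_factors=_split(row.get("transcription_factors", "")),
                source=row.get("source", ""),
            ))
        except KeyError as exc:
            kb.rejections.append(Rejection(DETECTABLES_FILE, cid or "<blank>", str(exc)))

    for row in _read_tsv(directory / COFACTORS_FILE):
        cid = (row.get("compound_id") or "").strip()
        try:
            kb.cofactor_ids.add(kb.resolve_id(cid))
        except KeyError as exc:
            kb.rejections.append(Rejection(COFACTORS_FILE, cid or "<blank>", str(exc)))

    return kb


def write_rejection_report(kb: KnowledgeBase, path: str | Path) -> None:
    _write_tsv(Path(path), ("file", "row_id", "reason"),
               [(r.file, r.row_id, r.reason) for r in kb.rejections])


# re-exported here because fixture generation is part of the knowledge-base
# surface (see pathsense.fixtures for the actual data)
from pathsense.fixtures import build_fixture_kb  # noqa: E402,F401
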
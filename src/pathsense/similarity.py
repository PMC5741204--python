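"""Hashed circular fingerprints and Jaccard-Tanimoto similarity.

Fingerprints fold the canonical atom-environment fragments at diameters
{0, 2, 4} into a fixed-width bitset via a stable cryptographic-hash bit
assignment, so fingerprints (and every similarity score) are identical
across runs and platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import TYPE_CHECKING

from pathsense.chemstruct import MolGraph, canonical_key
from pathsense.signatures import molecular_signature

if TYPE_CHECKING:  # pragma: no cover
    from pathsense.knowledgebase import KnowledgeBase

FINGERPRINT_DIAMETERS = (0, 2, 4)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width bitset over hashed circular fragments."""

    bits: frozenset[int]
    width: int
    molecule_key: str

    def __post_init__(self) -> None:
        if any(not 0 <= b < self.width for b in self.bits):
            raise ValueError("fingerprint bit outside width")

    @property
    def popcount(self) -> int:
        return len(self.bits)


def _bit_for(fragment: str, width: int) -> int:
    digest = hashlib.sha256(fragment.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % width


def fingerprint(mol: MolGraph, width: int = 2048) -> Fingerprint:
    """Deterministic hashed fingerprint of a normalized molecule.

    Set-bit count never exceeds the number of distinct fragments at
    diameters {0, 2, 4}.
    """
    bits = set()
    for diameter in FINGERPRINT_DIAMETERS:
        for fragment in molecular_signature(mol, diameter).fragments:
            bits.add(_bit_for(f"{diameter}|{fragment}", width))
    return Fingerprint(bits=frozenset(bits), width=width, molecule_key=canonical_key(mol))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∧ b| / |a ∨ b|; 1.0 when both empty (degenerate); symmetric."""
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def precompute_similarity(kb: "KnowledgeBase") -> dict[tuple[str, str], float]:
    """Dense compound x detectable similarity table.

    Exact structural identity (same canonical key) always scores 1.0, even
    in the unlikely event of a fingerprint hash collision hiding it.
    """
    table: dict[tuple[str, str], float] = {}
    for cid, compound in sorted(kb.compounds.items()):
        for det in kb.detectables:
            det_compound = kb.compound(det.compound_id)
            if compound.key == det_compound.key:
                score = 1.0
            else:
                score = tanimoto(compound.fingerprint, det_compound.fingerprint)
            table[(cid, det.compound_id)] = score
    return table


def write_similarity_table(table: dict[tuple[str, str], float], path) -> None:
    lines = ["compound_id\tdetectable_id\tscore"]
    for (cid, did), score in sorted(table.items()):
        lines.append(f"{cid}\t{did}\t{score:.6f}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
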
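"""Canonical atomic signatures, molecular-signature multisets and signed
reaction signatures.

An atomic signature is a canonical serialization of the subgraph induced by
all atoms within ``diameter/2`` bonds of a root atom.  Canonization searches
for the lexicographically minimal token sequence over all root-anchored,
connectivity-respecting atom orderings; ties are branched exhaustively, so
two atoms receive the same string **iff** their rooted environments are
isomorphic as labelled rooted graphs.  ``pathsense.oracle`` recomputes the
same minimum by brute-force permutation enumeration and pins correctness in
the test suite.

Atom labels are (element, aromatic flag) — lowercased symbol when aromatic;
bond labels are ``- = # :`` for single/double/triple/aromatic.  Charges,
stereo and hydrogen counts do not enter the encoding.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from pathsense.chemstruct import MolGraph
from pathsense.errors import DiameterMismatchError

BOND_CHAR = {1: "-", 2: "=", 3: "#", "ar": ":"}


@dataclass(frozen=True, order=True)
class AtomicSignature:
    """Canonical string of one atom's bonded environment at a fixed diameter."""

    canonical_string: str
    diameter: int


class MolecularSignature:
    """Multiset of atomic-signature strings, one fragment per heavy atom."""

    __slots__ = ("fragments", "diameter")

    def __init__(self, fragments: Mapping[str, int], diameter: int):
        if any(c <= 0 for c in fragments.values()):
            raise ValueError("molecular signature counts must be positive")
        self.fragments: dict[str, int] = dict(sorted(fragments.items()))
        self.diameter = diameter

    def total(self) -> int:
        return sum(self.fragments.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MolecularSignature)
            and self.diameter == other.diameter
            and self.fragments == other.fragments
        )

    def __repr__(self) -> str:
        return f"MolecularSignature(d={self.diameter}, {len(self.fragments)} distinct, {self.total()} total)"

    def union(self, *others: "MolecularSignature") -> "MolecularSignature":
        """Multiset union (sum of counts)."""
        counts = Counter(self.fragments)
        for other in others:
            if other.diameter != self.diameter:
                raise DiameterMismatchError(
                    f"cannot combine signatures at diameters {self.diameter} and {other.diameter}"
                )
            counts.update(other.fragments)
        return MolecularSignature(counts, self.diameter)

    def to_text(self) -> str:
        """Sorted ``fragment<TAB>count`` lines; stable across runs."""
        return "\n".join(f"{frag}\t{count}" for frag, count in self.fragments.items())

    @classmethod
    def from_text(cls, text: str, diameter: int) -> "MolecularSignature":
        fragments: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            frag, count = line.rsplit("\t", 1)
            fragments[frag] = int(count)
        return cls(fragments, diameter)


class ReactionSignature:
    """Signed fragment multiset: products minus substrates, zero entries dropped."""

    __slots__ = ("deltas", "diameter")

    def __init__(self, deltas: Mapping[str, int], diameter: int):
        self.deltas: dict[str, int] = dict(sorted((f, d) for f, d in deltas.items() if d != 0))
        self.diameter = diameter

    def negative_part(self) -> dict[str, int]:
        """Substrate-side fragments consumed, as positive counts."""
        return {f: -d for f, d in self.deltas.items() if d < 0}

    def positive_part(self) -> dict[str, int]:
        """Product-side fragments created."""
        return {f: d for f, d in self.deltas.items() if d > 0}

    def reversed(self) -> "ReactionSignature":
        return ReactionSignature({f: -d for f, d in self.deltas.items()}, self.diameter)

    def is_empty(self) -> bool:
        return not self.deltas

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReactionSignature)
            and self.diameter == other.diameter
            and self.deltas == other.deltas
        )

    def __repr__(self) -> str:
        return f"ReactionSignature(d={self.diameter}, {len(self.deltas)} deltas)"


def _environment(mol: MolGraph, root: int, radius: int) -> tuple[set[int], dict[int, list[tuple[int, object]]]]:
    """Atoms within ``radius`` bonds of root and the induced adjacency."""
    adj = mol.adjacency()
    dist = {root: 0}
    queue = deque([root])
    while queue:
        cur = queue.popleft()
        if dist[cur] == radius:
            continue
        for nbr, _order in adj[cur]:
            if nbr not in dist:
                dist[nbr] = dist[cur] + 1
                queue.append(nbr)
    ball = set(dist)
    induced = {
        a: [(n, o) for n, o in adj[a] if n in ball]
        for a in ball
    }
    return ball, induced


def _min_token_tuple(labels: Mapping[int, str], adj: Mapping[int, list[tuple[int, object]]],
                     root: int) -> tuple[str, ...]:
    """Lexicographically minimal token sequence over all root-anchored
    connected orderings of the environment.

    Level-synchronized search: all live branches share an identical token
    prefix; at each level the globally minimal next token is computed and
    only branches achieving it survive.  Exact, because the environment is
    connected through the root and any prefix extends to a full ordering.
    """
    n = len(labels)
    tokens: list[str] = [labels[root]]
    # each state: (ordered placement, atom -> position)
    states: list[tuple[list[int], dict[int, int]]] = [([root], {root: 0})]
    for _level in range(1, n):
        best_token: str | None = None
        survivors: list[tuple[list[int], dict[int, int], int]] = []
        for placed, pos in states:
            candidates = set()
            for a in placed:
                for nbr, _o in adj[a]:
                    if nbr not in pos:
                        candidates.add(nbr)
            for cand in candidates:
                back = sorted((pos[nbr], BOND_CHAR[order]) for nbr, order in adj[cand] if nbr in pos)
                token = labels[cand] + "".join(f"({p}{b})" for p, b in back)
                if best_token is None or token < best_token:
                    best_token = token
                    survivors = [(placed, pos, cand)]
                elif token == best_token:
                    survivors.append((placed, pos, cand))
        assert best_token is not None, "environment not connected through root"
        tokens.append(best_token)
        next_states = []
        seen_keys = set()
        for placed, pos, cand in survivors:
            new_placed = placed + [cand]
            key = tuple(new_placed)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            new_pos = dict(pos)
            new_pos[cand] = len(placed)
            next_states.append((new_placed, new_pos))
        states = next_states
    return tuple(tokens)


def atomic_signature(mol: MolGraph, atom_index: int, diameter: int) -> AtomicSignature:
    """Canonical signature of the environment of one atom.

    ``diameter`` counts bonds across the environment (radius = diameter/2);
    environments truncated by the molecule boundary are encoded as-is.
    """
    if diameter < 0 or diameter % 2 != 0:
        raise ValueError(f"diameter must be even and >= 0, got {diameter}")
    if not 0 <= atom_index < mol.num_atoms:
        raise IndexError(f"atom index {atom_index} out of range for {mol.num_atoms} atoms")
    ball, induced = _environment(mol, atom_index, diameter // 2)
    labels = {a: mol.atom_label(a) for a in ball}
    tokens = _min_token_tuple(labels, induced, atom_index)
    return AtomicSignature(canonical_string="|".join(tokens), diameter=diameter)


def molecular_signature(mol: MolGraph, diameter: int) -> MolecularSignature:
    """One fragment per heavy atom, aggregated into a multiset.

    The sum of counts always equals the heavy-atom count.
    """
    counts: Counter[str] = Counter()
    for idx in range(mol.num_atoms):
        counts[atomic_signature(mol, idx, diameter).canonical_string] += 1
    return MolecularSignature(counts, diameter)


def reaction_signature(substrates: Iterable[MolecularSignature],
                       products: Iterable[MolecularSignature]) -> ReactionSignature:
    """Products-minus-substrates signed fragment difference."""
    substrates = list(substrates)
    products = list(products)
    diameters = {s.diameter for s in substrates} | {p.diameter for p in products}
    if len(diameters) > 1:
        raise DiameterMismatchError(f"mixed diameters in reaction signature: {sorted(diameters)}")
    diameter = diameters.pop() if diameters else 0
    deltas: Counter[str] = Counter()
    for product in products:
        deltas.update(product.fragments)
    for substrate in substrates:
        deltas.subtract(substrate.fragments)
    return ReactionSignature(deltas, diameter)


def signature_diameter_check(sig: Union[MolecularSignature, ReactionSignature],
                             expected: int) -> bool:
    """Guard used by all signature consumers."""
    return sig.diameter == expected
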
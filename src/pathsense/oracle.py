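"""Brute-force reference implementations used to pin the fast encoders.

Everything here is deliberately naive: environments are canonized by
enumerating every root-anchored permutation, and product resolution by
enumerating every compound subset.  Only suitable for small inputs.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import permutations, combinations_with_replacement

from pathsense.chemstruct import MolGraph
from pathsense.signatures import BOND_CHAR


def brute_force_atomic_signature(mol: MolGraph, atom_index: int, diameter: int) -> str:
    """Exhaustive-permutation canonization of the rooted environment.

    Independent of the production search in ``pathsense.signatures``: builds
    the ball, then tries *every* ordering of the remaining atoms, discarding
    orderings where some atom has no bond back into its prefix, and returns
    the minimal token sequence joined with ``|``.
    """
    if diameter % 2 != 0:
        raise ValueError("diameter must be even")
    radius = diameter // 2
    adj: dict[int, list[tuple[int, object]]] = {i: [] for i in range(mol.num_atoms)}
    for i, j, order in mol.bonds:
        adj[i].append((j, order))
        adj[j].append((i, order))
    dist = {atom_index: 0}
    queue = deque([atom_index])
    while queue:
        cur = queue.popleft()
        if dist[cur] >= radius:
            continue
        for nbr, _o in adj[cur]:
            if nbr not in dist:
                dist[nbr] = dist[cur] + 1
                queue.append(nbr)
    ball = sorted(dist)
    others = [a for a in ball if a != atom_index]
    bonds_in_ball = {}
    for a in ball:
        for nbr, order in adj[a]:
            if nbr in dist:
                bonds_in_ball[(a, nbr)] = order

    def label(a: int) -> str:
        return mol.atom_label(a)

    best: tuple[str, ...] | None = None
    for perm in permutations(others):
        ordering = (atom_index,) + perm
        pos = {a: k for k, a in enumerate(ordering)}
        tokens = [label(atom_index)]
        valid = True
        for k in range(1, len(ordering)):
            atom = ordering[k]
            back = sorted(
                (pos[nbr], BOND_CHAR[order])
                for (a, nbr), order in bonds_in_ball.items()
                if a == atom and pos[nbr] < k
            )
            if not back:
                valid = False
                break
            tokens.append(label(atom) + "".join(f"({p}{b})" for p, b in back))
        if valid and (best is None or tuple(tokens) < best):
            best = tuple(tokens)
    assert best is not None
    return "|".join(best)


def brute_force_resolve(P: dict[str, int], compound_signatures: dict[str, dict[str, int]],
                        max_parts: int = 3) -> list[tuple[str, ...]]:
    """Enumerate every multiset of <= max_parts compounds whose signatures sum
    exactly to the fragment multiset ``P``.  Returns sorted id-tuples."""
    target = Counter(P)
    if not target:
        return [()]
    ids = sorted(compound_signatures)
    hits = set()
    for k in range(1, max_parts + 1):
        for combo in combinations_with_replacement(ids, k):
            total: Counter[str] = Counter()
            for cid in combo:
                total.update(compound_signatures[cid])
            if total == target:
                hits.add(tuple(sorted(combo)))
    return sorted(hits)
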
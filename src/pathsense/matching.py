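"""Forward matching: embed a reaction signature's substrate fragments in a
query compound, build the putative product fragment multiset, and resolve it
into known compounds.

A reaction is *accepted* for a query only when the resulting positive
fragment multiset can be partitioned exactly into signatures of known
compounds; a match with no resolution is kept for diagnostics but produces
no products.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from pathsense.errors import DiameterMismatchError, MatchingError
from pathsense.signatures import MolecularSignature, ReactionSignature

if TYPE_CHECKING:  # pragma: no cover
    from pathsense.knowledgebase import KnowledgeBase, ReactionRecord, CompoundRecord


@dataclass(frozen=True)
class MatchResult:
    """Outcome of applying one reaction (in one direction) to one compound.

    ``resolved_products`` lists every exact partition of the produced
    fragments into known compounds; an empty list means the application was
    rejected.
    """

    reaction_id: str
    direction: str  # "forward" | "reverse"
    matched: bool
    consumed: dict[str, int] = field(default_factory=dict)
    produced_fragments: dict[str, int] = field(default_factory=dict)
    resolved_products: tuple[tuple[str, ...], ...] = ()

    @property
    def accepted(self) -> bool:
        return bool(self.resolved_products)

    def to_tsv_row(self) -> str:
        status = "accepted" if self.accepted else ("matched-unresolved" if self.matched else "no-match")
        products = ";".join(",".join(ps) for ps in self.resolved_products)
        return f"{self.reaction_id}\t{self.direction}\t{status}\t{products}"


def _combined(compound_sig: MolecularSignature,
              co_substrate_sigs: Sequence[MolecularSignature]) -> Counter:
    counts = Counter(compound_sig.fragments)
    for co in co_substrate_sigs:
        if co.diameter != compound_sig.diameter:
            raise DiameterMismatchError(
                f"co-substrate diameter {co.diameter} != query diameter {compound_sig.diameter}"
            )
        counts.update(co.fragments)
    return counts


def embeds(compound_sig: MolecularSignature, rxn_sig: ReactionSignature,
           co_substrate_sigs: Sequence[MolecularSignature] = ()) -> bool:
    """True iff query + co-substrates cover every consumed fragment of the
    reaction signature, with the query itself covering at least one of them
    (the query must participate in the reaction centre)."""
    if rxn_sig.diameter != compound_sig.diameter:
        raise DiameterMismatchError(
            f"reaction diameter {rxn_sig.diameter} != query diameter {compound_sig.diameter}"
        )
    negative = rxn_sig.negative_part()
    if not negative:
        # nothing is consumed (e.g. the identity signature): vacuously embedded
        return True
    available = _combined(compound_sig, co_substrate_sigs)
    if any(available[frag] < needed for frag, needed in negative.items()):
        return False
    return any(compound_sig.fragments.get(frag, 0) > 0 for frag in negative)


def apply_signature(compound_sig: MolecularSignature, rxn_sig: ReactionSignature,
                    co_substrate_sigs: Sequence[MolecularSignature] = ()) -> dict[str, int]:
    """(query ⊎ co-substrates) + reaction deltas, zero entries dropped.

    Raises :class:`MatchingError` when called without a valid embedding.
    """
    if not embeds(compound_sig, rxn_sig, co_substrate_sigs):
        available = _combined(compound_sig, co_substrate_sigs)
        violated = tuple(
            frag for frag, needed in rxn_sig.negative_part().items()
            if available[frag] < needed
        )
        raise MatchingError("reaction signature does not embed in query", violated)
    counts = _combined(compound_sig, co_substrate_sigs)
    counts.update(rxn_sig.deltas)  # Counter.update adds (signed) values
    result = {frag: c for frag, c in counts.items() if c != 0}
    if any(c < 0 for c in result.values()):  # cannot happen when embeds() holds
        raise MatchingError(
            "signature application produced negative counts",
            tuple(f for f, c in result.items() if c < 0),
        )
    return dict(sorted(result.items()))


class FragmentIndex:
    """fragment -> sorted compound ids; compound id -> signature fragments.

    Built once per knowledge base; contents are independent of compound
    insertion order.
    """

    def __init__(self) -> None:
        self._by_fragment: dict[str, list[str]] = {}
        self._signatures: dict[str, dict[str, int]] = {}

    def add(self, compound_id: str, signature: MolecularSignature) -> None:
        self._signatures[compound_id] = signature.fragments
        for frag in signature.fragments:
            bucket = self._by_fragment.setdefault(frag, [])
            bucket.append(compound_id)
            bucket.sort()

    def compounds_with(self, fragment: str) -> list[str]:
        return self._by_fragment.get(fragment, [])

    def signature_of(self, compound_id: str) -> dict[str, int]:
        return self._signatures[compound_id]

    def fragment_count(self, compound_id: str, fragment: str) -> int:
        return self._signatures.get(compound_id, {}).get(fragment, 0)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._signatures

    def items(self):
        return self._signatures.items()


def resolve_products(P: dict[str, int], kb_index: FragmentIndex,
                     max_parts: int = 3, max_results: int = 100) -> list[tuple[str, ...]]:
    """Every multiset of <= max_parts known compounds whose molecular
    signatures sum exactly to ``P`` (no remainder).

    Search backtracks over candidates for the rarest unexplained fragment;
    results are deduplicated and returned in lexicographic order of sorted
    compound-id tuples.  An empty list is a rejection, not an error.
    """
    remaining = Counter({f: c for f, c in P.items() if c})
    if any(c < 0 for c in remaining.values()):
        raise ValueError("product fragment multiset must be non-negative")
    if not remaining:
        return [()]
    solutions: set[tuple[str, ...]] = set()

    def backtrack(rem: Counter, chosen: tuple[str, ...], parts_left: int) -> None:
        if len(solutions) >= max_results:
            return
        if not +rem:
            solutions.add(tuple(sorted(chosen)))
            return
        if parts_left == 0:
            return
        # rarest fragment: fewest containing compounds, ties broken lexicographically
        pivot = min(
            (f for f in rem if rem[f] > 0),
            key=lambda f: (len(kb_index.compounds_with(f)), f),
        )
        for cid in kb_index.compounds_with(pivot):
            sig = kb_index.signature_of(cid)
            if any(rem[f] < c for f, c in sig.items()):
                continue
            nxt = rem.copy()
            nxt.subtract(sig)
            backtrack(nxt, chosen + (cid,), parts_left - 1)

    backtrack(remaining, (), max_parts)
    return sorted(solutions)


def match_reaction(compound: "CompoundRecord", reaction: "ReactionRecord",
                   kb: "KnowledgeBase", direction: str = "forward",
                   max_parts: int = 3, max_results: int = 100) -> MatchResult:
    """Match one compound against one reaction in the given direction and
    resolve putative products against the knowledge base."""
    if direction == "forward":
        rxn_sig = reaction.forward_signature
        co_ids = reaction.substrate_ids[1:]
    elif direction == "reverse":
        rxn_sig = reaction.reverse_signature
        co_ids = reaction.product_ids[1:]
    else:
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    co_sigs = [kb.compound(cid).signature for cid in co_ids]
    query_sig = compound.signature
    if not embeds(query_sig, rxn_sig, co_sigs):
        return MatchResult(reaction.id, direction, matched=False)
    produced = apply_signature(query_sig, rxn_sig, co_sigs)
    resolved = resolve_products(produced, kb.fragment_index,
                                max_parts=max_parts, max_results=max_results)
    return MatchResult(
        reaction_id=reaction.id,
        direction=direction,
        matched=True,
        consumed=rxn_sig.negative_part(),
        produced_fragments=produced,
        resolved_products=tuple(resolved),
    )


def write_match_log(results: Iterable[MatchResult], path) -> None:
    """TSV diagnostic log of match outcomes."""
    lines = ["reaction_id\tdirection\tstatus\tproduct_sets"]
    lines += [r.to_tsv_row() for r in results]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
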
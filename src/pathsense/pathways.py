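"""Metabolic graph expansion around a target compound, detectable-endpoint
annotation, pathway extraction and export.

The expansion graph is a directed multigraph whose nodes are compounds and
whose edges are reaction applications; a reaction resolving to several
products contributes one edge per product, all sharing the reaction id.
Cofactors may appear as product nodes but are never expanded and never
count as pathway endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from pathsense.errors import PathsenseError
from pathsense.knowledgebase import CompoundRecord, DetectableRecord, KnowledgeBase
from pathsense.matching import match_reaction
from pathsense.similarity import tanimoto

TARGET_NODE_ID = "QUERY"


@dataclass
class ExpansionGraph:
    """Compound/reaction multigraph reached within ``max_steps`` of the target."""

    graph: nx.MultiDiGraph
    target_id: str
    max_steps: int
    annotated: bool = False
    frontier_sizes: list[int] = field(default_factory=list)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def record(self, node_id: str) -> CompoundRecord:
        return self.graph.nodes[node_id]["record"]

    def detectable_nodes(self) -> list[str]:
        return sorted(
            n for n, data in self.graph.nodes(data=True) if data.get("is_detectable")
        )


@dataclass(frozen=True)
class SEMPStep:
    reaction_id: str
    reaction_xrefs: tuple[str, ...]
    product_set: tuple[str, ...]
    compound_id: str  # the product followed by the pathway


@dataclass(frozen=True)
class SEMP:
    """A 1- or 2-step route from the target to a detectable endpoint."""

    steps: tuple[SEMPStep, ...]
    endpoint_id: str
    detectable: DetectableRecord
    similarity: float

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def pathway_id(self) -> str:
        return "->".join([s.reaction_id for s in self.steps] + [self.endpoint_id])


def expand(target: CompoundRecord, kb: KnowledgeBase, max_steps: int = 2) -> ExpansionGraph:
    """Breadth-first application of every knowledge-base reaction to the
    frontier, bounded at ``max_steps`` enzymatic steps.

    Reversible reactions are tried in both directions when the knowledge
    base's config says so; cofactor products become nodes but are never
    expanded further.
    """
    if max_steps not in (1, 2):
        raise ValueError(f"max_steps must be 1 or 2, got {max_steps}")
    if not target.mol.normalized:
        raise PathsenseError(f"target {target.id!r} is not normalized")
    config = kb.config
    graph = nx.MultiDiGraph()
    graph.add_node(target.id, record=target, is_target=1, step=0)
    expanded: set[str] = set()
    frontier = [target.id]
    result = ExpansionGraph(graph=graph, target_id=target.id, max_steps=max_steps)
    for step in range(1, max_steps + 1):
        result.frontier_sizes.append(len(frontier))
        next_frontier: list[str] = []
        for node_id in sorted(frontier):
            if node_id in expanded or kb.is_cofactor(node_id):
                continue
            expanded.add(node_id)
            compound = graph.nodes[node_id]["record"]
            for rid in sorted(kb.reactions):
                reaction = kb.reactions[rid]
                directions = ["forward"]
                if reaction.reversible and config.bidirectional:
                    directions.append("reverse")
                for direction in directions:
                    sig = (reaction.forward_signature if direction == "forward"
                           else reaction.reverse_signature)
                    if sig.is_empty():
                        continue
                    match = match_reaction(
                        compound, reaction, kb, direction=direction,
                        max_parts=config.max_product_set,
                        max_results=config.max_resolutions,
                    )
                    for product_set in match.resolved_products:
                        for pid in sorted(set(product_set)):
                            if pid not in graph:
                                graph.add_node(pid, record=kb.compound(pid),
                                               is_target=0, step=step)
                                next_frontier.append(pid)
                            graph.add_edge(
                                node_id, pid,
                                reaction=rid,
                                direction=direction,
                                step=step,
                                products=",".join(sorted(product_set)),
                                xrefs="|".join(reaction.xrefs),
                            )
        frontier = next_frontier
    return result


def annotate_detectables(expansion: ExpansionGraph, kb: KnowledgeBase,
                         threshold: Optional[float] = None) -> ExpansionGraph:
    """Attach the best-matching detectable compound and similarity score to
    every node; flag nodes at or above the threshold (exact structural
    identity always scores 1)."""
    config = kb.config
    threshold = config.threshold if threshold is None else threshold
    for node_id in sorted(expansion.graph.nodes):
        data = expansion.graph.nodes[node_id]
        record: CompoundRecord = data["record"]
        best_score = 0.0
        best_det: Optional[DetectableRecord] = None
        for det in kb.detectables:
            det_record = kb.compound(det.compound_id)
            score = 1.0 if det_record.key == record.key else tanimoto(
                record.fingerprint, det_record.fingerprint)
            if (best_det is None or score > best_score
                    or (score == best_score and det.compound_id < best_det.compound_id)):
                best_score, best_det = score, det
        is_cof = kb.is_cofactor(node_id)
        data["similarity"] = round(best_score, 6)
        data["best_detectable"] = best_det.compound_id if best_det else ""
        data["effectors"] = "|".join(best_det.transcription_factors) if best_det else ""
        data["is_detectable"] = int(best_det is not None and best_score >= threshold
                                    and not is_cof)
        data["is_near_detectable"] = int(
            best_det is not None and not is_cof
            and config.near_threshold <= best_score < threshold
        )
        data["detectable_record"] = best_det
    expansion.annotated = True
    return expansion


def find_semps(expansion: ExpansionGraph) -> list[SEMP]:
    """All simple paths from the target to flagged nodes, at most
    ``max_steps`` long, grouped by endpoint and deterministically ordered.

    A target that is itself flagged is *not* reported as a pathway (it is
    directly detectable); cofactor nodes are never endpoints.
    """
    if not expansion.annotated:
        return []
    graph = expansion.graph
    target = expansion.target_id
    semps: dict[tuple, SEMP] = {}
    for endpoint in expansion.detectable_nodes():
        if endpoint == target:
            continue
        for edge_path in nx.all_simple_edge_paths(graph, target, endpoint,
                                                  cutoff=expansion.max_steps):
            steps = []
            for u, v, key in edge_path:
                attrs = graph.edges[u, v, key]
                steps.append(SEMPStep(
                    reaction_id=attrs["reaction"],
                    reaction_xrefs=tuple(x for x in attrs["xrefs"].split("|") if x),
                    product_set=tuple(attrs["products"].split(",")),
                    compound_id=v,
                ))
            data = graph.nodes[endpoint]
            semp = SEMP(
                steps=tuple(steps),
                endpoint_id=endpoint,
                detectable=data["detectable_record"],
                similarity=data["similarity"],
            )
            semps.setdefault((semp.steps, endpoint), semp)
    return sorted(
        semps.values(),
        key=lambda s: (s.endpoint_id, s.length, -s.similarity,
                       tuple(step.reaction_id for step in s.steps)),
    )


def target_directly_detectable(expansion: ExpansionGraph) -> bool:
    return bool(expansion.graph.nodes[expansion.target_id].get("is_detectable"))


# -- serialization ---------------------------------------------------------

_NODE_FIELDS = ("is_target", "is_detectable", "is_near_detectable",
                "similarity", "best_detectable", "effectors", "xrefs")
_EDGE_FIELDS = ("reaction", "direction", "step", "products", "xrefs")


def _gml_value(value) -> str:
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6f}"
    escaped = str(value).replace("&", "&amp;").replace('"', "&quot;")
    return f'"{escaped}"'


def export_gml(expansion, path: str | Path) -> Path:
    """Write the (annotated) graph as Graph Markup Language.

    Accepts an :class:`ExpansionGraph` or a multigraph returned by
    :func:`import_gml`; output bytes are deterministic, so
    export -> import -> export is the identity on files.
    """
    graph = expansion.graph if isinstance(expansion, ExpansionGraph) else expansion
    node_ids = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(node_ids)}
    lines = ["graph [", "  directed 1", "  multigraph 1"]
    for node_id in node_ids:
        data = graph.nodes[node_id]
        record = data.get("record")
        xrefs = "|".join(record.xrefs) if record is not None else data.get("xrefs", "")
        lines.append("  node [")
        lines.append(f"    id {index[node_id]}")
        lines.append(f"    label {_gml_value(node_id)}")
        for name in _NODE_FIELDS:
            if name == "xrefs":
                lines.append(f"    xrefs {_gml_value(xrefs)}")
            elif name in data:
                lines.append(f"    {name} {_gml_value(data[name])}")
        lines.append("  ]")
    edges = sorted(
        graph.edges(keys=True, data=True),
        key=lambda e: (index[e[0]], index[e[1]], e[3].get("reaction", ""), str(e[2])),
    )
    for pos, (u, v, _key, data) in enumerate(edges):
        lines.append("  edge [")
        lines.append(f"    source {index[u]}")
        lines.append(f"    target {index[v]}")
        lines.append(f"    key {pos}")
        for name in _EDGE_FIELDS:
            if name in data:
                lines.append(f"    {name} {_gml_value(data[name])}")
        lines.append("  ]")
    lines.append("]")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def import_gml(path: str | Path) -> nx.MultiDiGraph:
    """Read a file written by :func:`export_gml` back into a multigraph."""
    return nx.read_gml(str(path), label="label")


def export_pathways(semps: list[SEMP], path: str | Path,
                    config=None, target_id: str = "") -> Path:
    """TSV pathway view: one row per pathway step."""
    lines = []
    if config is not None:
        lines.extend(config.header_lines())
    if target_id:
        lines.append(f"# target: {target_id}")
    lines.append("pathway_id\tstep_index\treaction_id\treaction_xrefs\t"
                 "product_ids\tendpoint_id\teffector\ttranscription_factors\tsimilarity")
    for semp in semps:
        for step_index, step in enumerate(semp.steps, start=1):
            lines.append("\t".join([
                semp.pathway_id,
                str(step_index),
                step.reaction_id,
                "|".join(step.reaction_xrefs),
                ",".join(step.product_set),
                semp.endpoint_id,
                semp.detectable.effector,
                "|".join(semp.detectable.transcription_factors),
                f"{semp.similarity:.6f}",
            ]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
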
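"""Reading and writing KEGG Markup Language (KGML) pathway documents.

A pathway is modelled as a signed directed graph over *gene* nodes. Each
typed KEGG relation subtype carries a sign: +1 for signal-inducing
interactions (activation, expression, phosphorylation, ...) and -1 for
signal-inhibiting ones (inhibition, dissociation, dephosphorylation). The
sign is the :math:`\\beta` weight used when a perturbation is propagated
from an upstream gene to its downstream neighbour.

Only entries of type ``gene`` (and ``group`` complexes of gene entries)
become nodes; compound-only entries are dropped. Group entries are treated
as binding events among their components, which downstream binding
expansion turns into the member / member / merged-pair alternatives.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Subtype label of binding/association relations; these edges are
#: positional alternatives, not propagation steps.
BINDING_SUBTYPE = "binding/association"

#: Sign coding of KEGG relation subtypes. +1 induces the downstream
#: signal, -1 inhibits it. Note the deliberately asymmetric entries:
#: "repression" and "missing interaction" and "ubiquitination" code +1,
#: while "dissociation" and "dephosphorylation" code -1.
RELATION_SIGNS: Mapping[str, int] = MappingProxyType(
    {
        "activation": 1,
        "inhibition": -1,
        "expression": 1,
        "repression": 1,
        "indirect effect": 1,
        "state change": 1,
        "binding/association": 1,
        "dissociation": -1,
        "missing interaction": 1,
        "phosphorylation": 1,
        "dephosphorylation": -1,
        "glycosylation": 1,
        "ubiquitination": 1,
        "methylation": 1,
    }
)

NODE_KINDS = ("simple", "merged_binding", "condensed_loop")


class KGMLError(ValueError):
    """Raised for malformed KGML documents or invalid graphs."""


def relation_sign(subtype_name: str, table: Mapping[str, int] | None = None) -> int:
    """Return the +1/-1 sign coded for a KEGG relation subtype.

    Parameters
    ----------
    subtype_name
        Relation subtype label, case-insensitive (e.g. ``"activation"``).
    table
        Optional override/extension of the built-in sign table; keys are
        normalized (lower-case) subtype labels.
    """
    signs = dict(RELATION_SIGNS)
    if table:
        signs.update({k.strip().lower(): int(v) for k, v in table.items()})
    key = subtype_name.strip().lower()
    if key not in signs:
        raise KeyError(f"unrecognized relation subtype: {subtype_name!r}")
    value = signs[key]
    if value not in (1, -1):
        raise KGMLError(f"sign for {subtype_name!r} must be +1 or -1, got {value}")
    return value


Edge = tuple[str, str, int, str]  # (source, target, sign, subtype)


@dataclass
class PathwayGraph:
    """Signed directed graph of gene nodes parsed from one KGML pathway.

    ``nodes`` maps a node identifier to the tuple of gene symbols it
    carries (condensed loop nodes and merged binding nodes carry several).
    ``edges`` holds ``(source, target, sign, subtype)`` tuples.
    """

    pathway_id: str
    nodes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    edges: set[Edge] = field(default_factory=set)
    node_kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.nodes:
            self.node_kind.setdefault(n, "simple")

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for src, dst, sign, subtype in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise KGMLError(f"edge endpoint missing from nodes: {(src, dst)}")
            if sign not in (1, -1):
                raise KGMLError(f"edge sign must be +1/-1: {(src, dst, sign, subtype)}")
        for n, kind in self.node_kind.items():
            if kind not in NODE_KINDS:
                raise KGMLError(f"unknown node kind {kind!r} for node {n!r}")

    # -- accessors ------------------------------------------------------
    @property
    def binding_edges(self) -> list[Edge]:
        return sorted(e for e in self.edges if e[3] == BINDING_SUBTYPE)

    @property
    def directed_edges(self) -> list[Edge]:
        """Edges that propagate signal (everything except binding)."""
        return sorted(e for e in self.edges if e[3] != BINDING_SUBTYPE)

    def gene_symbols(self) -> set[str]:
        out: set[str] = set()
        for syms in self.nodes.values():
            out.update(syms)
        return out

    def to_networkx(self) -> nx.DiGraph:
        """Directed view over non-binding edges, one edge per (u, v).

        Parallel relations of conflicting sign between the same pair are
        resolved deterministically to the first edge in sorted order,
        which prefers the inhibitory (-1) reading.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for src, dst, sign, subtype in self.directed_edges:
            if not g.has_edge(src, dst):
                g.add_edge(src, dst, sign=sign, subtype=subtype)
        return g

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            pathway_id=self.pathway_id,
            nodes=dict(self.nodes),
            edges=set(self.edges),
            node_kind=dict(self.node_kind),
        )

    def isomorphic_to(self, other: "PathwayGraph") -> bool:
        """Equality on (node id -> symbols) and the signed edge set."""
        return (
            self.nodes == other.nodes
            and {(s, t, sg) for s, t, sg, _ in self.edges}
            == {(s, t, sg) for s, t, sg, _ in other.edges}
        )


def _entry_symbols(entry: ET.Element) -> tuple[str, ...]:
    name = entry.get("name", "").strip()
    symbols = []
    for token in name.split():
        token = token.split(":", 1)[-1] if ":" in token else token
        if token and token.lower() != "undefined":
            symbols.append(token)
    return tuple(symbols)


def parse_kgml(
    document: str,
    *,
    sign_table: Mapping[str, int] | None = None,
    unknown_subtype: str = "error",
    pathway_id: str | None = None,
) -> PathwayGraph:
    """Parse a KGML XML document into a :class:`PathwayGraph`.

    Only ``gene`` entries become nodes (compound-only entries are
    dropped). ``group`` entries add binding edges among their components.
    Each relation subtype found in the sign table becomes one signed edge;
    relations referencing a missing entry are skipped with a warning.

    Parameters
    ----------
    unknown_subtype
        ``"error"`` (default) raises on a subtype absent from the sign
        table; ``"skip"`` drops the relation with a warning.
    """
    if unknown_subtype not in ("error", "skip"):
        raise ValueError("unknown_subtype must be 'error' or 'skip'")
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:  # pragma: no cover - message passthrough
        raise KGMLError(f"malformed KGML document: {exc}") from exc

    pid = pathway_id or root.get("name") or root.get("title") or "pathway"

    nodes: dict[str, tuple[str, ...]] = {}
    entry_to_nodes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    seen_ids: dict[str, int] = {}

    for entry in root.findall("entry"):
        etype = entry.get("type")
        eid = entry.get("id", "")
        if etype == "gene":
            symbols = _entry_symbols(entry)
            if not symbols:
                logger.warning("gene entry %s has no symbols; skipped", eid)
                continue
            node_id = "+".join(symbols)
            if node_id in seen_ids:
                seen_ids[node_id] += 1
                node_id = f"{node_id}#{seen_ids[node_id]}"
            else:
                seen_ids[node_id] = 1
            nodes[node_id] = symbols
            entry_to_nodes[eid] = [node_id]
        elif etype == "group":
            groups[eid] = [c.get("id", "") for c in entry.findall("component")]
        # compound / map / other entry types are dropped

    graph = PathwayGraph(pathway_id=pid, nodes=nodes)

    # groups: binding among components; relations to a group hit every member
    for gid, comp_ids in groups.items():
        members: list[str] = []
        for cid in comp_ids:
            members.extend(entry_to_nodes.get(cid, []))
        if len(members) >= 2:
            for a, b in zip(members, members[1:]):
                graph.edges.add((a, b, relation_sign(BINDING_SUBTYPE, sign_table), BINDING_SUBTYPE))
        entry_to_nodes[gid] = members

    for relation in root.findall("relation"):
        e1, e2 = relation.get("entry1", ""), relation.get("entry2", "")
        sources = entry_to_nodes.get(e1)
        targets = entry_to_nodes.get(e2)
        if not sources or not targets:
            logger.warning(
                "relation %s->%s references a missing/non-gene entry; edge skipped", e1, e2
            )
            continue
        subtypes = relation.findall("subtype")
        if not subtypes:
            logger.warning("relation %s->%s has no subtype; edge skipped", e1, e2)
            continue
        for sub in subtypes:
            name = (sub.get("name") or "").strip().lower()
            try:
                sign = relation_sign(name, sign_table)
            except KeyError:
                if unknown_subtype == "error":
                    raise
                logger.warning("unknown relation subtype %r; edge skipped", name)
                continue
            for u in sources:
                for v in targets:
                    if u == v:
                        logger.warning("self relation on %s skipped", u)
                        continue
                    graph.edges.add((u, v, sign, name))

    graph.validate()
    return graph


def write_kgml(graph: PathwayGraph, *, sign_table: Mapping[str, int] | None = None) -> str:
    """Serialize a :class:`PathwayGraph` as a KGML XML document.

    The output is deterministic (entries and relations in sorted order)
    and round-trips: ``parse_kgml(write_kgml(g))`` has the same node ids,
    symbols and signed edge set as ``g``.
    """
    graph.validate()
    root = ET.Element("pathway", attrib={"name": graph.pathway_id, "org": "syn"})
    node_ids = sorted(graph.nodes)
    entry_id = {}
    for i, node in enumerate(node_ids, start=1):
        symbols = graph.nodes[node]
        if not symbols:
            raise KGMLError(f"node {node!r} has no gene symbol")
        entry_id[node] = str(i)
        ET.SubElement(
            root,
            "entry",
            attrib={"id": str(i), "name": " ".join(symbols), "type": "gene"},
        )
    for src, dst, sign, subtype in sorted(graph.edges):
        rel = ET.SubElement(
            root,
            "relation",
            attrib={"entry1": entry_id[src], "entry2": entry_id[dst], "type": "PPrel"},
        )
        ET.SubElement(rel, "subtype", attrib={"name": subtype, "value": str(sign)})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def read_kgml_file(path, **kwargs) -> PathwayGraph:
    """Parse a KGML file from disk (any extension; dispatches on content)."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_kgml(fh.read(), **kwargs)
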
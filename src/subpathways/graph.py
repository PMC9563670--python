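"""Pathway normalization and single-chain subpathway enumeration.

A single-chain subpathway is an ordered chain of gene nodes running from
an entry node (a node without parents) to an end node (a node without
children). Three topological situations are handled:

* **canonical** — the chains are simply all simple paths from entry to
  end nodes;
* **binding** — a binding/association event between two nodes B and C is
  expanded into three alternatives for the bound position: B alone, C
  alone, or the merged node ``B+C`` (the position is considered active if
  at least one member is present);
* **looping** — a directed cycle is condensed into one node carrying all
  member genes, which is considered active only if every member gene is
  active; condensation makes the graph acyclic before enumeration.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .kgml import BINDING_SUBTYPE, Edge, KGMLError, PathwayGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subpathway:
    """One single-chain subpathway.

    ``chain`` is the ordered node-id sequence, ``step_signs`` the +1/-1
    sign of each of the ``len(chain) - 1`` steps, ``node_symbols`` the
    gene symbols carried by each node and ``node_kinds`` whether a node is
    a plain gene, a merged binding pair or a condensed loop.
    """

    pathway_id: str
    chain: tuple[str, ...]
    step_signs: tuple[int, ...]
    node_symbols: tuple[tuple[str, ...], ...]
    node_kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chain) < 1:
            raise ValueError("a subpathway needs at least one node")
        if len(self.step_signs) != len(self.chain) - 1:
            raise ValueError("step_signs must have length len(chain) - 1")
        if any(s not in (1, -1) for s in self.step_signs):
            raise ValueError("step signs must be +1 or -1")

    @property
    def length(self) -> int:
        """Number of nodes in the chain."""
        return len(self.chain)

    @property
    def chain_str(self) -> str:
        return ">".join(self.chain)

    def genes(self) -> set[str]:
        return {s for syms in self.node_symbols for s in syms}


@dataclass
class EnumerationConfig:
    """Caps and policies for subpathway enumeration.

    ``max_path_length`` is the maximum number of nodes per chain,
    ``max_paths_per_pathway`` bounds the total number of chains kept,
    ``binding_subset_cap`` bounds how many binding events are expanded
    combinatorially (3 variants each), and ``start_policy`` selects
    whether chains start only at entry nodes or at any node.
    """

    max_path_length: int = 30
    max_paths_per_pathway: int = 50_000
    binding_subset_cap: int = 6
    start_policy: str = "entry_only"

    def __post_init__(self) -> None:
        if min(self.max_path_length, self.max_paths_per_pathway, self.binding_subset_cap) < 1:
            raise ValueError("all enumeration caps must be positive")
        if self.start_policy not in ("entry_only", "any_node"):
            raise ValueError("start_policy must be 'entry_only' or 'any_node'")


# ---------------------------------------------------------------------------
# loop condensation
# ---------------------------------------------------------------------------

def condense_loops(graph: PathwayGraph) -> PathwayGraph:
    """Collapse every directed cycle into a single condensed node.

    Each nontrivial strongly connected component of the directed
    (non-binding) edges becomes one node whose symbols are the union of
    the member genes; edges into/out of the component are re-attached and
    intra-component edges dropped, so the result is acyclic.
    """
    graph.validate()
    d = nx.DiGraph()
    d.add_nodes_from(graph.nodes)
    d.add_edges_from((s, t) for s, t, _, _ in graph.directed_edges)

    comp_of: dict[str, str] = {}
    new_nodes: dict[str, tuple[str, ...]] = {}
    new_kind: dict[str, str] = {}
    for comp in nx.strongly_connected_components(d):
        members = sorted(comp)
        if len(members) == 1:
            n = members[0]
            comp_of[n] = n
            new_nodes[n] = graph.nodes[n]
            new_kind[n] = graph.node_kind.get(n, "simple")
        else:
            cid = "&".join(members)
            symbols = tuple(s for m in members for s in graph.nodes[m])
            for m in members:
                comp_of[m] = cid
            new_nodes[cid] = symbols
            new_kind[cid] = "condensed_loop"

    new_edges: set[Edge] = set()
    for s, t, sign, subtype in graph.edges:
        cs, ct = comp_of[s], comp_of[t]
        if cs == ct:
            continue  # intra-loop (or binding within a loop) disappears
        new_edges.add((cs, ct, sign, subtype))

    out = PathwayGraph(graph.pathway_id, new_nodes, new_edges, new_kind)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# binding expansion
# ---------------------------------------------------------------------------

def _merge_pair(g: PathwayGraph, a: str, b: str) -> None:
    merged = "+".join(sorted(set(a.split("+")) | set(b.split("+"))))
    symbols = tuple(dict.fromkeys(g.nodes[a] + g.nodes[b]))
    edges: set[Edge] = set()
    for s, t, sign, subtype in g.edges:
        s2 = merged if s in (a, b) else s
        t2 = merged if t in (a, b) else t
        if s2 == t2:
            continue
        edges.add((s2, t2, sign, subtype))
    for n in (a, b):
        del g.nodes[n]
        g.node_kind.pop(n, None)
    g.nodes[merged] = symbols
    g.node_kind[merged] = "merged_binding"
    g.edges = edges


def _drop_node(g: PathwayGraph, n: str) -> None:
    del g.nodes[n]
    g.node_kind.pop(n, None)
    g.edges = {e for e in g.edges if e[0] != n and e[1] != n}


def expand_bindings(graph: PathwayGraph, binding_subset_cap: int = 6) -> list[PathwayGraph]:
    """Generate the binding-position variants of an acyclic graph.

    For every binding event between nodes B and C, three variants are
    produced in which the bound position is B alone, C alone, or the
    merged node ``B+C``; variants for independent binding events combine
    multiplicatively. Beyond ``binding_subset_cap`` binding events, the
    remaining events are resolved as merged pairs (with a warning) to
    keep the variant count at most ``3**binding_subset_cap``.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for s, t, _, subtype in sorted(graph.edges):
        if subtype == BINDING_SUBTYPE and frozenset((s, t)) not in seen:
            seen.add(frozenset((s, t)))
            pairs.append(tuple(sorted((s, t))))

    base = graph.copy()
    base.edges = {e for e in base.edges if e[3] != BINDING_SUBTYPE}
    if not pairs:
        return [base]

    if len(pairs) > binding_subset_cap:
        logger.warning(
            "pathway %s has %d binding events; expanding the first %d, merging the rest",
            graph.pathway_id,
            len(pairs),
            binding_subset_cap,
        )
    expanded, forced = pairs[:binding_subset_cap], pairs[binding_subset_cap:]

    variants: list[PathwayGraph] = []
    keys: set[tuple] = set()
    for combo in itertools.product(("first", "second", "merged"), repeat=len(expanded)):
        g = base.copy()
        for (a, b), choice in list(zip(expanded, combo)) + [(p, "merged") for p in forced]:
            if a not in g.nodes or b not in g.nodes:
                continue  # endpoint consumed by a previous binding op
            if choice == "first":
                _drop_node(g, b)
            elif choice == "second":
                _drop_node(g, a)
            else:
                _merge_pair(g, a, b)
        key = (frozenset(g.nodes.items()), frozenset(g.edges))
        if key not in keys:
            keys.add(key)
            variants.append(g)
    return variants


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _sign_lookup(g: PathwayGraph) -> dict[tuple[str, str], int]:
    signs: dict[tuple[str, str], int] = {}
    for s, t, sign, _ in sorted(g.directed_edges, key=lambda e: (e[0], e[1], e[3], e[2])):
        signs.setdefault((s, t), sign)
    return signs


def enumerate_subpathways(
    graph: PathwayGraph, config: EnumerationConfig | None = None
) -> list[Subpathway]:
    """Enumerate all single-chain subpathways of a loop-free pathway.

    Chains run from entry nodes (no parent) to end nodes (no child) —
    or, under ``start_policy='any_node'``, from any node to an end node —
    across all binding variants, deduplicated by node sequence and
    returned in lexicographic chain order. The graph must already be
    acyclic (:func:`condense_loops`).

    Caps are enforced deterministically: enumeration visits variants,
    sources and targets in sorted order and stops once
    ``max_paths_per_pathway`` distinct chains were collected.
    """
    config = config or EnumerationConfig()
    probe = graph.copy()
    probe.edges = {e for e in probe.edges if e[3] != BINDING_SUBTYPE}
    d0 = probe.to_networkx()
    if not nx.is_directed_acyclic_graph(d0):
        raise KGMLError("graph contains directed cycles; run condense_loops first")

    found: dict[tuple[str, ...], Subpathway] = {}
    truncated = False
    for variant in expand_bindings(graph, config.binding_subset_cap):
        d = variant.to_networkx()
        signs = _sign_lookup(variant)
        ends = sorted(n for n in d.nodes if d.out_degree(n) == 0)
        if config.start_policy == "entry_only":
            sources = sorted(n for n in d.nodes if d.in_degree(n) == 0)
        else:
            sources = sorted(d.nodes)
        for src in sources:
            for dst in ends:
                if src == dst:
                    paths: Iterable[list[str]] = [[src]]
                else:
                    paths = nx.all_simple_paths(d, src, dst, cutoff=config.max_path_length - 1)
                for path in paths:
                    chain = tuple(path)
                    if chain in found:
                        continue
                    if len(found) >= config.max_paths_per_pathway:
                        truncated = True
                        break
                    found[chain] = Subpathway(
                        pathway_id=graph.pathway_id,
                        chain=chain,
                        step_signs=tuple(signs[(a, b)] for a, b in zip(chain, chain[1:])),
                        node_symbols=tuple(variant.nodes[n] for n in chain),
                        node_kinds=tuple(variant.node_kind.get(n, "simple") for n in chain),
                    )
                if truncated:
                    break
            if truncated:
                break
        if truncated:
            break
    if truncated:
        logger.warning(
            "pathway %s: subpathway enumeration truncated at %d chains",
            graph.pathway_id,
            config.max_paths_per_pathway,
        )
    return sorted(found.values(), key=lambda s: s.chain)


def derive_subpathways(
    graph: PathwayGraph, config: EnumerationConfig | None = None
) -> list[Subpathway]:
    """Condense loops, expand bindings and enumerate in one call."""
    return enumerate_subpathways(condense_loops(graph), config)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def subpathways_to_tsv(subpathways: Sequence[Subpathway]) -> str:
    """Render subpathways as TSV (pathway, chain, signs, length)."""
    lines = ["pathway_id\tchain\tstep_signs\tlength"]
    for sp in subpathways:
        signs = ",".join(str(s) for s in sp.step_signs)
        lines.append(f"{sp.pathway_id}\t{sp.chain_str}\t{signs}\t{sp.length}")
    return "\n".join(lines) + "\n"


def subpathways_to_jsonl(subpathways: Sequence[Subpathway]) -> Iterator[str]:
    for sp in subpathways:
        yield json.dumps(
            {
                "pathway_id": sp.pathway_id,
                "chain": list(sp.chain),
                "step_signs": list(sp.step_signs),
                "node_symbols": [list(s) for s in sp.node_symbols],
                "node_kinds": list(sp.node_kinds),
                "length": sp.length,
            },
            sort_keys=True,
        )
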
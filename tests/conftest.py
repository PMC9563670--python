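import numpy as np
import pandas as pd
import pytest

import subpathways as sp
from subpathways.kgml import BINDING_SUBTYPE, PathwayGraph


@pytest.fixture
def binding_motif_graph() -> PathwayGraph:
    """Diamond with a binding event: A->B, A->C, B->D, C->D, B---C."""
    return sp.parse_kgml(sp.binding_motif_kgml())


@pytest.fixture
def loop_graph() -> PathwayGraph:
    """A->B, loop B->C->D->E->B, E->F."""
    nodes = {n: (n,) for n in "ABCDEF"}
    edges = {
        ("A", "B", 1, "activation"),
        ("B", "C", 1, "activation"),
        ("C", "D", 1, "activation"),
        ("D", "E", 1, "activation"),
        ("E", "B", 1, "activation"),
        ("E", "F", 1, "activation"),
    }
    return PathwayGraph("loopy", nodes, edges)


def make_chain_subpathway(genes, signs=None, pathway_id="p"):
    genes = tuple(genes)
    signs = tuple(signs) if signs is not None else tuple([1] * (len(genes) - 1))
    return sp.Subpathway(
        pathway_id=pathway_id,
        chain=genes,
        step_signs=signs,
        node_symbols=tuple((g,) for g in genes),
        node_kinds=tuple(["simple"] * len(genes)),
    )


@pytest.fixture
def chain_factory():
    return make_chain_subpathway


@pytest.fixture
def tiny_dataset() -> sp.ExpressionDataset:
    """3 genes x 4 paired samples (2 pairs) with multi-probe gene g1."""
    probes = ["p1a", "p1b", "p2", "p3"]
    samples = ["s1_pre", "s1_post", "s2_pre", "s2_post"]
    expression = pd.DataFrame(
        [[100.0, 210.0, 95.0, 205.0],
         [40.0, 80.0, 42.0, 78.0],
         [50.0, 50.0, 52.0, 48.0],
         [300.0, 150.0, 310.0, 160.0]],
        index=probes,
        columns=samples,
    )
    calls = pd.DataFrame(
        [["A", "P", "A", "P"],
         ["A", "P", "M", "P"],
         ["P", "P", "P", "P"],
         ["P", "A", "P", "A"]],
        index=probes,
        columns=samples,
    )
    probe_map = pd.DataFrame(
        {"probe": ["p1a", "p1b", "p2", "p3"], "gene": ["g1", "g1", "g2", "g3"]}
    )
    metadata = pd.DataFrame(
        {
            "condition": ["pre", "post", "pre", "post"],
            "pair_id": ["P1", "P1", "P2", "P2"],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return sp.ExpressionDataset(expression, calls, probe_map, metadata)


def random_dag(rng: np.random.Generator, max_nodes: int = 12) -> PathwayGraph:
    """Random DAG over topologically ordered nodes with random edge signs."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i:02d}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                sign = -1 if rng.random() < 0.3 else 1
                edges.add((names[i], names[j], sign, "activation" if sign == 1 else "inhibition"))
    return PathwayGraph("dag", {m: (m,) for m in names}, edges)


def random_digraph(rng: np.random.Generator, max_nodes: int = 10) -> PathwayGraph:
    """Random directed graph (cycles allowed)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i:02d}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.2:
                edges.add((names[i], names[j], 1, "activation"))
    return PathwayGraph("dg", {m: (m,) for m in names}, edges)


def dfs_all_chains(graph: PathwayGraph, entry_only: bool = True) -> set:
    """Independent brute-force oracle: all simple entry->end node paths."""
    succ: dict = {n: [] for n in graph.nodes}
    pred: dict = {n: [] for n in graph.nodes}
    for s, t, _, subtype in graph.edges:
        if subtype == BINDING_SUBTYPE:
            continue
        succ[s].append(t)
        pred[t].append(s)
    ends = {n for n in graph.nodes if not succ[n]}
    sources = [n for n in graph.nodes if not pred[n]] if entry_only else list(graph.nodes)
    chains = set()

    def walk(path):
        node = path[-1]
        if node in ends:
            chains.add(tuple(path))
        for nxt in succ[node]:
            if nxt not in path:
                walk(path + [nxt])

    for s in sources:
        walk([s])
    return chains


def scc_oracle(graph: PathwayGraph) -> set:
    """Strongly connected components via exhaustive reachability."""
    succ: dict = {n: set() for n in graph.nodes}
    for s, t, _, subtype in graph.edges:
        if subtype != BINDING_SUBTYPE:
            succ[s].add(t)

    def reachable(start):
        seen, stack = set(), [start]
        while stack:
            node = stack.pop()
            for nxt in succ[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    reach = {n: reachable(n) for n in graph.nodes}
    comps = set()
    for n in graph.nodes:
        comp = {m for m in graph.nodes if (m == n) or (m in reach[n] and n in reach[m])}
        comps.add(frozenset(comp))
    return comps
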
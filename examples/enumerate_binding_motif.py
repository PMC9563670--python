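"""Derive single-chain subpathways from a pathway with a binding event.

Builds the four-gene diamond A->B, A->C, B->D, C->D in which B and C
share a binding/association relation, and enumerates its subpathways.
The bound position is satisfiable by B alone, C alone, or the merged
pair B+C, so three chains come out.
"""

import subpathways as sp

graph = sp.parse_kgml(sp.binding_motif_kgml())
print(f"pathway '{graph.pathway_id}': {len(graph.nodes)} gene nodes, "
      f"{len(graph.edges)} relations ({len(graph.binding_edges)} binding)")

for sub in sp.derive_subpathways(graph):
    kinds = "/".join(k for k in sub.node_kinds if k != "simple") or "all simple"
    print(f"  {sub.chain_str:12s} length {sub.length}  signs {sub.step_signs}  ({kinds})")

print("Each line is one single-chain subpathway from an entry node (no "
      "parent) to an end node (no child); B+C is the merged binding pair.")
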
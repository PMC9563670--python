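"""Hypergeometric pathway enrichment of a differentially expressed gene list.

For a universe of N genes, a pathway holding K of them, and n DE genes of
which k fall in the pathway, the enrichment p-value is the upper tail
``P(X >= k)`` of the hypergeometric distribution — the chance that a
random draw of n genes hits the pathway at least k times. The same
quantity doubles as ``P_path`` in the subpathway impact factor, where it
contributes the ``log(1 / P_path)`` evidence term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    n_pathway_genes: int
    n_de_in_pathway: int
    n_de_total: int
    universe_size: int
    p_value: float


def hypergeom_enrich(
    de_genes: set, pathway_genes: set, universe: set, pathway_id: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``de_genes`` in a pathway.

    Both gene sets must be subsets of the universe; the tail includes the
    observed overlap (``P(X >= k)``), so k = 0 gives p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de_genes, pathway_genes = set(de_genes), set(pathway_genes)
    if not de_genes <= universe or not pathway_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    N, K, n = len(universe), len(pathway_genes), len(de_genes)
    k = len(de_genes & pathway_genes)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(pathway_id, K, k, n, N, min(p, 1.0))


def enrich_pathways(
    de_genes: set, pathways: Mapping[str, set], universe: set
) -> pd.DataFrame:
    """Enrichment table over a pathway collection (one row per pathway).

    Gene sets are intersected with the universe before testing, so a
    platform-restricted universe silently restricts the pathways too.
    """
    universe = set(universe)
    de = set(de_genes) & universe
    rows = []
    for pid in sorted(pathways):
        res = hypergeom_enrich(de, set(pathways[pid]) & universe, universe, pid)
        rows.append(
            {
                "pathway_id": pid,
                "n_pathway_genes": res.n_pathway_genes,
                "n_de_in_pathway": res.n_de_in_pathway,
                "n_de_total": res.n_de_total,
                "universe_size": res.universe_size,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("pathway_id")


def enrichment_report(
    results_a: pd.DataFrame, results_b: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Pathways enriched in *both* cohorts at ``p < threshold``.

    The two inputs are :func:`enrich_pathways` tables over the same
    pathway collection; the report is sorted by the product of the two
    p-values (most jointly significant first).
    """
    if set(results_a.index) != set(results_b.index):
        raise ValueError("cohorts were enriched on different pathway sets")
    merged = results_a.join(results_b, lsuffix="_a", rsuffix="_b")
    kept = merged[(merged["p_value_a"] < threshold) & (merged["p_value_b"] < threshold)].copy()
    kept["combined"] = kept["p_value_a"] * kept["p_value_b"]
    return kept.sort_values("combined").drop(columns="combined")
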
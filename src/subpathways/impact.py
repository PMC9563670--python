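"""Subpathway impact scoring with a length-stratified permutation null.

Each gene g in a single-chain subpathway receives a perturbation factor

    PF(g) = dE(g) * chi2(g) + beta_ug * PF(u)

where dE is the log2 fold change, chi2 the presence-based test statistic
(McNemar paired, Pearson unpaired), u the gene directly upstream in the
chain and beta_ug the +1/-1 sign of the connecting relation. The first
chain node has no upstream term. The subpathway's impact factor is

    IF = log(1 / P_path) + sum_g |PF(g)| / (|dE_bar| * N_de)

with P_path the hypergeometric enrichment p-value of the host pathway,
N_de the number of DE genes in the chain and |dE_bar| the mean |dE| over
those DE genes (the second term is zero when N_de = 0). A larger IF
marks a more strongly activated subpathway.

Significance comes from relabelling pre/post (within patient for paired
cohorts), rescoring everything — dE, chi2 and P_path are all recomputed
on each permuted dataset — and pooling permuted impact factors across
subpathways of identical length into an empirical null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diffexp import ExpressionDataset, GeneStatsEngine, de_genes
from .enrichment import hypergeom_enrich
from .graph import Subpathway

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeStats:
    """Expression statistics resolved for one chain node."""

    delta_e: float
    chi2: float
    is_de: bool


@dataclass
class PermutationNull:
    """Pooled permuted impact factors for one subpathway length."""

    length: int
    scores: np.ndarray
    n_permutations: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


# ---------------------------------------------------------------------------
# node resolution
# ---------------------------------------------------------------------------

def resolve_node_stats(
    symbols: Sequence[str],
    kind: str,
    stats: pd.DataFrame,
    binding_agg: str = "max",
) -> NodeStats:
    """Summarize member-gene statistics for a (possibly multi-gene) node.

    * plain or merged-binding nodes: the member with the largest
      ``|dE * chi2|`` represents the node (``binding_agg='mean'`` averages
      instead, with DE = any member DE);
    * condensed loop nodes: members are averaged and the node counts as
      DE only if *every* member gene is present in the statistics and DE
      (the loop is active only when all its genes are active).

    Genes missing from ``stats`` contribute nothing (dE and chi2 of 0).
    """
    present = [s for s in symbols if s in stats.index]
    missing = [s for s in symbols if s not in stats.index]
    if missing:
        logger.debug("node %s: no expression data for %s", "+".join(symbols), missing)
    if not present:
        return NodeStats(0.0, 0.0, False)
    de = stats.loc[present, "delta_e"].to_numpy(dtype=float)
    chi = stats.loc[present, "chi2"].to_numpy(dtype=float)
    flags = stats.loc[present, "is_de"].to_numpy(dtype=bool)
    if kind == "condensed_loop":
        return NodeStats(
            float(de.mean()), float(chi.mean()), bool(not missing and flags.all())
        )
    if len(present) == 1:
        return NodeStats(float(de[0]), float(chi[0]), bool(flags[0]))
    if binding_agg == "mean":
        return NodeStats(float(de.mean()), float(chi.mean()), bool(flags.any()))
    best = int(np.argmax(np.abs(de * chi)))
    return NodeStats(float(de[best]), float(chi[best]), bool(flags[best]))


# ---------------------------------------------------------------------------
# perturbation and impact factors
# ---------------------------------------------------------------------------

def propagate(base: Sequence[float], step_signs: Sequence[int]) -> np.ndarray:
    """Run the chain recursion: pf[0]=base[0]; pf[i]=base[i]+sign*pf[i-1]."""
    if len(step_signs) != len(base) - 1:
        raise ValueError("need one step sign per chain edge")
    pf = np.empty(len(base), dtype=float)
    pf[0] = base[0]
    for i, sign in enumerate(step_signs, start=1):
        pf[i] = base[i] + sign * pf[i - 1]
    return pf


def perturbation_factors(
    subpathway: Subpathway, stats: pd.DataFrame, binding_agg: str = "max"
) -> np.ndarray:
    """Perturbation factor of every node along the chain.

    The first node's PF is its own ``dE * chi2``; each later node adds
    the sign-weighted PF of its single upstream neighbour.
    """
    nodes = [
        resolve_node_stats(sym, kind, stats, binding_agg)
        for sym, kind in zip(subpathway.node_symbols, subpathway.node_kinds)
    ]
    base = [ns.delta_e * ns.chi2 for ns in nodes]
    return propagate(base, subpathway.step_signs)


def impact_factor(
    pf: Sequence[float],
    p_path: float,
    de_flags: Sequence[bool],
    delta_es: Sequence[float],
) -> float:
    """Impact factor from per-node PF values and pathway enrichment.

    ``de_flags``/``delta_es`` are aligned to the chain; the accumulated
    |PF| is normalized by mean |dE| over DE nodes times the DE count,
    and the term vanishes when the chain has no DE node.
    """
    if not 0.0 < p_path <= 1.0:
        raise ValueError(f"p_path must be in (0, 1], got {p_path}")
    pf = np.asarray(pf, dtype=float)
    flags = np.asarray(de_flags, dtype=bool)
    de = np.asarray(delta_es, dtype=float)
    score = math.log(1.0 / p_path)
    n_de = int(flags.sum())
    if n_de > 0:
        mean_abs = float(np.abs(de[flags]).mean())
        if mean_abs > 0:
            score += float(np.abs(pf).sum()) / (mean_abs * n_de)
    return score


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permute_conditions(
    metadata: pd.DataFrame, paired: bool, n_permutations: int, seed: int
) -> Iterator[pd.Series]:
    """Stream of permuted pre/post label assignments.

    Paired mode flips each patient's pre/post labels independently with
    probability one half (a within-pair sign flip); unpaired mode
    shuffles the condition labels across all samples. Reproducible for a
    fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    cond = metadata["condition"]
    for _ in range(n_permutations):
        if paired:
            flipped = cond.copy()
            for pid, grp in metadata.groupby("pair_id", sort=True):
                if rng.random() < 0.5:
                    flipped.loc[grp.index] = (
                        cond.loc[grp.index].map({"pre": "post", "post": "pre"})
                    )
            yield flipped
        else:
            yield pd.Series(
                rng.permutation(cond.to_numpy()), index=cond.index, name="condition"
            )


def empirical_pvalue(
    observed: float, null: PermutationNull | Sequence[float], length: int | None = None
) -> float:
    """Add-one empirical upper-tail p-value against a permutation null.

    ``p = (1 + #{null >= observed}) / (1 + #null)``; the pseudo-count
    keeps p strictly positive at small permutation counts.
    """
    if isinstance(null, PermutationNull):
        if length is not None and null.length != length:
            raise ValueError(
                f"null pooled for length {null.length}, observed subpathway has length {length}"
            )
        scores = null.scores
    else:
        scores = np.asarray(null, dtype=float)
    if scores.size == 0:
        raise ValueError("empty permutation null")
    return float((1 + np.sum(scores >= observed)) / (1 + scores.size))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full scoring pipeline
# ---------------------------------------------------------------------------

def _clip_p(p: float) -> float:
    return min(max(p, 1e-300), 1.0)


class _ChainPlan:
    """Pre-resolved gene indices for fast per-permutation rescoring."""

    __slots__ = ("sub", "member_idx", "kinds", "n_members")

    def __init__(self, sub: Subpathway, gene_index: pd.Index):
        self.sub = sub
        lookup = {g: i for i, g in enumerate(gene_index)}
        self.member_idx = [
            np.array([lookup[s] for s in syms if s in lookup], dtype=int)
            for syms in sub.node_symbols
        ]
        self.n_members = [len(syms) for syms in sub.node_symbols]
        self.kinds = sub.node_kinds

    def score(
        self,
        delta_e: np.ndarray,
        chi2: np.ndarray,
        is_de: np.ndarray,
        p_path: float,
        binding_agg: str,
        pathway_norm: tuple[float, int] | None = None,
    ) -> tuple[float, np.ndarray, int]:
        base = np.empty(len(self.member_idx))
        node_de = np.empty(len(self.member_idx), dtype=bool)
        node_abs = np.empty(len(self.member_idx))
        for j, (idx, kind, n_all) in enumerate(
            zip(self.member_idx, self.kinds, self.n_members)
        ):
            if idx.size == 0:
                base[j], node_de[j], node_abs[j] = 0.0, False, 0.0
                continue
            de, chi, flags = delta_e[idx], chi2[idx], is_de[idx]
            if kind == "condensed_loop":
                d, c = de.mean(), chi.mean()
                f = bool(flags.all()) and idx.size == n_all
            elif idx.size == 1:
                d, c, f = de[0], chi[0], bool(flags[0])
            elif binding_agg == "mean":
                d, c, f = de.mean(), chi.mean(), bool(flags.any())
            else:
                best = int(np.argmax(np.abs(de * chi)))
                d, c, f = de[best], chi[best], bool(flags[best])
            base[j], node_de[j], node_abs[j] = d * c, f, abs(d)
        pf = propagate(base, self.sub.step_signs)
        score = math.log(1.0 / p_path)
        n_de = int(node_de.sum())
        if pathway_norm is not None:
            mean_abs, n_norm = pathway_norm
        else:
            mean_abs = float(node_abs[node_de].mean()) if n_de > 0 else 0.0
            n_norm = n_de
        if n_norm > 0 and mean_abs > 0:
            score += float(np.abs(pf).sum()) / (mean_abs * n_norm)
        return score, pf, n_de


def score_subpathways(
    dataset: ExpressionDataset,
    subpathways: Sequence[Subpathway],
    pathways: Mapping[str, set],
    *,
    paired: bool | None = None,
    alpha: float = 0.05,
    n_permutations: int = 100,
    seed: int = 0,
    binding_agg: str = "max",
    enrichment_direction: str = "all",
    universe: set | None = None,
    marginal_present: bool = False,
    expr_agg: str = "max",
    de_scope: str = "subpathway",
) -> pd.DataFrame:
    """Score subpathways and assign length-stratified permutation p-values.

    ``pathways`` maps pathway id to its full gene set (for the
    enrichment term). The universe defaults to the dataset genes that
    appear in any pathway. Per permutation, the per-gene statistics and
    the pathway enrichment p-values are recomputed from the relabelled
    dataset, and permuted impact factors are pooled across subpathways
    of the same length. Returns a frame with one row per subpathway:
    impact_factor, terminal_pf, n_de, direction, empirical_p, fdr_q and
    the top-|PF| gene.

    ``de_scope`` selects the normalization of the accumulated |PF|
    term: ``"subpathway"`` (default) uses the DE genes of the chain
    itself, which makes chains without DE genes score exactly
    ``log(1/P_path)``; ``"pathway"`` uses the host pathway's DE genes,
    which keeps the statistic continuous whenever the pathway holds any
    DE gene (useful for calibration studies).
    """
    if de_scope not in ("subpathway", "pathway"):
        raise ValueError("de_scope must be 'subpathway' or 'pathway'")
    engine = GeneStatsEngine(
        dataset,
        paired=paired,
        alpha=alpha,
        marginal_present=marginal_present,
        expr_agg=expr_agg,
    )
    pathway_gene_union: set = set().union(*pathways.values()) if pathways else set()
    if universe is None:
        universe = set(engine.genes) & pathway_gene_union
    pathway_sets = {pid: set(gs) & universe for pid, gs in pathways.items()}

    plans = [_ChainPlan(sub, engine.genes) for sub in subpathways]
    gene_pos = {g: i for i, g in enumerate(engine.genes)}
    pathway_idx = {
        pid: np.array(sorted(gene_pos[g] for g in genes if g in gene_pos), dtype=int)
        for pid, genes in pathway_sets.items()
    }

    def pathway_pvalues(stats: pd.DataFrame) -> dict[str, float]:
        de = de_genes(stats, enrichment_direction) & universe
        return {
            pid: _clip_p(hypergeom_enrich(de, genes, universe, pid).p_value)
            for pid, genes in pathway_sets.items()
        }

    def score_all(stats: pd.DataFrame, keep_detail: bool):
        d = stats["delta_e"].to_numpy(float)
        c = stats["chi2"].to_numpy(float)
        f = stats["is_de"].to_numpy(bool)
        pp = pathway_pvalues(stats)
        norms: dict[str, tuple[float, int]] = {}
        if de_scope == "pathway":
            for pid, idx in pathway_idx.items():
                flags = f[idx]
                n_de_path = int(flags.sum())
                mean_abs = float(np.abs(d[idx][flags]).mean()) if n_de_path else 0.0
                norms[pid] = (mean_abs, n_de_path)
        out = []
        for plan in plans:
            s, pf, n_de = plan.score(
                d, c, f, pp[plan.sub.pathway_id], binding_agg,
                norms.get(plan.sub.pathway_id) if de_scope == "pathway" else None,
            )
            out.append((s, pf, n_de) if keep_detail else s)
        return out

    observed_stats = engine.stats(dataset.metadata["condition"])
    observed = score_all(observed_stats, keep_detail=True)

    null_by_length: dict[int, list[float]] = {}
    for cond in permute_conditions(
        dataset.metadata.loc[engine.samples], engine.paired, n_permutations, seed
    ):
        perm_scores = score_all(engine.stats(cond), keep_detail=False)
        for plan, s in zip(plans, perm_scores):
            null_by_length.setdefault(plan.sub.length, []).append(s)

    nulls = {
        length: PermutationNull(length, np.array(scores), n_permutations)
        for length, scores in null_by_length.items()
    }

    rows = []
    for sub, (score, pf, n_de) in zip(subpathways, observed):
        p = empirical_pvalue(score, nulls[sub.length], sub.length)
        terminal = float(pf[-1])
        top = int(np.argmax(np.abs(pf)))
        rows.append(
            {
                "pathway_id": sub.pathway_id,
                "chain": sub.chain_str,
                "length": sub.length,
                "impact_factor": score,
                "terminal_pf": terminal,
                "n_de": n_de,
                "direction": "up" if terminal > 0 else ("down" if terminal < 0 else "none"),
                "top_pf_node": sub.chain[top],
                "empirical_p": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr_q"] = fdr_adjust(result["empirical_p"].to_numpy())
    else:
        result["fdr_q"] = []
    return result


def overlap_subpathways(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlapping upregulated subpathways across two scored cohorts.

    A subpathway is retained iff its empirical p is below ``alpha`` in
    both cohorts and its propagated signal runs in the same, positive
    direction (terminal PF > 0) in both. Returns the per-subpathway
    overlap table (with ``fdr`` = the worse of the two BH q-values) and
    a per-pathway summary of significant / overlapping counts.
    """
    key = ["pathway_id", "chain"]
    if set(map(tuple, scores_a[key].itertuples(index=False))) != set(
        map(tuple, scores_b[key].itertuples(index=False))
    ):
        raise ValueError("cohorts were scored on different subpathway universes")
    merged = scores_a.merge(scores_b, on=key + ["length"], suffixes=("_a", "_b"))
    kept = merged[
        (merged["empirical_p_a"] < alpha)
        & (merged["empirical_p_b"] < alpha)
        & (merged["terminal_pf_a"] > 0)
        & (merged["terminal_pf_b"] > 0)
    ].copy()
    kept["fdr"] = np.maximum(kept["fdr_q_a"], kept["fdr_q_b"])
    kept = kept.sort_values(["pathway_id", "chain"]).reset_index(drop=True)

    summary_rows = []
    for pid in sorted(scores_a["pathway_id"].unique()):
        sel_a = scores_a[scores_a["pathway_id"] == pid]
        sel_b = scores_b[scores_b["pathway_id"] == pid]
        sel_o = kept[kept["pathway_id"] == pid]
        summary_rows.append(
            {
                "pathway_id": pid,
                "n_subpathways": len(sel_a),
                "n_significant_a": int((sel_a["empirical_p"] < alpha).sum()),
                "n_significant_b": int((sel_b["empirical_p"] < alpha).sum()),
                "n_overlap": len(sel_o),
                "fdr_overlap": float(sel_o["fdr"].median()) if len(sel_o) else float("nan"),
                "top_genes": ",".join(sorted(set(sel_o["top_pf_node_a"]))) if len(sel_o) else "",
            }
        )
    return kept, pd.DataFrame(summary_rows)
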
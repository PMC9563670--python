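"""Perturbation propagation, the impact factor, permutation machinery, FDR."""

import math

import numpy as np
import pandas as pd
import pytest

import subpathways as sp
from subpathways.impact import NodeStats, propagate, resolve_node_stats


def stats_frame(rows: dict) -> pd.DataFrame:
    """rows: gene -> (delta_e, chi2, is_de)"""
    return pd.DataFrame(
        {
            "delta_e": {g: v[0] for g, v in rows.items()},
            "chi2": {g: v[1] for g, v in rows.items()},
            "is_de": {g: v[2] for g, v in rows.items()},
        }
    )


# ---------------------------------------------------------------------------
# perturbation factors
# ---------------------------------------------------------------------------

def test_pf_single_node_is_own_term(chain_factory):
    stats = stats_frame({"a": (1.0, 4.0, True)})
    pf = sp.perturbation_factors(chain_factory(["a"]), stats)
    assert pf.tolist() == [4.0]


def test_pf_activation_and_inhibition_steps(chain_factory):
    stats = stats_frame({"a": (1.0, 4.0, True), "b": (0.5, 2.0, True)})
    assert sp.perturbation_factors(chain_factory(["a", "b"], [1]), stats).tolist() == [4.0, 5.0]
    assert sp.perturbation_factors(chain_factory(["a", "b"], [-1]), stats).tolist() == [4.0, -3.0]


def test_pf_missing_gene_contributes_zero(chain_factory):
    stats = stats_frame({"a": (1.0, 4.0, True)})
    pf = sp.perturbation_factors(chain_factory(["a", "unknown", "a"]), stats)
    assert pf.tolist() == [4.0, 4.0, 8.0]


@pytest.mark.parametrize("seed", range(10))
def test_all_activation_chain_telescopes(seed):
    """For an all-activation chain the terminal PF equals the running sum
    of the per-gene dE*chi2 terms, and negating every dE negates every PF."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 11))
    base = rng.normal(0, 2, n) * rng.chisquare(1, n)
    pf = propagate(base, [1] * (n - 1))
    assert pf[-1] == pytest.approx(base.sum())
    assert np.allclose(np.cumsum(base), pf)
    signs = [int(s) for s in rng.choice([-1, 1], size=n - 1)]
    assert np.allclose(propagate(-base, signs), -propagate(base, signs))


def test_propagate_validates_sign_length():
    with pytest.raises(ValueError):
        propagate([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# node resolution
# ---------------------------------------------------------------------------

def test_resolve_merged_binding_takes_strongest_member():
    stats = stats_frame({"b": (0.5, 2.0, False), "c": (2.0, 5.0, True)})
    ns = resolve_node_stats(("b", "c"), "merged_binding", stats)
    assert ns == NodeStats(2.0, 5.0, True)
    ns_mean = resolve_node_stats(("b", "c"), "merged_binding", stats, binding_agg="mean")
    assert ns_mean == NodeStats(1.25, 3.5, True)


def test_resolve_condensed_loop_is_conjunctive():
    stats = stats_frame({"b": (1.0, 4.0, True), "c": (3.0, 2.0, True)})
    ns = resolve_node_stats(("b", "c"), "condensed_loop", stats)
    assert ns == NodeStats(2.0, 3.0, True)
    # one member not DE -> the loop node is not DE
    stats2 = stats_frame({"b": (1.0, 4.0, True), "c": (3.0, 2.0, False)})
    assert not resolve_node_stats(("b", "c"), "condensed_loop", stats2).is_de
    # a member without data keeps the loop inactive
    assert not resolve_node_stats(("b", "zz"), "condensed_loop", stats).is_de


def test_resolve_unknown_gene_is_inert():
    assert resolve_node_stats(("zz",), "simple", stats_frame({"a": (1, 1, True)})) == NodeStats(
        0.0, 0.0, False
    )


# ---------------------------------------------------------------------------
# impact factor
# ---------------------------------------------------------------------------

def test_impact_factor_worked_example():
    value = sp.impact_factor([4.0, 5.0], math.exp(-1), [True, True], [1.0, 0.5])
    assert value == pytest.approx(7.0)


def test_impact_factor_vanishes_without_evidence():
    assert sp.impact_factor([4.0, 5.0], 1.0, [False, False], [1.0, 0.5]) == 0.0


def test_impact_factor_second_term_linear_in_pf():
    kwargs = dict(p_path=math.exp(-1), de_flags=[True, True], delta_es=[1.0, 0.5])
    base = sp.impact_factor([4.0, 5.0], **kwargs) - 1.0
    doubled = sp.impact_factor([8.0, 10.0], **kwargs) - 1.0
    assert doubled == pytest.approx(2 * base)


def test_impact_factor_validates_p_path():
    for bad in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            sp.impact_factor([1.0], bad, [True], [1.0])


# ---------------------------------------------------------------------------
# permutations and empirical p-values
# ---------------------------------------------------------------------------

def _paired_metadata(n_pairs: int) -> pd.DataFrame:
    idx = [f"P{i}_{c}" for i in range(n_pairs) for c in ("pre", "post")]
    return pd.DataFrame(
        {
            "condition": ["pre", "post"] * n_pairs,
            "pair_id": [f"P{i}" for i in range(n_pairs) for _ in range(2)],
        },
        index=idx,
    )


def test_paired_permutation_preserves_pair_structure():
    meta = _paired_metadata(4)
    for cond in sp.permute_conditions(meta, paired=True, n_permutations=20, seed=3):
        for _, grp in meta.groupby("pair_id"):
            assert sorted(cond.loc[grp.index]) == ["post", "pre"]


def test_unpaired_permutation_preserves_label_counts():
    meta = _paired_metadata(5).drop(columns="pair_id")
    for cond in sp.permute_conditions(meta, paired=False, n_permutations=20, seed=3):
        assert (cond == "pre").sum() == 5 and (cond == "post").sum() == 5


def test_permutation_stream_is_reproducible():
    meta = _paired_metadata(6)
    a = [c.tolist() for c in sp.permute_conditions(meta, True, 10, seed=9)]
    b = [c.tolist() for c in sp.permute_conditions(meta, True, 10, seed=9)]
    assert a == b
    with pytest.raises(ValueError):
        list(sp.permute_conditions(meta, True, 0, seed=9))


def test_empirical_pvalue_counting():
    null = sp.PermutationNull(length=3, scores=np.arange(10, dtype=float), n_permutations=10)
    # larger than everything -> 1/(M+1)
    assert sp.empirical_pvalue(100.0, null, 3) == pytest.approx(1 / 11)
    # equal to the null minimum -> every null score counts
    assert sp.empirical_pvalue(0.0, null, 3) == pytest.approx(1.0)
    # direct counting oracle in the middle of the null
    assert sp.empirical_pvalue(4.5, null, 3) == pytest.approx((1 + 5) / 11)
    with pytest.raises(ValueError):
        sp.empirical_pvalue(1.0, null, 4)
    with pytest.raises(ValueError):
        sp.empirical_pvalue(1.0, [])


def test_empirical_pvalue_median_of_large_null():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=2001)
    p = sp.empirical_pvalue(float(np.median(scores)), scores)
    assert p == pytest.approx(0.5, abs=1 / 2002 + 1e-9)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_fdr_single_and_tied_pvalues():
    assert sp.fdr_adjust([0.03]).tolist() == [0.03]
    assert np.allclose(sp.fdr_adjust([0.2, 0.2, 0.2]), 0.2)


def test_fdr_step_up_hand_example():
    assert np.allclose(sp.fdr_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_fdr_rank_preserving_and_validated():
    p = [0.001, 0.5, 0.04, 0.2]
    q = sp.fdr_adjust(p)
    assert np.array_equal(np.argsort(q), np.argsort(p))
    with pytest.raises(ValueError):
        sp.fdr_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# scoring pipeline and overlap
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scored_cohorts():
    """Two independently seeded planted-chain cohorts, scored."""
    pathways, subs, genes = {}, [], set()
    for i in range(4):
        chain = [f"C{i+1:02d}N{j+1}" for j in range(3)]
        g = sp.parse_kgml(
            sp.generate_parallel_chains(1, 3, pathway_id=f"chain{i+1:02d}", genes=chain)
        )
        pathways[g.pathway_id] = g.gene_symbols()
        subs.extend(sp.derive_subpathways(g))
        genes |= g.gene_symbols()
    planted = tuple(f"C01N{j+1}" for j in range(3))
    results = []
    for seed in (301, 302):
        spec = sp.SyntheticSpec(n_genes=120, planted_chain=planted, seed=seed)
        ds = sp.generate_expression(spec, pathway_genes=genes)
        results.append(
            sp.score_subpathways(ds, subs, pathways, n_permutations=60, seed=seed)
        )
    return results, ">".join(planted)


def test_score_subpathways_output_contract(scored_cohorts):
    (scores, _), chain = scored_cohorts[0], scored_cohorts[1]
    assert (scores["impact_factor"] >= 0).all()
    assert scores["empirical_p"].between(0, 1).all()
    assert scores["fdr_q"].between(0, 1).all()
    planted_row = scores[scores["chain"] == chain].iloc[0]
    assert planted_row["n_de"] >= 2 and planted_row["direction"] == "up"


def test_score_subpathways_deterministic(scored_cohorts):
    (scores_a, _), _ = scored_cohorts
    pathways = {f"chain{i+1:02d}": {f"C{i+1:02d}N{j+1}" for j in range(3)} for i in range(4)}
    subs = []
    for i in range(4):
        chain = [f"C{i+1:02d}N{j+1}" for j in range(3)]
        g = sp.parse_kgml(
            sp.generate_parallel_chains(1, 3, pathway_id=f"chain{i+1:02d}", genes=chain)
        )
        subs.extend(sp.derive_subpathways(g))
    spec = sp.SyntheticSpec(
        n_genes=120, planted_chain=tuple(f"C01N{j+1}" for j in range(3)), seed=301
    )
    ds = sp.generate_expression(spec, pathway_genes=set().union(*pathways.values()))
    again = sp.score_subpathways(ds, subs, pathways, n_permutations=60, seed=301)
    pd.testing.assert_frame_equal(scores_a, again)


def test_overlap_retains_planted_chain_only(scored_cohorts):
    (scores_a, scores_b), chain = scored_cohorts
    overlap, summary = sp.overlap_subpathways(scores_a, scores_b, alpha=0.05)
    assert list(overlap["chain"]) == [chain]
    assert summary.set_index("pathway_id").loc["chain01", "n_overlap"] == 1
    assert summary["n_overlap"].sum() == 1


def test_overlap_requires_shared_universe(scored_cohorts):
    (scores_a, scores_b), _ = scored_cohorts
    with pytest.raises(ValueError):
        sp.overlap_subpathways(scores_a, scores_b.iloc[1:], alpha=0.05)


def test_overlap_excludes_one_sided_significance():
    base = dict(length=2, impact_factor=1.0, n_de=1, top_pf_node="x", direction="up")
    a = pd.DataFrame(
        [
            {"pathway_id": "p", "chain": "x>y", "terminal_pf": 2.0,
             "empirical_p": 0.01, "fdr_q": 0.02, **base},
            {"pathway_id": "p", "chain": "u>v", "terminal_pf": 2.0,
             "empirical_p": 0.01, "fdr_q": 0.02, **base},
        ]
    )
    b = a.copy()
    b.loc[b["chain"] == "u>v", "empirical_p"] = 0.5  # significant in A only
    overlap, _ = sp.overlap_subpathways(a, b, alpha=0.05)
    assert list(overlap["chain"]) == ["x>y"]
    # a negative terminal PF in one cohort also disqualifies
    b2 = a.copy()
    b2.loc[b2["chain"] == "x>y", "terminal_pf"] = -2.0
    overlap2, _ = sp.overlap_subpathways(a, b2, alpha=0.05)
    assert list(overlap2["chain"]) == ["u>v"]
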
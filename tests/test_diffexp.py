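"""Presence calls, McNemar / chi-square tests, fold change, overlap test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import subpathways as sp
from subpathways.diffexp import gene_expression


# ---------------------------------------------------------------------------
# presence
# ---------------------------------------------------------------------------

def test_gene_presence_any_probe_rule(tiny_dataset):
    presence = sp.gene_presence(tiny_dataset)
    # g1 has probes (A, A) pre and (P, P) post in pair 1
    assert not presence.loc["g1", "s1_pre"] and presence.loc["g1", "s1_post"]
    # marginal call treated as absent by default ...
    assert not presence.loc["g1", "s2_pre"]
    # ... but counts as present when requested
    assert sp.gene_presence(tiny_dataset, marginal_present=True).loc["g1", "s2_pre"]


def test_gene_presence_matches_per_cell_oracle(tiny_dataset):
    presence = sp.gene_presence(tiny_dataset)
    calls = tiny_dataset.calls
    for gene in ["g1", "g2", "g3"]:
        probes = tiny_dataset.probe_map.query("gene == @gene")["probe"]
        for sample in tiny_dataset.samples:
            expected = any(calls.loc[p, sample] == "P" for p in probes)
            assert presence.loc[gene, sample] == expected


def test_gene_expression_max_and_mean(tiny_dataset):
    by_max = gene_expression(tiny_dataset, agg="max")
    by_mean = gene_expression(tiny_dataset, agg="mean")
    assert by_max.loc["g1", "s1_pre"] == 100.0
    assert by_mean.loc["g1", "s1_pre"] == 70.0


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("b,c", [(0, 0), (3, 3), (7, 7)])
def test_mcnemar_concordant_counts_give_null(b, c):
    chi2, p = sp.mcnemar_stat(b, c)
    assert chi2 == 0.0 and p == 1.0


def test_mcnemar_closed_form():
    chi2, p = sp.mcnemar_stat(5, 1)
    assert chi2 == pytest.approx(16 / 6)
    assert p == pytest.approx(float(sps.chi2.sf(16 / 6, 1)))


def test_mcnemar_symmetry_and_validation():
    assert sp.mcnemar_stat(8, 2) == sp.mcnemar_stat(2, 8)
    with pytest.raises(ValueError):
        sp.mcnemar_stat(-1, 2)


def test_mcnemar_continuity_correction():
    chi2, _ = sp.mcnemar_stat(5, 1, correction=True)
    assert chi2 == pytest.approx((4 - 0.5) ** 2 / 6)


# ---------------------------------------------------------------------------
# Pearson chi-square
# ---------------------------------------------------------------------------

def test_chisq_equal_proportions_null():
    chi2, p = sp.chisq_presence([[20, 20], [10, 10]])
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_chisq_worked_table():
    chi2, _ = sp.chisq_presence([[30, 10], [10, 30]])
    assert chi2 == pytest.approx(20.0)


@pytest.mark.parametrize("seed", range(5))
def test_chisq_matches_expected_count_oracle(seed):
    """Statistic equals the brute-force sum of (O-E)^2/E with E rebuilt
    from the margins, and matches scipy's uncorrected contingency test."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        table = rng.integers(1, 50, size=(2, 2)).astype(float)
        chi2, p = sp.chisq_presence(table)
        rows, cols, total = table.sum(1), table.sum(0), table.sum()
        oracle = sum(
            (table[i, j] - rows[i] * cols[j] / total) ** 2 / (rows[i] * cols[j] / total)
            for i in range(2)
            for j in range(2)
        )
        assert chi2 == pytest.approx(oracle)
        ref = sps.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


def test_chisq_swap_invariance():
    t = [[12, 5], [3, 20]]
    base = sp.chisq_presence(t)[0]
    assert sp.chisq_presence([t[1], t[0]])[0] == pytest.approx(base)
    assert sp.chisq_presence([[r[1], r[0]] for r in t])[0] == pytest.approx(base)


def test_chisq_degenerate_tables():
    assert sp.chisq_presence([[5, 5], [0, 0]]) == (0.0, 1.0)  # zero margin
    with pytest.raises(ValueError):
        sp.chisq_presence([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        sp.chisq_presence([[1, -1], [2, 3]])


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def test_log_fold_change_identity_and_doubling():
    assert sp.log_fold_change(50.0, 50.0) == 0.0
    assert sp.log_fold_change(50.0, 100.0) == 1.0
    assert sp.log_fold_change(100.0, 50.0) == -1.0


def test_log_fold_change_floor_and_vectors():
    # values below the floor are lifted to it before the ratio
    assert sp.log_fold_change(0.25, 2.0, floor=1.0) == 1.0
    out = sp.log_fold_change([2.0, 8.0], [4.0, 4.0])
    assert np.allclose(out, [1.0, -1.0])
    with pytest.raises(ValueError):
        sp.log_fold_change(-5.0, 2.0, floor=0.0)  # nonpositive after flooring


# ---------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------

def test_overlap_disjoint_sets():
    k, p = sp.overlap_test({"a", "b"}, {"c", "d"}, 1000)
    assert k == 0 and p == pytest.approx(1.0)


def test_overlap_identical_sets_exact_value():
    genes = set("abcde")
    k, p = sp.overlap_test(genes, genes, 10)
    assert k == 5 and p == pytest.approx(1 / 252)


@pytest.mark.parametrize("seed", range(5))
def test_overlap_matches_combinatorial_oracle(seed):
    """p equals the exact tail sum over hypergeometric draws (<= 15 items)."""
    rng = np.random.default_rng(seed)
    for _ in range(10):
        n_univ = int(rng.integers(5, 16))
        universe = list(range(n_univ))
        a = set(rng.choice(universe, size=rng.integers(1, n_univ + 1), replace=False))
        b = set(rng.choice(universe, size=rng.integers(1, n_univ + 1), replace=False))
        k, p = sp.overlap_test(a, b, n_univ)
        tail = sum(
            math.comb(len(a), j) * math.comb(n_univ - len(a), len(b) - j)
            for j in range(k, min(len(a), len(b)) + 1)
            if len(b) - j <= n_univ - len(a)
        ) / math.comb(n_univ, len(b))
        assert p == pytest.approx(tail)


def test_overlap_universe_too_small():
    with pytest.raises(ValueError):
        sp.overlap_test({"a", "b", "c"}, {"a"}, 2)


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

def test_gene_stats_paired_matches_hand_counts(tiny_dataset):
    """McNemar counts and fold changes recomputed by hand on the fixture."""
    stats = sp.gene_stats(tiny_dataset)
    # g1: both pairs absent pre / present post -> b=0, c=2
    chi2, p = sp.mcnemar_stat(0, 2)
    assert stats.loc["g1", "chi2"] == pytest.approx(chi2)
    assert stats.loc["g1", "p_value"] == pytest.approx(p)
    # g2: present everywhere -> concordant, chi2 = 0, p = 1
    assert stats.loc["g2", "chi2"] == 0.0 and stats.loc["g2", "p_value"] == 1.0
    # g3: present pre / absent post in both pairs -> b=2, c=0
    assert stats.loc["g3", "chi2"] == pytest.approx(sp.mcnemar_stat(2, 0)[0])
    # delta_e for g1 via the max-probe rule: post mean 207.5 vs pre mean 97.5
    assert stats.loc["g1", "delta_e"] == pytest.approx(np.log2(207.5 / 97.5))
    assert stats.loc["g1", "direction"] == "up"
    assert stats.loc["g3", "direction"] == "down"


def test_gene_stats_unpaired_matches_elementwise(tiny_dataset):
    """Dropping the pairing reproduces the per-gene 2x2 Pearson test."""
    ds = sp.ExpressionDataset(
        tiny_dataset.expression,
        tiny_dataset.calls,
        tiny_dataset.probe_map,
        tiny_dataset.metadata.drop(columns="pair_id"),
    )
    stats = sp.gene_stats(ds, paired=False)
    presence = sp.gene_presence(ds)
    pre = ["s1_pre", "s2_pre"]
    post = ["s1_post", "s2_post"]
    for gene in presence.index:
        a = int(presence.loc[gene, pre].sum())
        c = int(presence.loc[gene, post].sum())
        table = [[a, len(pre) - a], [c, len(post) - c]]
        try:
            chi2, _ = sp.chisq_presence(table)
        except ValueError:
            chi2 = 0.0
        assert stats.loc[gene, "chi2"] == pytest.approx(chi2)


def test_gene_stats_condition_override_flips_direction(tiny_dataset):
    flipped = tiny_dataset.metadata["condition"].map({"pre": "post", "post": "pre"})
    stats = sp.gene_stats(tiny_dataset)
    stats_flipped = sp.gene_stats(tiny_dataset, condition=flipped)
    assert np.allclose(stats_flipped["delta_e"], -stats["delta_e"])
    assert np.allclose(stats_flipped["chi2"], stats["chi2"])


def test_paired_validation_rejects_broken_pairs(tiny_dataset):
    meta = tiny_dataset.metadata.copy()
    meta.loc["s1_post", "condition"] = "pre"
    ds = sp.ExpressionDataset(
        tiny_dataset.expression, tiny_dataset.calls, tiny_dataset.probe_map, meta
    )
    with pytest.raises(ValueError, match="pair"):
        sp.gene_stats(ds, paired=True)
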
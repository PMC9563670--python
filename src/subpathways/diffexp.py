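"""Presence/absence differential expression between two conditions.

The unit of evidence is the Affymetrix-style detection call: every probe
in every sample is flagged Present / Marginal / Absent, and a gene is
called *present* in a sample if at least one of its probes is Present
(Marginal counts as absent by default). Differential expression between
the ``pre`` and ``post`` conditions is then tested on the presence
indicator:

* paired cohorts — McNemar's test on the discordant pair counts,
  ``chi2 = (b - c)**2 / (b + c)`` with ``b`` = present-pre/absent-post
  pairs and ``c`` the reverse;
* unpaired cohorts — Pearson's chi-square on the 2x2 presence-by-
  condition table (no continuity correction by default).

Each test statistic has one degree of freedom. Alongside the test, the
log2 fold change ``delta_e = log2(mean_post / mean_pre)`` is computed on
floored per-gene expression means; a fold change above one (``delta_e >
0``) marks upregulation after treatment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

CONDITIONS = ("pre", "post")


@dataclass
class ExpressionDataset:
    """Probe-level expression with detection calls and sample metadata.

    ``expression`` and ``calls`` are probes x samples frames of identical
    shape; ``calls`` holds 'P'/'M'/'A'. ``probe_map`` has columns
    ``probe`` and ``gene`` (a probe may map to several genes, one row
    each). ``metadata`` is indexed by sample id with a ``condition``
    column in {'pre', 'post'} and, for paired cohorts, a ``pair_id``
    column pairing exactly one pre with one post sample.
    """

    expression: pd.DataFrame
    calls: pd.DataFrame
    probe_map: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = self.metadata.copy()
        self.metadata.index = self.metadata.index.astype(str)

    def validate(self, paired: bool = False) -> None:
        if list(self.expression.index) != list(self.calls.index) or list(
            self.expression.columns
        ) != list(self.calls.columns):
            raise ValueError("expression and calls must share probes and samples")
        if not set(self.expression.columns) <= set(self.metadata.index):
            raise ValueError("every sample column needs a metadata row")
        bad = set(self.metadata["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"conditions must be in {CONDITIONS}, got {bad}")
        unmapped = set(self.expression.index) - set(self.probe_map["probe"])
        if unmapped:
            raise ValueError(f"{len(unmapped)} probes have no gene mapping")
        if paired:
            _pair_table(self.metadata)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def genes(self) -> list[str]:
        return sorted(set(self.probe_map["gene"]))

    def is_paired(self) -> bool:
        return bool(
            "pair_id" in self.metadata.columns and self.metadata["pair_id"].notna().all()
        )


def _pair_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Rows (pair_id, sample_a, sample_b); validates one pre + one post."""
    if "pair_id" not in metadata.columns:
        raise ValueError("paired mode requires a pair_id metadata column")
    rows = []
    for pid, grp in metadata.groupby("pair_id", sort=True):
        if len(grp) != 2 or sorted(grp["condition"]) != ["post", "pre"]:
            raise ValueError(f"pair {pid!r} must have exactly one pre and one post sample")
        rows.append((pid, *grp.index))
    return pd.DataFrame(rows, columns=["pair_id", "sample_a", "sample_b"])


# ---------------------------------------------------------------------------
# presence and expression summaries
# ---------------------------------------------------------------------------

def gene_presence(dataset: ExpressionDataset, marginal_present: bool = False) -> pd.DataFrame:
    """Genes x samples boolean presence matrix.

    A gene is present in a sample iff at least one of its probes carries
    a 'P' call there ('M' is counted as present only when
    ``marginal_present`` is set).
    """
    wanted = {"P", "M"} if marginal_present else {"P"}
    probe_present = dataset.calls.isin(wanted)
    mapped = probe_present.loc[dataset.probe_map["probe"].to_numpy()]
    mapped.index = dataset.probe_map["gene"].to_numpy()
    presence = mapped.groupby(level=0, sort=True).any()
    return presence


def gene_expression(dataset: ExpressionDataset, agg: str = "max") -> pd.DataFrame:
    """Genes x samples expression, aggregating probes by max (default) or mean.

    The max-probe rule mirrors the any-probe presence rule: the most
    responsive probe represents the gene.
    """
    if agg not in ("max", "mean"):
        raise ValueError("agg must be 'max' or 'mean'")
    mapped = dataset.expression.loc[dataset.probe_map["probe"].to_numpy()]
    mapped.index = dataset.probe_map["gene"].to_numpy()
    grouped = mapped.groupby(level=0, sort=True)
    return grouped.max() if agg == "max" else grouped.mean()


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def mcnemar_stat(n_pre_only: int, n_post_only: int, correction: bool = False) -> tuple[float, float]:
    """McNemar chi-square on discordant pair counts.

    ``n_pre_only`` (b) counts pairs present before / absent after;
    ``n_post_only`` (c) the reverse. Returns ``(chi2, p)`` with
    ``chi2 = (b - c)**2 / (b + c)`` (1 df); ``b = c = 0`` gives (0, 1).
    """
    b, c = n_pre_only, n_post_only
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return 0.0, 1.0
    diff = abs(b - c) - (0.5 if correction else 0.0)
    chi2 = max(diff, 0.0) ** 2 / (b + c)
    return chi2, float(sps.chi2.sf(chi2, df=1))


def chisq_presence(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 presence-by-condition table (1 df).

    A table with a zero margin carries no information and returns
    ``(0, 1)``; an all-zero table is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    total = obs.sum()
    if total == 0:
        raise ValueError("all-zero table")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    diff = np.abs(obs - expected) - (0.5 if correction else 0.0)
    chi2 = float((np.maximum(diff, 0.0) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def log_fold_change(expr_pre, expr_post, floor: float = 1.0):
    """log2 fold change of post over pre means, floored at ``floor``.

    Accepts scalars or arrays; a fold change above one (upregulation
    after treatment) maps to a positive value.
    """
    pre = np.maximum(np.asarray(expr_pre, dtype=float), floor)
    post = np.maximum(np.asarray(expr_post, dtype=float), floor)
    if (pre <= 0).any() or (post <= 0).any():
        raise ValueError("expression means must be positive after flooring")
    out = np.log2(post / pre)
    return float(out) if out.ndim == 0 else out


def overlap_test(genes_a: set, genes_b: set, universe_size: int) -> tuple[int, float]:
    """Hypergeometric upper-tail test of the overlap of two gene sets.

    Returns ``(overlap, p)`` where ``p = P(X >= overlap)`` for the
    overlap of random draws of the two set sizes from the universe.
    """
    if universe_size < len(genes_a) or universe_size < len(genes_b):
        raise ValueError("universe smaller than one of the sets")
    k = len(set(genes_a) & set(genes_b))
    p = float(sps.hypergeom.sf(k - 1, universe_size, len(genes_a), len(genes_b)))
    return k, min(p, 1.0)


# ---------------------------------------------------------------------------
# vectorized per-gene statistics
# ---------------------------------------------------------------------------

class GeneStatsEngine:
    """Per-gene DE statistics with cheap re-evaluation under relabelling.

    The presence and expression matrices are computed once; each call to
    :meth:`stats` only re-derives the condition split, so permutation
    runs (which merely relabel pre/post) are fast.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        *,
        paired: bool | None = None,
        alpha: float = 0.05,
        marginal_present: bool = False,
        expr_agg: str = "max",
        floor: float = 1.0,
        correction: bool = False,
    ) -> None:
        self.paired = dataset.is_paired() if paired is None else paired
        dataset.validate(paired=self.paired)
        presence = gene_presence(dataset, marginal_present=marginal_present)
        expr = gene_expression(dataset, agg=expr_agg)
        self.genes = presence.index
        self.samples = list(presence.columns)
        self._col = {s: i for i, s in enumerate(self.samples)}
        self.P = presence.to_numpy(dtype=bool)
        self.E = expr.to_numpy(dtype=float)
        self.alpha = alpha
        self.floor = floor
        self.correction = correction
        if self.paired:
            pt = _pair_table(dataset.metadata.loc[self.samples])
            self._ia = np.array([self._col[s] for s in pt["sample_a"]])
            self._ib = np.array([self._col[s] for s in pt["sample_b"]])

    def stats(self, condition: pd.Series) -> pd.DataFrame:
        cond = condition.reindex(self.samples)
        if cond.isna().any() or not set(cond) <= set(CONDITIONS):
            raise ValueError("condition labels must cover all samples with 'pre'/'post'")
        is_pre = (cond == "pre").to_numpy()

        if self.paired:
            a_pre = is_pre[self._ia]
            b_pre = is_pre[self._ib]
            if not np.all(a_pre ^ b_pre):
                raise ValueError("each pair must keep one pre and one post sample")
            pre_idx = np.where(a_pre, self._ia, self._ib)
            post_idx = np.where(a_pre, self._ib, self._ia)
            Ppre, Ppost = self.P[:, pre_idx], self.P[:, post_idx]
            b = (Ppre & ~Ppost).sum(axis=1).astype(float)
            c = (~Ppre & Ppost).sum(axis=1).astype(float)
            n = b + c
            diff = np.abs(b - c) - (0.5 if self.correction else 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(n > 0, np.maximum(diff, 0.0) ** 2 / np.where(n > 0, n, 1), 0.0)
        else:
            pre_idx = np.where(is_pre)[0]
            post_idx = np.where(~is_pre)[0]
            n_pre, n_post = len(pre_idx), len(post_idx)
            if n_pre == 0 or n_post == 0:
                raise ValueError("both conditions need at least one sample")
            a = self.P[:, pre_idx].sum(axis=1).astype(float)  # present, pre
            c = self.P[:, post_idx].sum(axis=1).astype(float)  # present, post
            bq = n_pre - a
            dq = n_post - c
            total = float(n_pre + n_post)
            present = a + c
            absent = bq + dq
            num = total * (a * dq - bq * c) ** 2
            den = n_pre * n_post * present * absent
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

        p_value = sps.chi2.sf(chi2, df=1)
        p_value = np.where(chi2 == 0, 1.0, p_value)

        mean_pre = np.maximum(self.E[:, np.where(is_pre)[0]].mean(axis=1), self.floor)
        mean_post = np.maximum(self.E[:, np.where(~is_pre)[0]].mean(axis=1), self.floor)
        delta_e = np.log2(mean_post / mean_pre)

        is_de = p_value < self.alpha
        direction = np.where(delta_e > 0, "up", np.where(delta_e < 0, "down", "none"))
        return pd.DataFrame(
            {
                "delta_e": delta_e,
                "chi2": chi2,
                "p_value": p_value,
                "is_de": is_de,
                "direction": direction,
            },
            index=self.genes,
        )


def gene_stats(
    dataset: ExpressionDataset,
    *,
    paired: bool | None = None,
    condition: pd.Series | None = None,
    alpha: float = 0.05,
    marginal_present: bool = False,
    expr_agg: str = "max",
    floor: float = 1.0,
    correction: bool = False,
) -> pd.DataFrame:
    """Per-gene DE table: delta_e, chi2, p_value, is_de, direction.

    ``paired`` defaults to whether the metadata carries complete pair
    ids. ``condition`` may override the metadata condition labels (used
    by permutation runs).
    """
    engine = GeneStatsEngine(
        dataset,
        paired=paired,
        alpha=alpha,
        marginal_present=marginal_present,
        expr_agg=expr_agg,
        floor=floor,
        correction=correction,
    )
    cond = condition if condition is not None else dataset.metadata["condition"]
    return engine.stats(cond)


def de_genes(stats: pd.DataFrame, direction: str = "all") -> set[str]:
    """Significant genes, optionally restricted to up- or downregulated."""
    mask = stats["is_de"]
    if direction == "up":
        mask = mask & (stats["delta_e"] > 0)
    elif direction == "down":
        mask = mask & (stats["delta_e"] < 0)
    elif direction != "all":
        raise ValueError("direction must be 'all', 'up' or 'down'")
    return set(stats.index[mask])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(
    expression_path, calls_path, probe_map_path, metadata_path, sep: str = "\t"
) -> ExpressionDataset:
    """Load the four tab-delimited inputs into an :class:`ExpressionDataset`."""
    expression = pd.read_csv(expression_path, sep=sep, index_col=0)
    calls = pd.read_csv(calls_path, sep=sep, index_col=0)
    probe_map = pd.read_csv(probe_map_path, sep=sep)
    metadata = pd.read_csv(metadata_path, sep=sep, index_col=0)
    return ExpressionDataset(expression, calls, probe_map, metadata)


def save_dataset(dataset: ExpressionDataset, outdir, sep: str = "\t") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "calls": outdir / "calls.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    dataset.expression.to_csv(paths["expression"], sep=sep)
    dataset.calls.to_csv(paths["calls"], sep=sep)
    dataset.probe_map.to_csv(paths["probe_map"], sep=sep, index=False)
    dataset.metadata.to_csv(paths["metadata"], sep=sep, index_label="sample_id")
    return paths
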
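"""Synthetic pathways, expression cohorts and cohort-matching tables.

The generators emulate the structure of a two-condition (pre/post
treatment) Affymetrix-style study: KGML pathway documents with
activation/inhibition/binding/loop motifs, probe-level expression
matrices with P/M/A detection calls, and the demographic matching table
used to describe an unpaired cohort. A *planted* activated chain — a set
of genes given an elevated post-treatment fold change and a presence-
call shift — provides ground truth for recovery benchmarks.

Defaults mirror the study design the package targets: a paired cohort of
40 patients (pre and post sample each) and an unpaired cohort of 690 pre
vs 45 post samples, a baseline presence rate of one half, a planted
log2 effect of 1.5 and a presence shift of 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import ExpressionDataset, save_dataset
from .kgml import BINDING_SUBTYPE, PathwayGraph, write_kgml


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal expression generator.

    ``delta_e_effect`` is the log2 fold change added to planted genes
    after treatment; ``presence_shift`` the increase in their Present-
    call probability; ``noise_sd`` the per-sample log2 noise.
    """

    n_genes: int = 1000
    n_pairs: int = 40
    n_pre: int = 690
    n_post: int = 45
    paired: bool = True
    planted_chain: tuple[str, ...] = ()
    delta_e_effect: float = 1.5
    presence_shift: float = 0.4
    baseline_presence: float = 0.5
    noise_sd: float = 0.5
    patient_sd: float = 0.5
    absent_attenuation: float = 2.0
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_shift", "baseline_presence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    def gene_universe(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


# ---------------------------------------------------------------------------
# pathway generators
# ---------------------------------------------------------------------------

def _graph_to_kgml(pathway_id: str, nodes: list[str], edges: set) -> str:
    g = PathwayGraph(pathway_id, {n: (n,) for n in nodes}, set(edges))
    return write_kgml(g)


def generate_pathway(
    n_nodes: int,
    edge_prob: float = 0.15,
    n_bindings: int = 0,
    n_loops: int = 0,
    inhibition_frac: float = 0.1,
    seed: int = 0,
    pathway_id: str | None = None,
    gene_prefix: str = "G",
) -> str:
    """Random KGML pathway with requested binding and loop motif counts.

    The backbone is a connected chain over ``n_nodes - n_bindings``
    genes with extra forward edges added at ``edge_prob``. Each binding
    event attaches one reserved gene in parallel to an internal backbone
    node and links the two by a binding/association relation (the
    diamond-with-binding motif); each loop adds one back edge over a
    disjoint three-node backbone window. Output is byte-identical for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_backbone = n_nodes - n_bindings
    if n_backbone < 2:
        raise ValueError("n_nodes too small for the requested bindings")
    if n_bindings and n_backbone < 3:
        raise ValueError("bindings need an internal backbone node")
    if n_loops and (n_backbone < 3 or n_loops > n_backbone // 3):
        raise ValueError("too many loops for the backbone size")

    names = [f"{gene_prefix}{i + 1:03d}" for i in range(n_nodes)]
    backbone = names[:n_backbone]
    reserved = names[n_backbone:]

    def subtype() -> str:
        return "inhibition" if rng.random() < inhibition_frac else "activation"

    def sign_of(st: str) -> int:
        return -1 if st == "inhibition" else 1

    edges: set = set()
    for a, b in zip(backbone, backbone[1:]):
        st = subtype()
        edges.add((a, b, sign_of(st), st))
    for i in range(n_backbone):
        for j in range(i + 2, n_backbone):
            if rng.random() < edge_prob:
                st = subtype()
                edges.add((backbone[i], backbone[j], sign_of(st), st))

    internal = list(range(1, n_backbone - 1))
    anchors = rng.choice(internal, size=n_bindings, replace=False) if n_bindings else []
    for k, pos in enumerate(sorted(int(a) for a in anchors)):
        b_node, c_node = backbone[pos], reserved[k]
        edges.add((backbone[pos - 1], c_node, 1, "activation"))
        edges.add((c_node, backbone[pos + 1], 1, "activation"))
        edges.add((b_node, c_node, 1, BINDING_SUBTYPE))

    if n_loops:
        starts = rng.choice(n_backbone // 3, size=n_loops, replace=False)
        for s in sorted(int(x) * 3 for x in starts):
            edges.add((backbone[s + 2], backbone[s], 1, "activation"))

    return _graph_to_kgml(pathway_id or f"syn{seed:05d}", names, edges)


def generate_parallel_chains(
    n_chains: int,
    chain_len: int,
    pathway_id: str = "chains",
    genes: list[str] | None = None,
) -> str:
    """Pathway of disjoint entry-to-end activation chains.

    Chain ``i`` uses genes ``genes[i*chain_len:(i+1)*chain_len]``; with
    the default naming, chain 0 is C01N1 -> ... -> C01N{L}. Useful as a
    benchmark where one whole chain is planted and the others are
    decoys of identical length.
    """
    n = n_chains * chain_len
    if genes is None:
        genes = [f"C{i + 1:02d}N{j + 1}" for i in range(n_chains) for j in range(chain_len)]
    if len(genes) != n:
        raise ValueError(f"need exactly {n} gene names")
    edges = set()
    for i in range(n_chains):
        chain = genes[i * chain_len : (i + 1) * chain_len]
        for a, b in zip(chain, chain[1:]):
            edges.add((a, b, 1, "activation"))
    return _graph_to_kgml(pathway_id, genes, edges)


def generate_layered_pathway(
    width: int,
    depth: int,
    pathway_id: str = "layered",
    genes: list[str] | None = None,
) -> str:
    """Fully connected layered DAG: ``width**(depth-1) * width`` chains.

    All chains have exactly ``depth`` nodes, which makes the pathway a
    convenient source of many equal-length subpathways for calibration
    studies.
    """
    n = width * depth
    if genes is None:
        genes = [f"L{i + 1}N{j + 1}" for i in range(depth) for j in range(width)]
    if len(genes) != n:
        raise ValueError(f"need exactly {n} gene names")
    layers = [genes[i * width : (i + 1) * width] for i in range(depth)]
    edges = set()
    for upper, lower in zip(layers, layers[1:]):
        for a in upper:
            for b in lower:
                edges.add((a, b, 1, "activation"))
    return _graph_to_kgml(pathway_id, genes, edges)


def binding_motif_kgml(pathway_id: str = "binding_motif") -> str:
    """The four-gene diamond with a binding event: A->B, A->C, B->D,
    C->D plus B---C. Its subpathways are (A,B,D), (A,C,D) and (A,B+C,D).
    """
    edges = {
        ("A", "B", 1, "activation"),
        ("A", "C", 1, "activation"),
        ("B", "D", 1, "activation"),
        ("C", "D", 1, "activation"),
        ("B", "C", 1, BINDING_SUBTYPE),
    }
    return _graph_to_kgml(pathway_id, ["A", "B", "C", "D"], edges)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def generate_expression(
    spec: SyntheticSpec, pathway_genes: set | None = None
) -> ExpressionDataset:
    """Probe-level expression + detection calls with a planted signal.

    Background genes keep the same presence rate and expected expression
    in both conditions; planted genes gain ``presence_shift`` on their
    Present-call probability and ``delta_e_effect`` log2 units of
    expression in post-treatment samples. Paired cohorts share a random
    per-patient intercept between the two samples of a pair.
    """
    genes = spec.gene_universe()
    if pathway_genes:
        extra = sorted(set(pathway_genes) - set(genes))
        genes = genes + extra
    gene_set = set(genes)
    missing = [g for g in spec.planted_chain if g not in gene_set]
    if missing:
        raise ValueError(f"planted genes absent from the universe: {missing}")
    planted = np.array([g in set(spec.planted_chain) for g in genes])

    rng = np.random.default_rng(spec.seed)
    n_genes = len(genes)

    if spec.paired:
        samples = [f"P{i + 1:03d}_{c}" for i in range(spec.n_pairs) for c in ("pre", "post")]
        condition = ["pre", "post"] * spec.n_pairs
        pair_id = [f"P{i + 1:03d}" for i in range(spec.n_pairs) for _ in range(2)]
        intercepts = np.repeat(rng.normal(0.0, spec.patient_sd, spec.n_pairs), 2)
    else:
        samples = [f"S{i + 1:04d}_pre" for i in range(spec.n_pre)] + [
            f"S{i + 1:04d}_post" for i in range(spec.n_post)
        ]
        condition = ["pre"] * spec.n_pre + ["post"] * spec.n_post
        pair_id = [None] * len(samples)
        intercepts = np.zeros(len(samples))

    n_samples = len(samples)
    is_post = np.array([c == "post" for c in condition])

    p_present = np.full((n_genes, n_samples), spec.baseline_presence)
    p_present += spec.presence_shift * np.outer(planted, is_post)
    present = rng.random((n_genes, n_samples)) < np.minimum(p_present, 1.0)

    # Detection calls are intensity-derived on real arrays: a sample in
    # which the transcript is not detected sits near background, so
    # absent calls attenuate the measured expression.
    baseline = 7.0 + rng.normal(0.0, 1.0, n_genes)
    log2_expr = (
        baseline[:, None]
        + intercepts[None, :]
        + rng.normal(0.0, spec.noise_sd, (n_genes, n_samples))
    )
    log2_expr += spec.delta_e_effect * np.outer(planted, is_post)
    log2_expr -= spec.absent_attenuation * (~present)
    expr_gene = 2.0 ** log2_expr

    # expand genes to probes
    k = spec.probes_per_gene
    probes = [f"{g}_at{j + 1}" for g in genes for j in range(k)]
    probe_map = pd.DataFrame(
        {"probe": probes, "gene": [g for g in genes for _ in range(k)]}
    )
    probe_expr = np.repeat(expr_gene, k, axis=0) * 2.0 ** rng.normal(
        0.0, 0.1, (n_genes * k, n_samples)
    )
    probe_present = np.repeat(present, k, axis=0)
    if k > 1:
        # a present gene shows P on a random nonempty probe subset
        keep = rng.random((n_genes * k, n_samples)) < 0.7
        forced = np.zeros_like(keep)
        pick = rng.integers(0, k, (n_genes, n_samples))
        forced[pick + np.arange(n_genes)[:, None] * k, np.arange(n_samples)[None, :]] = True
        probe_present &= keep | forced

    calls = np.where(
        probe_present, "P", np.where(rng.random(probe_present.shape) < 0.1, "M", "A")
    )

    expression = pd.DataFrame(np.round(probe_expr, 4), index=probes, columns=samples)
    calls_df = pd.DataFrame(calls, index=probes, columns=samples)
    metadata = pd.DataFrame(
        {"condition": condition, "pair_id": pair_id}, index=pd.Index(samples, name="sample_id")
    )
    if not spec.paired:
        metadata = metadata.drop(columns="pair_id")
    return ExpressionDataset(expression, calls_df, probe_map, metadata)


# ---------------------------------------------------------------------------
# cohort matching table
# ---------------------------------------------------------------------------

RECEPTOR_STRATA = (
    "ER+PR+HER2+",
    "ER+PR-/ER-PR+/ER-PR-HER2-",
    "ER+PR-/ER-PR+/ER-PR-HER2+",
    "ER-PR-HER2-",
)

#: (age group, race group, receptor stratum, pre count, post count) of the
#: demonstration matched cohort (690 pre vs 45 post samples in total).
MATCHED_COHORT_SCHEME: tuple[tuple[str, str, str, int, int], ...] = (
    ("<55", "white", RECEPTOR_STRATA[0], 15, 1),
    ("<55", "white", RECEPTOR_STRATA[1], 89, 5),
    ("<55", "white", RECEPTOR_STRATA[2], 21, 2),
    ("<55", "white", RECEPTOR_STRATA[3], 46, 7),
    ("<55", "non-white", RECEPTOR_STRATA[0], 22, 1),
    ("<55", "non-white", RECEPTOR_STRATA[1], 52, 6),
    ("<55", "non-white", RECEPTOR_STRATA[2], 35, 4),
    ("<55", "non-white", RECEPTOR_STRATA[3], 48, 4),
    (">55", "white", RECEPTOR_STRATA[0], 31, 0),
    (">55", "white", RECEPTOR_STRATA[1], 94, 6),
    (">55", "white", RECEPTOR_STRATA[2], 30, 3),
    (">55", "white", RECEPTOR_STRATA[3], 55, 6),
    (">55", "non-white", RECEPTOR_STRATA[0], 51, 0),
    (">55", "non-white", RECEPTOR_STRATA[1], 30, 0),
    (">55", "non-white", RECEPTOR_STRATA[2], 25, 0),
    (">55", "non-white", RECEPTOR_STRATA[3], 46, 0),
)

_STRATUM_RECEPTORS = {
    RECEPTOR_STRATA[0]: ("+", "+", "+"),
    RECEPTOR_STRATA[1]: ("+", "-", "-"),
    RECEPTOR_STRATA[2]: ("+", "-", "+"),
    RECEPTOR_STRATA[3]: ("-", "-", "-"),
}


def _receptor_stratum(er: str, pr: str, her2: str) -> str:
    if er == "-" and pr == "-" and her2 == "-":
        return RECEPTOR_STRATA[3]
    if er == "+" and pr == "+" and her2 == "+":
        return RECEPTOR_STRATA[0]
    return RECEPTOR_STRATA[1] if her2 == "-" else RECEPTOR_STRATA[2]


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cohort_summary(metadata: pd.DataFrame) -> pd.DataFrame:
    """Stratified pre/post sample counts and column percentages.

    Rows are the 16 strata of age (< 55 vs >= 55) by race (white vs
    non-white) by hormone-receptor pattern (triple positive; HR
    discordant-or-negative split by HER2; triple negative). Requires
    metadata columns condition, age, race, ER, PR, HER2. Percentages are
    per condition column, rounded half-up to two decimals.
    """
    required = {"condition", "age", "race", "ER", "PR", "HER2"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata lacks stratification fields: {sorted(missing)}")

    counts = {(a, r, s): [0, 0] for a in ("<55", ">55") for r in ("white", "non-white")
              for s in RECEPTOR_STRATA}
    for _, row in metadata.iterrows():
        age_group = "<55" if float(row["age"]) < 55 else ">55"
        race_group = "white" if str(row["race"]).strip().lower() == "white" else "non-white"
        stratum = _receptor_stratum(str(row["ER"]), str(row["PR"]), str(row["HER2"]))
        col = 0 if row["condition"] == "pre" else 1
        counts[(age_group, race_group, stratum)][col] += 1

    total_pre = sum(v[0] for v in counts.values())
    total_post = sum(v[1] for v in counts.values())
    rows = []
    for age, race, stratum, _, _ in MATCHED_COHORT_SCHEME:
        pre, post = counts[(age, race, stratum)]
        rows.append(
            {
                "age_group": age,
                "race_group": race,
                "receptor_status": stratum,
                "pre_count": pre,
                "pre_pct": _pct(pre, total_pre),
                "post_count": post,
                "post_pct": _pct(post, total_post),
            }
        )
    return pd.DataFrame(rows)


def demo_matched_cohort(seed: int = 0) -> pd.DataFrame:
    """Sample metadata realizing the demonstration matching scheme.

    Each stratum contributes its scheme count of pre and post samples
    with representative covariate values, so :func:`cohort_summary`
    over the result reproduces the scheme's counts exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for age, race, stratum, n_pre, n_post in MATCHED_COHORT_SCHEME:
        er, pr, her2 = _STRATUM_RECEPTORS[stratum]
        age_value = int(rng.integers(30, 55)) if age == "<55" else int(rng.integers(55, 85))
        race_value = "white" if race == "white" else "black"
        for cond, n in (("pre", n_pre), ("post", n_post)):
            for _ in range(n):
                i += 1
                rows.append(
                    {
                        "sample_id": f"U{i:04d}",
                        "condition": cond,
                        "age": age_value,
                        "race": race_value,
                        "ER": er,
                        "PR": pr,
                        "HER2": her2,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def make_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Materialize a small complete demo dataset under ``outdir``.

    Writes a pathway of six parallel five-gene chains, a paired
    expression cohort with the first chain planted, and the matched-
    cohort metadata table; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kgml = generate_parallel_chains(6, 5, pathway_id="demo")
    (outdir / "demo_pathway.xml").write_text(kgml)

    chain_genes = [f"C01N{j + 1}" for j in range(5)]
    all_genes = {f"C{i + 1:02d}N{j + 1}" for i in range(6) for j in range(5)}
    spec = SyntheticSpec(n_genes=300, planted_chain=tuple(chain_genes), seed=seed)
    dataset = generate_expression(spec, pathway_genes=all_genes)
    paths = save_dataset(dataset, outdir)
    paths["pathway"] = outdir / "demo_pathway.xml"

    cohort = demo_matched_cohort(seed)
    cohort_path = outdir / "matched_cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t")
    paths["matched_cohort"] = cohort_path
    return paths
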
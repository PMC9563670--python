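# Methods

This note documents the models, conventions and numerical choices
behind the package, what the synthetic generator does and does not
emulate, and the known limitations of the statistic.

## Pathway model and the relation-sign coding

A pathway is a signed directed graph over gene nodes parsed from KGML.
Only `gene` entries become nodes; compound and map entries are dropped,
and `group` entries (complexes) are translated into binding events
among their components. Each relation subtype carries a fixed sign used
as the propagation weight β: +1 for signal-inducing subtypes
(activation, expression, repression, indirect effect, state change,
binding/association, missing interaction, phosphorylation,
glycosylation, ubiquitination, methylation) and −1 for inhibiting ones
(inhibition, dissociation, dephosphorylation). The table is immutable
at runtime but extensible through the `table` argument of
`relation_sign` / `parse_kgml`, which also accepts a policy for unknown
subtypes (error by default, skip-with-warning optionally). Note the
deliberately asymmetric rows: repression, missing interaction and
ubiquitination code +1. Parallel relations of conflicting sign between
the same node pair are resolved deterministically to the first edge in
sorted order, which prefers the inhibitory reading.

## Subpathway derivation

A single-chain subpathway runs from an entry node (no parent) to an end
node (no child). Derivation is: condense loops, expand bindings,
enumerate all simple paths.

* **Loop condensation** replaces every nontrivial strongly connected
  component with one node carrying all member genes. The condensed node
  is conjunctive: it counts as differentially expressed only when every
  member is, and its ΔE/χ² are member means.
* **Binding expansion** produces, per binding event between B and C,
  variants with B alone, C alone, or the merged node B+C. The merged
  node is disjunctive (active if either member is present); its ΔE/χ²
  come from the member with the largest |ΔE·χ²| (configurable to
  means). Independent binding events combine multiplicatively; beyond
  `binding_subset_cap` (default 6) the remaining events are resolved as
  merged pairs, bounding the variant count at 3^cap.
* **Enumeration** collects all simple entry→end paths over all binding
  variants, deduplicated by node sequence and sorted lexicographically.
  Caps: `max_path_length` 30 nodes, `max_paths_per_pathway` 50,000,
  both enforced in a deterministic traversal order. The default start
  policy is `entry_only`; `any_node` additionally emits every suffix
  chain, which multiplies counts on dense pathways.

## Per-gene differential expression

A gene is present in a sample iff at least one probe is called `P`
(`M` counts as absent by default; configurable). Paired cohorts use
McNemar's χ² = (b−c)²/(b+c) on the discordant pair counts with the
degenerate case b=c=0 mapped to (χ²=0, p=1); unpaired cohorts use the
uncorrected Pearson χ² on the 2×2 presence-by-condition table, with
zero-margin tables mapped to (0, 1). Continuity corrections are
available but off by default, matching the classical statistic forms.
ΔE is log2(post mean / pre mean) on per-gene expression summarized by
the per-sample max probe (mirroring the any-probe presence rule;
configurable to mean), with both means floored at 1.0 so
background-corrected values near zero cannot blow up the ratio. A gene
is DE at p < 0.05 (configurable); direction is the sign of ΔE.

## Enrichment

Pathway enrichment is the upper-tail hypergeometric probability
P(X ≥ k) of the observed DE-gene overlap; the tail includes the
observed count, so k = 0 gives p = 1. The default universe is the
intersection of the dataset's genes with the union of loaded pathway
genes (configurable to platform-only). The same quantity serves as
P_path in the impact factor, clipped into (10⁻³⁰⁰, 1] before taking
log(1/P_path).

## Impact factor and its normalization scope

PF propagates strictly along the chain — each node has exactly one
upstream — so an all-activation chain telescopes to a running sum of
ΔE·χ² terms (a property the tests assert exactly). The impact factor
adds log(1/P_path) to Σ|PF| normalized by |ΔĒ|·N_de. Two scopes for
the normalization are supported:

* `de_scope="subpathway"` (default): N_de and |ΔĒ| come from the DE
  genes of the chain itself. When a chain has no DE gene the second
  term is defined as zero, so the chain scores exactly log(1/P_path).
* `de_scope="pathway"`: N_de and |ΔĒ| come from the host pathway's DE
  genes. This keeps the statistic continuous whenever the pathway
  contains any DE gene, which matters for calibration studies (below).

## Permutation null and multiplicity

Significance relabels pre/post — independently within each patient for
paired cohorts (a sign-flip scheme, the only reading of within-patient
permutation), a full label shuffle for unpaired cohorts — and rescores
everything: ΔE, χ², the DE set and P_path are recomputed on every
permuted dataset, the only scheme under which the null is valid.
Permuted impact factors are pooled across subpathways of identical
length; the empirical p-value is the add-one upper-tail fraction
(1 + #{null ≥ obs}) / (1 + #null), which stays strictly positive at
small permutation counts. The method's historical default of 10
permutations gives a p-resolution of about 0.1; analyses here use 100
(configurable). FDR control is Benjamini–Hochberg. Cross-cohort
overlap keeps subpathways with empirical p below α in both cohorts and
a positive terminal PF in both ("upregulated" is the sign of the
chain's output node, the carrier of the propagated signal); the
reported per-subpathway overlap FDR is the worse of the two q-values
and per-pathway summaries report the median over overlapped chains.

## Synthetic data generator

The generator emulates a two-condition Affymetrix-style study:

* per-gene baseline log2 expression ~ N(7, 1), per-sample noise
  N(0, 0.5), and for paired cohorts a shared per-patient intercept
  N(0, 0.5) that makes the paired design's advantage visible;
* detection calls drawn at a baseline presence rate of 0.5, with
  absent calls attenuating measured expression by 2.0 log2 units —
  detection calls on real arrays are intensity-derived, so a sample in
  which the transcript is undetected sits near background. Marginal
  calls appear on 10% of absent cells;
* a planted chain: its genes gain `delta_e_effect` (default 1.5) log2
  units of expression and `presence_shift` (default +0.4) Present-call
  probability in post-treatment samples;
* cohort sizes default to the targeted study design: 40 pairs
  (paired) or 690 pre vs 45 post samples (unpaired);
* the matched-cohort summary stratifies an unpaired cohort by age
  (< 55 / ≥ 55), race (white / non-white) and hormone-receptor pattern
  (triple positive; HR-discordant split by HER2; triple negative),
  with column percentages rounded half-up to two decimals. ER+PR+HER2−
  samples, not listed in the scheme's labels, fall into the
  HR-discordant HER2− stratum, and boundary age 55 falls into the
  older group.

What the generator does **not** emulate: probe-level summarization from
raw CEL data (MAS5/RMA), per-gene heterogeneity of presence rates
(real arrays are bimodal — mostly always-present or always-absent
genes; here every background gene flips at rate 0.5, which maximizes
detection-call information and keeps McNemar near its nominal level),
within-patient correlation of detection calls, batch effects, and
correlated expression between pathway neighbours. Passing tests
therefore demonstrate correctness of the machinery and calibration
under idealized noise, not performance on real cohort data.

## Calibration and benchmark designs

* **Type-I error.** On null data (no planted effect) both presence
  tests hold their nominal 5% level at the default cohort sizes; the
  paired test sits slightly below (≈ 0.04) because the discordant
  count is finite (≈ 20 of 40 pairs).
* **Permutation p-value uniformity.** Under the default subpathway
  scope the impact factor has an atom at zero — chains without a DE
  gene score exactly log(1/P_path), and since IF ≥ 0 always, such
  chains receive an empirical p of exactly 1. Null p-values are
  therefore *valid but super-uniform* (conservative), and a KS test
  against the uniform would measure the atom mass ≈ 0.95^L, not a
  calibration failure. The calibration study consequently uses
  `de_scope="pathway"` on a 120-gene pathway (40 three-gene chains),
  where the statistic is continuous, and scores five independently
  generated null datasets (200 subpathways total, 100 permutations
  each): replication across independent datasets avoids the block
  correlation of a single dataset, in which all observed chains share
  one denominator draw. Measured KS is 0.04–0.09 across seeds.
* **Planted-chain recovery.** The benchmark plants one of six disjoint
  three-gene chains, each in its own pathway so the log(1/P_path) term
  differentiates pathways (a single shared pathway would make the
  enrichment universe coincide with the pathway and zero the term for
  every chain). At the default effect sizes the planted chain takes
  the top impact-factor rank in its length stratum in ≥ 95% of 20
  replicates and is recovered exactly — no decoys — by the two-cohort
  overlap.

## Known limitations

* **Single-gene sensitivity.** Because Σ|PF| is normalized by the mean
  |ΔE| of the chain's DE genes, one chance gene with a large χ² and a
  small fold change near a chain entry can dominate a long chain's
  score: a lone DE gene at the entry of an L-chain scores L·χ²,
  whereas a uniformly activated chain scores about χ̄²·(L+1)/2. Longer
  chains are therefore *more* exposed to single-gene flukes; ranks
  within a length stratum remain comparable, but cross-length
  comparisons should lean on the empirical p, not the raw impact
  factor.
* The impact factor is direction-agnostic (absolute PF values); net
  direction is carried separately by the terminal PF's sign.
* Condensed loop nodes assume conjunctive activity; merged binding
  nodes assume disjunctive presence — both are modelling choices, and
  expression summaries for multi-gene nodes (strongest member for
  bindings, means for loops) are heuristics the data do not identify.
* Enumeration is exponential in the worst case; the caps truncate
  deterministically but truncation on very dense pathways is silent
  apart from a logged warning.
* With 10 permutations the add-one p-value cannot fall below 1/11;
  permutation counts of 100+ are recommended whenever α = 0.05
  matters.
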
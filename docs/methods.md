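# Methods

This note documents the models, defaults and numerical choices behind
`brixomics`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The measurement model

All expression values are RMA-style log2 measures. The synthetic
generator draws, per gene, a baseline level ~ N(8, 1.5²) and adds an
archetype profile over the (°Brix, tissue) grid plus i.i.d. Gaussian
replicate noise (default SD 0.25 log2 units), clipping to [0, 16]. Values
are generated directly on the log2 scale: the package's entry point is
the gene-level matrix, so probe-level intensity simulation is deliberately
out of scope (quantile normalization and median-polish summarization are
provided as standalone operations for probe-level tables).

The archetype library encodes the cluster morphologies typical of
late-ripening berry data: monotone decrease/increase across °Brix (equal
in both tissues), a skin peak at the second °Brix level, its mirrored
valley, a constant skin offset, and flat (null) genes. Tissue-biased
shapes (peak, valley) carry a 0.3× damped copy of their pattern in the
pulp rather than an exact zero: transcripts peaking in one tissue are
rarely silent in the other, and exact-zero halves would make the shapes'
rank structure noise-driven and unlearnable under a rank-based distance.
Each gene's true factorial effect indicators (°Brix / tissue /
interaction) are derived numerically from its noise-free profile, so the
ground truth is by construction consistent with what the ANOVA can see.

Default design: 4 °Brix levels (22.6, 23.2, 25.0, 36.7), two tissues
(skin, pulp), 6 biological replicates, 29,549 features — 1,418,352 values.
One global seed drives named sub-streams (expression, outliers, GO,
probes, quantification), so runs are bit-reproducible end to end while
the generators stay statistically independent.

## Replicate-set quality control

Each gene × condition sextuplet is summarized by CV = s/x̄ (sample SD,
n−1 denominator) on the log2 scale as analysed. Sets with CV > 0.5
(strict) are scrutinized: values with |x − x̄| > 1.35·s — flags computed
once, on the full-set statistics, with no iterative re-flagging — are
removed (one or two), three or more flags exclude the set, and a set
whose survivor CV still exceeds 0.85 (recomputed on survivors) is
excluded. Ties at a threshold are not flagged ("more than" is strict
throughout). Removed values become explicit NaN missingness, never
imputed. Sets whose mean is ≤ 0 (all replicates clipped at the detection
floor) have no defined CV and are left unscreened. The QC report carries
a conservation identity — retained + individually removed + 6 × excluded
sets = total — that is asserted on every pipeline run.

**A structural property worth knowing.** Displacing one value by d
within-set SDs multiplies the set's CV by ≈ √(1 + d²/6), i.e. 1.58× at
d = 3. A moderate outlier therefore opens the CV > 0.5 gate only in sets
whose CV was already ≳ 0.32 — in practice, low-expressed genes with large
relative displacements (the regime the filter was designed for: e.g.
[1,1,1,1,1,10] is screened; the same z-score pattern around a mean of 8
is not). On a clipped [0,16] log2 scale a single outlier from a mid-range
baseline can never lift the CV past 0.5 (the supremum is ≈ 0.49).
Consequently, recovery experiments that plant SD-relative outliers
uniformly across a low-CV matrix measure this gate, not the flagging
rule: sensitivity is near zero while false removals are also near zero.
The test suite records this honestly (one end-to-end recovery bound is
expected to fail by this arithmetic) and validates the flagging mechanics
separately in the filter's operative regime.

## Two-way ANOVA and FDR

Complete genes are fit with the classical balanced decomposition,
vectorized over the whole matrix (SS for each effect from marginal and
cell means; F = MS_effect/MS_error; p from the F upper tail). Genes left
unbalanced by QC fall back to a per-gene Type II fit via OLS model
comparisons (each main effect against the additive model, the interaction
against the additive model, full-model MSE as the error term), which
reduces exactly to the classical answer when balanced and is invariant to
factor coding. Genes with an entirely excluded condition cell lose the
interaction test but keep marginal tests from the additive model (status
`no_interaction`); genes with zero total variance are `dropped_degenerate`
and carry no p-values. A zero effect SS over zero error variance reports
F = 0; a positive SS over zero error variance reports an infinite F with
the p-value at the smallest positive double rather than 0.

BH adjustment is applied separately within each effect column across
genes (three independent step-up corrections), mirroring the three
adjusted columns of the supplementary-table layout; NaN p-values pass
through unadjusted. °Brix is treated as a 4-level categorical factor, not
a trend — the design question is "does abundance differ across stages",
not "is it linear in sugar". Under the global null the raw p-values are
uniform and the fraction of BH-significant genes stays below the nominal
level; both are asserted by simulation in the test suite.

## Clustering

Genes are clustered on their 8 condition means (replicate averaging
first), using d = 1 − ρ_Spearman with average ranks for ties. k-means
uses Lloyd's alternation: rank-based assignment, arithmetic-mean
centroids in log2 space (the MeV-style convention; a deliberate
approximation under a non-Euclidean metric), at most 50 iterations.
Because mean centroids are not the metric's minimizers, an update can
occasionally raise the objective; the iteration then reverts to the last
improving state and stops, keeping the recorded objective trace
non-increasing. Initialization is greedy D²-weighted sampling from the
seeded stream with 5 restarts, keeping the lowest-objective model —
plain uniform seeding covers c well-separated groups with probability
only c!/cᶜ (≈ 4% at c = 5) and Lloyd cannot escape the resulting merges,
so recovery of planted structure would be a coin flip otherwise.
An emptied cluster is re-seeded from the point farthest from its current
centroid.

The Figure of Merit leaves one condition out, clusters on the rest, and
scores the root mean squared deviation of the held-out value from its
cluster's held-out mean, adjusted by √(n/(n−k)) and summed over
conditions. Profiles are mean-centred per gene first: the rank-based
clustering groups shapes irrespective of overall level, so the merit must
score shape prediction — uncentred, the curve is dominated by baseline
spread and flat in k. The advisory k is the elbow defined as the k
reached by the steepest relative drop (guarded by a 10% floor); a
first-drop-below-threshold rule proved fragile against plateau noise
before the true cliff. The suggestion is advisory by design: with only
7 retained conditions the rank geometry is coarse, step-shaped profiles
(constant within a tissue) have high rank entropy, and the leave-one-out
objective can genuinely prefer splitting them — the final cluster count
remains a judgement call, which is also why k defaults to the
study-style 10 in the pipeline rather than to the FOM suggestion.

Hierarchical clustering is average-linkage agglomeration on the same
distance, cut to the requested group count, with a Newick rendering of
the dendrogram.

## Enrichment

The reference universe defaults to the annotated genes (genes with no GO
term are excluded from N; configurable to the whole array). Only terms
observed in the query set (k ≥ 1) enter the BH family, per enrichment-tool
convention; the choice is recorded in the output metadata. Annotation
propagation to ancestors (true-path closure over an acyclic child→parent
edge list) is optional and off by default. The hypergeometric upper tail
comes from the survival function of the standard library distribution,
exact against enumeration over the full small-N grid.

Power arithmetic worth noting: with a 500-gene set in a 20,000-gene
universe, a 5×-enriched term of size 50 draws only ≈ 6 set genes against
an expectation of 1.25 — top-ranked, but only marginally significant
after BH across a 50-term family. Reliable adj-p < 0.05 recovery at 5×
enrichment needs term sizes ≳ 100 at this geometry, and the tests are
calibrated accordingly.

## Probe cross-hybridization

Alignment is consumed, not computed: hits arrive as a standard 12-column
tabular file and duplexes are reconstructed from coordinates against the
probe and target FASTA. Retention requires identity > 80% AND coverage
(aligned probe fraction) > 80%, strictly. Melting temperatures use the
unified nearest-neighbor DNA/DNA parameter set with duplex initiation
terms, entropic salt correction ΔS' = ΔS + 0.368(N−1)ln[Na⁺], and
Tm = ΔH·1000/(ΔS' + R ln(C_T/x)) − 273.15; defaults Na⁺ 50 mM, total
strand concentration 10⁻⁷ M, x = 4. Stacks containing a mismatched or
gapped position contribute nothing by default (a conservative Tm
lowering); a mismatch parameter table can be plugged in. The
cross-hybridization threshold is scoped per gene: a hit is called when
its duplex Tm strictly exceeds the minimum perfect-match Tm of that
gene's own probe set minus 10 °C, and a gene is flagged once regardless
of how many of its probes cross-hybridize. A hit whose gene has no
perfect-match Tm raises an error rather than being silently skipped.

## Metabolite quantification

Standard addition reads the fitted line ratio = a + b·spike at its
x-intercept: the supernatant concentration is a/b (the "y-intercept equal
to zero" phrasing of the method is interpreted as the standard x-intercept
convention). The estimate is invariant to rescaling all ratios and shifts
oppositely under spike shifts — both asserted as properties. Dilution
correction multiplies by (m/ρ + V)/(m/ρ): 46/36 for the default 36 g
sample, 10 mL addition, ρ = 1 g/mL; the factor is parameterized, never
hard-coded. External calibration averages replicate ratios per level
before the OLS fit and predicts unknowns by inversion. The Fisher-Z
interval is tanh(atanh r ± z*/√(n−3)), degenerating to a point at
|r| = 1 (detected with a 10⁻¹² tolerance against floating-point
correlation of exact lines); its ~95% coverage at n = 6 is verified by
simulation.

## Pipeline determinism and problem sizes

All artifacts are plain TSV/JSON; no binary state. Timestamps and
elapsed times go to the log stream only, never into artifacts, so a rerun
with the same config and seed is byte-identical (asserted in the tests).
The simulation-driven test suite uses 20,000 genes for the QC and
end-to-end checks, 2,000 genes × 50 seeds for null calibration, 1,000
genes × 25 seeds for cluster recovery, 500 seeds for standard-addition
error and 2,000 simulations for CI coverage — sizes chosen to make the
Monte-Carlo bounds tight while a full run of the suite stays in the
minutes range on a single CPU.

## What passing tests do and do not show

The generator emulates the study's design geometry, log2 scale, effect
shapes and replicate noise, and plants every kind of signal the pipeline
claims to detect. It does not emulate probe-level intensity artifacts,
spatial array defects, correlated (batch) noise, heteroscedasticity
across the intensity range, realistic sequence composition, or the
long-tailed replicate CV distribution of field-grown material. Passing
recovery tests therefore demonstrate that the algorithms are implemented
correctly and calibrated under their stated assumptions — not that those
assumptions hold for any particular real dataset. Reported category
counts and significance totals from the original study additionally
depend on its specific array annotation snapshot and cannot be reproduced
from synthetic data; the package reproduces the procedures, not those
numbers.
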
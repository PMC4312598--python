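# brixomics

Analysis toolkit for late-stage grape berry ripening transcriptomics: a
gene × sample log2 expression matrix measured on a 4 °Brix × 2 tissue
(skin/pulp) × 6 biological replicate factorial design is quality-filtered,
tested gene by gene for differential expression, clustered by profile
shape, screened for Gene Ontology overrepresentation and probe
cross-hybridization, and tied to metabolite concentrations measured by
standard addition. Every stage is also exercisable end to end on synthetic
data that emulates the study design (≈29,549 array features, 8 conditions
× 6 replicates, 4-probe probe sets), so the whole pipeline is testable
without any download.

It is written for researchers analysing factorial microarray (or
microarray-like) expression designs who want the complete, auditable chain
from raw replicate values to enriched categories and metabolite
correlations as plain TSV/JSON artifacts.

## The statistics at the core

**Replicate QC.** For each gene × condition replicate set (a "sextuplet"),
the coefficient of variation CV = s/x̄ (sample SD, n−1) is computed on the
log2 scale. Sets with CV > 0.5 are scrutinized: values with
|x − x̄| > 1.35·s are flagged in a single pass — one flag removes that
value, two remove both, three or more exclude the set — and any set whose
surviving CV still exceeds 0.85 is excluded outright.

**Differential expression.** Per gene, a fixed-effects two-way ANOVA
y = μ + α(°Brix) + β(tissue) + (αβ) + ε, with °Brix a 4-level categorical
factor. Balanced genes use the classical sums-of-squares decomposition
(vectorized across all genes); genes left unbalanced by QC fall back to
Type II sums of squares. Benjamini–Hochberg adjustment is applied per
effect across genes (adjBrix, adjTissue, adjInteraction); "significant"
means adjusted p < 0.05, strictly.

**Clustering.** Condition-mean profiles are grouped by k-means under the
Spearman correlation distance d = 1 − ρ (≤ 50 iterations, seeded
D²-weighted initialization, arithmetic-mean centroids), with the cluster
count advised by a leave-one-condition-out Figure of Merit curve and
average-linkage hierarchical clustering for smaller gene families.

**Enrichment.** One-sided hypergeometric overrepresentation of a gene set
against the annotated array universe, P(X ≥ k) for
X ~ Hypergeom(N, K, n), BH-corrected over the tested terms.

**Probe specificity.** Probe–target alignment hits with > 80% identity and
> 80% coverage are scored by a nearest-neighbor thermodynamic melting
temperature (unified DNA/DNA parameters, entropic salt correction,
Tm = ΔH°/(ΔS° + R ln(C_T/x)) − 273.15); a hit whose duplex Tm exceeds the
minimum perfect-match Tm of the gene's probe set minus 10 °C is a putative
cross-hybridization, and a gene with any such probe is flagged.

**Metabolite quantification.** Standard addition: the analyte/internal-
standard response ratio is regressed on the spiked concentration and the
supernatant concentration is the x-intercept magnitude a/b, then scaled to
the fruit by the homogenate dilution factor (46/36 for 36 g sample + 10 mL
spike at unit density). Transcript–metabolite agreement is a Pearson r
with a Fisher-Z 95% confidence interval tanh(atanh r ± 1.96/√(n−3)).

## Worked example

A full synthetic run from the command line:

```bash
brixomics run-all --seed 42
```

prints (abridged):

```
brixomics 0.1.0 run report (seed 42)

[counts]
  n_genes = 29549
  n_samples = 48
  n_values_retained = 1418352
  n_significant_brix = 19476
  n_significant_tissue = 23868
  n_significant_interaction = 5565
  n_clusters = 10
  n_enriched_terms = 3
  n_crosshyb_flagged_genes = 25

[results]
  clustered_effect = interaction
  cluster_sizes = [255, 72, 1092, 680, 420, 234, 1158, 999, 385, 270]
  planted_terms_recovered = 3
  supernatant_ng_L = 22.8322
  fruit_ng_L = 29.1745
  standard_addition_r2 = 0.998888
  transcript_metabolite_r = 0.986
```

Reading the numbers: of the 29,549 simulated features over 48 samples
(1,418,352 values), 19,476 change significantly with ripeness (°Brix),
23,868 differ between skin and pulp and 5,565 show a °Brix × tissue
interaction at BH-adjusted p < 0.05; the interaction genes split into 10
profile clusters; all 3 planted GO terms are recovered as overrepresented;
the standard-addition fit estimates 22.8 ng L⁻¹ of the aroma compound in
the homogenate supernatant, i.e. 29.2 ng L⁻¹ in the fruit after the 46/36
dilution correction (true planted value 25 ng L⁻¹); and the
ripening-declining transcript tracks the metabolite at r = 0.986.

Every stage also runs standalone (`brixomics qc`, `anova`, `cluster`,
`cluster-fom`, `enrich`, `crosshyb`, `quantify` — see `--help`), consuming
and producing plain TSV so intermediate results can be audited or swapped
for real data. The same functionality is available as a library:

```python
import brixomics as bx

cfg = bx.SimulationConfig(n_genes=2000, seed=1)
experiment, truth = bx.simulate_expression_experiment(cfg)
filtered, qc_report = bx.apply_replicate_qc(experiment)
anova = bx.fit_two_way_anova(filtered)
significant = bx.call_significant(anova, alpha=0.05)
```

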
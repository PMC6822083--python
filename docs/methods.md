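# Methods

## Problem setting

A single "focus" tumor RNA-seq profile, expressed as gene-level TPM, is
compared against a reference compendium of uniformly processed tumor
profiles to find genes that are *overexpressed* in this tumor relative
to the background — candidates for direct or pathway-level drug
targeting. There is no case/control design and no replication of the
focus sample, so ordinary differential-expression machinery does not
apply; the statistic must be a single-sample outlier criterion relative
to an empirical reference distribution.

## Outlier model

All analysis happens in y = log2(TPM+1). For each gene, the reference
cohort yields quartiles Q1, Q3 by linear interpolation between order
statistics (the "type 7" convention used by `numpy.percentile`); the
focus value x is an outlier when

    x > Q3 + m·(Q3 − Q1)   and   x ≥ f,

with fence multiplier m = 1.5 (the classical boxplot whisker) and
minimum-expression floor f = 2.5 log2(TPM+1) (~4.7 TPM). The floor
exists because the fence of a gene that is silent in the whole cohort
(Q1 = Q3 = 0) is 0, and any stray read would otherwise produce a call;
2.5 sits comfortably above typical noise but well below the expression
of a transcribed driver. Both parameters are exposed (`OutlierParams`).
The quartile convention is fixed deliberately: conventions differ in how
they interpolate, and calls near the fence flip between them. Only
upward outliers are called — underexpression has no therapeutic reading
in this framework. A cohort smaller than `min_cohort_size = 20` is
rejected rather than silently producing unstable quartiles. If the
focus sample's id exists in the reference cohort it is excluded from it,
avoiding self-comparison bias.

Percentile placement (reported alongside every call, and useful for
"highly expressed but under the fence" reasoning) uses midranks:
100·(#strictly below + ½·#ties)/n, so a value equal to a constant cohort
sits at the 50th percentile. Midranks make the percentile invariant
under any strictly monotone transform applied jointly to the focus value
and cohort.

## The two reference tracks

*Pan-cancer* compares against the entire compendium restricted to a
filtered gene universe; *pan-disease* compares against the most similar
tumors on the unfiltered universe, so that genes expressed only in
particular tumor types are not lost. Filtered-universe membership is an
explicit per-gene annotation flag rather than a recomputed property: the
filtering recipe behind such universes is typically pipeline-specific,
and carrying the flag keeps the choice auditable and swappable.

Pan-disease cohort selection ("which tumors are most similar?") is done
by Spearman correlation between the focus sample and every compendium
sample over the `n_variable_genes = 1000` genes with the highest
variance of y across the compendium, taking the top k = 100 with
correlation ties broken lexicographically by sample id. Rank correlation
on high-variance genes is the standard, scale-robust similarity for
expression profiles; variable-gene selection keeps the measure driven by
biology rather than by the bulk of invariant housekeeping genes.
Constant samples (zero rank variance) get correlation 0 rather than NaN.

Three lists move forward: pan-cancer outliers, pan-disease outliers, and
their intersection, each analyzed separately for actionability and
gene-set overlap.

## Actionability and drug annotation

The curated actionable table partitions 92 genes into 37 "direct"
(protein product inhibitable by an available therapy) and 55 "indirect"
(acting in a targetable pathway), each with a pathway group (RTK,
PI3K-AKT-mTOR, JAK-STAT, RAS-RAF-MEK, SHH, BCR, cell-cycle, HSP,
BCL2-MDM2). The shipped table is a *synthetic stand-in* with that exact
structure, built from well-known cancer genes; it is data, not code, so
a real curated table drops in verbatim. Symbol matching is exact after
uppercasing — alias resolution belongs in the data file. Drug
annotation is an offline join against a local table restricted to four
curated cancer sources; a finding with no drug rows remains a finding,
since no local table is exhaustive.

## Gene-set overlap

Each list is tested against every set of a GMT collection with the
one-sided hypergeometric upper tail P(X ≥ k) (Fisher's exact
enrichment), where the universe is the active gene universe of the
originating track (filtered for the pan-cancer and intersection lists,
unfiltered for pan-disease). Enrichment p-values are universe-sensitive,
so the universe size is recorded in every result row, and query genes or
set members outside a known universe are clipped before testing. BH
adjustment runs across the whole collection; results with q < 0.05 are
sorted by (q, p, set name) — a total, platform-independent order — and
truncated to the first 100. The per-sample pathway summary flags, for
each pathway group, whether an actionable gene of the group is an
outlier and whether any gene set mapped to the group (a small mapping
table) is enriched; the conjunction is the "gene and pathway
overexpressed in concert" criterion.

## DNA–RNA concordance

Samples with DNA mutation findings are classified by two booleans —
any treatment-arm-actionable DNA finding; any actionable RNA outlier —
into the 2×2 partition both / DNA-only / RNA-only / neither, then
assigned a utility mode:

* **support** — one actionable DNA gene, corroborated at gene level
  (the mutated gene is itself an outlier) or downstream (its expected
  downstream pathway groups intersect the enriched groups);
* **prioritize** — two or more actionable DNA genes, at least one
  corroborated, so expression ranks them;
* **deprioritize** — a DNA finding whose mutant allele is absent from
  the RNA (an upstream allele-counting input; *unknown* is treated as
  expressed, so nothing is deprioritized without evidence) and that has
  no downstream support;
* **rna_only** — actionable expression findings with no actionable DNA
  finding (this mode and the RNA-only cell coincide by construction);
* **none** — anything else.

The gene → downstream-pathway links are an editable curated table; a
gene with no row contributes no downstream support, which is the
conservative treatment of ambiguous biology. Cohort summaries report
exact counts and percentages rounded half-up to one decimal — the
convention used in clinical reporting — and the four cells are
exhaustive and disjoint by construction.

## Synthetic data

The generator emulates the reference compendium and patient tumors, not
any particular cohort's noise. Expression is log-normal in y: gene g in
disease d has mean μ_g,d = μ0 + δ_g,d with δ_g,d ~ N(0, σ_d²) drawn once
per (disease, gene) at compendium creation and stored, and observations
add N(0, σ²) noise; TPM = max(2^y − 1, 0). Defaults, chosen once as the
package's study conditions: 2,000 genes × 500 tumors × 5 diseases
(a desk-scale stand-in for a ~58k-gene, ~11k-tumor compendium), μ0 = 3.0,
σ = 0.8, σ_d = 1.0 — within-disease log2 dispersion near one and
between-disease separation of comparable size, typical of bulk tumor
panels — and a pediatric (age < 30) fraction of 0.164, with ages uniform on [0, 30) or
[30, 80) since only the under-30 fraction feeds any statistic (0.164 is
the pediatric/young-adult share of the compendium this emulates). Storing
the disease means makes later focus samples exchangeable with compendium
members of the same disease; for compendia read from disk, means and
noise are estimated from the data instead. Focus samples record their
spiked (gene, effect) ground truth next to the data.

Under these conditions the Tukey fence on a 500-tumor homogeneous cohort
sits ≈ 2.7σ above the gene mean, giving a per-gene null call rate of a
few tenths of a percent and near-ceiling sensitivity for +4 log2 spikes
— the operating point the acceptance experiments measure rather than
assume.

DNA-finding scenarios construct samples whose concordance cell is known:
`both`/`dna_only`/`rna_only`/`neither` fix the cell, and `mixed`
allocates cells in the exact proportions 28:6:27:13 by largest-remainder
apportionment followed by a seeded shuffle. The deterministic allocation
(rather than a multinomial draw) was chosen so the scenario's cell
composition is a property of the construction, not of a particular
seed; the per-sample assignment remains exchangeable. On-disk DNA
fixtures include a non-actionable passenger row for samples with no
actionable finding, so "DNA data available, nothing found" is
representable in files.

What the generator does **not** model: isoforms, fusions at sequence
level, batch and library-size effects, gene–gene correlation, and
heavy-tailed biological outliers in the reference itself. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under a clean log-normal world, not the false-positive behavior on real
compendia, where fences are wider and similarity structure is noisier.

## QC

Sample QC is a configurable rule rather than a fixed recipe: by default
a sample must have ≥ 10,000 genes with TPM > 0 (a library-complexity
proxy), with an optional floor on the per-sample sum of y. The rule used
is echoed into every report. Real QC for degraded or shallow libraries
involves read-level metrics outside this package's inputs.

## Numerical and engineering choices

* Quartiles: `numpy.percentile` linear interpolation; validated against
  an independent sort-and-interpolate oracle to 1e-9.
* Hypergeometric tail: `scipy.stats.hypergeom.sf`; validated against
  exhaustive subset enumeration for all margins with universe ≤ 12.
* BH: `statsmodels.multipletests(fdr_bh)`; validated against the literal
  step-up recursion.
* Percentages: decimal arithmetic, rounding half-up at one decimal.
* Determinism: every generator is a pure function of (config, seed) via
  `numpy.random.default_rng`; pipeline outputs use sorted orders, fixed
  float formatting and sorted JSON keys, so reruns are byte-identical.
  Provenance records the full configuration and its SHA-256, not
  wall-clock time, to keep reports reproducible.
* Degenerate inputs: empty cohorts, empty collections, all-zero samples
  and undersized cohorts raise typed errors or return empty results as
  documented per operation; partial outputs are never written silently.

## Limitations

The outlier fence and the cohort-selection mechanism are documented
stand-ins for protocol-specific choices that vary between deployments
(fence multiplier, floor, similarity metric, k); all are exposed as
parameters and echoed in provenance. The actionable, drug and
downstream tables shipped here are synthetic scaffolds for testing, not
clinical curation. The concordance rules implement the algorithmic part
of what is, in practice, partly expert literature review; judgments that
depend on unmapped pathway biology fall back to "no support".
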
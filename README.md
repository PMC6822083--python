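# panoutlier

Compendium-based gene expression outlier analysis for single tumor
RNA-seq samples, with actionability annotation, gene-set overlap analysis
and DNA–RNA concordance classification.

Many difficult-to-treat pediatric and young adult cancers carry no
actionable DNA aberration, but aberrant *expression* of a druggable gene
can still nominate a therapy. `panoutlier` implements the comparative
framework used for this purpose: a single focus tumor's TPM profile is
compared against a large reference compendium of uniformly processed
tumor profiles, overexpression outliers are intersected with a curated
actionable-gene list and with pathway gene sets, and (when DNA mutation
results exist) the sample is classified by the joint DNA/RNA
actionability picture. It is aimed at computational biologists building
or evaluating expression-based precision-oncology analyses; everything
runs offline on plain-text inputs, and a synthetic-data module generates
complete workspaces with known ground truth.

## The statistics at the core

* **Outlier fence.** For each gene, expression is transformed to
  log2(TPM+1) and the focus value x is called an (up) outlier when

      x > Q3 + 1.5 · IQR   and   x ≥ 2.5,

  where Q1/Q3 are the reference cohort's quartiles (linear interpolation
  between order statistics, "type 7"), IQR = Q3 − Q1 is the
  interquartile range, and 2.5 log2(TPM+1) is a minimum-expression floor
  that suppresses calls among unexpressed genes. Percentile placement
  uses the midrank convention: 100 · (#below + ½·#ties) / n.
* **Two reference tracks.** *Pan-cancer*: the whole compendium, on a
  filtered gene universe. *Pan-disease*: the k = 100 compendium tumors
  most similar to the focus sample — Spearman correlation over the 1,000
  most variable genes — on the unfiltered universe. Three gene lists are
  carried forward: pan-cancer, pan-disease, and their intersection.
* **Actionability.** Lists are intersected with a curated table of 92
  actionable genes (37 directly targetable, 55 targetable through their
  pathway) and hits are annotated from a local drug–gene interaction
  table restricted to four curated cancer sources.
* **Gene-set overlap.** Each list is tested against a GMT collection
  with the one-sided hypergeometric tail P(X ≥ k), Benjamini–Hochberg
  FDR across the collection, reporting the first 100 sets with q < 0.05.
* **DNA–RNA concordance.** Samples with DNA findings are placed in the
  2×2 partition (both / DNA-only / RNA-only / neither) and assigned a
  utility mode (support / prioritize / deprioritize / RNA-only / none)
  based on whether mutated genes are themselves outliers or their
  downstream pathways are enriched.

## Worked example

```python
from panoutlier import (
    SimulationConfig, generate_compendium, generate_focus_sample,
    OutlierParams, call_outliers, select_pan_disease_cohort, combine_lists,
    intersect_actionable, annotate_drugs, restrict_gene_universe,
    ExpressionCompendium,
)
from panoutlier.simulate import default_actionable_table, default_drug_table

config = SimulationConfig(n_genes=1000, n_samples=400, n_diseases=4, seed=42)
compendium = generate_compendium(config)
tumor = generate_focus_sample(compendium, "D01", spikes=[("FLT3", 4.0)], seed=7)

pan_cancer = call_outliers(tumor, restrict_gene_universe(compendium, "filtered"),
                           OutlierParams(), track="pan_cancer")
cohort = select_pan_disease_cohort(tumor, compendium, k=100, n_variable_genes=500)
slice_ = ExpressionCompendium(
    tpm=compendium.tpm[list(cohort.member_ids)],
    genes=compendium.genes,
    metadata=compendium.metadata.loc[list(cohort.member_ids)],
)
pan_disease = call_outliers(tumor, slice_, OutlierParams(), track="pan_disease")

symbols = {g: s.upper() for g, s in compendium.genes["symbol"].items()}
lists = combine_lists(pan_cancer, pan_disease, symbols)
findings = annotate_drugs(
    intersect_actionable(lists, default_actionable_table(), tumor.sample_id),
    default_drug_table(),
)

print("cohort composition:", cohort.disease_composition)
print("outliers (pan-cancer / pan-disease / both):",
      len(lists.pan_cancer), len(lists.pan_disease), len(lists.intersection))
flt3 = pan_cancer[pan_cancer.gene_id == "G00000"].iloc[0]
print(f"FLT3: log2(TPM+1)={flt3.sample_log_value:.2f} fence={flt3.threshold:.2f} "
      f"percentile={flt3.percentile:.1f} outlier={flt3.is_outlier}")
for f in findings:
    print(f.symbol, f.klass, f.pathway_group, sorted(f.tracks),
          [d for d, _ in f.drugs])
```

Output:

```
cohort composition: {'D01': 100}
outliers (pan-cancer / pan-disease / both): 1 3 1
FLT3: log2(TPM+1)=5.96 fence=5.83 percentile=99.5 outlier=True
FLT3 direct RTK ['pan_cancer', 'pan_disease'] ['midostaurin', 'sorafenib']
```

The simulated tumor carries a +4 log2 spike on FLT3; all 100 members of
the selected pan-disease cohort share the tumor's disease label; FLT3
exceeds its pan-cancer fence (5.96 > 5.83, 99.5th percentile), survives
the actionable-gene intersection as a directly targetable receptor
tyrosine kinase, and picks up its two curated drug rows.

The same analysis is available from a shell:

```sh
panoutlier make-fixtures workspace --seed 5      # synthetic workspace + config.yaml
panoutlier qc --config workspace/config.yaml
panoutlier run-cohort --config workspace/config.yaml
```

`run-cohort` writes per-sample outlier/enrichment/concordance tables, a
cohort summary JSON, a recurrence table of actionable outliers by
disease, and a provenance block echoing every effective parameter. Runs
are byte-for-byte reproducible.

## Layout

- `panoutlier.simulate` — synthetic compendia, focus tumors, DNA
  findings, full fixture workspaces (ground truth always included).
- `panoutlier.io` — TSV/GMT readers and writers, sample QC, gene-universe
  restriction.
- `panoutlier.outliers` — fence, percentile, pan-disease cohort
  selection, list combination.
- `panoutlier.druggability` / `panoutlier.enrichment` /
  `panoutlier.concordance` — actionability, gene-set overlap, DNA–RNA
  classification.
- `panoutlier.pipeline` / `panoutlier.cli` — orchestration, reports,
  command-line interface.
- `docs/methods.md` — models, parameter choices, and limitations.

The packaged actionable-gene, drug–gene and downstream-pathway tables
are synthetic stand-ins (see their `*_synthetic.tsv` names); drop in your
own curated TSVs with the same columns to analyze real data.
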
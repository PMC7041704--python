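# matchloci

Tools for asking whether a transcriptional response program is enriched for
GWAS risk loci, built around the analysis of IL-10 signalling in human
macrophages.  IL-10-receptor-deficient macrophages fail to restrain their
LPS response, and inflammatory-bowel-disease (IBD) risk loci concentrate
among the genes IL-10 normally represses.  `matchloci` implements that
analysis as a reusable, fully tested pipeline:

1. **Category classification** — from per-contrast differential-expression
   summaries (wild-type vs receptor-mutant genotypes under LPS, IL-10, and
   combined stimulation), genes are classified by explicit set algebra into
   non-exclusive categories: LPS-induced/-suppressed in both genotypes,
   IL-10-repressed, IL-10-rescued, IL-10-alone, and their union
   (IL-10-regulated).  A call requires FDR < 0.05 and linear fold change > 2.
2. **Matched-null locus enrichment** — for a query gene list *G* and a locus
   catalog, the observed statistic is the number of loci containing at least
   one gene of *G*.  Its null distribution comes from *B* = 10,000 resampled
   gene sets in which each query gene is replaced by a gene within ±5
   percentile points on **both** mean expression and gene length, excluding
   the query genes and previously drawn null genes.  Fold enrichment is
   `observed / mean(null)`; the one-tailed empirical P is
   `#{null ≥ observed} / B`.
3. **Overlap and subnetwork** — exact gene-list intersections, and
   first-neighbor expansion of seed genes over a user-supplied interaction
   edge list filtered to genes deregulated by IL-10 during the LPS response.
4. **Synthetic data** — a generator that emulates the study conditions with
   planted category labels and a configurable planted locus enrichment, so
   every stage can be validated against known ground truth.

## Worked example

```sh
matchloci run --simulate --seed 7 --out demo/
cat demo/fractions.json demo/enrichment_il10_repressed.json
```

generates a 10,000-gene dataset, classifies it, and tests the
IL-10-repressed list for locus enrichment.  Output (abridged):

```
"counts": { "lps_up_shared": 1050, "lps_down_shared": 950,
            "il10_repressed": 304, "il10_rescued": 76, ... },
"repressed_fraction": 0.2895,
"rescued_fraction": 0.08,

{ "observed_overlap": 12, "null_mean": 10.9078,
  "enrichment_ratio": 1.1001, "empirical_p": 0.4031,
  "p_display": "0.4031", "n_widened": 0, "n_null": 10000 }
```

Reading: 1,050 genes are LPS-induced in both genotypes and IL-10 represses
28.95% of them; the repressed list hits 12 of 165 loci against a matched
null expectation of 10.9 — a 1.10-fold enrichment with P = 0.40, i.e. no
enrichment, as expected since this simulation planted none
(`planted_fold: 1.0`).  Planting a 3-fold enrichment
(`matchloci simulate --config sim.yaml ...` with `planted_fold: 3.0`) makes
the same pipeline report a ratio near 3 with P below 1/B, displayed as
`"< 0.0001"`.

Every stage is also exposed individually (`matchloci simulate / classify /
enrich / overlap / subnet`) over plain TSV/YAML/JSON files; see
`matchloci <cmd> --help` for the file formats, and the module docstrings for
the library API.

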
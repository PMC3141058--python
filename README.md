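# mirconcord

Integrated miRNA–mRNA concordance analysis for two-group expression studies.

## The problem

miRNAs are expected to repress their target mRNAs, so when a miRNA goes up
between two conditions its predicted targets should go down. In practice —
for example comparing laser-captured ovarian cancer epithelial cells (CEPI)
against normal ovarian surface epithelium (OSE) — only a small minority of
predicted targets behave that way. `mirconcord` implements the analysis that
quantifies this: it classifies every (miRNA, predicted target) pair as

* **IC** (inversely correlated): the target passes differential-expression
  thresholds and moves *opposite* to its regulating miRNA,
* **PC** (positively correlated): it passes and moves *with* the miRNA,
* **NC** (no change): it fails the thresholds,

and aggregates the class fractions per miRNA, per study arm, and across
target-prediction algorithms. It is aimed at computational biologists who
want to reproduce or extend this style of concordance analysis with full
control over every filter and threshold.

## What is in the box

| Piece | What it does |
|---|---|
| `expression_io` | log2 expression matrices with Present/Marginal/Absent calls; Absent-in-all-samples and sd < 0.5 filters; per-probe z-scoring; complete-linkage clustering on 1 − Pearson correlation |
| `diffexpr` | pooled-variance two-sample t-tests; named threshold presets (tissue mRNA: p < 0.005 and \|Δlog2\| ≥ 1; tissue miRNA: p < 0.01 and \|Δlog2\| ≥ 1; transfection: SAM q ≤ 5 %, \|Δlog2\| ≥ 0.5, P/M call in ≥ 1 sample); SAM-style permutation FDR; hypergeometric target enrichment with BH correction |
| `target_maps` | parsers for miRanda (with the mirSVR < −0.1 "good score" filter), TargetScan (family expansion) and PicTar dialects; gene-symbol-level intersection; projection onto probesets via annotation tables |
| `concordance` | the IC/NC/PC classifier, fraction summaries, cross-algorithm averages, experimentally-validated-target derivation and cross-tabulation, recovery scoring against planted truth |
| `qpcr_rest` | ΔΔCt relative quantification against a reference gene and a fixed-reallocation randomization test (exhaustive or Monte-Carlo) |
| `synthetic_data` | generators for prediction maps, planted IC/PC/NC regulation, tissue and transfection expression matrices, and qPCR Ct tables — every downstream stage is testable against known ground truth |
| `pipeline` / `cli` | YAML-configured end-to-end runs writing a report bundle; `mirconcord` console entry point with `simulate`, `de`, `targets`, `qpcr`, `enrich`, `run` subcommands |

The aggregation rule throughout is *mean of group means*: per-miRNA
percentages are averaged (unweighted) within the up-regulated and
down-regulated miRNA groups, and the overall row is the mean of those two
group means. The same unweighted-mean rule combines prediction algorithms
and validation methods, so every summary row is recomputable from the rows
above it.

## Worked example

Simulate a study with planted regulation (11 % IC, 10 % PC, a 2-log2 effect,
noise sd 0.5, 3 cases vs 3 controls) and run the full pipeline:

```python
from mirconcord import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/demo",
    simulation=SimulationConfig(targets_per_mirna=(200, 300), seed=1),
    seed=1,
)
result = run_pipeline(cfg)
o = result["summaries"]["M"].overall
print({k: round(v, 2) for k, v in o.items()})
print({k: round(v * 100, 2) for k, v in result["recovery"]["fraction_abs_error"].items()})
```

prints

```
{'IC': 11.52, 'NC': 78.72, 'PC': 9.75}
{'IC': 0.65, 'NC': 1.21, 'PC': 0.56}
```

i.e. the pipeline estimates 11.52 % of pairs inversely correlated against a
planted ~11 %, with pooled per-class fraction errors around a point. (Single
seeds scatter around the planted value; averaged over 20 seeds the estimate
sits a couple of points below 11 % — the finite power of a 3 + 3 t-test at
p < 0.005.) In the
noise-free limit (`noise_sd=0`) recovery is exact. The bundle written to
`out_dir` contains per-source fraction tables with aggregate rows, the full
per-pair concordance records, DE tables, an enrichment table, and a
`manifest.yaml` with seeds, thresholds and per-stage counts; identical
config + seed reproduces it byte for byte.

The same machinery reproduces published summary rows from their per-miRNA
inputs, e.g.:

```python
from mirconcord import reference_data as ref
from mirconcord.concordance import FractionSummary

s = FractionSummary.from_per_mirna(ref.tissue_frame(ref.TISSUE_MIRANDA_ROWS))
print(round(s.overall["IC"], 2), round(s.overall["NC"], 2))   # 11.16 78.56
```

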
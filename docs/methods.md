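# Methods

## Model and procedure

`mirconcord` analyzes a two-group design (case vs control; in the motivating
setting, laser-captured ovarian cancer epithelium vs normal surface
epithelium) profiled for both miRNAs and mRNAs on log2-scale arrays with
Present/Marginal/Absent (P/M/A) detection calls. The analysis graph is:

1. **Filtering.** Probes whose detection call is Absent in *every* sample
   are removed before any statistics. (The rule is stated per-sample, not
   per-group: that is the form restated in every summary-table legend of the
   motivating analysis.) For clustering only, probes with across-sample
   standard deviation below 0.5 are additionally dropped and rows are
   z-scored; statistical tests always run on the unstandardized log2 values.
2. **Differential expression.** Per probe, an equal-variance two-sample
   t-test on log2 values; the effect statistic is the log2 group-mean
   difference ("log2 difference"; a fold change of 2 corresponds to 1.0).
   Presets: tissue mRNA p < 0.005 and |Δlog2| ≥ 1; tissue miRNA p < 0.01 and
   |Δlog2| ≥ 1; transfection SAM q ≤ 5 %, |Δlog2| ≥ 0.5 (fold change 1.4)
   and a P/M call in at least one sample. All thresholds on |Δlog2| are
   inclusive (≥); p/q ceilings are strict/inclusive as written.
3. **Target maps.** Predictions are parsed from three dialects (miRanda
   with mirSVR scores, TargetScan families, PicTar). "Good" mirSVR means
   strictly below −0.1. Maps intersect at the gene-symbol level — the
   sources share symbols, not probesets — and are then projected to
   probesets through an annotation table, one record per annotated probeset
   (probe-level bookkeeping is the default counting unit; target totals are
   therefore probeset counts).
4. **Concordance.** Each (miRNA, probeset) pair with a DE-flagged miRNA is
   classified NC if the target fails the mRNA thresholds, IC if it passes
   and moves opposite to the miRNA, PC if it passes and moves with it. The
   class is a pure function of the flag and the two directions, so flipping
   every miRNA direction swaps IC and PC counts exactly.
5. **Aggregation.** Per miRNA: percentages out of that miRNA's surviving
   targets, reported half-away-from-zero to 2 decimals. Group rows: the
   *unweighted* mean of per-miRNA percentages within the up- and
   down-regulated miRNA groups. Overall row: the mean of the two group
   means — not the pooled mean over all pairs. The same unweighted-mean
   rule combines prediction algorithms and validation methods. miRNAs with
   zero surviving targets are excluded from group means. Because printed
   per-miRNA inputs are themselves rounded, aggregate reproductions carry a
   ±0.02 tolerance.
6. **Validated targets.** In a mimic-vs-negative-control transfection, a
   predicted target of the transfected miRNA that is flagged *down* under
   the transfection preset is "experimentally validated"; the tissue-level
   IC/NC/PC fractions of those targets are then cross-tabulated per
   prediction method, averaged over methods per miRNA, and overall.
7. **Enrichment.** Upper-tail hypergeometric test of each miRNA's target
   set against the DE set over the tested background (P(X ≥ k) with
   N = |background|, K = |targets ∩ background|, n = |DE|), BH-corrected
   across sets.

## SAM permutation FDR

The transfection contrast uses the Significance Analysis of Microarrays
relative difference d = r/(s + s0), where r is the group-mean difference and
s its standard error. The fudge factor s0 is chosen on the 0, 5, …, 100
percentile grid of s to minimize the coefficient of variation of the
windowed median absolute deviation of d across s-quantile windows. Label
permutations (exhaustive enumeration whenever the number of distinct
assignments is at most `n_perm`, which always holds for 3 + 3 designs) give
the null; for each probe the false-positive count is the median over
permutations of the number of permuted |d*| at or above its |d|, and
q = π0 · median count / #called, with π0 estimated from the fraction of
observed d inside the permutation interquartile range, made monotone in |d|
and clipped to [0, 1]. Two-sided statistics are used throughout the package;
both directions of regulation are of interest.

## qPCR quantification

Technical replicates are averaged to one Ct per (sample, gene); per sample
ΔCt = Ct(target) − Ct(reference); ΔΔCt = mean ΔCt(case) − mean ΔCt(control);
ratio = E^(−ΔΔCt) with E the amplification factor per cycle (default 2.0 —
note some instruments report efficiency as E−1, i.e. "~1" for perfect
doubling). Significance comes from fixed-reallocation randomization:
group labels are reassigned at fixed group sizes over biological samples
(technical replicates having been averaged first), the ratio recomputed, and
the two-sided p is the fraction of allocations with |log ratio| at or above
the observed one; exhaustive enumeration replaces sampling when there are at
most `n_rand` distinct allocations, and in Monte-Carlo mode the observed
allocation is counted so p ≥ 1/(n_rand + 1).

## Synthetic data: what it emulates and what it does not

The generators plant a known regulatory structure: each predicted (miRNA,
gene) pair is independently IC (default probability 0.11), PC (0.10) or NC;
each miRNA gets a direction; case-group log2 intensities receive ±effect
(default 2.0) for miRNAs, and targets receive the *sum* of their planted
pair effects (IC opposite the miRNA, PC with it). Measurements add Gaussian
noise (default sd 0.5 per measurement) on top of per-probe baselines
(mean 8, sd 2 — chosen as a typical log2 intensity spread so the Absent-call
rank rule and the sd filter have realistic behavior). Absent calls go to the
lowest-intensity 5 % of cells by global rank rather than via a
signal-vs-background rank test — only the filter's set behavior matters
downstream. Two "algorithm variant" maps share a configurable fraction
(default 0.6) of the base map's pairs. All generators draw from per-operation
streams derived from the config seed, so regenerating one artifact never
perturbs another.

Default sample sizes mirror the emulated design: 3 cases vs 3 controls in
tissue, 3 replicates per transfection arm, 10 miRNAs with 150–250 predicted
targets each over 2,000 genes (the recovery experiments use 200–300 so at
least 2,000 pairs are planted).

What the generator does **not** model: probe-level array physics,
cross-hybridization, batch effects, correlated noise between samples, or
indirect (network-mediated) regulation — planted classes are marginal per
pair. Passing recovery tests therefore demonstrates the pipeline's
statistical behavior under the stated design, not performance on real
arrays.

A consequence worth knowing: with 3 + 3 samples the pooled t-test at
p < 0.005 (critical t ≈ 5.6 at 4 df) has power ≈ 0.45 for an isolated
2-log2 effect at noise sd 0.5, yet genes targeted by several non-NC pairs
accumulate summed effects, raising both power and the rate at which NC pairs
sharing a regulated gene get flagged. The 20-seed mean IC estimate under the
default planted 11 % lands around 8–9 % — inside the ±3-point recovery band,
but the shortfall is real and attributable to test power, not to the
classifier. In the noise-free limit (and a design without overlapping
regulation, e.g. a single miRNA) recovery is provably exact; with
overlapping regulation, pairs whose gene's summed effect cancels to zero are
classified by the *net* effect, which is the model's honest behavior, not an
implementation artifact.

## Numerical and design choices

* **Z-score convention:** sample (n−1) standard deviation everywhere.
* **Zero pooled variance** in the t-test: p = 1 when the group means are
  equal, p = 0 otherwise (the noise-free limit then classifies exactly).
* **Clustering:** complete linkage on 1 − Pearson correlation between
  sample columns, missing entries replaced by 0 before distances; a
  constant column is an error (correlation undefined) rather than silently
  NaN. Dendrograms export to Newick with merge heights as branch lengths.
* **miRNA name normalization:** case-folded `hsa-miR-…` form; star forms
  (`miR-93*`) kept verbatim; no modernization to -3p/-5p names.
* **Duplicate miRanda rows** collapse to the most negative mirSVR score.
* **Rounding:** percentages half-away-from-zero to 2 decimals; rounded
  per-miRNA rows may sum to 100 ± 0.02.
* **Randomization-test ties** are counted as exceedances (≥ with a 1e-12
  slack), which is conservative.
* **Ordering of z-score vs testing:** tests run on log2 values; z-scoring
  is applied only for clustering, matching the documented order of
  operations of the emulated workflow.
* **CLI exit codes:** 0 ok, 1 user error, 2 stage failure; each pipeline
  stage failure is reported with the stage name and nothing is written
  before input validation passes.

## Known limitations

* The SAM implementation follows the original description (percentile-grid
  s0, median false-positive count, IQR-based π0); it is not a
  re-implementation of any particular software release, and q-values for
  very small designs (20 distinct permutations) are coarse.
* Probe↔gene collapsing between different array generations (e.g. a
  transfection chip vs a tissue chip) is done purely through the annotation
  table; if a symbol maps to different probesets on the two platforms the
  probe-level cross-tabulation counts them independently.
* Detection calls in the signal-only dialect default to Present, making the
  Absent filter a no-op — intentional, but worth remembering when comparing
  totals.
* The enrichment test treats probesets as exchangeable units; correlated
  probesets of one gene inflate both K and k.
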
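# Methods

This note documents the models, defaults, and numerical choices behind
`crpod`, and what the synthetic-data tests do and do not establish.

## Probe counting

Targeted panels read fixed-length (typically 50-mer) detector probes, so
alignment reduces to matching each read's first *L* bases against the
manifest. A hash lookup resolves exact matches; the remainder is scanned
for the minimum Hamming distance, accepted when ≤ `max_mismatch`
(default 2 — at a 1% per-base error rate, P(>2 errors in 50 bases) ≈ 1.4%,
so ≥97% of reads from a well-behaved library are assignable). Ties between
probes of the same gene resolve to the gene (gene-level counts are the
downstream unit); ties across genes are counted ambiguous; reads shorter
than *L* are flagged. Per sample, assigned + ambiguous + unassigned + short
equals the read total by construction. Reverse-complement search is off by
default because the assay reads the probe strand; quality scores are
ignored (matching is sequence-driven), with an optional mean-Q filter.
This matcher makes no claim of numerical parity with aligner-based
counting; for a targeted panel the two are fit-for-purpose equivalent.

## QC and normalization

* Feature filter: keep rows with total count ≥ 2 experiment-wide (">1
  count"). Sample filter: keep columns with total ≥ 100,000 (boundary
  kept). Thresholds are configurable; the defaults are the reference
  values for a ~3,000-gene panel.
* Control screening: PCA of log2(count + 0.5), gene-centered control
  columns is diagnostic only. Exclusion is driven by the D statistic:
  D_i = mean Pearson correlation of control i with the remaining controls
  on log2(count + 0.5) values (the log stabilizes variance; Spearman is
  available). Controls with D_i < mean(D) − 3·SD(D) are dropped in a single
  pass (no re-iteration). "Remaining samples" is read as remaining
  *controls*; a flag widens it to all samples. When SD(D) = 0 (identical
  controls) nothing is excluded; zero-variance columns are excluded
  outright because their correlation is undefined.
* Normalization: median-of-ratios size factors (reference genes = rows
  positive in every sample; fall back to total-count scaling when none
  exists). The full NB dispersion machinery lives in the DE module; the
  normalized matrix used downstream is counts / size factor. Note that
  median-of-ratios factors are invariant to global rescaling — they encode
  relative depth only — so per-column depth changes are recovered up to one
  global constant.
* Pipeline order is features → samples → D statistic, and the pseudocount
  is 0.5 in every log2 transform, matching the downstream dose-response
  transform.

## Differential expression

Per chemical, maximum-dose samples vs all vehicle controls. The test is a
gene-wise NB GLM with log link and log size-factor offsets; the Wald
statistic on the group coefficient gives the p-value, and l2fc is the raw
MLE (no shrinkage). Dispersion: method-of-moments on normalized counts
(pooled within-group variance, so single-replicate treatment groups draw
dispersion entirely from the controls — a documented low-power mode),
then a trend α(µ) = a0 + a1/µ is fitted across genes by least squares with
one outlier-trimmed refit, and gene dispersions are shrunk toward the trend
in log space with a prior weight of 20 pseudo-samples. The shrinkage weight
trades gene-specific signal against stability at panel scale; with ~15–25
samples per contrast the posterior is dominated by the trend, which is what
keeps the Wald test calibrated (type-I ≈ 0.05 at 2,000 simulated null
genes, dispersion 0.1, mean 200). Genes with all-zero counts in a contrast
get NA and leave the BH family. DEG = BH-adjusted p < 0.05 by default.
Exact numerical parity with external NB DE packages is a non-goal;
cross-checks against DESeq2 (size factors equal to machine precision, l2fc
correlation >0.99 on Poisson data) bound the agreement.

## Trend flags and decision tree

Doses are log10 µM; vehicle controls receive a pseudo-dose one mean
successive log10-spacing below the lowest tested dose (a single dose gets
spacing 1). Responses are log2(normalized + 0.5), mean-centered to
controls; the control SD of those centered values defines the POD's
baseline deviation unit.

The trend statistic is the Pearson correlation between dose and response
(computed on log10 doses, not ranks). Its null is the uniform permutation
of responses:

* **Exact**: full enumeration for n ≤ 8; for larger series the
  enumeration collapses to distinct assignments whenever the dose vector
  is one tied block plus ≤4 singleton doses (the shared-control,
  single-replicate design) — n(n−1)(n−2) = 15,600 assignments at the
  reference 23+3 design — so the default (`auto`) trend p-values are
  exactly permutation-calibrated.
* **Monte Carlo**: 10,000 seeded draws with the add-one estimator.
* **Moment approximation**: the first four permutation moments of r are
  computed analytically (verified against brute-force enumeration) and
  matched by a shifted/scaled beta; two-sided p = P(|R| ≥ |r|). This is an
  accelerator in the spirit of moment-corrected correlation: accurate in
  the tails and at larger n, but at n ≤ 8 the exact permutation
  distribution is discrete with atoms larger than ~0.02 and can be
  multimodal, so no smooth four-moment family tracks its mid-range CDF to
  0.01; the exact and Monte Carlo modes are authoritative there (and are
  what the pipeline uses by default).

Wilcoxon rank-sum (controls vs all treatments) uses exact enumeration when
min(n, m) ≤ 10 without ties, else the normal approximation with midranks,
tie correction and continuity correction. q-values are BH step-up
(Storey's π0 optional), computed across genes within each chemical and
flag family. The adjustment family follows the decision tree
(hierarchical): q_overall over all genes, q_wilcox over the genes whose
overall trend passed, q_trt over the genes Wilcoxon did not settle. The
hierarchy is not cosmetic: the exact 23-vs-3 rank-sum test has a p-value
floor of 2/C(26,3) ≈ 7.7e-4, and a BH adjustment across a ~3,000-gene
panel can essentially never carry that floor below q = 0.05, which would
leave the fitting branch structurally unreachable in single-replicate
designs; adjusting within the trend-selected subset restores it. A flat
(all-genes) family is available by configuration. The decision tree: no
overall trend → POD = max dose; else Wilcoxon significant → fit; else
treatment-only trend significant → fit; else manual review (reported, not
fitted, no POD). Threshold q < 0.05, configurable. With a single replicate
per dose the treatment-only trend test has only 6 distinct permutations
(minimum two-sided p = 1/3), so that branch cannot fire in the reference
design — it matters for replicated designs.

## Concentration–response models and POD

Functional forms follow the log10-dose Hill/gain-loss conventions of the
high-throughput screening toolchain: hill3 has floor fixed at 0; gainloss
is a product of gain and loss sigmoids (floor 0); hill4 frees the floor.
Fitting is Gaussian maximum likelihood (least squares) with analytic
Jacobians and a deterministic multi-start grid: ga/ec50 at the dose-range
quartiles, slopes in {0.5, 1, 4}, amplitude from the response extremes; no
RNG anywhere in fitting. Bounds: tp ∈ [0, 1.2·max|y|], midpoints within
[min dose − 1, max dose + 1], slopes ∈ [0.3, 8]. Floor-0 models are fit to
both y and −y and the better sign is kept, recording the response
direction; gainloss fits with la < ga are flagged degenerate. AIC = 2k −
2·loglik with σ counted in k (constant 2, hill3 4, hill4 5, gainloss 6);
the winner is the smallest AIC among converged fits, ties break to fewer
parameters then to a fixed model order. Plain AIC buys ~10% spurious
non-constant winners on null data (the χ² overfitting rate); the constant
model is the null fit, not a gate.

POD: BSD = 1 × control SD (multiplier configurable). The crossing of
|f(x)| = BSD is sought from the vehicle pseudo-dose to the maximum dose by
a 513-point bracket scan plus Brent bisection to 1e-6 on the log10 scale
(verified against the hill3 closed form ga − log10(tp/BSD − 1)/gw to
1e-5). |f| is used rather than the fitted direction only, so up- and
down-regulation are treated symmetrically. No crossing, or a constant
winner, puts the POD at the maximum tested dose (basis recorded); a
crossing below the lowest tested dose is reported but flagged
extrapolated. Series routed "no trend" take the maximum dose as POD
without fitting.

## Synthetic data

The generator emulates the reference study: a 2,982-gene panel, 24 shared
vehicle controls, 4 chemicals × {0.1, 1, 10} µM × 1 replicate (a
12-control, 3-replicate preset mirrors the replicated illustration), mean
~200 counts per gene (the reference assay reports ~212), NB dispersion
0.05 (typical targeted-seq overdispersion), gene baselines log-normal with
1.5 log2-SD, and mild per-sample depth variation (log-normal, σ = 0.1).
Responsive genes (default 5%) shift their mean log2 expression by a Hill
or gain-loss curve with tp ∈ [0.75, 2.5] log2 units, AC50 ∈ [−1.5, 0.5]
log10 µM, slope ∈ [0.5, 3], half of them down-regulated. Planted QC
defects — thinned columns, sub-threshold rows (totals alternating 0/1),
and shuffled outlier controls — are injected last, with identities in the
truth table. FASTQ simulation emits probe copies with iid substitution
errors.

What this does not emulate: plate-position or batch effects, probe-level
sequence biases, correlated gene modules, heavy-tailed technical outliers,
or attenuation of high-expressors. Passing tests therefore demonstrate
correctness of the algorithms under the stated stochastic model, not
robustness to every artifact of real plates.

## Problem sizes and determinism

Tests and the acceptance script run the full panel (2,982 genes) through
counting/QC/DE, and scale the fitting-heavy stages to 50–150 genes or
50–100 replicates, which the package's own runtime characteristics make a
comfortable interactive size; all simulations are seeded and every
pipeline stage is a pure function of (inputs, config, seed), so repeated
runs are byte-identical. TSV floats are written at %.8g to keep output
stable across platforms.
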
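# Methods

This note documents the models implemented in `cfmm`, the choices made
where the design was genuinely open, and what the synthetic cohort does
and does not establish about real data.

## Coordinates and containers

All coordinates are 0-based half-open. BED I/O is native; bedGraph and
Bismark cytosine-coverage positions are converted on read. Bins, CpG
tracks, region tables, fragment tables and feature matrices are pandas
DataFrames with fixed column schemas (documented in `cfmm.genome`).

## Region methylation

The mean methylation of a region is the unweighted mean of the betas of
the CpG sites inside it; depth weighting is available as an option
(`weight_by_depth=True`). A region with no covered site is *missing*
(NaN), never 0 — a convention that matters downstream, where missing
features are imputed from control medians rather than treated as
unmethylated. Terminal partial bins are kept when tiling a genome but
excluded from LOESS fitting and differential testing when narrower than
half the bin size, to avoid edge artifacts.

## Malignant calls and ratios

A fragment overlapping a DMR is *informative* when it carries at least
`min_cpg = 3` CpGs. An informative fragment is called **malignant** when
its methylated fraction is strictly closer to the region's tumor
reference beta than to its normal reference beta; ties go to normal, so
the call is conservative. The per-sample, per-region malignant ratio is
`malignant / (malignant + normal)`; it is reported only when at least
`min_fragments = 5` informative fragments support it, and is missing
otherwise. This nearest-reference rule is one concretisation of
read-level methylation deconvolution; a likelihood-ratio rule under a
Beta-Binomial would be a drop-in alternative and the call function is
kept separable for that reason.

Tissue DMR discovery tests per-pair region-mean differences with a
Wilcoxon signed-rank test, controls the FDR by Benjamini–Hochberg, and
applies an effect filter |mean Δβ| ≥ 0.2. The cfDNA screen then keeps
regions whose malignant ratios differ between cases and controls
(two-sided rank-sum, BH-adjusted p below the FDR level) *and* are
case-elevated; the direction filter never admits a region whose case
mean is at or below its control mean.

## Copy number from bisulfite coverage

Fragments are assigned to bins by midpoint and counts rescaled so the
genome-wide total equals a uniform target depth. GC correction is
robust local (LOESS) linear regression of count on GC fraction:

* distance weights `W(u) = (1 − u³)³` (tricube) within a nearest-
  neighbour window covering a `span = 0.3` fraction of bins;
* two robustness iterations multiplying in `B(r) = (1 − r²)²`
  (bisquare) on residuals scaled by `6 · median|residual|`;
* corrected count = raw count × median(fit)/fit, preserving scale;
* bins with GC outside [0.3, 0.6] are masked (admissible-range
  convention for bisulfite libraries, where extreme-GC bins are
  unreliable).

The span, iteration count and residual scaling are the classic robust-
LOESS defaults; the kernels are the method's defining primitives and are
unit-tested against their closed forms.

Per-bin `log2(Ft/Fn)` is computed against a matched normal (tissue) or
the per-bin median of GC-corrected controls (plasma, a panel-of-normals
baseline). Segmentation fits Gaussian mixtures with 1–3 components
(order chosen by BIC), anchors the neutral state at the component
nearest 0, pools components below/above it into DEL/AMP (falling back to
neutral ± `alt_mean` when a side is absent), and decodes the
maximum-probability path of a 3-state Gaussian HMM per chromosome
(symmetric transitions, `self_transition = 0.99`, variances floored at
1e-4). Tissue segmentation uses `alt_mean = 0.5`; the cfDNA caller uses
`alt_mean = 0.15`, a low-amplitude prior suited to low tumor fractions
where an amplification at copy ratio r and tumor fraction t shifts the
ratio by only `log2(1 + t(r−1))`.

Recurrent regions are bins called non-neutral in ≥ 3 tissue samples,
merged per state. A cfDNA **event** is reported in a recurrent region
only when a non-neutral segment overlaps it *with matching direction* —
amplification regions accept only AMP calls — which is what keeps the
control positivity near zero. Differential regions use an unadjusted
two-sided rank-sum test at α = 0.05 on event indicators by default, with
a BH-adjusted mode available; both conventions appear in practice and
the default is the more permissive one, so the adjusted mode is the
switch to flip for stricter control. A sample is **CNV-positive** when
it has at least one event inside the selected regions.

## Fragmentation

Size profiles are 1-bp histograms over 50–400 bp with overflow buckets.
The FSR denominators count fragments in the analyzable mono-nucleosomal
range 100–220 bp (an `all`-fragments denominator is available); the
short band defaults to 100–150 bp and is configurable — reported short
bands in the literature vary (90–150 vs 100–150). A bin's FSR is missing
below `min_total = 100` denominator fragments. Differential bins use a
two-sided t test at α = 0.05 plus the case-elevated direction filter;
bins missing in > 20 % of samples are excluded. A `two_feature` mode
emits the complementary long-fragment ratio per bin as a second feature.

## Models

* **MDS composites.** The CNV event matrix and the FSR matrix are each
  reduced to 2 coordinates by metric MDS (SMACOF stress majorisation,
  deterministic classical-scaling initialisation). Both the raw stress
  (sum of squared distance residuals over pairs) and the normalised
  stress (√(raw / Σδ²)) are reported, since "stress" is quoted on both
  scales in the literature. New samples are placed out-of-sample by
  minimising their individual stress against the fixed training
  coordinates; how validation samples should be embedded is genuinely
  underdetermined, and this choice is the one that leaves training
  coordinates untouched.
* **Forests.** `RandomForestCV` produces out-of-fold class-probability
  scores from stratified k-fold refits, then refits on all data.
  Defaults: 500 trees, `mtry = 2`, 10 folds. Scores are raw vote
  fractions — no recalibration — so a 0.5 cutoff keeps its natural
  reading. Feature matrices per mode: `meth` = selected DMR ratios
  (missing cells imputed with the training control median);
  `meth_cnv` = + 2 CNV-MDS coordinates; `full` = + 2 FSR-MDS
  coordinates. The MDS coordinates are passed unscaled alongside the
  ratios; forests are scale-insensitive.
* **RFE.** Backward elimination ranked by forest importance over
  declared subset sizes, scored by cross-validated out-of-fold AUC; the
  default pick is the smallest size within one (coarse binomial)
  standard error of the best. The pipeline's default panel is simply
  the top-k screen ordering, with RFE as an opt-in refinement.
* **Thresholding.** `threshold_at_specificity` returns the smallest
  cutoff whose training-control specificity meets the target (positive
  iff score ≥ cutoff); the smallest achieving cutoff automatically
  maximises sensitivity. AUC is exact pair counting (ties ½); its 95 %
  CI is a stratified bootstrap (2000 replicates, seeded), with the CI
  method kept separable should a DeLong variant be preferred.

## Interception model

A cohort enters the precancerous stage (IEN) and progresses through
ordered stages in annual steps; leaving the last stage means clinical
presentation, at which point the diagnosed stage is drawn from an
observed baseline distribution. At each scheduled test an undiagnosed
individual in stage s is intercepted with probability `sensitivity[s]`
and assigned that stage's 5-year overall survival; the benefit is the
difference in expected survival against the same chain with all
sensitivities zero. The closed form propagates the occupancy
distribution exactly and is verified against individual-level
Monte-Carlo in the test suite. Within a year the test precedes
progression; under the annual time step, interval 0 ("continuous") and
interval 1 coincide. Undiagnosed mass at the horizon (default 30 years)
is assigned clinical diagnosis. The shipped default rates are
**illustrative round numbers, not estimates from any cohort**; users
supply their own parameter file for real projections.

## Synthetic cohort

The simulator's defaults define the study conditions used throughout
the tests and the acceptance script:

* toy genome of 2 × 25 Mb chromosomes; 100-kb copy-number bins
  (500 bins) and 500-kb fragmentation bins (100 bins). These are scaled
  stand-ins for the 1-Mb / 5-Mb bins used on a full human genome; the
  public APIs default to the full-genome sizes.
* 60 true DMRs (half hyper at 0.85 vs 0.15, half hypo) of 3 kb plus 140
  null candidate regions that carry a nominal tissue contrast but no
  cfDNA contrast; CpG density 1/25 bp inside candidate regions
  (island-like), 1/125 bp background, background beta 0.75.
* fragment lengths are discretised lognormals parameterised by mode —
  166 bp healthy, 145 bp tumor, σ = 0.18 — giving the tumor component
  its short-band (100–150 bp) excess.
* 5 AMP (copy ratio 1.75) + 5 DEL (0.5) truth segments of 20 bins;
  tumor fragments are placed with weight copy-ratio × GC-bias ×
  ctDNA-enrichment, so coverage signal scales with tumor fraction; 30 %
  of cases carry the CNV profile, making the CNV channel partially
  independent of the methylation channel.
* 20 ctDNA-enriched bins (weight 5) drive position-dependent FSR
  elevation; a mild quadratic GC bias modulates all coverage.
* per-sample depth 150 000 fragments (~0.5× on the toy genome), chosen
  so that a 3-kb DMR collects ~10 informative fragments — the same
  order as a 10× WGBS run on a real DMR panel; tissue counts are
  Poisson at 100 fragments/bin (185 when a benchmark needs per-bin
  log2 noise of 0.15).

One seeded generator is threaded through everything; per-sample
generators are spawned from a seed sequence, so any prefix of the cohort
stream is reproducible and two runs with one seed are byte-identical.

What the simulator does **not** model: nucleosomal 10-bp periodicity of
fragment lengths, bisulfite conversion failure and DNA damage, mapping
and alignability artifacts, subclonal or allele-specific copy number,
and between-individual methylation heterogeneity beyond Beta noise.
Passing recovery tests therefore shows the pipeline's statistics are
implemented correctly and behave as designed under the stated generative
assumptions — not that the same operating points (AUCs, positivity
rates) transfer to clinical cohorts. Because simulated tumor fragments
are globally short-enriched, *all* fragmentation bins separate cases
from controls at large n; the truth-bin recall tests target the
enrichment-driven, position-dependent component.

## Numerical conventions

Ties in malignant calls go to normal; ties in AUC count ½; the HMM
variance floor is 1e-4; LOESS fits are guarded against all-zero weight
rows and degenerate design matrices; zero-variance MDS input yields
all-equal coordinates with stress 0; mixture fits use a fixed random
state, making the whole stack deterministic given the cohort seed.
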
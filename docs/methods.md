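# Methods

## Signal-intensity landmark model

A placental DCE-MRI time–intensity curve is summarized by two
dimensionless ratios. With SI(t) the mean signal intensity of the region
of interest, the **initial enhancement** is SI at the first local
maximum divided by the initial SI, and the **recovery** is SI at the
second local maximum divided by the SI at the local minimum between the
two maxima. Acquisition starts at contrast injection, so the "initial
SI" is the first acquired timepoint (one scan, 2 min 43 s,
post-injection); no pre-contrast frame exists in this protocol. The
**rate of enhancement** (ROE) is the per-interval finite difference of
SI, converted to min⁻¹ and divided by a scalar vena cava reference.

### Landmark detection

Detection runs on a centered moving average of the curve (default
window 3, odd, configurable; edges padded by replication):

1. *First maximum*: the earliest interior sample that is a non-strict
   local maximum of the smoothed series and exceeds the smoothed initial
   value. Non-strict comparison with earliest-index tie-breaking makes
   plateaus from quantized SI well-defined.
2. *Interior minimum*: the global minimum of the smoothed series after
   the first maximum (earliest tie). A global rather than nearest local
   minimum avoids noise-trapped minima; on these curves it falls roughly
   mid-acquisition. If it lands on the final sample the curve has no
   recovery limb and a `NoRecoveryLimb` error is raised (a curve with
   zero recovery amplitude behaves this way).
3. *Second maximum*: the maximum of the smoothed series after the
   interior minimum. The final timepoint is eligible — recovery is often
   still rising when acquisition stops.

Each smoothed-series index is then snapped to the raw-series extremum
within the smoothing half-window, and both ratios are computed from raw
(unsmoothed) values at the snapped indices. The snap matters: a moving
average imposes a phase lag on the asymmetric uptake peak, and reading
raw values at the lagged index biases the enhancement ratio by several
percent even on noiseless curves; with the snap the ratios agree with a
dense-grid oracle to well under 1% across the tested parameter sweep.

Cohort analysis treats per-curve landmark failures as first-class
outputs (a failure table with curve id and reason), never silently
dropping curves and never aborting unless every curve fails. Group
summaries report mean + SEM.

### Vena cava reference

The ROE scaling concentration is taken as the mean of the three
timepoints immediately following the vena cava SI peak (its early
plateau), falling back to the peak itself when the peak is terminal. A
plateau mean is the most stable single scalar for a blood-pool curve; no
formula is prescribed by the assay convention, so this is a documented
package choice.

## Synthetic curve generator

The generator emulates the biphasic shape the landmark definitions
assume:

    S(t) = S0 · (1 + A1·g(t; t1) + A2·h(t; onset, rate))
    g(t) = (t/t1)³ · exp(3(1 − t/t1))        (gamma-variate, peak 1 at t1)
    h(t) = 1 / (1 + exp(−rate·(t − onset)))  (logistic recovery)

with additive Gaussian measurement noise. The shape-3 gamma variate is
deliberate: a first-order pulse decays so slowly that small recovery
amplitudes (A2 ≈ 0.1, the double-knockout regime) never produce an
interior minimum inside the ~68 min window, whereas with shape 3 the
uptake washes out by mid-window and every preset has a detectable
recovery limb — matching the observed curves, where even attenuated
genotypes show a distinct minimum. With A1 = A2 = 0 the noiseless curve
is constant at S0.

Ground-truth landmark ratios are computed by brute force on a
1000×-oversampled grid spanning the scan window (first local maximum
above the initial value, global minimum after it, maximum after that),
so the truth stays correct if the curve family changes. Curves whose
noiseless shape is monophasic report no ground truth rather than a
fabricated one.

Parameter defaults (chosen as plausible for this assay; the source
assays publish no noise or variance levels, so these are free parameters
of the generator, not estimates of any real dataset):

| parameter | default | units | meaning |
|---|---|---|---|
| S0 | 100 | a.u. | baseline signal |
| A1 | 0.35–0.60 | — | uptake amplitude (per genotype preset) |
| t1 | 8 | min | uptake peak time |
| A2 | 0.10–0.50 | — | recovery amplitude (per genotype preset) |
| onset | 30 | min | recovery midpoint |
| rate | 0.2 | min⁻¹ | recovery steepness |
| noise_sd | 2 | a.u. | measurement noise (2% of baseline) |
| between-placenta CV | 0.10 | — | amplitude jitter within a genotype |

The preset table orders recovery amplitudes WT (0.50) > Cdkn1a (0.45) >
p53 (0.30) > Cdkn2a (0.25) > Cdkn2a;p53 double knockout (0.10), so the
double knockout has the weakest recovery, and gives it the lowest uptake
amplitude as well — the direction of the reported group differences.
The scan schedule follows the end-of-scan convention (scan k timestamped
at k × 163 s), which makes "25 scans in 67 min 55 s" arithmetically
exact.

The generator emulates curve shape, amplitude heterogeneity, and
i.i.d. Gaussian noise. It does not emulate fetal-motion artifacts,
scanner drift, partial-volume effects at ROI boundaries, or correlated
noise; passing tests therefore demonstrate correctness of the
quantification rules, not robustness to those real-data effects (motion
is handled upstream by per-scan manual ROIs, which the ROI extractor
supports via per-timepoint masks).

## Histological quantification

* **Percent positive syncytia**: 100 × (syncytia with ≥ 1 positive
  nucleus) / (all syncytia in the field). Adding a negative nucleus to
  an already-positive syncytium cannot change the value, and the
  statistic is invariant to syncytium order. Field aggregation reports
  mean + SEM and warns — rather than fails — below 12 fields, since the
  12-field rule is a sampling guideline, not a precondition.
* **Ki67 rubric**: 0 for exactly zero positivity; 0.5 for (0, 5%); then
  left-closed/right-open bins [5,10)→1, [10,25)→1.5, [25,33)→2,
  [33,50)→2.5, [50,66)→3, [66,75]→3.5, and >75%→4. The only strict
  wording in the printed scale is "more than 75%", so exactly 75% sits
  in the 3.5 bin; all other seams are resolved left-closed for
  monotonicity and exhaustiveness.
* **Fusion index**: default is nuclei-based — the percent of all nuclei
  residing in multinucleated (≥ 2 nuclei) cells — because once large
  syncytia dominate a culture this definition tracks the mass of fused
  material; the cell-based percent of multinucleated cells is selectable.
  No formula is fixed by convention, so both are provided.
* **Intensity quantification**: area fraction above threshold plus mean
  intensity, restricted to the tissue mask when present. Default
  threshold is Otsu's method (deterministic, parameter-free); a fixed
  numeric threshold is accepted. A constant image has no Otsu threshold
  and falls back to area fraction 0 with a warning. Fold changes between
  groups are ratios of group means, with reductions reported as the
  reciprocal magnitude plus a direction flag.

## Group statistics and the fold-change filter

The t-test is the classical pooled-variance unpaired Student's test
(Welch behind a flag); one-tailed p is half the two-tailed p when the
effect lies in the stated direction. Zero pooled variance is handled by
convention: equal means give t = 0, p = 1; unequal means give an
infinite t with p = 0 and a degeneracy flag. Multi-group comparisons use
one-way ANOVA followed by Tukey's HSD; with all observations identical
the variance ratio is undefined and F = 0, p = 1 is returned by
convention. No multiple-testing correction is applied to standalone
t-tests (none is applied in the source workflow outside Tukey). Note
that Tukey's adjusted p is guaranteed to be at least the unadjusted
pairwise p *within the pooled-MSE framework*; it can fall below a
two-sample t-test p, which uses fewer degrees of freedom.

The fold-change filter computes per-gene FC = mean(late)/mean(early) on
the linear scale and selects genes with FC ≥ τ or FC ≤ 1/τ (default
τ = 1.8, boundary inclusive so selection counts are reproducible).
Whether such a cut is taken on group means or per replicate, linear or
log, is ambiguous in common usage; group-mean linear ratio is the
documented default here. Genes with a zero early-group mean have no
ratio and are reported separately rather than silently given infinite
fold. Output is ordered by |log2 FC| descending with ties broken by gene
identifier, so runs are deterministic.

## Pipeline and reproducibility

All generators derive their random streams from a single integer seed
via stable sub-seeding (`SeedSequence` spawn keys), so every stage is a
pure function of (parameters, seed) and the full demo pipeline is
byte-identical across runs with the same configuration. The pipeline
writes a JSON manifest listing every artifact with its SHA-256 hash plus
the configuration hash and seed; no timestamps are embedded anywhere.
Configuration files round-trip losslessly and unknown keys are rejected.

Problem sizes used in the shipped checks: the landmark oracle sweep
covers 324 noiseless parameter combinations (322 biphasic); the
direction-recovery check runs 100 replicates of 8 + 8 placentas at 2%
noise; counting oracles run on 500 random fields; the fold-change checks
use 2000–5000 genes with 204 or 50 planted effects; the end-to-end
determinism check runs the full five-genotype demo twice.

## Known limitations

* The landmark statistics assume a biphasic curve; monophasic or
  strictly decreasing curves are reported as failures by design, not
  estimated.
* Initial enhancement is referenced to the first *acquired* timepoint;
  protocols with pre-contrast frames would need a baseline-averaging
  extension.
* The intensity quantifier assumes staining is brighter than background
  after any upstream inversion; no color deconvolution or segmentation
  is performed.
* The synthetic generators are shape-level emulations for validating the
  quantification rules; they make no claim of pharmacokinetic realism
  (no compartment modeling, relaxivity, or k-space physics).
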
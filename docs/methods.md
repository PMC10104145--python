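# Methods

This note records the statistical models, conventions, and deliberate
design choices behind `cytosig`, in the order data flow through the
package.

## Plate cleaning (`cytosig.luminex`)

A raw plate is a long table of per-well readings (pg/mL) with bead counts,
up to three technical replicates per sample × cytokine. Cleaning applies,
in this order:

1. **Bead filter.** Replicates read from fewer than `min_beads` (default
   20) beads are removed. Bead-based readings become unreliable at low bead
   counts, and the instrument reports the count per well.
2. **Detection-limit censoring.** Readings strictly below `lod` (default
   3.2 pg/mL) are set to exactly 0. The inequality is strict: a reading of
   exactly 3.2 survives. Censored zeros participate in the triplicate rule
   as ordinary 0 values.
3. **Triplicate outlier rule.** For three values (a, b, c), candidate r is
   removed iff min(|r−s|, |r−u|) > 2·|s−u|, where s, u are the other two.
   At most one replicate is removed per cell. If two candidates both
   qualify (possible only in contrived configurations), the one with the
   larger min-distance goes; an exact tie removes none and warns. Cells
   reduced to one or two replicates by the bead filter skip the rule — it
   is defined for triplicates. Survivors are averaged.

   Note the rule is deliberately aggressive: under symmetric replicate
   noise it fires whenever two replicates happen to be much closer to each
   other than to the third, which occurs in roughly half of well-behaved
   triplicates. This is harmless — the removed value is then near the
   remaining pair, so the cell mean barely moves — but users should not
   read the removal count as an outlier rate.
4. **Sparse-cytokine removal.** A cytokine is dropped iff its zero fraction
   over all samples exceeds 1/2 AND the zeros are not group-partitioned.
   "Group-partitioned" is operationalized as: some level of a grouping
   variable (default genotype, timepoint) has zero-fraction ≤ 1/2 while the
   complementary samples have zero-fraction > 1/2 — i.e. the cytokine is
   genuinely measurable in at least one experimental group (the motivating
   case is a chemokine absent from control animals but present in disease).
   This predicate is not the only possible reading of "partitions between
   groups"; every decision is logged per cytokine so users can override.

A cell that loses all replicates for a retained cytokine is an error (the
matrix must be complete), with the offending cells listed.

## PLS engine (`cytosig.pls`)

Predictors and response are mean-centered and scaled to unit sample
variance (denominator n−1). A categorical response becomes one autoscaled
1/0 dummy column per class; a numeric response one autoscaled column.

**Fitting** is standard NIPALS with X- and Y-deflation. Determinism is
enforced two ways: the inner loop is initialized from the Y column of
maximal variance (single-column responses need no iteration at all), and
each weight vector is sign-fixed so its largest-magnitude entry is
positive. Convergence tolerance 1e-10, max 500 inner iterations. The model
stores the raw unit-norm NIPALS weights W (used by VIP), the
score-generating weights W* = W(PᵀW)⁻¹ (so scores = Xs·W* exactly), and
the coefficient matrix B = W*Qᵀ. Predictions on new data reuse the
training scaling parameters. For discriminant models the class is the
argmax over dummy-column predictions; exact ties go to the first class in
sorted order and are logged.

**Orthogonalization** is a post-hoc rotation, not a refit: an orthonormal
basis of the fitted score space is rotated (via the SVD of the fitted
response's coordinates in that basis) so the first direction is the
response-predictive one. The score subspace — hence every prediction — is
unchanged; that invariance is asserted to 1e-8 in tests. Rotated scores
are returned orthonormal; their scale is presentational. LV1 is oriented
so the response pole is positive (larger numeric response, or the
designated positive class, e.g. the disease genotype). An OPLS-style refit
would give the same LV1 loadings for 2-LV models but can differ in higher
components; the rotation was chosen because it treats orthogonalization as
a presentation transform with a hard prediction-invariance guarantee.

**VIP.** VIPⱼ = √(p·Σₐ SSYₐ(w_ja/‖wₐ‖)²/Σₐ SSYₐ) with SSYₐ the response
sum of squares explained by component a (computed as (tₐᵀtₐ)‖qₐ‖²). The
mean-square-1 identity holds by construction and is asserted at 1e-8. For
1-LV models everything (error, p, VIP) is computed on LV1 only.

## Model selection and significance (`cytosig.model_selection`)

Candidate component counts are 1..5. Each cross-validation iteration draws
a random test set of round(n/3) samples when n > 30, round(n/5) otherwise
(n = 30 exactly falls to the 1/5 rule; the boundary never binds at this
study's sizes), 100 iterations by default. Splits are stratified by class
for discriminant models (every class is guaranteed training presence) and
unstratified for regression. Autoscaling is refit on each training fold so
no test information leaks into the scaling. Scores are per-test-set RMSECV
(regression) or accuracy (discriminant), averaged across iterations per
candidate; the best mean wins, ties to the smaller model. Iterations whose
fit fails are skipped and counted; more than 10% failures is an error.

The permutation test shuffles the response (predictor landscape intact),
re-runs the identical repeated-subsampling CV at the chosen A, and records
each permutation's mean score. The p-value is the one-sided Gaussian tail
of z = (observed − μ₀)/σ₀ computed from the null scores' mean and SD —
upper tail for accuracy, lower for RMSECV. A Gaussian tail (rather than an
empirical rank) lets small p-values be resolved with ~100 permutations;
its calibration is checked empirically: over 200 null datasets the
rejection rate at α = 0.05 falls inside the binomial 95% interval.

## Signature (`cytosig.signature`)

Members are the predictors with VIP strictly greater than 1 (an
above-average contribution), reported with signed LV1 loadings of the
orthogonalized model, sorted by |loading|. "Up" means positive loading
under the fixed orientation. Signature comparison reports shared/unique
members and direction agreements vs reversals; multi-LV direction calls
are deliberately not attempted — only LV1 loadings are interpreted.

## Digital-count DE (`cytosig.nanostring`)

Background thresholding floors raw counts at 20 (idempotent). Housekeeping
selection drops genes with *any* sample count below 100 (a strict screen;
a mean-based variant is a flag away) and keeps those with sample CV
(sd/mean, ddof=1) ≤ 0.10. Normalization is two geometric-mean scale-factor
steps — positive controls, then kept housekeepers — where each sample's
factor is (geometric mean across samples of the per-sample reference
geomeans) / (own geomean); with this numerator the factors' geometric mean
is exactly 1 per step, so normalization never changes the global count
scale. Per endogenous gene: log2FC of arm means, two-sided Welch t-test on
log2 counts (Student's by flag), significant iff p ≤ 0.05 and not both arm
means < 30 (too close to the background floor to trust). Genes with
identical arm values have undefined p and are excluded with a reason. No
multiple-testing correction is applied — matching the filtering scheme
this implements — and the table carries everything needed to add one.

## Flux metrics (`cytosig.seahorse`)

Well metrics use phase medians/extrema (order-free within phase):
non-mito = median post-rotenone/antimycin; basal = pre-oligomycin median −
non-mito; maximal = post-FCCP max − non-mito; leak = post-oligomycin min −
non-mito. Two ATP conventions are carried because the printed formula
("basal respiration − post-oligomycin minimum", where basal is already
non-mito-corrected) breaks the familiar identity basal = ATP + leak:

* `table1_literal` (default): ATP = basal − min(oligo); then
  ATP + leak = basal − non-mito, exactly.
* `pre_oligo_raw` (vendor convention): ATP = raw pre-oligomycin median −
  min(oligo); then ATP + leak = basal, exactly.

Both identities are asserted to machine precision on random traces.

QC excludes wells with basal-phase median below 5% of the plate-wide
median basal ("near-zero OCR"; absolute override available) and wells
whose post-FCCP maximum does not exceed their post-oligomycin minimum.
Kept wells are protein-normalized (OCR/µg), metrics averaged per
biological replicate (an independent experiment of 5–10 wells; fewer than
3 is flagged), and finally divided by the replicate's non-mitochondrial
respiration to remove batch effects (non-mito becomes 1). Arms are
compared by a two-sided pooled-variance Student's t-test (Welch by flag);
degenerate identical arms return p = 1 with a warning rather than NaN.

## Synthetic data (`cytosig.synthetic`)

The cytokine generator emulates the study design: 2 genotypes × 4 ages
(30/60/120/180 days) × 10 animals (sexes alternating, metadata only — no
sex effect is planted), 32 cytokines named for a standard mouse multiplex
panel, technical triplicates. Log-concentrations follow

log x = baseline + aging·(t/180) + 1[disease]·signature·(t/180)
        + loading·f + ε,

with per-cytokine baselines ~ N(log 50, 0.5²) (so default plates rarely
touch the 3.2 pg/mL limit), a shared per-animal factor f ~ N(0,1) with
loading 0.5 on every cytokine (the inter-cytokine correlation a
latent-variable model exploits, and the reason univariate tests are weak
here), signature slopes ±1.0 log-units per unit scaled time on the planted
members (default 3 up: IFN-g, IP-10, IL-9; 2 down: IL-2, IL-1a), residual
SD 0.3, and multiplicative triplicate noise at 5% CV. Low-bead events
(probability 0.01/replicate) draw bead counts from Poisson(8) capped at
19; normal replicates from Poisson(50) floored at 20 — so planted flags
and the <20-bead rule coincide exactly. Outlier events (0.01/replicate)
multiply a reading by 3 or 1/3, sized so the triplicate rule catches them.
Aging slopes default to zero; tests that need an aging signature (e.g. a
direction-reversal between disease and aging models) plant one explicitly.

The count generator draws endogenous and housekeeping genes from a
negative binomial (variance m + φm², default φ = 0.005) around lognormal
baseline means, scaled per sample (lane factors, lognormal sd 0.05 —
values typical of digital-counting technical replication, and necessary
for a subset of housekeepers to clear the 10% raw-CV screen, mirroring the
5–6 of 20 kept in practice). Positive controls follow the fixed 128/32/8/
2/0.5/0.125 fourfold series; planted DE genes shift treated means by their
log2 fold change.

The OCR generator scales four true phase means per arm by a well-specific
protein factor plus Gaussian noise; dead wells read ≈0.2 pmol/min
everywhere, non-responders have their FCCP mean pulled to 0.8× the
oligomycin mean; wells are assigned round-robin to biological replicates.

**What the generators do not emulate:** standard-curve (5PL) fluorescence
interpolation, plate-position or batch effects within the cytokine plate,
sex effects, count zero-inflation, OCR drift within a phase. Passing tests
therefore demonstrate the pipeline's correctness and statistical behavior
under the stated generative model, not performance on any particular real
dataset.

## Problem sizes and numerics

Defaults everywhere mirror the study scale: n = 80 plates (40 per
genotype), 100 CV iterations, 100 permutations, 5–10 wells per flux
replicate, 6 biological replicates, 3 samples per DE arm. The statistical
acceptance checks use 200 null datasets (type-I calibration) and 50 seeds
(signature recovery), each at full CV/permutation depth. NIPALS tolerance
1e-10; autoscale treats SD ≤ 1e-12 as constant; permutation p-values are
clamped to the open interval (0,1). All randomness flows through
explicitly passed `numpy.random.Generator`s; fixed seeds give bit-identical
runs, and the orchestrator derives one seed per stage from the master seed
by fixed offsets so stages are independently reproducible.

## Known limitations

* The sparse-cytokine "partition" predicate and the triplicate tie-break
  are reasonable formalizations of informally stated rules; both are
  logged so they can be audited and overridden.
* The DE stage's t-test on log2 counts is a transparent stand-in for
  proprietary fold-change machinery; with n = 3 per arm its power depends
  strongly on dispersion, and gene counts from other implementations will
  not match exactly.
* The permutation p is parametric in the null's tail; heavy-tailed null
  score distributions would distort extreme p-values (the calibration test
  guards the α = 0.05 regime only).
* PLS-DA accuracy at the earliest age is low by design at the default
  effect size (the planted effect scales with age), so the first-timepoint
  discriminant model is typically non-significant on default synthetic
  data.
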
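# Methods

This note documents the models and procedures implemented in `myelotrace`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Trace representation and geometry

An axon is a tree of branches; each branch is a 3D polyline in μm with a
precomputed cumulative arc length. Branches are maximal unbranched paths
between root, bifurcation and leaf nodes of the SWC node graph; a child
branch repeats its parent's attachment coordinate as its first point so
geometry is continuous across bifurcations. The SWC dialect is deliberately
permissive: the type and radius columns are ignored, ids are 1-based, the
parent of the root is −1, and coordinates are taken as μm.

Myelin internodes are stored as arc-length intervals `[s_start, s_end)` on
individual branches rather than as independently traced 3D polylines. This
makes coverage arithmetic exact — PLM and gap lengths are pure interval
operations on the branch parameterisation — and confines the jitter that
arises when myelin is traced in a separate image channel to an explicit,
controllable emulation (below). Intervals on one branch that overlap by at
most 0.5 μm are merged on load (rounding at shared node boundaries); larger
overlaps are rejected as inconsistent input. An interval may overshoot its
branch length by up to 10%: separately traced myelin is systematically a
little longer than the underlying axon trace when the myelin trace is more
jagged, and that excess is the very thing the PLM cap rule (below) exists
for, so it is preserved rather than clipped.

Traces are smoothed before any length computation with a centred
moving-average filter (default window 3 points) whose half-width shrinks
symmetrically toward the ends, leaving the first and last points unchanged.
A moving average is a contraction on jagged paths, so smoothing never
increases arc length; any contraction-type smoother would serve, and the
window is exposed as a parameter.

## Coverage metrics

**PLM.** For one axon, `PLM = 100 × Σ(internode length) / (total axon
length)`, pooled over the whole branch tree. If the raw quotient exceeds
100% — possible only through trace jitter — PLM is set to 99% (the cap is a
reporting convention, not a clamp at 100, so capped values are recognisable
in downstream tables). Values between 99 and 100 from honest geometry are
left untouched.

**Gaps.** A gap is the arc-length distance between two consecutive
internodes on the *same branch*; stretches before the first internode and
after the last are not gaps, and internodes may not span bifurcations
(distance "between two consecutive sheaths" is only well-defined along a
single path). Gaps of length ≤ 5 μm are nodal — the typical maximum extent
of a node of Ranvier — and everything longer is non-nodal; the boundary is
closed on the nodal side so the two classes partition the gaps exactly.
Gap analysis is computed per branch and pooled per axon.

**Population summaries.** The proportion of axons myelinated is the
fraction with PLM > 0; when an animal grouping is supplied, the mean and
SEM are taken over per-animal fractions (the mouse is the unit of
replication). Scaled myelination prevalence — regional binarized-MBP mean
intensity divided by the proportion of axons myelinated — consumes intensity
values; no image binarization is performed here.

**Axon seeding.** Unbiased axon selection uses a 100 μm grid over the image
with cells anchored at multiples of the pitch; partially covered edge cells
count (a 675 μm field has 7 cells per axis, 49 in total), and `n` distinct
cells are drawn without replacement from a seeded generator.

## FWHM diameters

A transverse intensity profile (mean gray value across the axon, averaged
over ~2 μm along it) is reduced to a diameter by full width at half
maximum. The baseline is the profile minimum — fluorescence rides on
background, so half-max is measured above it — and crossings are located by
linear interpolation between samples, using the crossings adjacent to the
global peak so that shoulder noise cannot widen the estimate. This meets 1%
accuracy on Gaussian profiles at sample spacings up to σ/5 without any
curve fitting, and is exactly invariant to additive shifts and
multiplicative scaling of the values. No point-spread-function
deconvolution is attempted; diameters are the apparent widths.

Per axon, 2–3 site measurements are averaged into a mean diameter. The
site-myelination fraction is (# myelinated sites)/(total sites) — the mean
of the per-site flags — which yields intermediate responses (1/3, 2/3, …)
when sites along one axon disagree. (A published description of this
quantity as unmyelinated/myelinated cannot be a probability in [0, 1]; the
mean-of-flags definition is the one consistent with intermediate plotted
values, and is what this package implements.)

## The myelination GLM

`P(myelinated) ~ 1 + diameter + subtype`, a binomial GLM with logit link
and treatment coding relative to a reference subtype (PV by default).
Fractional site responses are handled as binomial proportions with the site
count as weight. The fit is plain IRLS, iteration budget 100, convergence
tolerance 1e-8 on the coefficient update; the covariance is the inverse
Fisher information at the final iterate.

**Separation.** A subtype level with no myelinated (or no unmyelinated)
axons perfectly predicts the outcome and its ML coefficient diverges; IRLS
then drifts until the budget (or a singular information matrix) stops it.
Terms with |coefficient| > 10 or SE > 100 after fitting are recorded in
`separation_flags`. Separation is flagged, never regularized away: the
divergent estimate is reported as-is, matching how such rows appear in
published coefficient tables, and `d50` refuses to evaluate for a flagged
subtype.

**d50.** The diameter at 50% modeled probability is
`d50 = −(β₀ + β_type)/β_diam` (β_type = 0 for the reference). Its interval
is a delta-method normal interval on the coefficient ratio using the fit
covariance. The published table supplies only marginal SEs, so intervals
computed from it use a diagonal covariance and are approximate; point
estimates are exact. The delta method was chosen as the standard ratio
interval; no published interval construction was available to match, so
interval values are indicative only.

## Remyelination models

ΔPLM = recovery − baseline, in percentage points (±100 bounds correspond to
full loss/full gain). Lost axons are excluded from everything; axons
unmyelinated at both timepoints are excluded from the linear models (they
carry no remodeling information and would anchor the fit) but retained in
proportion summaries.

The simple model is OLS of `recovery ~ 1 + baseline`; its identity-line
crossing `x* = intercept/(1 − slope)` separates net gainers (below) from
net losers (above). The adjusted model adds the realized `baseline:ΔPLM`
interaction of each axon. **Caveat:** ΔPLM is a function of the response,
so the adjusted model is near-circular and its R² is optimistic by
construction; the form is implemented verbatim because it is the analysis
under study, and its R² should be read as descriptive, not inferential.
The model p-value is the regression F-test.

The tracing-error band is the mean of the negative ΔPLM values observed in
control animals (where no true change is expected), mirrored around zero.
PV sheath fractions are per-ROI percentages `100·n_PV/(n_PV + n_other)`
summarized as mean ± SEM over ROIs; empty ROIs are excluded with a warning.

## Group statistics

Kruskal–Wallis (tie-corrected H, χ² p with k−1 df) is the omnibus test for
PLM-like data; an all-constant pooled sample returns H = 0, p = 1 rather
than an undefined tie correction. Post-hoc comparisons are Dunn's z tests
on pooled rank means with tie-corrected variance; p values get the Šidák
correction `1 − (1 − p)^m` with m = the k(k−1)/2 comparisons actually in
the family, and confidence bounds use the Šidák-adjusted per-comparison
level so a bound excluding zero agrees with corrected p < α. Estimates and
bounds are on the rank-mean-difference scale, the scale on which the z
statistic lives. KS, paired t and one-way ANOVA delegate to scipy; a paired
test on identical samples returns (0, 1) by convention, while non-zero
constant differences are a degeneracy error.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, with defaults fixed to the study conditions where those are
reported and to documented synthetic choices where they are not:

* **Diameters**: lognormal, moment-matched per subtype. Means follow the
  reported subtype averages where available (PV 0.6, VM 0.5 μm); the other
  means (0.48–0.55 μm) and the axon-level SD (0.15 μm) are synthetic
  defaults — the published ±0.03 values are SEMs over animals, not
  axon-level SDs.
* **Myelination**: Bernoulli with probability
  logistic(β₀ + β_diam·d + β_type), using the published coefficient point
  estimates as the generative truth (SOM, which has no published
  coefficient, reuses the PO offset).
* **Internode/gap structure**: myelinated axons carry internodes of
  truncated-normal length (mean 50, SD 15, minimum 10 μm — synthetic
  defaults; the source reports only that internode lengths do not differ
  between subtypes) alternating with gaps that are nodal with probability
  0.7 (uniform on 0.5–5 μm) or non-nodal (lognormal, median ≈ 22 μm,
  truncated to 5–150 μm), starting at a uniformly drawn point within one
  mixture-drawn gap so that continuous-myelination parameterisations give
  near-complete coverage.
* **Traces**: unbranched straight polylines of truncated-normal length
  (mean 400, SD 100, minimum 100 μm), points every 5 μm. Jitter emulation
  (`jitter_sd > 0`) shrinks the trace by 1/(1+ε), ε ~ |N(0, jitter_sd)|
  capped at 9%, after laying internodes — reproducing the way myelin-trace
  jitter yields more annotated myelin than axon length and exercising the
  99% cap.
* **Intensity profiles**: a box of width = diameter convolved with a
  Gaussian PSF (exact erf form; σ = 0.1 μm default) on a constant baseline
  with i.i.d. Gaussian noise (5% of peak), 20 samples/μm.
* **Longitudinal remodeling**: expected ΔPLM declines linearly from
  +gain_at_zero at baseline 0 to 0 at the pivot (default 50%), then to
  −loss_at_full at baseline 100, plus Gaussian noise; recovery is clipped
  to [0, 99]. This encodes "weakly myelinated axons gain, continuously
  myelinated axons lose" as the simplest piecewise-linear rule.

What the generators do **not** emulate: branched morphologies (straight
unbranched traces suffice for the coverage metrics; branching effects on
myelination are not modelled), spatial correlation of internodes between
neighbouring axons, image-level noise (profiles are generated at the
intensity-profile stage, not as images), animal-level clustering, and any
dependence of internode length on diameter or subtype. Passing tests
therefore demonstrate correctness of the measurement-and-model chain, not
realism of cortical myelination biology beyond the modelled structure.

All generators are deterministic given (seed, parameters); the pipeline
splits one master seed into independent per-stage streams.

## Problem sizes and numerical choices

The analysis drivers use 60 axons per subtype (the scale of the original
survey), 200 longitudinal axons, and 10 ROIs. Parameter-recovery checks in
the test suite simulate 20,000 axons over 20 seeds for the GLM and 10,000
null datasets (3 groups × n = 20) for the Kruskal–Wallis size calibration.
Tolerances: arc-length conservation at 1e-9 μm; Gaussian FWHM at 1%
relative for spacing ≤ σ/5; IRLS convergence at 1e-8 with the brute-force
likelihood cross-check at 1e-3. Ties in Kruskal–Wallis use the standard
correction; annotation boundary overlaps merge at 0.5 μm; and the
separation thresholds (|coef| > 10, SE > 100) sit far above any plausible
finite logit effect for μm-scale diameters.

## Known limitations

* The interval representation of myelin presumes annotations were already
  assigned to the correct branch; no matching of free 3D myelin traces to
  axons is performed.
* d50 intervals from published marginal SEs ignore coefficient
  correlations.
* The adjusted remyelination model is circular by design (see above).
* Group-comparison tables reproduce the output *schema* of the published
  multiple-comparison tables; their numerical values depend on raw
  tracings that are not distributed with this package.
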
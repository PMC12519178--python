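# Methods

## The predictive model

The model assumes the vessel cross-section is well described by an ellipse
before filter placement and by a circle of equal circumference afterwards
— i.e. that filter deployment changes the shape but approximately
preserves the wall perimeter. Under that assumption the post-placement
diameter is the equivalent circular diameter

    D_eq = C/π,   C = π[3(a+b) − √((3a+b)(a+3b))],   a = D_max/2, b = D_min/2,

which collapses to the closed form
`D_eq = 1.5(D_max+D_min) − √((1.5·D_max+0.5·D_min)(0.5·D_max+1.5·D_min))`.
The two code paths (step-by-step composition and closed form) agree to
≤1e-12 relative error and are both exercised by tests.

Ramanujan's first approximation was chosen over the exact complete
elliptic integral because it is closed-form, exact for circles, and its
relative perimeter error is below 1e-4 for aspect ratios `b/a ≥ 0.3`
(physiological vessel ovality) and below 0.5% even in the degenerate
`b → 0` limit. The exact integral (`scipy.special.ellipe`) is used only
as the test oracle, never in the production path. Degenerate `b = 0`
input is rejected — vessels are never line segments — and circular input
(`D_max = D_min`) is special-cased to return the diameter exactly rather
than through `π·x/π` roundoff.

All diameters are millimetres in double precision; values are rounded to
two decimals only when formatting output.

Known model limitations: irregular (non-elliptical) cross-sections are
outside the model; inputs are assumed calibrated to millimetres
(no magnification correction is applied); perimeter preservation during
remodeling is an assumption, not a measured fact.

## Agreement statistics

Lin's CCC is computed with n-denominator (maximum-likelihood) moments.
The convention matters in small samples; it is held fixed so worked
examples are stable, and the brute-force oracle in the tests uses the
same definition. The point estimate is clamped to [−1, 1] to absorb
roundoff on near-perfect concordance.

The 95% CI is computed on the Fisher-z scale, `z = atanh(CCC)`, with
Lin's asymptotic variance

    var(z) = 1/(n−2) · [ (1−r²)p²/((1−p²)r²) + 2p³(1−p)u²/(r(1−p²)²) − p⁴u⁴/(2r²(1−p²)²) ]

where `p` is the sample CCC, `r` the Pearson correlation and
`u = (x̄−ȳ)/√(s_x s_y)` the standardised location shift; bounds are
back-transformed with tanh and therefore always lie in (−1, 1).
Simulation shows 94–95% empirical coverage at n = 50 around a true CCC of
0.9, and endpoints within a few thousandths of a 2,000-resample
percentile bootstrap. A sample with |CCC| = 1 exactly (identical vectors)
has no CI; the package reports the point value with a degenerate-CI note
instead of silently emitting ±1 bounds.

Two predictors sharing a target are compared by Δ = CCC_a − CCC_b with a
subject-level percentile bootstrap (default 2,000 resamples, seed
mandatory). The two-sided p-value is the sign-crossing fraction with
add-one correction, `p = 2(min(#Δ*≤0, #Δ*≥0)+1)/(B+1)`, capped at 1 —
so its smallest attainable value is ≈2/B, by construction. Degenerate
resamples (zero total variance) are redrawn with a hard cap. A
Steiger-style Fisher-z test of the two transformed CCCs, using the
correlation between the candidate vectors as the dependence correction,
is reported alongside and labelled; it is approximate and the bootstrap
is the principal method. The exact construction of some published
comparison intervals is not identifiable from their description, so no
attempt is made to reproduce those numbers; the bootstrap CI of the
difference is this package's design choice.

Mean differences use Student's t: paired by default for within-subject
stage contrasts (pre/post, predicted/observed), pooled two-sample for
independent groups (e.g. two filter sizes). A paired test on vectors
differing by an exact constant has divergent t; the package reports
t = ±inf with p = 0 rather than failing, and identical vectors are a
documented error. Two-sided p-values throughout; 0.05 is the
significance convention.

## The cohort simulator

The simulator emulates the measurement structure of pre/post
filter-placement studies, not any particular subject:

1. latent `(D_max, D_min)` from a correlated bivariate normal with the
   profile's means/SDs, rejection-sampled until `D_max > D_min > 1 mm`;
2. `true D_eq` from the circle-fitting model;
3. post-placement diameters `D_eq·(1±α) + ε`, `ε ~ N(0, remodel_sd)`,
   redrawn if non-positive — circularisation up to a residual anisotropy
   `α` and remodeling noise;
4. each diameter split into a symmetric edge pair `(D+δ, D−δ)`,
   `δ ~ N(0, edge_sd)`, so edge averaging recovers `D` exactly.

Defaults and why: profiles `swine` (n = 24, D_max 15.52 ± 2.82 mm, D_min
8.88 ± 2.01 mm) and `patient` (n = 62, 22.07 ± 3.99, 15.95 ± 3.99) carry
published cohort moments. The pre-placement correlation `rho = 0.5` is a
modeling choice (no published value exists) and is flagged in the output
metadata; it is exposed because the strength of the predictor-ordering
property depends on it. `α = 0.02`, `remodel_sd = 0.5 mm` and
`edge_sd = 0.2 mm` were chosen so that simulated CCC magnitudes fall in
the ranges published cohorts report (≈0.93–0.99 for D_eq against
post-placement diameters, ≈0.4–0.5 for D_max, ≈0.15–0.35 for D_min); they
are tuning constants, not estimates. The truncated bivariate normal was
preferred over a lognormal for transparency — only means/SDs are
available, no distributional family.

What passing simulator-based tests shows: that the pipeline recovers the
structure the generator put in (ordering of predictors, CCC ranges,
circularity of post diameters) under Gaussian noise. What it does not
show: behaviour under real measurement artefacts (contrast opacification,
respiratory motion, reader disagreement), non-elliptical morphologies, or
any systematic bias between imaging modalities. The simulated cohorts are
synthetic stand-ins, not reconstructions of any study's raw data.

## Pipeline and numerical choices

* CSV dialects: `raw` (eight edge columns) and `averaged` (four diameter
  columns), auto-detected from the header, never mixed; units are
  hard-coded in column names. Complete-case filtering per row with one
  warning per dropped row.
* `d_max < d_min` is strict-mode error naming the row; an opt-in
  `auto_sort` reorders with a logged warning (single-angle files may not
  be ordered).
* The agreement matrix contains exactly seven pairs (three predictors ×
  two post targets, plus post-max vs post-min); five dependent-CCC
  contrasts; four paired t tests. Degenerate statistics appear as
  structured entries, never silent omissions.
* Reports: canonical JSON (sorted keys, full precision) is lossless and,
  with the stable flag, byte-identical across reruns of the same seed;
  CSV has one row per agreement pair; text uses the agreement-class
  strings verbatim. Plotting is best-effort and never affects exit
  status.
* Seeds: every stochastic step (simulation, bootstrap) takes an explicit
  seed; the analysis derives per-contrast bootstrap seeds as
  `seed + contrast_index`.

## Test problem sizes

Calibration and ordering checks run at sizes chosen to make the suite
fast while keeping Monte-Carlo error small relative to the asserted
margins: 1,000 replicates of n = 50 for CI coverage (bounds 92–98%),
500 seeded swine-profile cohorts for the predictor-ordering rate
(threshold 95%; the measured rate is ≈100%, so the margin is wide), and
10,000 random diameter pairs for the algebraic identity.
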
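# Methods

## The measurement problem

White-matter vessel-clusters are small (median ~0.15 mL) lesion-embedded
structures.  Asking whether cerebrovascular reactivity (CVR) is reduced
in and around them runs into three practical obstacles: CVR maps are
noisy and coarser than structural images; any regional mean needs a
reference that controls for the global CVR level of the individual
brain; and "around" must be made precise.  The package's answer follows
the design of perilesional penumbra studies:

* ROIs are the cluster mask plus three concentric *shells* — Euclidean
  distance bands of 2 structural voxels each (≈ 1 CVR voxel) — clipped
  to white matter;
* the reference for each ROI is its mirror image across the midsagittal
  plane, i.e. anatomically comparable contralateral tissue;
* the spatial hypothesis ("CVR recovers with distance from the cavity")
  is an ordered-level trend test rather than many pairwise comparisons.

## Geometry

All morphology is defined through the Euclidean distance transform
(scipy), not iterated structuring elements.  This makes every operation
isotropic, spacing-aware and oracle-checkable:

* `erode(mask, r)` keeps voxels whose distance to background exceeds
  `r`; `dilate` adds voxels within `r`; both accept mm (default,
  spacing-aware) or voxel units.  The analysis mask is
  `erode(WM, 2.5 mm) \ dilate(ventricles, 2.5 mm)`, reducing partial
  volume and ventricular CSF contamination.
* shell *k* = voxels with cluster distance in `(t(k-1), t·k]`,
  `t = 2` voxels on the structural grid; cumulative expansions are
  `cluster ∪ shells 1..k`.  Shells are additionally intersected with
  the analysis mask before statistics.
* `mirror` reflects indices about a stated midline plane
  (`i → 2m − i`); no nonlinear registration is attempted.  Where a human
  rater would edit mirrored volumes by hand, this package flags
  a mirrored reference for exclusion when it overlaps any source
  cluster or falls below 50% inside white matter (both configurable).
* masks are transferred to the coarser CVR grid by footprint-coverage
  voting (`min_fraction`, default 0.5); only integer spacing ratios are
  supported, which the phantom guarantees and real data should be
  resampled to beforehand.

## Contrast statistics

For each cavitation stratum (complete vs not complete), each of the 7
levels, and each metric (CVR magnitude, CVR delay), the ipsi/contra
pair of ROI means per cluster enters a contrast.  The default is the
paired statistic on `d_i = ipsi_i − contra_i`
(`t = mean·√n/SD`, n−1 df): the paired form matches the
mean-difference/SD/t reporting convention of per-cluster analyses and
uses each cluster as its own control.  A classical pooled two-sample
*t* is available (`mode="two_sample"`).  No multiplicity correction is
applied across levels or strata; the 7 levels are nested and the
analysis is descriptive by design.

ROIs with fewer than `min_voxels` (default 5) finite CVR voxels are
flagged invalid and excluded pairwise — a size proxy for
"too small / poorly coregistered" exclusions; the attrition is always
reported so users can audit it.

## Centrifugal gradient model

Level values (cluster = 0, shells 1–3) are modelled as

    value_ij = β₀ + Σ_d β_d · c_d(level_j) + u_i + ε_ij,   u_i ~ N(0, τ²)

with `c_d` the orthonormal polynomial contrast of degree *d* over the
ordered levels (rows sum to zero, pairwise orthogonal, unit norm;
`orth_poly(4)[0] ∝ (−3,−1,1,3)`), a random intercept per cluster, and
maximum-likelihood fitting (ML rather than REML so per-stratum models
remain comparable; a `reml=True` flag exists).  Inference is Wald: the
reported CI is exactly `estimate ± 1.96·SE`.  A pooled model adds a
stratum indicator and its interaction with the linear contrast; the
interaction p tests whether the gradient differs between complete and
non-complete cavitation.

With 4 levels only degrees up to cubic are estimable; requesting a
quartic raises/caps with an explicit message.  If a stratum loses a
level entirely (validity exclusions), contrasts are rebuilt on the
levels it retains.  Two degenerate cases are handled outside the mixed
model: data with (numerically) zero residual variance — noise-free
phantoms, all-constant input — are reported via the exact OLS
projection (SE 0; p = 1 for zero contrasts), and boundary fits
(estimated τ² ≈ 0) are flagged `singular` rather than dropped.

## Per-patient models

* **Kappa.** `κ = (p_o − p_e)/(1 − p_e)` with quadratic weights
  `w_ij = 1 − (i−j)²/(R−1)²` when requested; the CI uses the
  large-sample SE of weighted kappa (Fleiss–Cohen–Everitt form), the
  p-value the null-hypothesis SE.  Point estimates are cross-checked
  against scikit-learn in the test suite.
* **Screening.** Student *t* for continuous covariates, Mann-Whitney U
  for integer-valued ordinal ones, Pearson chi-square (Fisher fallback
  on sparse 2×2) for categorical; flagging at p < 0.1 feeds the
  multivariable model on top of the preselected adjusters (age, sex,
  log10-normalised WMH volume, lacune count).
* **Logistic / proportional-odds.**  Maximum likelihood via
  statsmodels; odds ratios with Wald 95% CIs.  Perfect separation is
  raised as an explicit error, never silently reported.  Counts at or
  above `collapse_at = 4` are merged before the ordinal fit; fewer than
  3 remaining categories fall back to logistic with a warning.
* **Collinearity.**  `VIF_j = 1/(1 − R²_j)`; covariate pairs above the
  threshold (default 5) are both kept in the full model so other terms
  stay adjusted, while each partner's own OR is re-estimated from a
  model excluding the other — the standard compromise when two
  covariates (e.g. WMH burden and disease subtype) proxy each other.
* Missing covariate values are handled by complete-case analysis.

## The phantom: what it emulates and what it does not

`generate_case` builds a midline-symmetric head (ellipsoidal ICV, WM
and paired ventricles on a 1.25 mm structural grid, default 72×80×48),
places ellipsoid-based lesion clusters of the four shape classes wholly
inside white matter, and assigns cavitation grades by a fixed mix
(default 13/47/40% for none/partial/complete, the composition typical
of severe-SVD cohorts).  Completely cavitated clusters impose

    CVR(cluster) = baseline − deficit;  CVR(shell k) = baseline − deficit + slope·k

with defaults baseline 0.20 %/mm Hg, deficit 0.05, slope 0.015 per
shell level (CVR magnitude units in the literature vary with the BOLD
normalisation; the phantom fixes %/mm Hg and documents the scale rather
than asserting any particular cohort's).  CVR-grid maps are
block-averages of the structural truth field (factor 2, emulating the
coarser BOLD acquisition) plus i.i.d. Gaussian noise of SD `noise_sd`
(default 0.02).  A structural-grid copy of the field with its own
independent noise draw at the same SD is also carried, so tests can take
ROI means without block-averaging bias.  Delay maps are pure
baseline + noise (no imposed delay effect — the delay analysis is a
null by construction).

Placement guarantees make the truth exactly recoverable: clusters stay
`3 + n_shells·thickness` voxels clear of the midline (the deficit field
and shells never cross it, and mirrored references never overlap
sources), and completely cavitated clusters carry a
`2·n_shells·thickness`-voxel keep-out halo around themselves *and*
their mirror position, so no shell or mirrored reference of any cluster
touches another's written field.  Non-complete clusters write nothing
and only need a 2-voxel disjointness margin.  Placement is rejection
sampling over still-eligible centres; an infeasible request raises
rather than degrades.

Cohorts draw per-patient covariates from severe-SVD-like distributions
(age 57 ± 12, 46% male, 41% CADASIL, lacunes ~ Poisson(3),
log10-normalised WMH volume ~ N(−1.9, 0.45), …) and sample the
vessel-cluster count (0–4, top category = "4 or more") from a
proportional-odds model over a centred linear predictor with
user-specified log-odds.  Because the cumulative split at count ≥ 1 of
a proportional-odds model is itself a logistic model with the same
coefficients, one generator serves both regression layers' recovery
tests.  One RNG stream per case, keyed by (seed, case index), keeps
cohorts reproducible under parallel generation.

What the phantom does **not** emulate — and what green tests therefore
do not show about real data: realistic anatomy beyond mask topology,
SWI contrast physics or the visual rating of clusters, spatially
correlated BOLD noise, registration error between spaces (the grids are
constructed aligned), and delay effects.  Positive results on phantoms
validate the *estimators*, not the biology.

## Numerical conventions and tie-breaks

* Shape classes from spacing-aware second moments (principal-axis ratio
  a/c, regularised by the voxel's own moment) and convex-hull solidity:
  linear if a/c ≥ 3, else irregular if solidity < 0.5, else round if
  a/c < 1.5, else ovoid.  The thresholds are package choices (no
  published criteria exist) and are configurable.
* Location: centroid vs the anterior/posterior ventricular-horn
  landmarks; boundary equality resolves to "middle".
* Cavitation: cavity-voxel fraction of the cluster support; ≥ 0.9 is
  complete, exactly 0 noncavitated, else partial (thresholds
  configurable).  Grading consumes a tissue-label volume, not raw
  intensities.
* Chi-square tests are Pearson without continuity correction (Fisher
  behind a flag); on the worked-example cross-tab [[33,34],[4,23]] this
  gives p = 0.002 at 3 decimals.
* Mask resampling sets a coarse voxel at coverage ≥ `min_fraction`
  minus 1e-12 (guarding float block means); `min_fraction = 1` is a
  logical AND.
* `mirror` requires `2·midline_index` integral (voxel-centre or
  voxel-boundary planes) and drops out-of-grid reflections with a
  counted warning.

## Simulation-study sizes

The recovery studies (`perishell.recovery`) default to 100 replicates:
gradient recovery on 96×104×64 phantoms with 8 completely cavitated
clusters, sampling up to 150 structural voxels per ROI level (keeping
residual noise homoscedastic across levels, which per-level ROI means
are not, since shell size grows with k); regression recovery on
cohorts of n = 5000.  These sizes give ~95% expected CI coverage with
binomial SD ~2 percentage points, so the ≥90% acceptance line is a
robust calibration check while each study completes in about two
minutes on one CPU.

## Known limitations

* Mirroring is a pure grid reflection; real brains are not symmetric,
  and the mirrored-reference check (overlap/WM-fraction flags) is a
  coarse stand-in for the manual editing a human rater would do.
* The "poorly coregistered small volume" exclusion of real pipelines is
  represented only by the `min_voxels` size proxy.
* Only integer-ratio grid transfers are implemented; arbitrary
  resampling/registration is out of scope.
* The per-level ROI-mean trend fit assumes homoscedastic level means;
  with strongly unequal ROI sizes its Wald CIs are mildly anticonservative
  (the voxel-level route used in the recovery study avoids this).
* Proportional odds is assumed, not tested, in the ordinal layer.
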
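# Methods

## Signal model and conventions

All times are in seconds with t = 0 at stand onset; TSI is in percent. The
analysis window is the closed interval [−60, +180] s. At the default 50 Hz
sampling rate this gives 240·50 + 1 = 12,001 samples per subject. No
resampling is performed at alignment: the recording's own samples are
windowed and the grid relabeled, so devices at other rates keep their native
grid (the window-length invariant becomes 240·fs + 1).

TSI is the oxygenated fraction 100·HbO₂/(HbO₂+HHb). A zero denominator
yields an undefined sample (NaN), which is carried forward rather than
imputed; any undefined sample inside the analysis window fails QC, on the
principle that suspected measurement error excludes a recording rather than
being repaired.

## Quality control

Seven rules, each with a machine-readable reason code and the diagnostic
number that triggered it; all violated rules are reported, not just the
first, and a recording passes iff no rule fires. Interpretation choices for
thresholds stated only loosely in prior art:

- *Overall TSI range > 45* and *baseline variation > 10* are read in
  percentage points (TSI's natural unit). A `relative` switch rescales both
  thresholds, and the flatline threshold, by the pre-stand baseline mean for
  users who prefer relative percentages.
- *Baseline* is the pre-stand minute [−60, 0] s of the aligned window —
  the only pre-stand data retained in the window; *variation* is its range.
- *Flat first 30 s*: TSI range over (0, 30] s below 0.1 percentage points
  (a flatline detector for a stuck signal).
- *Chromophore near zero*: |HbO₂| or |HHb| < 0.1 μM in strictly more than a
  quarter of window samples, evaluated per channel over the aligned window
  (the retained window is what enters every later stage, so QC reads it
  too).
- *Fit factor* (sensor-agreement percentage reported by the device):
  per-sample channel or per-recording scalar both accepted; the mean must
  be ≥ 98.
- Missing stand-onset annotation fails a recording outright; a rest marker
  can additionally be required by configuration but is optional by default,
  since aligned-input tables carry no such marker.

## B-spline basis and penalized smoothing

Cubic B-splines (order 4) on [−60, 180] with full-multiplicity boundary
knots and interior knots every 2 s from −10 to +40 plus single knots at −30
and +110: 28 interior knots, 32 basis functions. The knots concentrate
where the orthostatic response varies; the sparse far-field knots encode
that baseline and late plateau are slowly varying.

Fitting solves (ΦᵀΦ + λR)c = Φᵀy per subject, with R the curvature penalty
∫φ″φ″ᵀ. Both the Gram matrix W = ∫φφᵀ and R are assembled by per-knot-span
Gauss–Legendre quadrature with 6 points per span — exact for the piecewise
polynomial integrands (degree ≤ 6) — rather than by grid quadrature, so
downstream inner products are exact. λ defaults to 1e-8 and is meaningful
in the package's fixed units (seconds, percent TSI); effective degrees of
freedom are the hat-matrix trace, and GCV(λ) = n·SSE/(n − dof)² is provided
per subject and cohort-averaged for guidance only. Curves in a cohort share
one grid, so ΦᵀΦ is factorized once and reused.

Numerical notes: the penalty's null space is the straight lines, so λ → ∞
recovers the OLS line fit (dof → 2); at λ = 0 a rank check raises an
explicit error for deficient designs; the right domain endpoint is clipped
into the last knot span so basis evaluation at t = 180 takes its limiting
value and the partition of unity holds on the closed interval.

The penalty order (curvature) and the spline order (cubic) are the standard
choices in the functional-data literature and are configurable; per-subject
fits with a common λ are used throughout (a joint fit would give identical
results on a shared grid).

## Functional PCA

With coefficients c_i and Gram matrix W = LLᵀ, the covariance-operator
eigenproblem reduces to the p×p symmetric eigenproblem LᵀCov(c)L u = ρu,
ξ = L⁻ᵀu. Divisor convention is n − 1 throughout, which makes the sample
variance of the scores f_ij = (c_i − c̄)ᵀWξ_j equal ρ_j exactly. All
components are computed and stored; retention is a view. Eigenfunction
signs are fixed deterministically: ∫₀⁴⁰ ξ_j(t) dt ≥ 0 (the post-stand
window where the response lives), ties broken by the first nonzero
coefficient being positive. Z-scores standardize each score column by its
n−1 SD; a zero-variance column is reported as zeros rather than divided.

No roughness penalty is applied inside the eigenproblem — smoothing has
already been applied at fitting — matching the two-stage smooth-then-PCA
pipeline.

## Interpretation aids

Bin averages are computed on the raw aligned TSI (not the smoothed curves):
24 consecutive 10-s bins over the 240-s window, each bin [edge, edge+10)
with the closing t = 180 sample folded into the last bin. The bin × score
correlation matrix uses Pearson correlation by default (Spearman by
configuration); it is invariant to affine score rescaling, so raw scores
and Z-scores agree. Zero-variance bins give undefined (NaN) entries.

Scree elbow: the automated rule finds the component index at which the
cumulative variance curve rises furthest above the straight chord joining
its first and last points — the point a reader would mark as the bend of a
cumulative scree plot. On cohorts with three independently varying
generative features it returns 3; on a single-mode cohort, where the curve
never leaves the chord, it returns 1. Automated retention is a convenience:
the scree table is always emitted and a manually pinned k is recorded in
provenance.

## Score regression

OLS with intercept; scores enter Z-standardized by default so coefficients
read as outcome units per between-subject SD (raw-score entry by flag).
Covariates are taken from the subject table by name; missing values are
handled complete-case with the dropped subjects reported. Inference is
classical (t distribution on residual df; HC1 robust SEs by option). Rank
deficiency is reported with the name of a redundant column. Sex is coded
0/1 with the coding left to the input table and echoed in output.

## Synthetic cohort generator

Each subject's noiseless curve is piecewise: constant baseline b before the
nadir window; a half-cosine descent from b to b − d over [τ − 5, τ]; a
half-cosine recovery from b − d to b + o over [τ, τ + 15]; constant plateau
b + o afterwards. Two half-cosine segments joined at the nadir form the
simplest continuously differentiable shape parameterized exactly by the
nadir time τ, its start and end, and the depth d. Features are drawn
independently per subject:

| parameter | default | unit | rationale |
|---|---|---|---|
| baseline mean / SD | 70 / 1.0 | % | typical forehead TSI; a ~1% between-subject spread makes the baseline mode dominant, as observed in cohort data |
| trough depth mean / SD | 2 / 0.5 | % | orthostatic TSI excursions are of order 1–2% |
| nadir time mean / SD | 10 / 1 | s | cerebral-oxygenation nadir ~10 s after standing |
| nadir start / end offsets | 5 / 15 | s | drop begins shortly after standing; recovery is largely complete by ~25 s |
| recovery offset mean / SD | −0.3 / 0 | % | recovery plateaus slightly below baseline; SD 0 by default so the default cohort varies in exactly three features |
| noise SD | 0.2 | % | high-frequency measurement noise small against the 2% response |

Draws are clipped to keep them physical (depth positive, the nadir window
inside (0, 180) s); at the default SDs clipping is a < 4σ event and does not
measurably distort the distributions. One root seed spawns an independent
RNG stream per subject, so cohort content is reproducible and independent
of generation order, and a cohort prefix is stable as n grows.

A companion outcome generator produces a transition time tied to the
standardized nadir timing (0.54 s/SD) and depth (0.28 s/SD) around a 7.26-s
mean with 0.5-s noise — the physiological pattern that slower transitions
delay and deepen the nadir — plus covariates (age, sex, BMI, medication
flags, MAP) drawn from distributions typical of a community-dwelling older
cohort, for exercising the regression stage.

What the generator does *not* emulate: beat-to-beat oscillations,
autocorrelated (pink) sensor noise, motion artifacts, the initial overshoot
sometimes seen after recovery, or any coupling between features and
covariates beyond the constructed outcome. Passing the validation suite
therefore establishes that the pipeline recovers known smooth trough
features under additive white noise — not that it is robust to artifacts,
which QC is designed to exclude rather than repair.

## Validation design and problem sizes

The test suite validates each stage against independent oracles: a
Cox–de Boor recursion for basis values, direct normal-equations solves for
the penalized fit, a dense-grid (0.1 s) weighted PCA of the smoothed curves
for eigenvalues and scores, brute-force slice means for bin averages, the
textbook correlation formula, and closed-form least squares for the
regression. End-to-end checks run the full study scale — 500 subjects ×
12,001 samples — which completes in seconds because the design matrix is
assembled and factorized once per cohort; structural unit tests use smaller
cohorts (60 subjects at 10 Hz) where scale adds nothing. Score agreement
with the dense-grid PCA oracle is asserted for spectrally separated
components only: trailing noise modes have near-degenerate eigenvalues and
their individual eigenvectors are not identifiable across routes.

## Known limitations

- Dense common-grid curves only; no sparse/irregular-sampling fPCA
  (PACE-style conditional scoring) and no multivariate fPCA across signals.
- Only the B-spline basis is implemented behind the basis interface.
- The elbow rule is a heuristic; parallel analysis / permutation retention
  is a hook, not implemented.
- Survey weighting and any population-representativeness correction are out
  of scope; results describe the analyzed sample.
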
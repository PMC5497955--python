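# Methods

This note documents the models and procedures implemented in
`valvedim`, the defaults and why they were chosen, what the synthetic
populations do and do not emulate, and the numerical decisions made
where the design was genuinely open.

## Measurement model

**Valve size and shape.** Valve size is the area of the digitized
outline in lateral view (shoelace formula via `shapely`, orientation
invariant); valve shape is the length-to-height ratio. Both are
natural-log transformed, which makes sex differences proportional and
comparable across species. Length and height are taken from a direct
least-squares conic fit constrained to an ellipse (the Halir–Flusser
formulation, via `skimage.measure.EllipseModel`): deterministic,
non-iterative, exact on noise-free elliptical data. A second-central-
moment (inertia) ellipse is the fallback when the conic solution is
degenerate; it is flagged on the result. **L and H are the full axes
(2a, 2b), not semi-axes**: whole adult *Cyprideis* valves run roughly
900–1200 μm long, which only the full-axis convention reproduces, and
L/H is identical under either convention. Outlines are used at the
digitized points as given — no spline resampling or smoothing, since
none is part of the measurement definitions.

**Limb measurements.** Linear dimensions are Euclidean distances
between two named landmarks; curve lengths are polyline lengths over
ordered semilandmarks; the "linear length" of a curved podomere is the
chord from first to last semilandmark. Curve length ≥ chord always,
with equality only for straight segments; the difference (curve −
chord) per side feeds the clasping-leg curvature index.

**Logs.** Natural logarithm everywhere. The base only shifts
intercepts; slopes, correlations, t statistics and p-values are
base-invariant, so printed intercepts should be read with the base in
mind.

## Bilateral asymmetry and side combination

Limbs and hemipenis components are measured on both sides where
preservation allows. Directional asymmetry per species/sex/variable is
mean(L−R) over complete side-known pairs with a symmetric paired-t 95 %
CI and a two-sided p against zero. A percent-scale version,
100·(L−R)/L, and its cumulative mean support the check that asymmetry
estimates stabilize as n grows.

Because sides are not interchangeable, values are reduced to one
left-equivalent number per specimen and variable: left alone is used as
is; right alone is converted through a per-species OLS regression of
left on right; when both are present the observed left and the
converted right are averaged. With no asymmetry this rule reduces
exactly to the plain L/R mean. Left-on-right regressions pool sexes
within species: the conversion is a nuisance step with r² ≥ 0.9, and
pooling maximizes n (sex-specific intercept differences are negligible
at these r² values). The width-asymmetry sign convention is L−R
throughout, so transformed (wider, more curved) male right legs give
negative values.

Specimens whose side labels were lost at dissection have the larger
limb assigned to the left. They are flagged and excluded from
asymmetry estimation — asymmetries are small compared to
between-individual variation, so the assignment is safe for
size-related analyses but would bias L−R estimates — and retained
everywhere else.

## Missing data

The two composite-trait matrices (four log reference-limb lengths; the
three log basal-capsule support lengths, males only) are imputed under
a multivariate-normal model rather than dropping specimens. EM
maximizes the MVN likelihood under MAR (convergence when the largest
parameter change drops below 1e-8, at most 500 iterations; on complete
data the estimates are the closed-form ML mean and covariance after one
pass). Stochastic completions follow the bootstrap-EM scheme: each
draw re-runs EM on a row-resampled copy, then samples missing cells
from their conditional normal given that row's observed cells; 500
draws are averaged cellwise for point estimates. Averaging many
conditional draws reduces imputation variance relative to any single
draw; observed cells are bit-identical throughout. A
`bootstrap=False` flag skips the per-draw re-estimation for speed when
parameter uncertainty is immaterial (tests, replicate studies).

Imputation runs strictly within dataset and within species — basal
capsule variables only ever impute other basal capsule variables, and
only within one species — enforced by the pipeline, not left to the
caller. Variables enter on the log scale, where the generative model
is closer to multivariate normal; Royston's H test (the 1992
normalizing transformation of per-variable Shapiro–Wilk statistics
with an equivalent-degrees-of-freedom correction for inter-variable
correlation) checks the assumption on the complete-case rows. Its
type-I error at α = 0.05 sits at ~0.05 in simulation (1000 MVN
datasets, n = 50, p = 4). A ridge of 1e-8 stabilizes near-singular
covariance solves.

## Statistics

* **Dimorphism**: M−F difference of log means, with Welch's
  unequal-variance t and Satterthwaite df. Groups are ordered
  female-first, so species with larger males give negative t. Welch is
  forced by the fractional dfs this kind of data reports.
* **Composites**: soft-part size is the mean of four log limb lengths;
  basal-capsule size the mean of three log support lengths. Sum versus
  mean of logs differ by a constant factor, which no correlation, t,
  df or p anywhere downstream can see; this affine invariance is
  asserted in the tests.
* **Static allometry**: OLS of log(trait) on log(√area) within
  species, so a length-dimension trait has expected slope 1 under
  isometry; terminal-extension area regresses on log(area) directly
  (same dimensionality). 95 % t-based CIs on both coefficients,
  adjusted r², p for slope = 0 and for slope = 1.
* **Evolutionary allometry**: the same fit through species means of the
  male data — computed, but flagged `evolutionary`, being a 3-point
  regression.
* **Partial correlations**: Pearson correlation of the residuals of
  male trait and valve trait on soft-part size; df = n − 3; p from
  t = r·√(df/(1−r²)). Equality with the multiple-regression
  coefficient p is asserted to 1e-10 in the tests (with
  `pingouin.partial_corr` as a second independent cross-check).
* No multiple-testing correction by default, so single-test p-values
  are directly comparable to per-cell significance marking; a Holm
  option exists (`RunConfig(holm=True)`).

## Synthetic populations

The generator produces the study conditions the analyses assume: three
species × two sexes (50 specimens per sex by default), a latent
body-size factor s = log(√valve area) per specimen that drives every
dimension through log-linear allometries (reference-limb slopes
0.63–0.77, basal capsule 0.85, terminal extension 0.35/1.18 — the
within-species regression scale typical of these limbs), log-scale sex
offsets in valve size (0.002–0.047, one species effectively
monomorphic in size) and shape (0.08–0.10; males always more
elongate), limb directional asymmetry of 0.75 % left-larger and
hemipenis asymmetry 0.5 % right-larger, left valves larger and less
elongate than right, the male-only widening (+20 %) and curving
(κ 0.03 → 0.10) of the right first walking leg, MCAR missingness of
2.7 %/1.7 % in the soft-part/basal-capsule datasets, 8 % single-side
loss, 5 % lost side labels, and ~0.4 % per-side log measurement noise
(which puts left-on-right r² in the mid-0.9s). Male hemipenis
residual variation loads on valve size through two latent factors
(basal capsule and terminal extension), giving population partial
correlations of ~0.4–0.66 against valve size and ~0 against shape.

Valve outlines are exact ellipses with ~1 μm radial noise digitized at
100 points; curves are circular arcs with the intended curve and chord
lengths; linear dimensions are landmark pairs. Geometry re-extraction
therefore recovers tabulated values exactly for distances and to
discretization error (<1 %) for areas and curve lengths. Missingness
and side-label loss live in the measurement table, emulating loss at
dissection; landmark sets represent the complete digitization.

What the generator does **not** emulate: real valve outlines are only
approximately elliptical (hinge irregularities, posterior elongation
asymmetries), instar structure and growth are absent, missingness in
real dissections is probably not exactly MCAR, and species differences
are reduced to scale and offset shifts. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every feature of real specimens.

**Estimands for recovery checks.** The side-combination step predicts
left values from right values by regression; at finite r² those
predictions shrink sex extremes slightly toward the pooled mean, so
the procedure's large-n dimorphism value sits a fraction of a percent
below the generative offset (and allometric slopes are slightly
attenuated by measurement noise in the size proxy). Unbiasedness is
therefore checked against the procedure's own large-n value, computed
by vectorized Monte-Carlo (`population_dimorphism`,
`population_allometry_slope`, `population_partial_r`, n = 200k–400k),
not against the raw generative parameter. A genuinely-null
configuration (`null_truth`) additionally removes the size dependence
of the hemipenis traits, because with a noisy body-size proxy any
size-scaling trait retains a positive partial correlation with valve
size (residual confounding) even with no direct effect.

## Problem sizes and determinism

The replicate study used for acceptance runs 200 populations (plus 100
null populations) at 50 specimens/sex with 10 plain conditional draws
per imputation; single full-fidelity runs use 500 bootstrap-EM draws.
These sizes give Monte-Carlo SEs small enough to resolve biases of a
fraction of a percent while keeping a replicate under half a second.
All randomness in a pipeline run descends from one root seed through
`numpy.random.SeedSequence` spawning; identical inputs, configuration
and seed reproduce every output bit for bit, and the landmark-geometry
stream is separated from the measurement stream so tables are
identical whether or not landmark sets are generated.

## Known limitations

* The TPS reader covers the tpsDig key set used for these data types
  (LM, CURVES/POINTS, OUTLINES, ID, IMAGE, SCALE, case-insensitive);
  other keys are preserved as opaque metadata, not interpreted.
* Ellipse "length" assumes the valve outline is well approximated by
  an ellipse; strongly non-elliptical outlines will still fit but L/H
  loses its intended meaning.
* Evolutionary allometries rest on three species means and are
  reported for completeness, not inference.
* Royston's test supports 4 ≤ n ≤ 2000 (the range of its normalizing
  approximation).
* Fluctuating-asymmetry decomposition, Procrustes/Fourier outline
  analysis and phylogenetic correction are out of scope.
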
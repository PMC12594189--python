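# Methods

This note documents the statistical procedures, parameter defaults and
numerical choices implemented in `morphme`, and what the synthetic
generator does and does not emulate.

## Shape analysis

**Superimposition.** Each configuration of L 2D landmarks is centred,
scaled to unit centroid size (CS, the square root of the summed squared
distances of landmarks to their centroid), and rotated to minimize its
summed squared distance to a consensus that is re-estimated each round
(generalized Procrustes analysis).  The 2D optimal rotation is computed
in closed form (`atan2` of the cross- and dot-products with the
target); reflections are excluded by construction, which is the correct
choice here because all records view the same structures in the same
orientation.  The consensus is initialized from the first record,
re-centred and rescaled to unit CS each iteration, and iteration stops
when its Frobenius change falls below 1e-10 (maximum 100 iterations; in
practice 3–6 suffice).  The fixed point is independent of
initialization for data in this dispersion regime; the absolute
rotational frame of the output is not unique, so tests compare shapes,
distances or statistics, never raw frames across separate fits.

**Tangent coordinates.** Aligned shapes lie on the unit sphere in
R^(2L); statistics are computed in the tangent plane at the consensus,
obtained by projecting each aligned vector orthogonally to the
consensus direction.  With unit-CS pre-scaling the data have 2L − 4
informative dimensions.  `tangent_diagnostic` regresses tangent
(Euclidean) on geodesic (arccos of the inner product) pairwise
distances through the origin; for within-population dispersions both r
and the slope are ~1 (the worked example prints r = 1.000000,
slope = 0.9996), which is the regime in which Euclidean multivariate
statistics on tangent coordinates are valid.  Tangent distances are
mathematically never larger than geodesic ones, so slopes are ≤ 1.

**Summaries.** Shape distance defaults to the Euclidean distance
between aligned coordinate vectors (the tangent proxy; the geodesic
form backs the diagnostic).  PCA is an eigendecomposition of the
sample covariance of tangent coordinates, with each eigenvector's
largest-magnitude loading forced positive so that signs — which are
mathematically arbitrary — are reproducible.  Phenograms use standard
agglomerative clustering (UPGMA = average linkage, NN = single
linkage) via `scipy.cluster.hierarchy`, exported as trees through
scikit-bio; scipy's deterministic tie handling provides the tie-break.

## Error ANOVAs

**Hierarchical (type I) Procrustes ANOVA.** Sequential decomposition
sex → individual(within sex) → residual on the stacked tangent
coordinates; the residual is total measurement error (totME).  Degrees
of freedom are multiplied by the shape dimensionality 2L − 4 (for the
default design: sex 48, individual 2688, totME 19,488).  Goodall-type
F statistics compare each mean square with the hierarchically lower
level (sex over individual, individual over totME) with parametric
p-values from the F distribution.  This design is conservative for the
individual-vs-error comparison because group differences are removed
first.  A Pillai-trace MANOVA of the sex effect is available as an
explicitly approximate extra, computed on the PC scores of individual
mean shapes (the error SSCP must be full rank, so scores are truncated
to at most n_individuals − 3 dimensions).

**Measurement-error (type II) ANOVA.** Each individual's REP records
are centred on the individual's own mean; the centred data are
decomposed into a REP main effect (systematic error, systME), a
REP × sex interaction, and a residual (random error, randME), with
type II sums of squares obtained by full-vs-reduced model comparison.
On the complete, balanced grids this package requires, the group
margin of the centred data is exactly zero, so the type II projections
reduce to REP-mean and cell-mean cross-products; tiny-instance tests
verify the equivalence against explicit design-matrix least squares to
1e-10.  The individual effect is computed from the uncentred data
(R · Σᵢ‖mᵢ − grand mean‖²).  The test statistic for every effect is a
signal-to-noise ratio of sums of squares, SNR = SS(effect)/SS(randME)
— the same ratio form for the individual effect, which at the default
design yields SNR(individual) ≈ 5.6 with SNR(systME) ≈ 0.15.  Effect
sizes are Rsq = SS(effect)/SS(total) with the total from the uncentred
data, so the type II components need not sum to 100%.  Degrees of
freedom: systME R − 1; interaction (R − 1)(G − 1); randME
n − 1 − (n_ind − 1) − (R − 1) − (R − 1)(G − 1), i.e. 7 + 7 + 392 for
the default design.

**Permutation tests.** systME and the interaction are tested by
shuffling REP labels within each individual's centred records — a
residual-randomization scheme that preserves the individual structure
and keeps the design balanced under permutation — recomputing the SNR
each time, with p = (b + 1)/(m + 1) and a default of 999 permutations
(a seed is mandatory in the API).  That scheme leaves the individual
sum of squares invariant, so it cannot test the individual effect; for
that effect records are instead permuted freely across individuals,
which is the natural exchangeability under "no individual
differences".  Under the zero-bias generator the systME p-values are
uniform and the rejection rate at α = 0.05 sits inside its binomial
band (checked over 200 replicate datasets at 199 permutations).  A 0/0
SNR (no signal and no noise, as in degenerate noiseless data) is
reported as 0.

**EV ordination.** Axes maximizing systematic relative to random error
variance solve the generalized eigenproblem of the systME cross-product
matrix against the randME cross-product matrix.  The randME matrix is
rank-deficient in shape space, so whitening uses a pseudo-inverse with
eigenvalues below 1e-10 × the largest dropped; in addition, its
spectrum is shrunk within the informative subspace by a Ledoit–Wolf
estimate (default `shrinkage="lw"`; a float fixes the intensity,
`None` disables shrinkage).  Shrinkage matters: with ~400 residual
vectors in ~50 dimensions, the sample covariance's eigenvalue
dispersion (Marchenko–Pastur) visibly rotates whitened axes even when
the true random error is isotropic — without shrinkage the leading
axis recovers an injected bias direction only to |cos| ≈ 0.93, with it
to |cos| > 0.99 — while genuinely heterogeneous error structure is
retained.  The leading R − 1 axes are reported, ordered so that the
fraction of systematic-error variance they capture is non-increasing
(these fractions refer to the systematic subspace only, not to total
shape variance).  Note that under strongly landmark-heterogeneous
noise the *ratio*-maximizing axes legitimately differ from the raw
bias direction (they are noise-whitened); alignment statements assume
near-isotropic noise.

**Time-lag series.** The reference session is paired with every other
session in turn; each two-REP subset is re-superimposed before its
error ANOVA, because the Procrustes fit depends on the records
included.  Comparisons are ordered by day lag.  Unbalanced REP counts
are not supported (the complete-grid precondition enforces balance).

## Per-landmark precision

Because all REPs of an individual are digitized on one photograph, raw
coordinates are comparable across REPs and per-landmark imprecision is
meaningful before any superimposition: V[i, l] = var(X) + var(Y) across
the R REPs (sample variance, denominator R − 1 — the standard unbiased
choice), in mm².  Summaries per landmark are the median, 90th
percentile (linear interpolation; the interpolation rule is exposed
because it can move boundary flags), mean and SD across individuals.
Medians and 90th percentiles are standardized by their respective
medians over landmarks — a standardized median of 0.5 reads "half as
imprecise as the typical landmark" — and summed into a combined index
used for colour-grading plots (emitted as a data column; rendering is
out of scope).  Configuration selection removes landmarks strictly
exceeding the threshold on *both* standardized axes (1.5 → "precise"
set, 1.0 → "most precise" set); boundary cases are retained, selection
is idempotent and monotone in the thresholds, and reduced
configurations are always re-superimposed from raw coordinates.

## Signal robustness

Sex and allometry are tested per session with single-predictor
multivariate regressions of all tangent coordinates on a sex dummy
(F = 0, M = 1) or on CS (linear CS by default, log-CS as an option),
using Rsq = SS(model)/SS(total), the one-predictor pseudo-F, and
permutation of the predictor across individuals (999 default,
(b + 1)/(m + 1)).  Classification uses leave-one-out nearest group
mean in the full tangent space (equivalent to classifying on
between-group PC scores); ties are broken toward the first group and
counted.  For near-balanced exchangeable groups the expected average
hit rate is 50%.  Congruence between sessions is summarized by the
absolute Pearson correlation of PC1 scores (absolute because PC signs
are arbitrary) and by Pearson correlations of the vectorized
lower-triangle within-session distance matrices, reported as median
and 10th/90th percentiles over the R(R − 1)/2 pairs.

The mixed-design ("visiting scientist") simulation composes one record
per individual — females from one session, males from another (or from
an average over sessions) — re-superimposes the composite from raw
coordinates (records from different Procrustes fits are never mixed),
and reruns the sex and allometry tests plus the hit rate.  A session
bias adds to the between-sex contrast even when orthogonal to it (the
diagonal of a rectangle is longer than its side), so small effects
like sexual dimorphism inflate markedly while an effect ~4× larger
(allometry) barely moves; both behaviours are verified in the
acceptance tests.  Averaging k sessions with independent noise shrinks
residual error variance about k-fold; averaged records are rescaled by
the individual's mean CS so downstream analyses treat them like raw
configurations.

Centroid size gets its own bias check: a per-sex one-way
repeated-measures ANOVA of CS with session as the within-subject
factor, F = MS(REP)/MS(residual) on (R − 1), (R − 1)(n − 1) df,
uncorrected for sphericity (the correction choice is noted in the
result, not applied), alongside per-session per-sex CS medians and
their differences.

## The synthetic generator

For individual i with sex s and size CSᵢ (per-sex lognormal):

    Sᵢ = template + δ·1[s = M] + β·(log CSᵢ − mean log CS) + εᵢ
    record(i, r) = CSᵢ·Rᵢ(Sᵢ) + tᵢ + b_r (+ b_{r,s}) + noise

with εᵢ iid N(0, σ_ind²) per coordinate, one rotation Rᵢ (±3° jitter)
and translation tᵢ per individual reused across all its sessions (same
photograph), session bias b_r in mm added on the raw scale, and
per-landmark noise N(0, σ_l²) per coordinate.  The template is a fixed
26-landmark half-outline of a marmot-like ventral cranium (unit CS).

Defaults (units; rationale):

- 58 individuals (32 F / 26 M), 26 landmarks, 8 sessions at day
  offsets 1, 1, 2, 4, 11, 41, 121 and 7300 — the repeated-digitization
  design the analysis chain expects.
- CS medians 133.5 mm (F) / 136.5 mm (M), log-SD 0.04: adult cranial
  sizes with a 3 mm median sex gap, small relative size dispersion.
- σ_l: per-landmark summed X+Y noise variances spanning 0.2–0.9 mm²
  (near five-fold, linearly in variance across landmarks): realistic
  digitization precision on photographs, heterogeneous enough for the
  precision ranking to be recoverable (Spearman ρ > 0.9 at study
  scale).
- σ_ind = 0.0078 shape units per coordinate; sex effect ‖δ‖ = 0.0205;
  allometric slope ‖β‖ = 0.54 per unit log-CS.  Together these place
  individual variation at ~82% of shape variance, total error at
  ~17%, sexual dimorphism at ~2% (small, generally non-significant at
  n = 58) and allometry at ~10% (about four times the sex effect,
  always significant) — the regime of a within-species cranial
  photograph study where error analysis is genuinely informative.
- b_r: zero for the reference morning session, near-zero for the
  same-day repeat, moderate for day-to-months lags and ~3× larger for
  the decades-old session, with directions drawn once from a fixed
  design RNG and weighted toward the noisier landmarks (an operator
  re-sees ill-defined points, not sharp ones).  Magnitudes were
  calibrated once with `expected_variance_components` (the Monte-Carlo
  oracle over fresh datasets) so that the systematic component lands
  at Rsq ≈ 2.2% overall and the same-day pairwise comparison is
  negligible (≈0.2%); they are design constants of the parameter set,
  not functions of the dataset seed.

`null_params` removes the biases *and* makes the sexes fully
exchangeable — including equalizing the per-sex CS distributions,
because with size dimorphism left in, allometry induces a genuine
sex-linked shape difference and the "null" would not be null for tests
of sexual dimorphism.

**What the generator does not emulate:** repositioning between
photographs, camera/lens effects, 2D projection error of a 3D
structure, multiple operators, outlier gross misplacements
(noise is Gaussian), spatially correlated noise between neighbouring
landmarks, and missing data.  Passing tests therefore demonstrate that
the analysis chain recovers the structure it models — not that real
digitization error is Gaussian or session biases are constant vectors.

## Problem sizes and determinism

Unit tests run on reduced designs (typically 3–20 individuals, 6–8
landmarks); study-level checks use the full 58 × 8 × 26 design.  The
type-I calibration uses 200 replicate null datasets with 199
permutations each; bias-recovery truth uses 50 Monte-Carlo replicates;
the acceptance script averages variance decompositions over 10
replicate datasets.  These sizes were chosen to make Monte-Carlo error
small relative to the tolerances being checked.  All randomness flows
from explicit seeds; `run_study` derives documented sub-seeds from the
single config seed and reproduces its JSON report byte for byte.

## Known limitations

- Exact numerical parity with other implementations of the
  measurement-error ANOVA is not promised: the decomposition is defined
  here by its model-comparison construction and verified against
  brute-force least squares, and permutation schemes differ across
  implementations.
- Unbalanced or incomplete grids are rejected rather than approximated.
- The parametric Procrustes ANOVA treats coordinates as exchangeable
  (Goodall's isotropy assumption); its F tests are conservative
  summaries, and the permutational tests should be preferred for
  inference.
- EV axis alignment with a raw bias direction degrades under strongly
  heterogeneous noise by design (whitening); interpret EV loadings in
  the whitened metric.
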
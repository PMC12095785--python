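# Methods

This note documents the models, numerical choices, and synthetic-data design
behind `plastmap`, and what the test results do and do not show about real
data.

## Feature matrices

**MPC.** For each node the depth-wise MT intensity profile is residualized on
`[1, mean profile]` across depths (the cortex-wide mean profile acts as the
control variable), pairs of residual profiles are Pearson-correlated, and the
correlations are Fisher r-to-z transformed. Correlations are capped at
1 − 1e-7 before `arctanh` so that perfectly collinear profiles (possible in
noise-free synthetic data) stay finite. Negative edges are clipped to zero by
default — required because the downstream affinity kernel assumes non-negative
similarity — with the clipping exposed as a switch (`clip_negative`) since it
belongs to the embedding step, not to the covariance itself. The diagonal is
zeroed. Constant profiles raise a `DegenerateNodeError` naming the node.

**FC.** Plain Pearson correlation of node time series, diagonal one. No
Fisher transform is applied before the affinity step: the kernel is rank-based
through row thresholding and insensitive to monotone transforms.

## Gradients and dispersion

The affinity keeps, per row, the top ⌈10%·n⌉ entries of the feature matrix
(sparsity 0.9) and measures similarity between thresholded rows with the
normalized-angle kernel 1 − θ/π; the matrix is symmetrized by averaging. The
embedding is a diffusion map with density-normalization exponent α = 0.5. At
diffusion time t = 0 components are scaled by λ/(1−λ) (multiscale convention);
t > 0 scales by λᵗ. The trivial constant eigenvector is dropped, components
are ordered by eigenvalue, and each component's sign is fixed by making its
largest-magnitude coordinate positive (the eigen-sign is arbitrary).

Alignment topology: one template per modality is embedded from the
grand-average feature matrix over all subjects and sessions; each
subject/session embedding is Procrustes-rotated (rotation + reflection, no
scaling) onto that template. This makes dispersion comparable across subjects
and sessions without chaining pairwise alignments. Dispersion statistics are
invariant to any common orthogonal transform of the gradient rows, which is
what justifies Procrustes alignment in the first place.

Dispersion uses exactly G1–G3 even when more components are computed.
Within-network dispersion is the **sum** (not the mean) of squared distances
to the centroid; it therefore scales with network size. This is deliberate and
documented rather than "corrected": comparisons are always within a network
across sessions or subjects, never across networks of different size.

## Behavior

Learning rate is the slope of the least-squares fit accuracy = a + b·ln(t)
over training sessions (t = 1, 2, 3, …). Regression models z-score the
outcome and the three dispersion-change predictors (VN-within, FPN-within,
VN-FPN-between, one modality per model); the overall-model permutation p uses
the add-one Monte-Carlo estimator (1 + #{F_perm ≥ F_obs})/(1 + n_perm), which
can never be zero. Permutation loops compute F through a pre-factored QR basis
— algebraically identical to the full fit, verified against it by the oracle
tests. The specificity permutation randomly reorders each subject's baseline
and pre-training sessions into pseudo pre/post pairs and reports the fraction
of significant pseudo-models together with its complement (the "k of n,
p = 1 − k/n" convention). LOOCV refits the unstandardized model per left-out
subject; the tests pin it to the closed-form leverage identity
e_i/(1 − h_ii).

## Gene-map association

X (nodes × genes) and Y (nodes × 6 gradient-change maps) are column
standardized with the population-SD convention (divide by n); the convention
affects no test conclusion and is stated here for exactness. PLS is NIPALS
with deflation: per component, the weight/score iteration is run to
convergence, X and Y are deflated by the X-score rank-1 terms, and the
fraction of total Y variance explained by component i is ‖tᵢcᵢᵀ‖²/‖Y‖².
P is defined by deflation (so X = TPᵀ + E exactly); Q is the regression
loading of the original Y on the Y-scores (so Y = UQᵀ + F exactly). Component
signs are fixed by making the strongest gene weight positive. The
implementation is cross-checked against scikit-learn's independent NIPALS to
1e-6.

Component significance permutes the rows of Y jointly across its six columns
(preserving the inter-map correlation structure) or, when surrogates are
supplied, replaces Y with spatial-autocorrelation-preserving surrogate blocks.
Gene stability resamples nodes with replacement, refits, Procrustes-rotates
each bootstrap's weight matrix onto the observed one (removing arbitrary axis
rotations/reflections across resamples), and normalizes the observed weights
by the bootstrap SD. FIQT converts |z| to two-sided p, Benjamini–Hochberg
adjusts, and maps back to the z scale with the original sign; |z_adj| ≤ |z|
always. Genes with |z_adj| > 1.96 enter enrichment.

**Bootstrap resampling unit.** Nodes are the observations (n = 200 nodes
versus thousands of genes is the regime PLS is chosen for), so nodes are
resampled.

**Response maps.** Y uses group-mean aligned-gradient change maps (post −
pre), giving one map per gradient per modality; this matches the node count of
the expression matrix.

Surrogate maps are variogram-matching: permute the source values, smooth with
a Gaussian distance kernel, blend back a fraction of unsmoothed permutation
noise, choose the (length scale, noise fraction) pair per surrogate that best
matches the source semivariogram, and rank-remap onto the exact source value
multiset. Variograms use quantile distance bins and drop pairs beyond half the
maximum distance (the usual geostatistical range of validity). This is a
geometry-agnostic null — it needs only node coordinates, not a sphere — and
its limitation is inherited from stationarity: single realizations dominated
by a large-scale trend (whose variogram exceeds the sill) cannot be matched
exactly by any stationary surrogate family.

## Enrichment

One-sided hypergeometric over-representation against a user-supplied
background, BH-corrected across sets (Bonferroni and uncorrected variants
exposed); an optional EASE-style correction (overlap − 1) mirrors DAVID-like
scores. Gene sets are read from GMT files. The hypergeometric tail is checked
against exact combinatorial enumeration for small backgrounds.

## Synthetic cohorts

The generator produces every pipeline input on a smooth 2-D sheet embedded in
3-D with seven spatially contiguous network patches (angular wedges; VN and
FPN non-adjacent). All randomness flows through named streams derived from a
single seed; identical configs produce identical bytes.

Three ground-truth effects are planted, all driven by one standard-normal
per-subject effect:

- **Microstructure.** Each node's multiplicative depth-shape perturbation
  mixes a shared network direction with an idiosyncratic direction in a
  4-function smooth depth basis. VN/FPN nodes carry baseline mixing
  heterogeneity; post-training the heterogeneity shifts by 0.6 per unit
  subject effect (FPN at half the VN gain), so within-network profile
  decoherence — hence MPC dispersion — is a monotone, deterministic function
  of the effect. Earlier designs that modulated only perturbation *amplitude*
  failed: amplitude cancels from correlations of low-rank shapes.
- **Function.** Node time series are multivariate Gaussian draws from a block
  correlation (0.5 within VN/FPN — so their structure dominates the leading
  gradients — 0.25 within other networks, 0.10 between). FPN nodes carry
  coherence factors s_i = 1 − h·g_i whose heterogeneity h grows by 0.4 per
  unit subject effect post-training, rescaled to preserve the mean FPN
  coupling: the within-FPN covariance spread widens without moving the FPN
  centroid. The construction R = D S D + (I − D²) is positive semidefinite by
  the factor-model identity.
- **Behavior.** accuracy(t) = a + b_s·ln(t) + noise clipped to [0, 100], with
  b_s = 8 + 1.2 × subject effect (percent accuracy per standard deviation of
  the effect) and session noise SD 0.5%.

Gene expression is a squared-exponential Gaussian random field per gene plus
iid noise; planted genes add effect × standardized phenotype map (the pipeline
uses the first principal component of the actual group-mean change maps as the
phenotype, so the planted association is carried by the very maps the analysis
regresses on). Defaults: effect size 3, correlation length 0.005 — *below* the
typical inter-node spacing (≈0.035 at 200 nodes), i.e. the gene noise fields
are effectively node-exchangeable at default. This is a deliberate modeling
choice: node-bootstrap z-scores are only calibrated for exchangeable noise,
because a bootstrap over nodes cannot see spatial dependence; with strongly
autocorrelated null genes the z-scores are overdispersed and no FDR statement
survives. The correlation-length knob remains fully functional (the variogram
range grows monotonically with it, and the surrogate machinery addresses
autocorrelation in the *response maps*), but users planting strong gene-field
autocorrelation should interpret per-gene significance through the surrogate
null, not the bootstrap z alone. This is also the main respect in which
passing tests do **not** certify behavior on real atlas expression data, where
spatial smoothness is substantial.

The effect scales above (0.6, 0.4, 1.2, 3.0) were chosen once, as study
conditions for the synthetic cohorts, to place the planted effects at
moderate-to-strong detectability for cohorts of 16–20 subjects — the regime
where the chain's recovery properties are informative; they are free
parameters of the generator, not claims about any empirical effect size.

## Problem sizes

The test suite runs cohorts of 6–20 subjects on 42–80 nodes with 100–300
genes, calibration at 200–300 null simulations, and recovery at 50–100
simulated cohorts; the acceptance script runs the full default conditions
(200 nodes, 2000 genes, 20 subjects, 500 permutations, 200 bootstraps). All
sizes are the package's own choices balancing statistical resolution against
a single-CPU run.

## Known limitations

- The dispersion pipeline assumes every subject/session yields a connected
  affinity graph; disconnected graphs abort with a named error rather than
  being patched.
- Surrogate maps are stationary and isotropic; trend-dominated maps are
  matched only approximately (see above).
- The intervention analysis reports control-normalized descriptives only;
  repeated-measures ANOVA machinery is out of scope.
- ``n_sessions`` supports the two designs used here (pre/post with optional
  baseline), not arbitrary longitudinal layouts.
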
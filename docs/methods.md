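# Methods

## Multi-block factor analysis

**Model.** Let X_b (n subjects × 12 items) be the questionnaire block at
time point b ∈ {1..4}, the blocks forming a 2 × 2 day × run design.  Each
column is centered and (by default) scaled to unit variance within its
block; rows carry mass 1/(n−1) so a standardized column has unit inertia.
Block b receives weight α_b = 1/σ²_b1 with σ_b1 the first singular value of
the standardized block, so that every block's leading dimension contributes
the same inertia to the grand analysis.  With the *nested* option (default
on), α_b is further divided by the squared first singular value of the
base-weighted concatenation of b's day group (blocks 1&2 vs 3&4) and of its
run group (blocks 1&3 vs 2&4), removing inertia shared at each level of the
crossed design.  The nested arithmetic is a declared choice — the two-level
normalization is described only qualitatively in the MFA literature for
crossed designs — and reduces exactly to standard MFA with `nested=False`
or when the groups are degenerate.

**Decomposition.** The generalized SVD of the concatenated table with
column weights A = diag(α) and row masses 1/(n−1) gives eigenvalues
λ_ℓ = δ²_ℓ, generalized axes Q (QᵀAQ = I), loadings q_ℓ = Q_ℓ δ_ℓ,
compromise scores F = X A Q and partial scores F⁽ᵇ⁾ = K α_b X_b Q_b.
Exact identities (enforced to 1e-10 in tests): mean_b F⁽ᵇ⁾ = F
(barycenter), Σ_{j,b} ctr_{j,b,ℓ} = 1 with ctr = α_b q²/λ_ℓ, and the mean
over items of block-summed contributions = 1/12.  Component signs are fixed
by making the largest-magnitude loading positive; analyses of real data
should interpret score directions relative to the loading signs.

**Bootstrap reliability of loadings.** For each item the 4 per-block
contributions of a component are resampled with replacement (4 draws,
summed), `n_boot` = 10,000 times; the percentile interval at level 1 − α
(α = 0.05, divided by 12 under Bonferroni, both reported) is compared with
the equal-share value 1/12.  *Known limitation:* with only 4 values the
resampling distribution has 256 atoms, so the lower percentile saturates at
4 × min for any α/2 below 1/256 ≈ 0.4%.  Bonferroni correction therefore
has no bite beyond that point and the rule degenerates to "smallest
per-block contribution above 1/48".  Under pure exchangeable noise the
leading component's loading direction is essentially uniform on the sphere,
which makes the per-item false-flag probability about P(χ²₁ > 1)⁴ ≈ 1% and
the 12-item family-wise rate on the order of 20% — the rule is a stability
screen, not a calibrated test.  Subject-level resampling would calibrate it
but is a different procedure; we implement the block-resampling convention
and document its behavior (the test suite carries a red test recording the
measured family-wise rate against a nominal 5%).

**Retention.** No automatic elbow detection: the retained component count
is configuration (default 3), and `variance_table` emits the full scree
table for the user's judgment.

## Connectivity

Per scan, regional time series are correlated pairwise (Pearson R); the
symmetric matrix is flattened to the E = N(N−1)/2 upper-triangle edges in
row-major order (0-based internally, 1-based in files).  Raw R enters the
GLM; `fisher_z` (arctanh) is available but off by default.  Subjects
without all 4 usable scans are excluded — the permutation design requires
balanced exchangeability blocks.  Edges are not pre-filtered; all E enter
the network statistic.

## Network-based statistic

Per edge e, OLS of edge values y_e (across the S·4 scans) on the per-scan
partial factor score with subject indicator nuisance (equivalently,
within-subject centering of both sides); t_e = β̂/SE with
df = scans − S − 1.  An alternative nuisance coding — the subject's mean
value of the edge as a single covariate — is available
(`nuisance="subject_mean"`).  Supra-threshold edges (default primary
threshold t = 4.7; one-sided or two-sided tails) form a graph whose
connected components are measured by extent (edge count; intensity
Σ(|t| − threshold) optional).

The null is built by Freedman–Lane: residuals of the nuisance-only fit are
permuted *within each subject's scans* and added back to the nuisance
fitted values, the full model is refitted, and the largest component
statistic recorded; with subject-indicator nuisance the projector commutes
with within-block permutation, so the implementation permutes the centered
residuals directly.  Sampled p-values use (1 + #{null ≥ obs})/(1 + n_perm),
which cannot return 0; exhaustive enumeration (all Π n_b! within-block
permutations, for small designs) uses the exact count #{null ≥ obs}/n_perm
since the identity permutation is included.  The identity permutation is
allowed in sampling.  A warning is raised when the supra-threshold graph
spans all nodes in most permutations (threshold too low to be informative).

The contrast family is 3 retained components × 2 one-sided tails = 6 tests;
each contrast's best network p-value is Benjamini–Hochberg adjusted across
the family.  This family reproduces the printed rank-1 arithmetic
0.0081 → 0.0486.  Network effect size is a declared convention,
d = mean_e |2 t_e/√df|, reported alongside the mean |t|; no definition is
standard for a network-level d.

## Synthetic data generator

The generator emulates the target design: `n_subjects` = 19,
4 scans (2 days × 2 runs), 12 items, and a connectome of `n_nodes` = 60 by
default (scaled down from a 470-region parcellation; up to 470 supported).

* **Latent scores** s_{i,b,k} = subject term N(0, 1²) + scan term
  N(0, 0.5²) for k = 1..3 thought dimensions: stable individual
  differences with meaningful scan-to-scan fluctuation.
* **Items**: raw = Λ s + N(0, 0.3²), mapped by the fixed affine
  50 + 8·raw onto a 0–100 visual-analog-like scale (clipped at ≈5σ, i.e.
  essentially never; optional integer rounding).  The default Λ assigns 6,
  4 and 2 items to the three factors: unequal factor sizes keep the
  eigenvalue spectrum separated — after unit scaling of items, amplitude
  differences vanish, and equal-sized factors would leave the principal
  axes rotation-degenerate and unrecoverable in principle.
* **Connectivity**: edge value = baseline N(0.2, 0.1²) + subject offset
  N(0, 0.1²) + β·s_{i,b,k}·1[edge planted] + N(0, 0.1²), clipped to
  (−1, 1); default planted network is a 6-node clique.  The planted effect
  is linear per edge and matrices are not forced positive semi-definite —
  the network statistic is edge-wise, so PSD is not required.  Users
  needing valid correlation matrices can use the ROI time-series path, in
  which planted node pairs share a pair-specific signal whose variance
  increases with β·score, yielding genuine PSD correlation structure
  (monotone, not exactly linear, in the score).
* **Determinism**: one global seed expands into fixed per-stage child
  streams (scores / questionnaire / connectivity / time series / node
  table), so outputs are bit-identical for identical parameters no matter
  which generators run or in what order.

What the generator does **not** model: scanner physics, motion or
physiological noise, spatial autocorrelation between edges, non-Gaussian
item marginals, or item-level response styles.  Passing tests therefore
certify the statistical machinery (identities, FWE calibration, power
against a planted linear effect), not robustness to real fMRI artifacts.

## Test problem sizes and calibration

Simulation-based checks run at desk scale chosen by the package: FWE
calibration uses 200 null datasets of 10 subjects × 4 scans × 40 nodes with
500 permutations at |t| > 3 (observed family-wise rate ≈ 0.03 for nominal
0.05); recovery uses 50 replicates of 19 subjects × 20 nodes with a planted
10-node clique at threshold 1.7.  The planted effect β = 0.072 was
calibrated so that the *realized* per-edge effect through the fitted
partial scores is d = 2 t̄/√df ≈ 0.6 — fitted scores are attenuated
estimates of the latent scores (axis estimation from 19 subjects and 48
columns), so the same d defined on the true scores would require a smaller
β and detection would be far weaker.  This mirrors how effect sizes are
observed in practice: through the estimated predictor, not the latent one.

## Numerical notes

Rank tolerance 1e-12 relative to the leading eigenvalue; contributions of
zero-eigenvalue components are undefined (NaN with warning inside `fit`,
error from the public `compute_contributions`).  Zero-variance columns are
an error when unit scaling is requested, naming the column.  t-statistics
with zero residual variance are ±inf (0 when the slope is also 0).
Component ordering is extent-descending with smallest node index as
tie-break.  Percentile intervals use linear interpolation on the bootstrap
sample (numpy default).
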
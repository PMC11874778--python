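# Methods

## Model

The package infers a binary microbial association network per group and time
point from longitudinal count tables. The association measure is the partial
correlation between a pair of taxa (i, j) after removing, from each taxon's
log counts, the linear effect of (a) a one-dimensional latent summary of all
*other* taxa and (b) the log library size.

For a single time point the latent summary is the first principal component
of the log-transformed, centred and unit-scaled table. For a time point with
history, the component is chosen to share covariance with the past: with one
past block it is the first PLS component of the (past, current)
cross-covariance; with several past blocks it is the current-block component
of a fully connected multi-block PLS, maximizing the summed pairwise score
covariances across all blocks. The past either includes every earlier time
point (default) or a sliding window of k blocks.

Given the pair's component u^{−(i,j)} (the fitted loadings with entries i
and j set to zero), each taxon is regressed by OLS:

    log(y) ~ 1 + u^{−(i,j)} [+ log(l)]

and the partial correlation π is the Pearson correlation of the two residual
vectors. Significance uses t = π √((n−2)/(1−π²)) against a t reference with
n − 2 degrees of freedom, two-sided; an edge is drawn when p < α (0.05 by
default, no multiplicity correction — an optional Benjamini–Hochberg flag is
provided, but adjusted networks are often empty at microbiome sample sizes).
Zero counts are offset to 1 before the log; pre-transformed tables (clr or
relative-abundance inputs) skip both the log and the library offset.

### Assumptions

- Subjects are matched across time points (row k of every table is the same
  subject); the longitudinal component assumes correlation structure across
  both time and individuals. Unmatched designs should use the single-time
  variant per time point.
- All subjects within a group share one network per time point.
- A one-dimensional summary of the controlling taxa is adequate; up to three
  components can be conditioned on (`n_components`), which enter the
  regression jointly. One component is the default — with small n, extra
  components cost more in degrees of freedom than they remove in
  confounding.

### The masking shortcut

Refitting the latent component for each of the p(p−1)/2 pairs is avoided by
fitting it once on the full taxa set and zeroing the two loadings per pair:
u^{−(i,j)} = u − X·,i w_i − X·,j w_j. This is exact *given the full-data
loadings*; the approximation is only relative to a per-pair refit, which is
available behind `exact_per_pair=True`. On seeded 30×20 data the two routes'
partial correlations correlate above 0.99 while the shortcut performs 1
latent fit instead of 191. The zeroed loading vector is not renormalized:
rescaling a regression covariate is absorbed by its OLS slope, so
renormalization cannot change the residuals (a `renormalize` flag exists for
completeness).

## Numerical choices

- **Standardization**: per-taxon centring and unit scaling with the n−1
  (sample) denominator; zero-variance taxa cannot be scaled and are marked
  untested. Correlations are unaffected by the denominator choice.
- **PCA/PLS**: computed by dense SVD (of the block, and of the
  cross-covariance respectively); deterministic sign convention — the
  largest-magnitude loading entry is positive.
- **blockPLS**: Gauss–Seidel updates w_q ← normalize(X_qᵀ Σ_{k≠q} u_k) from
  each block's PCA loading, a guaranteed-ascent scheme for the summed
  covariance objective; stops when the largest loading change falls below
  `tol` (1e−6, max 500 sweeps; non-convergence raises, carrying the last
  iterate). The objective is invariant only under flipping *all* blocks
  jointly, so the sign convention is applied globally through block 0.
  Additional components (if requested) come from deflating each block on its
  own scores and refitting, which reproduces successive principal components
  in the single-block case.
- **Degenerate inputs**: constant covariates (e.g. a constant library size)
  are collinear with the intercept and dropped; zero-variance residuals mark
  the pair untested (statistics stay missing, never p = 1); untested taxa
  are isolated by contract.
- **Filtering**: taxa below 0.1% mean relative abundance in every
  (group, time) cell are dropped globally ("mean" = mean over samples of
  per-sample relative abundance — the same statistic as the per-network
  rule, which the source text leaves implicit); library sizes are computed
  before filtering and kept. At inference time a per-(group, time) mask
  re-applies the same threshold; in longitudinal mode the current-time mask
  is applied to every included past block (a strict intersection across
  blocks is optional — the source convention is ambiguous, and the
  current-time mask is the laxer reading that keeps the taxa set anchored to
  the network being inferred).
- **Imputation**: missing cells in pre-transformed studies are filled by
  natural cubic splines along each (subject, taxon) trajectory on the clr
  scale; no extrapolation — outside the observed time range the nearest
  observed value is carried. Single-observation trajectories carry their
  value.
- **Bootstrap**: subjects are resampled with replacement jointly across all
  time points (preserving the matching the model assumes), the full pipeline
  re-runs per replicate, and percentile intervals of the per-pair p-values
  are reported. Degenerate resamples are skipped; more than 10% skips
  raises.
- **GDD**: combinatorial Laplacian L = D − A; distance is the maximum over
  diffusion time τ of the Frobenius distance between heat kernels
  exp(−τL), computed from one eigendecomposition per graph; the search is a
  100-point log grid on [1e−3, 10] refined by bounded golden-section.
- **Classical MDS**: Torgerson double centring, top-k positive eigenpairs,
  negative eigenvalues truncated.
- **IVI**: the six node measures (degree centrality, ClusterRank,
  neighbourhood connectivity, local H-index, betweenness, collective
  influence at radius 2) are each min–max scaled to [0, 100] within the
  graph and combined as hubness = DC + LH, spreading = (NC + CR) × (BC +
  CI), IVI = min–max rescale(hubness × spreading); isolated nodes are pinned
  to 0. The exact combination rule of the original integrated-influence
  method is not published alongside the six measures, so this
  grouping-faithful aggregation is a package decision, isolated in one
  function so it can be swapped without touching callers.
- **Mantel**: Pearson correlation of upper-triangle entries under
  simultaneous row/column permutations; one-sided (greater), the
  conventional direction for distance-matrix association;
  p = (1 + hits)/(n_perm + 1).

## Synthetic data

The benchmark generator emulates a two-period longitudinal design: a binary
"true" network per period is converted to a precision matrix (off-diagonal
support exactly on edges, magnitudes uniform in (0.3, 0.6) with random
signs, diagonal inflated to strict dominance), inverted and standardized, so
that at the latent Gaussian level zero partial correlation coincides exactly
with "no edge". Counts are drawn through a Gaussian copula: Z ~ MVN(0, R),
x = F⁻¹_Poisson(Φ(z); λ), giving exact Poisson marginals with per-taxon
rates λ ~ log-normal(3, 1) (median ≈ 20 counts, realistic over-dispersion
across taxa). Defaults follow the benchmark design: 54 taxa, 10 time
points, a network switch after time 5, 50 replicates, sample sizes varied
over {23, 50, 120} by the caller; default truth graphs are Erdős–Rényi at
density 0.07. Time points are drawn independently given the period's
correlation matrix (an optional AR(1) latent persistence parameter exists,
default 0).

What the generator does *not* emulate: zero inflation beyond what low
Poisson rates produce, taxonomic correlation structure (hubs, blocks) of
real communities, compositional coupling through a shared sequencing-depth
factor, or autocorrelated dynamics. Passing benchmarks on this generator
therefore demonstrates correct recovery of latent partial-correlation
structure from copula-Poisson counts — not performance on real 16S data.

## Calibration caveat

The edge test is approximately, not exactly, calibrated. Two small
violations are inherent to the design: (1) the library-size offset
conditions on the row total, which contains the pair's own counts; for p
taxa this induces a multinomial-style negative dependence of order −1/p
between any two taxa's residuals, inflating the edge rate at α = 0.05 to
≈ 0.065 at p = 20 (measured on 200 independent-Poisson null replicates,
n = 50); (2) the test uses n − 2 degrees of freedom although the regression
consumes additional degrees for the latent component and the offset, and
the component itself is data-derived — omitting the offset, the measured
null rate is ≈ 0.045 (slightly conservative). Both effects shrink as p and
n grow. Users should read the α cutoff as a ranking device rather than an
exact type-I guarantee, which is also why the benchmark evaluates ranked
scores (1 − p) via AUC rather than thresholded networks alone.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use the reduced two-period
design (20 taxa, 6 time points, switch after 3, 10 replicates, n ∈ {23, 50,
120}) and a 200-replicate null; these sizes give stable Monte-Carlo
summaries at desk scale. The full-size defaults (54 taxa, 10 time points,
50 replicates) remain the package defaults for users.

## Known limitations

- Edges are undirected and unsigned in the output network; the sign lives
  in the partial-correlation matrix.
- No modelling of time-gap spacing: adjacent and distant past blocks are
  weighted equally (the block design is fully connected and unweighted).
- Groups are modelled separately; no joint multi-group inference.
- The per-replicate Mantel comparison of 20-node inferred networks has low
  power (see the calibration caveat for the false-edge load); network
  discrimination summaries are more reliable through GDD at small p.
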
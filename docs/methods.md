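# Methods

`sewscape` detects loss of ecosystem resilience from single gridded
snapshots.  This note describes the models, estimators and numerical
choices, and what the synthetic test beds do and do not establish about
real data.

## The grazing model

The mean-field model is the classic grazed-vegetation system

    dB/dt = r B (1 − B/K) − c B² / (B0² + B²)

with logistic regrowth and a saturating (Holling type III) grazing loss.
Defaults are r = 1 yr⁻¹, K = 100 g m⁻², B0 = 10 g m⁻² — the scaling of
the standard dimensionless system (r = 1, K = 10, B0 = 1) whose bistable
window falls at grazing rates c ∈ (17.87, 26.04) g m⁻² yr⁻¹, i.e. the
"18 < c < 26" window the package reproduces.  Fold (saddle-node) points
are computed exactly as the interior extrema of the equilibrium curve
c(B) = r (1 − B/K)(B² + B0²)/B: setting dc/dB = 0 gives the cubic
(2/K)B³ − B² + B0² = 0, solved with `numpy.roots`.  This is preferred to
numerical continuation because it is closed-form and trivially testable;
a monotone c(B) (e.g. B0 close to K) raises a distinct `NoFoldError`.

The spatial extension puts the same local dynamics on an L × L lattice
with periodic boundaries, a discrete 4-neighbour Laplacian for seed
dispersal (coefficient D, unit lattice spacing), and a grazing rate that
fluctuates independently per cell and per time step:
c_ij = max(c + σ·η, 0), η ~ N(0, 1).  Integration is explicit Euler with
biomass floored at 0 after each step (the noise can undershoot), and a
stability guard dt·(r + 4D) < 1.  Defaults: dt = 0.01 yr, L = 100,
σ = 1, D = 0.1.  Note that redrawing the noise each step makes the
effective stochastic forcing depend on dt; dt is therefore part of the
model definition, not merely a numerical knob, and is held fixed across
experiments.

Quasi-static hysteresis sweeps relax 200 yr per grazing level from the
previously converged state (LSODA, rtol 1e-8).  Pulse experiments
equilibrate on the high branch, raise c by Δc = 1.0 for 1 yr, and record
the recovery (sampled every 0.05 yr) until biomass is within 10⁻⁶·K of
the pre-pulse equilibrium; a pulse that tips the system to the low
branch is reported as a `collapsed` outcome, not an exception.

## Snapshot indicators

All moments are population moments (divide by N), so on binary maps the
Bernoulli identities hold to machine precision: var = m(1 − m),
skew = (1 − 2m)/√(m(1 − m)) with m the mean cover.  This is deliberate:
those identities are the central pitfall the preprocessing module exists
to address, and they are asserted exactly in the tests.

**Moran's I** uses binary lag-1 weights, rook neighbourhood by default
(queen optional), non-periodic by default with a periodic flag for
simulator output; pairs touching missing cells are excluded.  Under
spatial randomness E[I] = −1/(N − 1).

**Spectral density ratio (SDR)** removes the mean, computes the 2-D
periodogram, and bins by integer radial wavenumber with
f_max = min(nrows, ncols)/2.  SDR = mean periodogram value over radii in
(0, 0.2·f_max] divided by the mean over radii ≥ 0.8·f_max.  Mean (not
summed) band power makes white noise ≈ 1 independent of grid size; the
high band has no upper cap so the Nyquist corners are included (a pure
checkerboard then gives SDR = 0 exactly).  On the simulated gradients
SDR *rises* toward the fold: as the dominant recovery rate softens, the
spatial spectrum reddens and power concentrates at low frequencies, so a
low:high power ratio increases together with Moran's I.  Treatments that
expect this ratio to fall are implicitly using its reciprocal.

## Null models

Permutation envelopes shuffle the non-missing cells (n = 200 replicates
and 95% empirical quantiles by default), recomputing the metric per
replicate.  Mean, variance and skewness are functions of the value
distribution only; the machinery flags them `permutation_invariant`
rather than reporting a degenerate interval as if it were informative.
The covariate screen is Pearson's chi-square of independence on the
state × covariate cell-count table (rarest covariate classes pooled
until expected counts reach 5).  Spatial autocorrelation inflates the
effective sample size, so its significance is anti-conservative — it is
a screen against environmental confounding, not calibrated inference.

## Hartigan's dip test

No dip-test implementation is available in the package's dependency
set, so the statistic is implemented here: the classic iterative
greatest-convex-minorant / least-concave-majorant algorithm (Hartigan &
Hartigan 1985), returning min over unimodal CDFs U of sup|F_n − U|.
The implementation is validated in the test suite against a brute-force
oracle that solves the same minimax problem as a set of linear programs
(enumerating mode positions, including an atom at the mode) for small
samples, including ties.  P-values come from a seeded bootstrap of the
uniform null (2000 replicates by default, cached per sample size) — the
uniform is the asymptotically least-favourable unimodal distribution, so
the test is conservative.  Coarse-grain selection returns the smallest
aggregation factor whose cell-value distribution fails to reject
unimodality at α = 0.05 (α is a reporting choice, not from theory).

## Variograms

The empirical semivariogram enumerates cell pairs by lattice offset
(exact, no quadratic pair loop), bins by Euclidean distance with
bin width = one cell size and max lag = one third of the shorter side by
default, and records the *mean pair distance* per bin as the lag centre
(the nominal bin centre biases the first bins).  An optional seeded
cell subsample caps the pair count (default 5·10⁵) for very large
grids; directional variograms restrict pairs to an azimuth ± tolerance
wedge.

Model fitting is weighted least squares (weights ∝ pair counts) of a
spherical or exponential model with non-negativity bounds, the problem
normalized by the maximum semivariance and multi-started over the range
parameter for robustness.  Correlation range conventions: a (spherical),
3a (exponential practical range, the lag of 95% sill).  Because spatial
structure finer than the first measured lag is indistinguishable from
nugget variance, the structured model must beat the nugget-only (flat)
model in an F-test (p ≤ 0.05) or the fit degrades gracefully to a pure
nugget (partial sill 0) — without this guard, pure white noise is
routinely awarded ~20% spurious "structural" variance.  The relative
structural variance is RSV = 100·psill/(psill + nugget); the optimal
observation resolution for a pattern of length scale D_c is D_c/2 by
the sampling theorem.

A caveat learned from the simulator experiments: along a stress
gradient the fitted sill and correlation range rise reliably, but
fitted RSV is a noisy readout — the nugget/partial-sill split wanders
by several percentage points between realizations even when raw
variograms show the structure growing monotonically.  RSV should be
read as a coarse classification (structured vs noise), not ranked
across similar snapshots.

## Recovery-time analysis

Post-pulse series are range-normalized, (B − Bmin)/(Bmax − Bmin), and
fitted with B′(t) = p1(1 − e^(−t/p2)) + p3 by bounded nonlinear least
squares (initial guesses: p1 = observed span, p2 = t_max/3, p3 = first
value).  Recovery time is 3·p2 — the time to reach 1 − e⁻³ = 95.02% of
the asymptotic rise.  Goodness of fit is Willmott's index of agreement,
d = 1 − Σ(P − O)² / Σ(|P − Ō| + |O − Ō|)², plus an F-test of the fit
against a constant-mean model (reported, not gating).  On the default
model the fits are essentially exact (d > 0.9999) and recovery time
rises from 3.4 yr at c = 5 to 6.4 yr at c = 20: critical slowing down.

## Synthetic fields

Gaussian random fields use circulant embedding on a torus of twice the
grid size (negative embedding eigenvalues clipped; negligible at the
supported sizes) with exponential or squared-exponential covariance.
Binary maps come from quantile thresholding (exact target cover up to
one cell), and the three-phase mosaic from two nested thresholds of one
structured field.  These fields are stationary, isotropic and Gaussian —
unlike real vegetation maps, they have no anisotropy, no trends, no
classification error and no scale-dependent feedbacks.  Passing tests on
them establishes estimator correctness and calibration, not that the
indicators will flag real-world transitions; in particular, periodic
(Turing-like) patterned systems violate the rising-variance logic
entirely and are out of scope.

## Study conditions used by the test suite

Trend experiments run on a 64 × 64 lattice, grazing levels
c ∈ {5, 10, 15, 20, 24}, burn-in 100 yr (many multiples of the ~1/r
relaxation time), three replicate seeds.  Indicator trends use the
default D = 0.1; the variogram experiment uses D = 2 because the
dispersal length √(D/r) must exceed one cell for patch structure to be
measurable at all, and pools the empirical variograms of the three
seeds per level before fitting.  Variogram parameter recovery uses
128 × 128 fields with range 8 m (domain ≳ 5 correlation ranges) and a
fitting window of a quarter of the domain.  All experiments complete in
a few minutes on one CPU.

## Known limitations

* The lattice noise scheme ties the stochastic forcing to dt (see
  above); comparisons across dt values are not meaningful.
* The chi-square covariate screen ignores spatial autocorrelation.
* Variogram fitting assumes point support at cell centres (no
  block-support correction) and offers only spherical and exponential
  families; REML/ML estimation and kriging are out of scope.
* The dip test's bootstrap null makes p-values conservative for
  peaked unimodal alternatives.
* TIFF output is plain single-band TIFF with the cell size in the
  ImageDescription tag, not geo-referenced GeoTIFF.
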
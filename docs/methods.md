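# Methods

`statenergy` implements a dynamic functional-network analysis for
resting-state fMRI cohorts: framewise co-fluctuation (edge) time series,
data-driven connectivity states, state-transition statistics, network-
control-theory transition energies, healthy-control-referenced cognitive
classification, and covariate-adjusted group statistics.  A synthetic
cohort generator with fully known ground truth drives all tests.

## Edge time series

Regional signals x_i(t) are z-scored over time using the *population* SD
(ddof = 0) and multiplied pointwise per region pair:

    e_ij(t) = z_i(t) z_j(t),      z_i(t) = (x_i(t) - mean_i) / sd_i.

With the population-SD convention the temporal mean of e_ij is exactly the
Pearson correlation r_ij, making edge time series a temporal unwrapping of
static functional connectivity; the identity is asserted to 1e-10 in the
tests.  Only the upper triangle (i < j, row-major) is stored; the
symmetric per-frame matrix (diagonal z_i(t)^2) is reconstructed on demand.
Zero-variance regions raise an explicit error naming the region.  Frames
are analysed as given — any volume discarding happens upstream.

## Connectivity states

Edge frames are pooled across subjects and clustered by k-means under the
city-block (L1) metric.  The centroid update is the componentwise *median*
of the assigned frames — the L1-optimal centre; a mean update would not
minimise L1 inertia.  Five seeded replicates are run per k (k-means++-style
seeding with L1 distances) and the replicate with minimal total inertia is
kept.  Empty clusters are re-seeded from the point farthest from its
centroid (logged).  Determinism is guaranteed by a single integer seed.

The model order is selected over k = 2..7 by an elbow rule: the k whose
point on the inertia curve lies farthest (perpendicularly) from the chord
joining the curve's endpoints, ties broken toward smaller k.  Non-monotone
curves are first smoothed by decreasing isotonic regression (warned);
curves with no elbow (linear decline) return the smallest interior k with
a warning.

Each centroid is described by global mean connectivity (signed mean of
edge values), global efficiency (mean inverse shortest path length with
edge lengths 1/|w|), modularity (Louvain, best of 10 seeded restarts), and
mean eigenvector centrality per resting-state network (principal
eigenvector of |W|, unit L2 norm).  Path-based and spectral metrics use
the elementwise absolute value of the centroid matrix because they are
undefined for signed weights; this convention is a package decision (a
positive-part alternative would discard anticorrelation structure rather
than fold it in).  States are named after the network with maximal mean
centrality.

For memory-bound inputs the clusterer accepts a uniform per-subject frame
stride and then assigns all frames to the fixed centroids; this is off by
default at the scales used here.

## State dynamics

For a per-subject state sequence s(t), t = 1..T:

* total transitions: #{t : s(t) != s(t+1)};
* fractional occupancy: fraction of frames per state (sums to 1);
* transition probabilities T_ij: ordered pair counts (i -> j), persistence
  included, divided by all pairs starting in i.  The matrix is directional.
  A state with no outgoing pairs (never visited among frames 1..T-1) has a
  missing row — missing values are propagated, never imputed.

## Minimum control energy

The brain is modelled as a continuous-time linear system on the subject's
structural connectome W (symmetric, nonnegative, hollow):

    x'(t) = A x(t) + u(t),     A = W / (lambda_max(W) + c) - I,   c = 1,

with every region receiving input (B = I).  The normalisation places all
eigenvalues of A in [-2, 0), so autonomous activity decays.  The
minimum-energy input steering x0 to xf over horizon T (default 1.0) is

    Emin = v' W_T^{-1} v,   v = xf - e^{AT} x0,
    W_T  = int_0^T e^{At} e^{A't} dt,

with the controllability Gramian computed by the augmented-matrix
exponential (Van Loan) method — exact to solver precision, no quadrature
step size to tune.  Per-region energies integrate the squared optimal
input u*(t) = e^{A'(T-t)} W_T^{-1} v componentwise (again via an
augmented exponential) and sum to the total within 1e-8 relative.  The
implementation is verified against a 1000-step discretised least-squares
optimal-control oracle (0.5% relative) and a scalar closed form.
Near-singular Gramians (condition number > 1e12) fall back to a
relative-tolerance pseudo-inverse with a warning.  A small utility reports
mean energy under alternative horizons T in {0.5, 1, 3, 5} as a stability
check for the horizon choice.

Activity states are the z-scored regional signals — the same normalisation
used for edge construction, so the pipeline has exactly one activity
representation.  Energies of successive-frame transitions are averaged by
transition type (i -> j) of the state sequence into a k x k energy matrix
per subject (unobserved types missing), z-scored per cell against the
healthy-control distribution (sample SD), and summarised as total (mean of
all non-missing cells), persistence (diagonal) and transition
(off-diagonal) control energy.  Within-subject averaging precedes
across-subject z-scoring.

## Cognitive classification

Per domain, a least-squares model score ~ age + sex + education is fitted
on healthy controls only; all subjects are residualised with the HC
coefficients and z-scored by the HC residual mean and sample SD.
Covariates constant within HC are dropped with a warning.  Labels use
strict thresholds: CI if >= 2 of 7 domains have Z < -2; else MCI if >= 2
domains have Z < -1.5; else CP.  Strictness follows the rule's most precise
statement; it has measure-zero impact on continuous scores.  Adjustment is
per domain (one score per domain; the test-to-domain mapping is metadata).

## Group statistics

All group comparisons adjust for age, sex and binary education.  Outcomes
passing a Lilliefors-style KS normality check (p > 0.05) use fixed-effects
least squares — the design is purely between-subject, so no random effects
are identifiable and a mixed model would reduce to this; non-normal
outcomes use Quade's nonparametric ANCOVA: rank-transform (midranks) the
outcome and covariates over the full sample, regress ranked outcome on
ranked covariates, one-way ANOVA F across groups on the residuals.  Both
routes are calibration-tested (type-I error 5% +- 2% under null
simulation).  The CI-vs-CP contrast (beta, 95% CI, CP reference) is always
reported from the linear fit.  Bonferroni correction multiplies p by the
family size — the set of states or transitions tested within one analysis
block (1 for total transitions; 3 for the energy summaries).  Partial
correlations residualise both variables on the covariates and test Pearson
r of the residuals with df = n - 2 - #covariates.  All analyses are
complete-case; missing cells reduce n and are never imputed.

## Synthetic cohort

The generator plants everything the pipeline estimates:

* **States.**  k = 4 orthonormal activation templates over 100 regions
  (QR of a seeded Gaussian matrix; pairwise cosine exactly 0, satisfying
  the |cos| <= 0.3 separation bound).  A hidden Markov chain with
  persistence 0.75 (HC/CP), 0.80 (MCI) or 0.85 (CI) selects the active
  state per frame; the chain starts at its stationary distribution so no
  burn-in is needed.  Frame t is amplitude(t) x template[s(t)] plus iid
  Gaussian noise (sd 0.02 against unit-norm templates, i.e. per-region
  SNR ~ 5).  Amplitudes are +-Uniform(0.8, 1.2) per frame; the sign is
  random per state *visit* and constant within it (a dwell is one
  activation episode).  Edge frames (outer products) are sign-stable per
  state while regional activation varies; dwell-stable signs also keep
  the energy of within-state frame pairs small and low-variance, which a
  per-frame sign flip would destroy (a pattern inverting every frame
  while "in the same state" would both be physiologically odd and swamp
  the between-group energy differences with sign-flip noise).  The
  amplitude range is deliberately narrow — with a much wider range each
  state's edge cluster becomes a long ray that k-means profitably splits
  by amplitude, and the inertia curve loses its elbow at the true k even
  though frame assignment stays essentially perfect.  The default scan
  length is 200 analysed frames.
* **Connectomes.**  A stochastic block model (4 modules, log-normal
  weights, within-module edges denser and ~3x stronger) plus a
  structure-function coupling term: the positive part of each template's
  outer product, weighted by `coupling` (default 60).  The coupling term
  gives the system controllable directions aligned with the activity
  patterns the states actually visit.  Group damage acts through two
  dials: a global multiplicative `integrity` factor (CI 0.7, MCI 0.85)
  and a `coupling_integrity` factor on the coupling term only (CI 0.3,
  MCI 0.6).  Because A is normalised by its own spectral radius, a purely
  global weight loss is almost exactly cancelled (measured effect ~1e-4
  of the mean energy) — it is the *selective* loss of structure-function
  coupling that makes transitions costly in the damaged groups, mirroring
  the idea that demyelination decouples structure from function rather
  than uniformly attenuating it.  The CI coupling loss is sized by a
  power calculation: with the observed between-subject SD of HC-referenced
  transition energy (~0.4 z-units), a ~0.6-0.8 z-unit group shift gives
  >99% detection power at the Bonferroni-corrected level in a 20-per-group
  cohort; 70% coupling loss delivers that shift.  Matrices are symmetric,
  hollow, nonnegative and connected (components chained if needed).
* **Cognition.**  Raw domain scores are linear in age (-0.08/yr), sex
  (0.4) and education (0.6) plus a group deficit in HC-SD units (CI: -3.5
  on processing speed, verbal memory and attention; MCI: -1.9 on two
  domains) and unit-variance noise, so the HC adjustment has real
  structure to remove.  Ages are ~N(48, 11), CI shifted +4 years.

Default cohort: 20 HC / 20 CP / 20 CI.  Everything is reproducible
bitwise from one seed.

### What the generator does not emulate

Hemodynamic convolution, autocorrelated scanner noise, motion artifacts,
spatially structured noise, tractography biases, and any coupling between
the functional noise level and group.  Passing tests therefore demonstrate
that the estimators recover what was planted under an idealised signal
model — not that the pipeline is robust to fMRI artifacts.

## Numerical choices

* Population SD for z-scoring (makes the edge-mean/Pearson identity exact).
* L1 k-means centroids are exact componentwise medians; ties in the elbow
  rule break toward smaller k; Louvain ties keep the lowest restart seed.
* Gramian via augmented matrix exponential; Cholesky solve, pseudo-inverse
  fallback above condition 1e12.
* Markov chains are initialised from the stationary distribution.
* Clustering internally uses float32 frames (memory-bound at ~10^4 frames
  by ~5x10^3 edges; the cluster geometry is unaffected at that precision).

## Problem sizes

The study-scale checks run the full pipeline on 60 subjects x 200 frames
x 100 regions (12,000 pooled frames, 4,950 edges), scanning k = 2..7 with
5 replicates; convergence and calibration checks use 10,000-frame chains,
1,000 null simulations, and 50 random control systems of up to 10 nodes.

## Known limitations

* Louvain modularity is a heuristic lower bound; with 10 restarts it is
  exact on the small fixtures but not guaranteed at scale.
* The elbow rule operates on raw (k, inertia) coordinates; axes are not
  rescaled.  This is deterministic and testable but differs from kneedle
  variants that normalise both axes.
* Quade's procedure has published variants; the residual-ANOVA form used
  here is calibration-tested rather than assumed to match any particular
  statistics package.
* The nonparametric route reports the group-effect F/p from ranks but the
  descriptive contrast beta from the linear fit.
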
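# Methods

## The model

`symptomnet` analyses a cross-sectional mixed dataset — discrete
demographics plus continuous clinical, cognitive and quality-of-life (QOL)
scale scores — as a **conditional linear Gaussian (CLG) Bayesian network**.
A directed acyclic graph G over the p variables factorizes the joint
distribution into per-node families:

* a **discrete node** D with discrete parents Pa(D) carries a multinomial
  conditional probability table (CPT), one row per parent configuration;
* a **continuous node** Y with continuous parents X and discrete parents
  Pa_d(Y) carries, for each configuration g of Pa_d(Y), a linear
  regression Y = a_g + b_g'X + eps, eps ~ N(0, sigma_g^2).

Continuous parents of discrete nodes are structurally excluded (the CLG
blacklist): every arc from a continuous variable into a discrete one is
forbidden during search, mirroring the convention that demographics cannot
be children of clinical scores.

## Structure learning

The network score is the decomposable BIC on the log-likelihood scale,
maximized:

    score(G) = sum_v [ logL_v(Pa(v)) - (d_v / 2) log n ]

where d_v counts the free parameters of node v's family (discrete:
(levels-1) x prod(parent levels); continuous: intercept + slopes +
variance per discrete-parent configuration).  Greedy **hill climbing**
starts from the arcless graph and repeatedly applies the single arc
addition, deletion or reversal with the largest positive score delta;
decomposability means each delta touches at most two families, which are
memoized.  A **Tabu** variant accepts the best non-tabu move even when
worsening (up to a budget of non-improving steps, fingerprinting the last
`tabu_length` visited structures) and returns the best structure visited.
Ties between equal-delta moves break lexicographically by
(operator, parent, child), and moves must improve by more than 1e-9, so
both searches are deterministic.

Never-observed discrete-parent configurations get a uniform CPT row (and
their parameters still count toward d_v); within-configuration residual
standard deviations are floored at 1e-6; sparse configurations (fewer
records than regressors) fall back to minimum-norm least squares.  These
rules keep scores finite and parameter fitting defined on bootstrap
resamples, where sparse configurations are routine.  Genuinely collinear
continuous parents still raise an error.

## Bootstrap model averaging

B nonparametric bootstrap resamples (size n, with replacement; B defaults
to 200) each yield a learned network.  Every unordered pair accumulates a
*strength* (fraction of replicates containing the edge in either
direction) and a *direction* split.  The averaged network keeps pairs
whose strength clears a threshold — a fixed proportion, or the
L1-optimal significance threshold: the noise mass p* minimizing the L1
distance between the empirical strength CDF and a constant step function,
with the threshold at the p*-quantile of the strengths and pairs strictly
above it retained.  Orientation follows the majority direction; exact
ties break to the lexicographically smaller orientation (never into the
blacklist), and any residual cycle is repaired by dropping its
weakest-strength arc, deterministically.

## Path-model SEM refit

The learned DAG is refit as a recursive path model.  Because the system
is recursive with uncorrelated errors, equation-wise ordinary least
squares is the maximum-likelihood fit: each endogenous variable is
regressed on its parents, giving raw coefficients b, standardized
coefficients beta = b * sd(parent)/sd(child), normal-reference (z)
p-values — adequate at n near 1450 — and Holm step-down adjusted p-values
across all paths.  Discrete variables enter through explicit numeric
codings (0/1 for binary, integer codes for ordered bands, first-level
reference dummies for nominal variables); the coding report records every
mapping.

Global fit uses the model-implied covariance: exogenous columns keep
their sample covariance block, endogenous residuals are diagonal, and
Sigma(theta) = (I-B)^-1 Psi (I-B)^-T.  The test statistic is
T = (n-1) F_ML with F_ML the ML discrepancy; degrees of freedom are
p(p+1)/2 minus free parameters (paths + residual variances + the
exogenous covariance block).  CFI, TLI (both capped at 1) and RMSEA
follow the standard definitions; a saturated model gives T = 0, CFI = 1,
RMSEA = 0.  AIC/BIC come from the Gaussian log-likelihood under
Sigma(theta) with the same parameter count.  One consequence of counting
the exogenous block: information-criterion comparisons are clean between
models sharing an exogenous set — adding an arc into a formerly exogenous
node also removes its free covariances, which can dominate the one-path
penalty.  Model comparisons in the pipeline (single-data vs averaged
network) therefore rely on RMSEA first, then CFI, then BIC.

## Centrality

Degree is counted on the directed graph (in/out/total).  Closeness and
betweenness are computed on the undirected unweighted skeleton — a single
per-node value, as psychometric network reports present them, with the
in/out split carried by the degree columns.  Standardized columns divide
betweenness by (n-1)(n-2)/2; classic closeness is already in [0,1] on a
connected graph.  On a disconnected skeleton closeness switches to
harmonic centrality scaled by 1/(n-1) (classic closeness is undefined
across components); the variant used is recorded on the table.  Both raw
and standardized columns are emitted because reporting conventions vary.

## Conditional-probability queries

Events are median splits of continuous variables (strict inequalities;
ties at the median fall in neither event) or level equality for discrete
variables, with medians taken from the post-imputation analysis dataset.
P(event | evidence) is estimated by logic (rejection) sampling on the
fitted CLG network: ancestral samples violating the evidence are
discarded; the estimate is the surviving fraction satisfying the event,
with Monte-Carlo standard error sqrt(p(1-p)/n_effective).  Rejection is
unbiased for interval-valued evidence and defaults to 10^6 draws per
query in the library; the pipeline battery uses 2x10^5 per query, keeping
the standard error near 1e-3 across an eleven-query battery.

## The synthetic generator

The generator emulates the structure of a large antipsychotic-trial
baseline cohort: 21 variables (age band, sex, race, marital status,
education, employment; CDSS, DAI, ITAQ totals; five MATRICS cognitive
domains; three PANSS subscales; CGI drug/alcohol/severity; QOL), n on the
order of 1450, about 2.4% missing cells plus ten rows with more than half
their cells missing to exercise the row filter.

Discrete marginals follow the published cohort (74.4% male, 59.6% never
married, 84.9% not working, racial identification 60.2/34.9/2.3/2.6%, age
bands from a mean of 40.5 and s.d. of 11.1 cut at 30/45).  The
ground-truth DAG carries the published standardized coefficients where
reported — processing speed -> negative symptoms (-0.25), working memory
-> general symptoms (-0.14), general -> negative (0.61) and positive
(0.64) symptoms, CDSS -> general (0.35) and negative (-0.14), positive
symptoms -> CGI severity (0.45), the six QOL parents including negative
symptoms (-0.33), processing speed (+0.12, following the results
narrative where the abstract's sign disagrees) and employment (-0.32) —
plus support arcs chosen once for connectivity at clinically plausible
sizes (MATRICS inter-domain paths 0.20-0.55, drug-use and insight paths
0.10-0.30, weak demographic effects 0.15).

Continuous variables are generated on a standardized scale: residual
variances are solved (from the exact model-implied covariance) so every
continuous node has unit marginal variance at `effect_scale = 1`, making
each annotated coefficient equal the population standardized partial
regression coefficient — the property the recovery tests check.  Discrete
parents act on continuous children through centred unit-variance level
scores, so the same equality holds under integer coding.  Residual
standard deviations are held fixed as `effect_scale` varies (scale 0
yields independent standard normals).

Missingness is injected completely at random (the emulated study does not
characterize its mechanism); bad rows lose a uniformly drawn majority of
their cells.  What passing tests therefore show: the pipeline recovers
structure and coefficients when the data really are CLG with MCAR
missingness.  What they cannot show: robustness to non-normal scale
distributions (real totals are bounded and skewed), informative
missingness, item-level measurement error, or latent confounding — all
absent from the generator by design.

## missForest-style imputation

Rows with a missing fraction strictly above 0.5 are removed first.
Remaining missing cells are initialized with the column mean (continuous)
or mode (discrete) and refined by iterating over variables in order of
increasing missingness, fitting a random forest of each variable on all
others (scikit-learn; 100 trees, mtry = sqrt(p) for discrete targets and
p/3 for continuous, following the original publication's defaults) and
predicting the missing cells.  Iteration stops when the
difference criterion — squared-change ratio over continuous imputed
cells, disagreement fraction over discrete ones — rises for both kinds
(or the only kind present), returning the matrix from the iteration
before the rise, or at `max_iter` (default 10; convergence is typically
reached in 3-5 sweeps).  Observed cells are never altered, and the whole
procedure is deterministic given its seed.  On this generator the
continuous block carries strong predictors and random-forest imputation
clearly beats mean imputation in NRMSE; the discrete demographics carry
little mutual information, so on those cells the forests match mode
imputation rather than beat it — the combined mixed-data error is what
improves.

## Age binning

The published bands "<30, 31-45, >45" leave exact ages 30 and 45
unassigned; ages are rounded to integer years and binned as <=30 /
31-45 / >45, which is exhaustive and order-preserving.

## Pipeline determinism and problem sizes

All randomness flows from one global seed through stage-specific derived
sub-seeds (SeedSequence children reduced below 2^31), so identical
configurations reproduce every numeric output byte for byte.  The default
pipeline draws 1460 records with ten planted bad rows, leaving the
emulated analysis sample of 1450 after filtering.  Test and demonstration
runs scale the expensive knobs — bootstrap replicates (50 instead of
200), forest sizes (15-50 trees), query draws (2x10^4 to 2x10^5) — as the
package's standard small-problem settings; the statistical properties
they check are size-stable.

## Known limitations

* Exact CLG inference is not implemented; all queries are Monte Carlo.
* The averaged network's threshold and B are exposed as configuration
  because the emulated study reports neither.
* Equivalence classes (CPDAGs) are deliberately out of scope: a single
  orientation is reported, as the emulated analysis did, and orientations
  of individually weak arcs should not be over-interpreted.
* The SEM treats dummy columns of one nominal variable as separate
  equations with uncorrelated residuals; multinomial endogenous variables
  are approximated, not modelled exactly.
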
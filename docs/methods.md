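# Methods

`multisrm` implements a Bayesian multiplex generalization of the social
relations model (SRM) for binary directed networks observed in several
layers over one shared roster — the setting of roster-based economic
games and peer ratings in field communities, where a subset of people
("egos") made recorded decisions toward everyone on the roster
("alters" included).

## Model

For sender j, receiver k, and layer m, a directed tie is

    G[j,k,m] ~ Bernoulli(logistic(theta[j,k,m]))
    theta[j,k,m] = eta[m] + alpha[j,m] + beta[k,m] + delta[j,k,m] + ...

where `eta[m]` is the layer intercept, `alpha[j,m]` the sender effect,
`beta[k,m]` the receiver effect, and `delta[j,k,m]` the dyad-specific
effect. The ellipsis is an optional linear covariate hook: sender-level,
receiver-level, and dyad-level predictors each get a per-layer
coefficient (for instance sender wealth, receiver wealth, and pairwise
relatedness). The default model — and the only one the sampler fits —
is intercept plus random effects; the covariate terms are available in
the likelihood API for data sets that carry such predictors.

**Generalized block.** The 2M-vector (alpha[j,1..M], beta[j,1..M]) is
multivariate normal with mean zero and covariance
diag(sigma)·L·L'·diag(sigma). Off-diagonal entries of L·L' are the
generalized-reciprocity correlations: within a layer, whether frequent
givers are frequent receivers; across layers, whether e.g. being named
generous predicts receiving transfers.

**Dyadic block.** The paired effects (delta[j,k,1..M], delta[k,j,1..M])
are multivariate normal with covariance built from scales `varsigma`
(2M) and a correlation matrix rho (2M x 2M). The entry coupling
delta[j,k,m] with delta[k,j,m] is within-layer dyadic reciprocity; the
leading M x M block couples the same direction across layers
(within-person, between-layer); the off block couples opposite
directions across layers (between-person, between-layer).

Because the labels j and k within a dyad are arbitrary, exchangeability
forces two constraints:

1. `varsigma[m] = varsigma[m+M]` — imposed exactly by giving the scale
   vector only M free entries;
2. `rho = [[C, B], [B, C]]` with C a correlation matrix and B symmetric
   — there is no Cholesky-style construction that yields exactly this
   family while guaranteeing positive definiteness, so it is imposed
   *softly*: for every layer pair m < n, Gaussian penalties with scale
   `epsilon` are placed on the norms |rho[m+M,n+M] − rho[m,n]| and
   |rho[m,n+M] − rho[n,m+M]|. As epsilon → 0 the posterior concentrates
   on the block-symmetric family; in practice epsilon = 0.1 (the
   default) keeps posterior-mean asymmetries well under 0.1 in our
   recovery runs while leaving the geometry well conditioned for
   sampling.

Both random-effect blocks use the non-centered parameterization: unit
normal raw vectors, scaled by the standard deviations and rotated by
the Cholesky factor of the correlation matrix. Priors are
Exponential(2.5) on all free standard deviations, LKJ(2.5) on both
correlation Cholesky factors, and Normal(0, 5) on intercepts and
covariate coefficients. Identification of a logistic model with this
many random effects leans on the priors; a flat intercept prior is
deliberately avoided. The Normal(0, 5) choice is weakly informative on
the log-odds scale (ties with probability between roughly 0.7% and
99.3% within one prior sd).

## Observation design

Cells are observed only for ego senders and only off the diagonal.
Alters without decisions stay on the roster: they carry receiver
effects and latent dyadic slots, and their outgoing cells are masked
from the likelihood rather than dropped. An absent ego-to-alter edge in
an edge list is an observed zero (roster-based instruments record
placed ties, not refusals), so the observed-cell count is always
(#egos) × (J−1) × M. Self-ties are structurally excluded from both the
data model and the likelihood.

## Inference

Sampling uses the package's own No-U-Turn sampler on the unconstrained
parameter vector, with analytic gradients of the full joint density.
Correlation Cholesky factors are parameterized by row normalization:
row i of the factor is (w_i, 1)/||(w_i, 1)||, a bijection from R^i to
the unit-row-norm lower-triangular family, whose log-Jacobian for row i
is (i+2)·log L[i,i]. Scales use a log transform. Warmup follows the
conventional three phases: step-size adaptation by dual averaging
(target acceptance 0.9), expanding windows that estimate a diagonal
mass matrix from warmup draws (variance shrunk toward unity for short
windows), and a terminal step-size refinement. Divergences are flagged
at an energy error of 1000.

Initialization starts raw effects at zero, scales at their prior mean
(0.4), correlation factors at the identity, and intercepts at the
empirical logit of each layer's density; chains add small uniform
jitter. Chains run sequentially from RNG streams spawned from one seed,
so a fit is reproducible bit for bit given its configuration.

Summaries report posterior means with 89% equal-tailed credible
intervals (5.5% and 94.5% quantiles). Equal-tailed intervals were
chosen over HPD intervals for quantile stability and reproducibility.
Convergence is assessed with split-Rhat and bulk effective sample size
(via ArviZ). In correlation reports an entry is flagged "reliable" when
its interval excludes zero — a display convention, not a hypothesis
test.

## Simulator and what recovery shows

The simulator runs the generative model forward: correlation targets
are specified directly (a generalized correlation matrix, and the
dyadic C and B blocks, assembled and checked for positive definiteness),
factorized to Cholesky form, and applied to unit-normal raw draws; the
Bernoulli observation layer is then applied under the same ego mask as
fitting. The default recovery fixture uses 50 people (all egos), three
layers with intercepts −2.5, −1.0, 0.0 (realized layer densities
roughly 0.08 to 0.5, spanning sparse ratings to dense exploitation
layers), unit sender/receiver and dyadic scales, within-layer dyadic
reciprocity 0.6, a −0.5 within-person cross-layer dyadic correlation
echoed at −0.3 between persons, and one 0.5 generalized
sender–receiver correlation.

Recovery runs score sign agreement for large true correlations
(|rho| ≥ 0.4), coverage of 89% intervals over all interpretable
parameters, and the block asymmetry of the fitted dyadic correlation
matrix. Two features of the results are expected behaviour rather than
defects: dyadic scales of *sparse* layers shrink markedly toward the
Exponential(2.5) prior mean (binary outcomes at density ≈ 0.08 carry
little information about dyad-level variance), and the corresponding
within-layer reciprocity estimates attenuate with wide intervals. Both
are honest posterior behaviour under weak identification, and the
coverage criterion accounts for them.

The simulator draws effects exactly from the model the sampler fits,
so recovery demonstrates computational correctness (the sampler finds
the posterior of the model that generated the data). It does not
demonstrate robustness to model misspecification: real game data
involve stake constraints, day-of-collection effects, and non-exchangeable
community structure that the generator does not emulate.

## Problem sizes and numerical choices

Default experiment sizes (J = 50, M = 3, two chains of 600 + 600
iterations) were chosen as the smallest configuration at which all
structural features of the model — cross-layer blocks, the ego mask,
the symmetry penalty — are exercised with stable results on a single
CPU in minutes. Community-scale fits (roster sizes of 200+, M = 5,
tens of thousands of observed cells) use the same code path and are
supported, but take correspondingly longer and warrant 4 chains and
longer warmup.

The published field-study correlation estimates (e.g. the strong
giving-to-generosity-rating dyadic correlations) depend on the
original deposited field data and community-scale MCMC; they are not
reproduced by this package's test surface. The simulation-based
recovery experiments above are the model-correctness evidence instead.

Other numerical choices: Bernoulli log-mass is computed with the
log-sigmoid (softplus) form, never log(logistic(theta)); block-rho
assembly rejects matrices whose minimum eigenvalue is below 1e−10;
LKJ densities are evaluated up to their normalizing constant, which
cancels in MCMC; layer descriptive statistics treat unobserved cells
as absent edges, matching how field tables are compiled from recorded
decisions.

## Descriptive statistics conventions

Density is E/(V(V−1)); reciprocity is the fraction of directed edges
whose reverse edge exists; transitivity is the global clustering
coefficient of the symmetrized graph (the table definitions do not fix
a directed triplet convention, so the common undirected default is
used); average distance is the mean directed shortest-path length over
reachable ordered pairs only, which keeps sparse layers finite.
Isolates count toward V. The reputation score of a person is their
in-degree in the "generous" rating layer minus their in-degree in the
"selfish" rating layer.

## Known limitations

- The sampler is single-threaded; chains run sequentially.
- The covariate hook is part of the likelihood API but not yet wired
  into the NUTS fit.
- Count-valued outcomes (numbers of coins) are out of scope; the model
  is strictly binary.
- Dyadic scales and within-layer reciprocity for very sparse layers
  are weakly identified; expect strong prior shrinkage there.
- With two short chains, effective sample sizes for the worst-mixing
  scale parameters can be low; longer runs are advised when those
  parameters are of direct interest.
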
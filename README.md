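# multisrm

Bayesian multiplex social relations model (SRM) for binary directed
multi-layer networks.

Field studies of cooperation increasingly collect *several* directed
networks over one community roster — who gave to whom in an allocation
game, who took from whom, who punished whom, who rates whom as generous
or selfish. The scientific questions live in the correlations between
those layers: do people reciprocate within a relationship (dyadic
reciprocity), do givers also receive (generalized reciprocity), and do
reputations channel giving, taking, and punishment across layers?
`multisrm` estimates all of these jointly instead of one network at a
time.

## Model

For sender *j*, receiver *k*, layer *m*:

```
G[j,k,m] ~ Bernoulli(logistic(θ[j,k,m]))
θ[j,k,m] = η[m] + α[j,m] + β[k,m] + δ[j,k,m] + (optional covariates)
```

- (α[j,·], β[j,·]) ~ MVN(0, diag(σ) L L' diag(σ)) — sender/receiver
  ("generalized") effects correlated within and across the M layers;
- (δ[j,k,·], δ[k,j,·]) ~ MVN(0, diag(ς) Γ Γ' diag(ς)) — dyad effects
  whose 2M × 2M correlation matrix ρ = Γ Γ' carries within-layer dyadic
  reciprocity and all cross-layer dyadic correlations.

Exchangeability of the two direction labels inside a dyad requires
ς[m] = ς[m+M] (imposed exactly) and ρ = [[C, B], [B, C]] with B = Bᵀ
(imposed softly by Gaussian penalties of scale ε = 0.1 on the block
asymmetries, since no Cholesky construction yields that family while
guaranteeing positive definiteness). Priors: Exponential(2.5) scales,
LKJ(2.5) correlation factors, Normal(0, 5) intercepts. Only ego
senders' outgoing off-diagonal cells enter the likelihood; roster-only
alters keep receiver effects and latent dyad slots.

Posterior sampling uses the package's own No-U-Turn sampler with
analytic gradients (non-centered parameterization, dual-averaged step
size, diagonal mass adaptation). Summaries report posterior means,
89% equal-tailed credible intervals, split-R̂, and effective sample
sizes. See `docs/methods.md` for the full account.

## Worked example

Simulate a three-layer community from known ground truth, fit it, and
read off the dyadic correlation matrix:

```python
import numpy as np
from multisrm import (
    FitConfig, correlation_report, default_recovery_config,
    fit, simulate, summarize_network,
)

config = default_recovery_config(seed=7)   # J=50 people, M=3 layers
net, truth = simulate(config)

print(summarize_network(net))
#      layer  vertices  edges   density  avg_distance  reciprocity  transitivity
# 0     give        50    249  0.101633      2.683640     0.144578      0.297569
# 1  exploit        50    737  0.300816      1.775918     0.360923      0.583674
# 2     rate        50   1182  0.482449      1.517959     0.534687      0.743012

samples = fit(net, FitConfig(chains=2, warmup_iterations=500,
                             sampling_iterations=500, seed=8))
report = correlation_report(samples)
print(report.dyadic[report.dyadic["reliable"]][
    ["row_label", "col_label", "mean", "ci_low", "ci_high"]])
#    row_label col_label      mean    ci_low   ci_high
# 11   rate:ij   rate:ji  0.537006  0.255133  0.791733
```

The three layers span sparse to dense regimes (densities 0.10 / 0.30 /
0.48), mirroring rating, giving, and exploitation layers in real
roster-based game data. In this short two-chain run the densest layer's
within-layer dyadic reciprocity (truth 0.6) is estimated at 0.54 with
an 89% interval [0.26, 0.79] and flagged "reliable" (interval excludes
zero); sparse layers' dyadic parameters shrink toward their priors, as
expected for binary data with few ties.

The command line mirrors the library:

```
multisrm describe --edges edges.csv --roster roster.csv --out table.csv
multisrm simulate --config sim.yaml --out-dir sim/
multisrm fit --edges sim/edges.csv --roster sim/roster.csv --seed 1 --out-dir fit/
multisrm recover --config sim.yaml --out-dir recovery/
```

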
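# mataboot

Model-averaged confidence intervals for parameters shared across a set of
candidate normal linear models, aimed at designed experiments — the
motivating case is a 2³ factorial global-change experiment with a lognormal
response (e.g. surface hydronium ion concentration under crossed pH,
irradiance and water-velocity treatments), where the scientific question is
the mean response in each treatment combination but the right set of
interaction terms is unknown.

Instead of selecting one model and ignoring model uncertainty, `mataboot`
averages over every hierarchical submodel with AIC weights
w_m ∝ exp(−AIC_m/2) and builds six confidence intervals for a cell mean
θ (via η = log θ = μ_cell + σ²/2 on the log scale):

| method | construction |
|---|---|
| `full_wald` | θ̂ ± t_{ν,1−α}·se from the full model |
| `ma_wald` | θ̄ ± z_{1−α}·√V̂(θ̄), V̂(θ̄) = Σ w_m{(t_{ν_m,1−α}/z_{1−α})²V̂(θ̂_m) + (θ̂_m−θ̄)²} |
| `mata_wald_z`, `mata_wald_t` | limits solve Σ w_m Pr(T_m ≤ (θ̂_m−θ_U)/se_m) = α (and the mirror equation for θ_L) with T_m ~ N(0,1) or t_{ν_m} |
| `mata_sboot` | the same tail-area equations with each T_m's distribution *estimated* by a studentized parametric bootstrap, T*_m = (θ̂*_m−θ̂_m)/√V̂(θ̂*_m) |
| `pb` | percentiles of AIC-best-model estimates over full-model bootstrap resamples |

The studentized-bootstrap tail-area interval (`mata_sboot`) only requires
each T_m to be approximately pivotal, so it stays calibrated when the
response is skewed and the sample is small — the regime where Wald-type
model-averaged intervals under-cover on the upper side. A scenario-based
simulation study for measuring lower/upper error rates and relative
half-widths is included.

## Worked example

Simulate a 2³ design with five replicates per cell, strong pH (P) and
irradiance (I) effects and a P×I interaction, then compute the AIC weight
table and intervals:

```python
import numpy as np, mataboot as mb

design = mb.FactorialDesign(("P", "I", "V"), r=5)
effects = mb.EffectSet(mu=0.5, main=(1.0, 0.8, 0.05),
                       two_way=(0.6, 0.02, 0.03), three_way=0.01, sigma2=0.4)
data = mb.simulate_dataset(effects, design, np.random.default_rng(0))
mb.write_dataset(data, "example.csv")
```

```text
$ mataboot weights example.csv
...
P+I                              -4.842 0.000
P+I+PI                          -48.780 0.119
P+I+V+PI                        -46.785 0.044
P+I+V+PI+PV                     -45.705 0.026
P+I+V+PI+IV                     -51.347 0.431
P+I+V+PI+PV+IV                  -50.433 0.273
P+I+V+PI+PV+IV+PIV              -48.582 0.108
```

(columns: model, AIC, AIC weight; zero-weight rows elided here). Models
containing P, I and PI carry essentially all the weight, as the generating
effects suggest, but no single model dominates — exactly the situation
model averaging is for.

```text
$ mataboot intervals example.csv --seed 1 -B 9999 --methods ma_wald,mata_wald_t,mata_sboot
HDS    ma_wald      1.599409e+01 3.657632e+01
HDS    mata_wald_t  1.599317e+01 3.651314e+01
HDS    mata_sboot   1.614857e+01 3.679113e+01
```

Each row is one treatment combination (H/L = ambient/acidified pH,
D/B = dark/bright irradiance, S/F = slow/fast velocity) with the lower and
upper limits for the mean response on the original scale at 95% nominal
coverage (α = 0.025 per tail). The MATA-SBoot interval sits slightly higher
than both Wald-type intervals: the bootstrap detects the negative skewness
of the studentized statistics and shifts the interval up to protect the
upper error rate.

The simulation study sweeps the ten effect-magnitude scenarios
(LLL … HHH):

```sh
mataboot simulate --scenarios LLL,MMM --r 2 --n-sim 2000 -B 199 --seed 0 --tsv-out results.tsv
```

reporting per method the lower/upper error rates and mean relative
half-widths averaged over the eight cells. At r = 2 the MA-Wald upper error
rate exceeds the nominal 2.5% while MATA-SBoot stays close to it; at r = 50
all studentized methods are near-nominal and the percentile interval is
conservative. See `docs/methods.md` for the estimators, solver details and
study design.

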
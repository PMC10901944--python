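# scsm — shared component spatial modelling of two areal count outcomes

`scsm` implements a Bayesian shared component spatial model (SCSM) for
jointly mapping two correlated count outcomes observed on the same small
areas — the motivating application is offender counts and offense counts
per census dissemination area, but any pair of areal counts with a common
latent driver fits (paired disease outcomes, two crime types, two species).
It is aimed at spatial epidemiologists and environmental criminologists who
want, instead of two separate disease-mapping runs, a single model that
splits each area's risk into what the outcomes *share* and what is
*specific* to each, with probabilistic hotspots for all three surfaces.

## Model

Counts O_ik (area i, outcome k = 1, 2) are Poisson with mean e_ik·r_ik,
where e_ik are indirectly standardized expected counts and

    log r_i1 = α₁ + δ·θᵢ + s_i1 + u_i1
    log r_i2 = α₂ + (1/δ)·θᵢ + s_i2 + u_i2

θ is a shared spatial field with intrinsic-CAR (ICAR) prior on the queen
contiguity graph, scaled reciprocally (δ and 1/δ) for identifiability;
s_k are outcome-specific ICAR fields and u_k iid normal effects (the BYM
convolution). Hyperpriors: Gamma(0.1, 0.1) on structured precisions,
Gamma(0.01, 0.01) on unstructured ones, log δ ~ N(0, 1/5.9) — calibrated so
the risk-gradient ratio δ² stays within [1/5, 5] with 95% prior
probability. Fitting is by a Metropolis-within-Gibbs sampler written for
this package (single-site random-walk updates plus likelihood-invariant
transfer moves that mix the weakly identified shared/specific split, and
conjugate Gibbs for precisions), with Brooks–Gelman–Rubin and
Monte-Carlo-error diagnostics. Outputs are per-area posterior risk
surfaces, exceedance probabilities Pr(risk > 1 | data) for hotspot
mapping, and the variance decomposition of each outcome's log-relative-risk
into shared / structured-specific / unstructured fractions.

Details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Because the study data that motivated the model are restricted, the package
ships a generator that simulates from the model itself at the study's
scale (populations 400–800 per area, outcome-1 counts 0–35). Fit a 15×15
lattice and read off the headline quantities:

```python
import scsm

data = scsm.simulate_dataset(scsm.SyntheticConfig(seed=42))   # 225 areas
fit = scsm.run_chains(
    data.areas, data.adjacency, scsm.PriorSpec(),
    scsm.SamplerConfig(n_chains=2, burn_in=20000, retained=20000,
                       thin=100, seed=1),
)
scaling = scsm.scaling_summary(fit)
decomp = scsm.variance_decomposition(fit)
print("max BGR          ", round(float(fit.rhat.rhat.max()), 3))
print("delta            ", round(scaling["delta"]["mean"], 2),
      (round(scaling["delta"]["lo"], 2), round(scaling["delta"]["hi"], 2)))
print("fraction shared  ", decomp.frac_shared_draws.mean(axis=0).round(2),
      " truth", data.true_fraction_shared.round(2))
```

prints (about 15 s)

```
max BGR           1.028
delta             1.2 (0.54, 2.14)
fraction shared   [0.2  0.15]  truth [0.36 0.21]
```

Both chains converge (all BGR < 1.1). The scaling parameter δ (truth 1.17)
is recovered with an interval that includes 1 — the two outcomes load
similarly on the shared surface. The posterior fraction of each outcome's
log-risk variance explained by the shared component tracks the realized
truth for outcome 2 and understates it for outcome 1: at this data
strength (~8 events per area) the shared/specific split is weakly
identified and the posterior shrinks toward the prior, a behaviour
quantified in the recovery study and discussed in the methods note. Hotspot
surfaces come from `scsm.summarize_surfaces(fit)`: per-area posterior means
of exp(θᵢ), exp(s_ik + u_ik) and r_ik with Pr(· > 1 | data) exceedance
probabilities, binned for mapping with `classify_hotspots` (top probability
class [0.96, 1]).

The same pipeline is scriptable from the shell via a YAML run
configuration:

```sh
scsm simulate cfg.yaml   # or: scsm prepare cfg.yaml  (GeoJSON + event CSVs)
scsm fit cfg.yaml        # samples, diagnostics, summary & surface tables
scsm summarize cfg.yaml  # recompute summaries from the cached posterior
```

`prepare` builds queen contiguity from a GeoJSON polygon layer, aggregates
point events by a point-in-polygon rule, and computes expected counts and
standardized ratios by indirect standardization; `fit` writes the posterior
(long CSV + npz cache), BGR / Monte-Carlo-error diagnostics, a
variance-decomposition summary table and per-area surface tables
(CSV/GeoJSON), plus a manifest with seeds and input checksums sufficient to
reproduce every output bitwise.

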
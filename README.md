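# nichepart

Bayesian partitioning of bivariate isotopic niches into within- and
between-individual components, for trophic ecologists studying individual
specialisation and coexistence in sympatric consumers.

## The problem

Stable-isotope ratios (δ¹³C, δ¹⁵N) locate a consumer in a two-dimensional
trophic niche space. When several tissues with different turnover windows
are sampled from the same individual, they act as repeated measures, and
the population's total niche width (TNW) can be split into

- **WIC** — the within-individual component: how broad the average
  individual's diet is, estimated as the sum of the eigenvalues (= trace)
  of the residual covariance **R** of a bivariate mixed model;
- **BIC** — the between-individual component: how far apart individual
  diet centroids sit, the eigenvalue sum of the random-intercept
  covariance **G**;

with TNW = WIC + BIC and the individual-specialisation index
**IS = BIC / TNW** ∈ [0, 1] (higher = individuals use narrower, more
distinct subsets of the population niche).

The model, fitted per species × season group to within-tissue z-scored
values, is

y<sub>it</sub> = μ + β<sub>campaign(it)</sub> + b<sub>i</sub> + e<sub>it</sub>,  b<sub>i</sub> ~ N₂(0, G),  e<sub>it</sub> ~ N₂(0, R),

sampled by a Gibbs cycle with inverse-Wishart priors on G and R, so that
every derived quantity — WIC, BIC, TNW, IS, the 67% total-niche confidence
ellipses and their directional overlap, and the posterior probabilities of
four coexistence mechanisms (M1 population-niche segregation, M2 enhanced
individual specialisation, M3 population-niche expansion, M4 individual
niche expansion) — carries full posterior uncertainty.

Two community-level indicators complete the picture: the phylogenetically
weighted effective abundance of competitors
N<sub>z</sub> = Σ N(z′)·exp(−d(z,z′)²/2σ²<sub>α</sub>) on max-normalised
patristic distances (σ²<sub>α</sub> = 0.05 by default), and prey richness /
inverse Simpson diversity as ecological-opportunity proxies.

Because individual-level isotope data of this kind are rarely deposited,
the package ships a first-class synthetic-data generator that mirrors the
fitted model and plants known G/R truth, so the whole pipeline is testable
end-to-end.

## Worked example

```python
from nichepart import (MixedModelConfig, default_study_design, run_analysis,
                       simulate_isotopes)

records = simulate_isotopes(default_study_design(), seed=42)
config = MixedModelConfig(n_iterations=4000, burn_in=1000, thin=10,
                          n_chains=2, seed=5)
result = run_analysis(records, config)
print(result.metric_summary().round(3).to_string(index=False))
for season, ov in result.overlaps.items():
    print(season, {k: round(v["mean"], 1) for k, v in ov.summary_percent().items()})
for row in result.mechanisms["M4"]:
    print(f'{row["label"]}: {row["probability"]:.3f}')
```

prints

```
   species       season metric  mean    sd  q2.5  q97.5
dispersive     breeding    TNW 2.807 0.375 2.143  3.578
dispersive     breeding    WIC 2.194 0.325 1.645  2.884
dispersive     breeding    BIC 0.613 0.238 0.300  1.265
dispersive     breeding     IS 0.217 0.069 0.106  0.391
  resident     breeding    TNW 1.185 0.201 0.854  1.647
  resident     breeding    WIC 0.652 0.109 0.481  0.897
  resident     breeding    BIC 0.533 0.183 0.265  0.966
  resident     breeding     IS 0.442 0.092 0.258  0.618
dispersive non_breeding    TNW 3.406 0.717 2.373  5.155
dispersive non_breeding    WIC 1.790 0.306 1.308  2.512
dispersive non_breeding    BIC 1.615 0.676 0.696  3.437
dispersive non_breeding     IS 0.461 0.104 0.250  0.672
  resident non_breeding    TNW 1.448 0.200 1.116  1.897
  resident non_breeding    WIC 1.040 0.149 0.797  1.377
  resident non_breeding    BIC 0.408 0.136 0.214  0.719
  resident non_breeding     IS 0.279 0.069 0.161  0.428
breeding {'dispersive_in_resident': 37.3, 'resident_in_dispersive': 87.6}
non_breeding {'dispersive_in_resident': 43.7, 'resident_in_dispersive': 97.2}
P(WIC[dispersive] breeding > non_breeding): 0.815
P(WIC[resident] breeding > non_breeding): 0.013
```

Read this as: the dispersive species has a ~2.4-fold broader total niche
than the resident in both seasons; the narrow resident niche sits almost
entirely inside the broad dispersive one (88–97% directional overlap)
while the converse overlap is under 44%; individual specialisation is
higher in the dispersive species outside breeding (0.461 vs 0.279) but the
contrast reverses during breeding (0.217 vs 0.442); and the posterior
probability that the dispersive species' individual niche width expands in
breeding (mechanism M4) is 0.815, while for the resident it is 0.013
(i.e. its WIC almost surely contracts). These recoveries match the truth
planted by `default_study_design()`.

The same stages are available from the shell:

```bash
nichepart simulate --seed 3 --out sim/
nichepart standardize --in sim/isotopes.csv --out sim/std.csv
nichepart fit --in sim/isotopes.csv --group resident:breeding --seed 2 --out fit/
nichepart metrics --posterior fit/resident_breeding_draws.csv --out metrics.csv
nichepart analyse --in sim/isotopes.csv --seed 2 --out analysis/
nichepart compete --tree sim/tree.nwk --census sim/census.csv --focal species_01 --out nz.csv
nichepart opportunity --in sim/prey_counts.csv --out opp.json
```

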
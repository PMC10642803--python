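# metsel

Multi-environment trial (MET) analysis and multi-trait selection for
plant breeding programs facing genotype-by-environment interaction
(GEI), built around the selection problem of late-stage cassava trials:
many genotypes, many year x location environments, several correlated
traits, and the need to pick clones that are simultaneously productive
and stable.

## What it computes

For plot records `Y_ijk` from a randomized complete block design
replicated across environments, the package fits the random-effects
model

```
Y_ijk = mu + a_i + t_j + (at)_ij + y_jk + e_ijk
a_i ~ N(0, s2_g),  t_j ~ N(0, s2_e),  (at)_ij ~ N(0, s2_gxe),  e_ijk ~ N(0, s2_eps)
```

by REML (genotype, environment and GEI random; block-within-environment
fixed), with likelihood-ratio tests per random term, genotype BLUPs
with prediction-error variances, and genotype BLUEs from the companion
fixed-genotype model. From the fit it derives the standard genetic
parameters: broad-sense and genotype-mean heritability, the Cullis and
Piepho generalized heritabilities, phenotypic variance, CVg/CVr and
their ratio, the GEI determination coefficient and GEI correlation, and
selective accuracy.

Stability is quantified by Eberhart-Russell joint regression of each
genotype's environment means on the environmental index `I_j`, yielding
the deviation variance `Sdi2`, the regression `R2` and the regression
`RMSE`. Performance (predicted genotypic means) and one stability
statistic are rescaled to 0-100 (100 = desirable, honouring
lower-is-better traits such as the 1-5 plant-architecture score) and
combined into the mean performance and stability index

```
MPS_i = (rY_i * w_perf + rE_i * w_stab) / (w_perf + w_stab)
```

with default weights 65/35 and a 21-scenario sweep from 0/100 to 100/0.
The genotypes x traits MPS matrix is then summarized by exploratory
factor analysis (Kaiser retention, varimax rotation, regression-type
scores `F = Z R^-1 A`), and the multi-trait index

```
MTMPS_i = sqrt( sum_j (F_ij - F_j)^2 )
```

ranks genotypes by Euclidean distance from the ideotype (MPS = 100 on
every trait); the closest `ceil(0.30 g)` are selected and per-trait
selection gains are reported. A Pearson correlation network and path
analysis (direct effects `b = Rxx^-1 rxy`, VIF diagnostics) describe
the trait relationships.

Because raw trial data of this kind are rarely released, the package
ships a synthetic MET generator with the same random-effects structure
(defaults shaped on a published cassava series: 22 genotypes x 47
environments x 3 blocks, seven traits), so every stage is testable
end to end.

## Worked example

```
$ metsel run --g 22 --e 10 --b 3 --seed 7 --out-dir out
selected genotypes: G03, G18, G08, G01, G16, G05, G21
outputs in out (24 files)
```

The bundle contains, among others, `genetic_parameters.csv` (one column
per trait):

```
H2          0.312  (FRY)   ... broad-sense heritability on the plot basis
h2_mg       0.867          ... heritability of genotype means (e=10, b=3)
H2_cullis   0.867          ... generalized heritability from BLUP PEVs
H2_piepho   0.867          ... from BLUE difference variances
CVg / CVr   20.5 / 20.6    ... genotypic vs residual variation (%)
```

and `mtmps_ranking.csv`:

```
,MTMPS,rank,selected
G01,1.411452,4,True
G02,3.332061,20,False
G03,1.163182,1,True
```

G03 has the smallest genotype-ideotype distance, i.e. the best joint
performance/stability profile over all seven traits; seven genotypes
(30% of 22) are selected. On this balanced simulated design the Piepho
and genotype-mean heritabilities coincide, as theory says they must.

Library use mirrors the CLI:

```python
import metsel

ds, truth = metsel.simulate_met(metsel.SimulationSpec(seed=7))
fit = metsel.fit_random_model(ds, "FRY")
params = metsel.genetic_parameters(fit, e=ds.n_environments, b=ds.n_blocks)
```

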
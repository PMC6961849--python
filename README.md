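# groomnet

Social grooming networks from scan-sampling data, and multi-model
mixed-effects inference on individual network positions.

The package targets a common design in primate behavioural research:
group-housed individuals (here, sanctuary chimpanzees observed over many
years) are scan-sampled every 2 minutes during 20-minute sessions, and
the question is how individual characteristics — sex, wild-caught vs
captive-born origin, housing condition during infancy, arrival age — and
the stability of group composition shape each individual's grooming
behaviour. `groomnet` turns raw scan records into per-period directed
grooming matrices, computes two weighted network measures per
individual, and runs the full information-theoretic inference chain over
linear mixed models.

## The measures and the model

For each observation period (an interval of fixed group composition,
labelled stable or unstable), the weight from individual *i* to *j* is
the percent of their co-present scans in which *i* groomed *j*:
`w_ij = 100 · groom_ij / copresent_ij`. With strength `s_i = Σ_j w_ij`:

* **VSC** (vertex strength centrality) `= s_i/(N−1)` — mean percent of
  opportunity spent grooming a given partner; grooming *activity*.
* **DEWD** (deviation from edge weight disparity)
  `= Σ_j (w_ij/s_i)² − 1/(N−1)` — how far grooming departs from an even
  spread over all partners, 0 (perfectly even) to (N−2)/(N−1) (one
  partner only); grooming *choosiness*. Undefined for non-groomers.

Each measure is analysed with Gaussian LMMs: five binary fixed factors
(stability, arrival age, sex, origin, infant housing) and crossed random
intercepts for individual and period. All 32 factor subsets are fitted
by ML, ranked by AICc; models with ΔAICc < 10 are conditionally
averaged, each factor gets a relative variable importance (RVI = sum of
Akaike weights over subset models containing it), and final per-term
tests use Type-III F with Satterthwaite degrees of freedom. A synthetic
scan generator (Dirichlet-multinomial partner choice, logistic activity
model) provides study-scale data for end-to-end validation.

## Worked example

Simulate a study-scale dataset, run the pipeline, and read the averaged
model table:

```python
from groomnet import SimConfig, measures_from_simulation
from groomnet import enumerate_candidates, fit_lmm, rank_models, \
    average_conditional

measures = measures_from_simulation(SimConfig(seed=1))
print(len(measures))                      # 119 individual-period records
fits = [fit_lmm(measures, s) for s in enumerate_candidates(response="vsc")]
ranked = rank_models(fits)
averaged = average_conditional(ranked)
print(averaged.table.round(3))
print(averaged.rvi.round(2))
```

Output:

```
119
               estimate     se  adjusted_se      z      p
term
(Intercept)       2.460  0.352        0.355  6.930  0.000
Origin           -0.949  0.351        0.354  2.677  0.007
TPstability      -0.513  0.288        0.291  1.761  0.078
ArrivalAgeCat    -0.618  0.359        0.362  1.708  0.088
Sex              -0.300  0.322        0.325  0.922  0.357
PHCinfant        -0.226  0.295        0.298  0.761  0.447
                rvi  n_containing_models
factor
TPstability    0.58                   14
ArrivalAgeCat  0.58                   16
Sex            0.33                   13
Origin         0.88                   16
PHCinfant      0.31                   12
```

The generating model gave wild-caught individuals a 1-logit deficit in
grooming activity and no other covariate effects: the averaged Origin
coefficient is negative (wild-caught lower VSC) with the highest RVI,
while the inert factors carry small estimates and middling RVIs.

The same stages are available from the shell:

```sh
groomnet simulate --seed 1 --out data/
groomnet pipeline --roster data/roster.csv --periods data/periods.csv \
    --scans data/scans.csv --out results/
```

which writes grooming matrices, GraphML networks, the measures table,
candidate-model and averaged-coefficient tables, RVI, VIF and Type-III
ANOVA CSVs plus a JSON run report.

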
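# dtmediate

Mediation analysis with survival outcomes, via the discrete-time logistic
hazard model embedded in a recursive path system.

## The problem

Epidemiologists studying inequalities in time-to-event outcomes (e.g. cancer
survival by social class) often need more than the *direct* effect of a
baseline exposure: the interesting policy questions concern the *pathways* —
does deprivation raise the hazard of death because deprived patients are more
often admitted as emergencies, or treated at low-volume hospitals? Standard
continuous-time survival models make this hard: proportional-hazards models
are not closed under marginalization, so comparing Cox fits with and without
a mediator is not a valid decomposition.

Working in discrete time solves this. Follow-up is split into periods
(quarters, here), and the hazard

$$h_{ij} = P(T_i = j \mid T_i \ge j) = \operatorname{expit}\big(\beta_j + \kappa' x_i\big)$$

is a logistic regression on the person-period expansion of the data, with
survival $S_j = \prod_{k \le j}(1 - h_k)$. Under the latent-response reading
of the logit (a continuous propensity crossing a threshold $\tau_j = -\beta_j$),
the hazard equation is *linear* in the latent metric. Embedding it as the
terminal equation of a recursive path system — binary mediators modelled by
linear probability equations — makes the whole system linear, so:

- each **natural indirect effect** is a product of path coefficients
  (e.g. exposure → mediator × mediator → hazard),
- its standard error follows from the first-order **delta method**,
- the **total effect** is the direct effect plus the sum over all indirect
  paths, and the **mediation proportion** is their ratio.

The package provides the person-period machinery, the maximum-likelihood
hazard model (unstructured / constant / piecewise baselines, proportionality
LR test, cluster-robust standard errors), the path-system estimator and
mediation engine (path enumeration on the DAG, products, delta-method and
bootstrap intervals), and a synthetic-cohort generator for validation by
parameter recovery.

## Worked example

`examples/` ships the published direct effects from an Irish colon-cancer
cohort (5178 patients diagnosed 2004–2008, followed quarterly up to 24
periods): affluence (0–1 scale) affects emergency admission and hospital
caseload, which in turn affect the hazard of death. The decomposition needs
only the coefficient table, not the raw registry data:

```bash
dtmediate decompose \
    --coefficients examples/colon_direct_effects.csv \
    --config examples/colon_model.yaml \
    --out decomposition.csv
```

prints

```
             effect                                        label  estimate    se      z     p
             direct                                    affluence    -0.596 0.271 -2.199 0.028
           indirect              affluence -> caseload -> hazard    -0.100 0.043 -2.317 0.021
           indirect             affluence -> emergency -> hazard    -0.124 0.036 -3.452 0.001
           indirect affluence -> emergency -> caseload -> hazard    -0.003 0.002 -1.705 0.088
     total_indirect                         all indirect effects    -0.227 0.057 -3.958 0.000
              total                                    affluence    -0.823 0.277 -2.971 0.003
proportion_mediated                                    affluence     0.276   NaN    NaN   NaN
```

Reading: moving from the most deprived to the most affluent neighbourhood
lowers the latent hazard of colon-cancer death by 0.82 SD in total, of which
0.60 is direct and 0.23 flows through the two mediators — about 28% of the
total effect is mediated, split roughly evenly between admission route and
hospital caseload.

The same engine runs end-to-end from data:

```bash
dtmediate simulate --out sim --n 5178 --jmax 24 --seed 1   # synthetic cohort
dtmediate fit --data sim/cohort.csv --config examples/colon_model.yaml --out fit
dtmediate recovery --out recovery.csv --replicates 100 --n 5000 --seed 1
```

or from Python:

```python
import dtmediate as dm

cfg = dm.SyntheticConfig(n=5178, seed=1)
frame, truth = dm.simulate_frame(cfg)
fit = dm.fit_path_system(frame, cfg.model_spec())
print(dm.decompose(fit).to_frame())
```

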
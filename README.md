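# recruitmap

Trait × density recruitment modelling for sessile organisms.

After a pulse of larval settlement, a cohort of sessile invertebrates
(the motivating system is the intertidal barnacle *Semibalanus
balanoides*) loses individuals to crowding: as survivors grow, the space
they occupy — *cover*, the product of density and mean individual area —
can keep rising even while numbers fall, so the strength of
density-dependent mortality is set jointly by numbers and body size.
`recruitmap` implements a closed-cohort model built on that idea, the
regression pipeline that fits it to quadrat census data, a synthetic-data
generator shaped like the motivating field study, and a spatial
individual-based simulator for probing the microscopic assumptions behind
the macroscopic survival forms.

## The model

Cohort density `N_t` and mean body size `φ_t` evolve in discrete steps:

    N_{t+1} = N_t · λ(N_t · φ_t)
    φ_{t+1} = φ_t e^{−K} + φ_∞ (1 − e^{−K})        (Ford–Walford growth)

where `u = N·φ` is resource use and `λ(u)` the per-step survival
fraction, in one of three two-parameter forms (all with `λ(0) = α`, the
resource-independent survival, and β the resource-use-dependent
mortality parameter, `1/β` ∝ carrying capacity):

| form        | λ(u)                         | linearized response        |
|-------------|------------------------------|----------------------------|
| exponential | `α·exp(−β·u)`                | `ln S = ln α − β·X`        |
| logistic    | `1/(1 + α'·e^{β·u})`, `α' = 1/α − 1` | `ln(1/S − 1) = ln α' + β·X` |
| hyperbolic  | `α/(1 + β·u)`                | `1/S = 1/α + (β/α)·X`      |

Plotting `N_t` against the initial density `N_0` gives the
settler–recruit map.  Its shape diagnoses the functional form: the
hyperbolic map rises monotonically, the exponential map is humped
(overcompensating) and only flattens with time, while the logistic map
develops **two or more points of compensation** at later steps — a
signature no density-only model reproduces.

Fitting works on quadrat censuses at irregular calendar intervals:
interval survival `S = N_end/N_start` is standardized to a common 30-day
step (`S_30 = S^{30/T}`), linearized per form, and regressed by OLS on a
resource-use descriptor `X` (density `N`, basal cover `B·N`, or operculum
cover `O·N`).  An extended logistic model adds period-specific α and a
dead-shell-cover mortality term; the four on/off combinations are
compared by Gaussian-OLS AIC with the standard parsimony-within-2-units
selection rule.

## Worked example

Generate a study-shaped synthetic dataset (2 shores × 52 quadrats × 3
census intervals, binomial survival, known truth), fit all form ×
descriptor combinations, and run AIC selection:

```sh
recruitmap generate --seed 42 --out census.csv --truth-out truth.json
recruitmap fit    --input census.csv --out-prefix fit
recruitmap select --input census.csv --out-prefix sel
```

`fit_adj_r2.csv` (adjusted R², transformed scale):

```
  shore  descriptor  exponential  hyperbolic  logistic
Shore-1 basal_cover        0.035       0.055    -0.003
Shore-1     density        0.108       0.132     0.046
Shore-1 operc_cover        0.456       0.480     0.323
Shore-2 basal_cover       -0.006      -0.006    -0.003
Shore-2     density       -0.004      -0.005     0.008
Shore-2 operc_cover        0.391       0.348     0.500
```

Operculum cover — the non-plastic trait times density — explains survival
far better than density alone or basal cover (the plastic trait shrinks
at high density, destroying its information content).  `sel_winner.csv`:

```
  shore              model           period  alpha  beta_live  beta_dead
Shore-1 alpha(period)+dead        June-July 0.9736     0.0428     0.0348
Shore-1 alpha(period)+dead     July-October 0.9258     0.0428     0.0348
Shore-1 alpha(period)+dead October-February 0.9226     0.0428     0.0348
Shore-2 alpha(period)+dead        June-July 0.9804     0.0325     0.0888
Shore-2 alpha(period)+dead     July-October 0.9604     0.0325     0.0888
Shore-2 alpha(period)+dead October-February 0.9612     0.0325     0.0888
```

AIC selects the full model (period-varying α plus dead cover) on both
shores, and the estimates recover the generating truth — Shore-1 was
simulated with α = (0.97, 0.92, 0.92), β_live = 0.0408, β_dead = 0.0361;
Shore-2 with α = (0.98, 0.96, 0.96), β_live = 0.0321, β_dead = 0.0836.

Settler–recruit maps and the individual-based simulator:

```sh
recruitmap simulate-map --form logistic --alpha 0.99 --beta 0.2 \
    --steps 0,100,300,500 --out map.csv
recruitmap ibm --response threshold --intensities 50,100,200,400,800 \
    --n-steps 10 --replicates 6 --seed 7 --out ibm.csv
```

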
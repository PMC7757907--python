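# zonarisk

Invasion-risk mapping for the peach fruit fly *Bactrocera zonata* (and any
pest with presence-only records): a presence-background maximum-entropy
climatic-suitability model, a host-availability overlay, and a Gaussian
dispersal-kernel model of short-distance natural spread — built as a
reusable, fully testable pipeline that runs end to end on synthetic
landscapes with known truth.

## Who this is for

Quantitative ecologists and biosecurity analysts who want the standard
presence-only risk-mapping chain — occurrence cleaning, collinearity
pruning, MaxEnt-style niche modelling, suitability reclassification,
habitat overlay, kernel-based spread — as an importable Python library with
explicit seeds, provenance logs and oracle-tested primitives, rather than a
chain of GUI tools.

## The models

**Climatic suitability.** A Gibbs (maximum-entropy) density over
environmental feature space,

    q_λ(x) = exp(λ·f(x)) / Z,

is normalized over a background sample (plus the presences) and fitted by
maximizing the L1-penalized mean presence log-likelihood
`(1/m) Σ log q_λ(x_i) − Σ_j β_j |λ_j|`. Features `f` are the linear,
quadratic and hinge transforms of each covariate rescaled to [0, 1]; the
per-feature penalty is scaled by a regularization multiplier (default 2).
Predictions use the logistic output `p = e^H q / (1 + e^H q)` with `H` the
entropy of the fitted distribution, so an uninformative model scores 0.5
everywhere. Evaluation: rank-sum AUC of held-out presences against the
background, percent contribution from the coordinate-descent gain trace,
leave-one-out / single-variable jackknife, and the 10th-percentile
training-presence threshold.

**Overall habitat suitability.** With min–max normalization
`n(x) = (x − min) / (max − min)`,

    S = (n(cs) + n(h)) / 2  ∈ [0, 1],

the equal-weight mean of climatic suitability `cs` and host availability
`h` (harvested area, ha). Maps are cut into four classes at
0.15 / 0.30 / 0.60 (not suitable / low / medium / high).

**Natural spread.** Reading the species' maximum recorded dispersal
distance `D_max = 40.2 km` (25 miles) as 3σ of a Gaussian displacement
distribution gives σ = 13.4 km, `c1 = 1/(σ√2π) ≈ 0.03`,
`c2 = 1/(2σ²) ≈ 0.003`, and the per-cell likelihood of natural spread

    l = [(k1·n(cs) + k2·n(h)) / (k1 + k2)] · c1·exp(−c2·x²),

with `x` the great-circle distance (km) to the nearest occurrence and
`k1 = k2 = 0.5`.

## Worked example

`examples/03_fit_niche_model.py` fits the model on the default synthetic
landscape (100×100 cells, 12 predictors of which 8 informative and 4
collinear duplicates, 150 presences sampled from a known truth surface):

```
records after 10-km thinning: 93 (70 train / 23 test)
predictors retained after |r|>0.7 pruning: ['bio01', 'bio02', 'bio03', 'bio05', 'bio06', 'bio07', 'bio08', 'bio12']
  dropped: ['bio09', 'bio10', 'bio04', 'bio11']
held-out AUC (test presences vs background): 0.943
Spearman rho, predicted vs true suitability: 0.904
```

Thinning enforces a 10-km minimum between records; the pruning step
recovers the 8-variable structure planted in the stack; AUC 0.943 means a
held-out presence outranks a random background cell 94% of the time; the
Spearman value says the predicted map reproduces the generating truth's
ranking. The other examples cover the landscape generator, occurrence
cleaning, the habitat overlay, the dispersal kernel
(`kernel(0) = 0.03`, `kernel(13.4 km) = 0.0175`) and the full file-based
pipeline with a +2 °C scenario.

A thin CLI mirrors the stages:

```bash
zonarisk simulate --out fixture --seed 0
zonarisk thin fixture/occurrences.csv thinned.csv --min-km 10
zonarisk select-vars fixture/predictors --cutoff 0.7
zonarisk disperse --cs cs_norm.asc --host host_norm.asc \
    --sources thinned.csv --out spread.asc --dmax 40.2
```

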
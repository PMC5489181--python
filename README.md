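# camrecap

Robust-design capture-recapture analysis for long-term camera-trap monitoring
of individually identifiable animals (e.g. jaguars, tigers, leopards — any
species with stable natural markings).

## The scientific problem

A camera-trap grid photographs animals over a series of annual survey seasons.
Individuals are identified from their coat patterns, giving a multi-year record
of *who* was seen *when*. Three things complicate the analysis:

1. **Imperfect detection.** An animal present on the grid may simply not walk
   past a camera; raw counts underestimate abundance, differently per sex.
2. **Temporary emigration.** Ranges are larger than the grid, so an animal can
   be alive but off-grid for a whole season and undetectable.
3. **Open population.** Across years, animals die, are recruited, and move —
   but within one short survey season the population is effectively closed.

The **Pollock robust design** exploits the two time scales: *secondary*
occasions (here, week-long blocks within one survey) estimate detection
probability and abundance under closure, while transitions between *primary*
occasions (years) estimate apparent survival φ and temporary emigration γ.
`camrecap` implements this as a three-state hidden Markov model (on-grid,
off-grid, dead), fitted by maximum likelihood conditional on first capture
(Huggins-style), with AICc model selection, Akaike-weight model averaging,
and derived abundance N̂ = n / p\*.

Beyond the core model, the package includes:

- event ingestion: CSV parsing, a 24-hour independence filter, binning into
  primary × secondary detection histories, MARK-format export/import;
- derived demography: annual rate of change λ, geometric mean growth,
  recruitment with survival correction, minimum ages, entry cohorts;
- population structure: resident/transient classification (three consecutive
  detection years), Monte-Carlo permutation tests, exact small-sample rank
  tests, detection-span regressions, quarterly subsampling of year-long
  surveys;
- a synthetic event generator with a complete truth ledger, used for
  end-to-end parameter-recovery validation.

## Worked example

Simulate a 14-year monitoring program (12 annual surveys with a two-year gap,
film cameras then digital), push the events through the same pipeline field
data would take, and fit the constant-survival, random-emigration model:

```python
import camrecap as cr

config = cr.paper_preset(seed=42)
ledger, events = cr.simulate_population(config)
events = cr.filter_independent(events)               # 24-h independence rule
history, report = cr.build_capture_histories(
    events, config.design, drop_unknown_sex=True
)
print(f"individuals detected: {history.n_individuals}")

fit = cr.fit_model(cr.TOP_STRUCTURE, history, config.design, n_starts=3, seed=42)
print(f"model: {fit.name}")
print(f"log-likelihood: {fit.loglik:.2f}   AICc: {fit.aicc:.2f}")
phi = fit.real[fit.real["param"] == "phi"].iloc[0]
gam = fit.real[fit.real["param"] == "gamma_pp"].iloc[0]
print(f"apparent survival  phi = {phi['estimate']:.3f} (SE {phi['se']:.3f})")
print(f"temporary emigration gamma = {gam['estimate']:.3f} (SE {gam['se']:.3f})")

ab = cr.derived_abundance(fit, history, config.design)
print(ab[ab["sex"] == "male"].head(4).to_string(index=False))
```

Output:

```text
individuals detected: 63
model: phi(.) gamma(random,.) p(sex*era(./time))
log-likelihood: -1208.46   AICc: 2445.66
apparent survival  phi = 0.774 (SE 0.031)
temporary emigration gamma = 0.224 (SE 0.052)
 sex  year  n   p_star     N_hat       se  estimable
male  2002 16 0.992317 16.123875 0.354879       True
male  2003 14 0.996830 14.044521 0.211803       True
male  2004 13 0.988040 13.157365 0.400945       True
male  2005  8 0.995065  8.039676 0.200017       True
```

The generating values were φ = 0.78 and γ = 0.20; both are recovered within
one standard error on this single replicate.

Derived demography works on any tidy abundance/survival table; the package
ships a reference table (`camrecap.datasets`) of model-averaged estimates from
a long-term jaguar monitoring program:

```python
from camrecap import datasets
ab = datasets.reference_abundance()
phi = datasets.reference_survival()
lam = cr.lambda_series(ab)
gm = cr.geometric_mean_lambda(lam["total"])
print(f"geometric mean lambda (total): {gm.gmean:.2f}  (n = {gm.n})")
rec = cr.recruits(ab, phi)
print(f"mean recruits per year (total): {cr.recruit_summary(rec['total']).mean:.1f}")
w = cr.akaike_weights(datasets.reference_model_selection()["aicc"])
print(f"top-model Akaike weight: {w['weight'].iloc[0]:.2f}")
```

Output:

```text
geometric mean lambda (total): 1.04  (n = 10)
mean recruits per year (total): 6.1
top-model Akaike weight: 0.70
```

A `camrecap` command-line interface wraps the same pipeline
(`camrecap simulate | build | fit | demography | structure`); see
`camrecap --help`.

## Model structure DSL

Structures are named like MARK models, e.g.
`phi(.) gamma(random,.) p(sex*era(./time))`:

- `phi(.)` constant survival; also `sex`, `time`, `sex*time`, `sex(./time)`
  (females time-varying), `sex(time/.)` (males time-varying);
- `gamma(random,.)` random temporary emigration (γ′ = γ″), `markovian` frees
  both, `none` fixes no emigration; `.` vs `time` for time dependence;
- `p(sex*era(./time))` sex-specific detection, constant over the film era and
  year-specific over the digital era; also `.`, `sex`, `sex*era`, `era(./time)`.

Parse with `cr.parse_structure(name)`; the seven-model ranked candidate set is
`cr.printed_candidate_set()`.

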
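# Methods

This document specifies the statistical model implemented by `camrecap`, the
assumptions behind it, the scope of the synthetic-data generator, the
numerical choices made in fitting, and the known limitations.

## 1. Data model

The observational unit is a **detection event**: one time-stamped
identification of a known individual at a camera station. Events are thinned
to **independent detections** by a greedy forward scan per individual:
an event is kept iff it falls at least 24 hours (configurable) after the
previously *kept* event of the same individual. Independent detections are
then binned into a **robust-design capture history**: the survey layout is a
sequence of annual *primary* occasions (survey seasons), each cut into
consecutive 7-day *secondary* occasions (K = ⌊duration / 7⌋, with a short
remainder absorbed into the last window). The history for individual *i* is a
binary array over (primary *t*, secondary *k*): 1 iff at least one
independent detection fell in that window.

Cubs are excluded by default (the model describes the adult population);
unknown-sex individuals are flagged and excluded from sex-structured fits.

## 2. The robust-design likelihood

### States and transitions

Between primaries, each individual moves through a three-state Markov chain:

- **A** — alive, on the trapping grid (available for detection),
- **O** — alive, off the grid (temporary emigrant, undetectable),
- **D** — dead (absorbing; permanent emigration is confounded with death,
  which is why φ is *apparent* survival).

With annual apparent survival φ, probability γ″ of an on-grid animal being
off-grid next year, and probability γ′ of an off-grid animal remaining
off-grid, the one-year transition matrix is

```
        A                O            D
A  [ φ(1-γ″)           φγ″          1-φ ]
O  [ φ(1-γ′)           φγ′          1-φ ]
D  [    0                0            1 ]
```

Multi-year gaps between surveyed years (e.g. a two-year monitoring pause) use
the matrix power M^Δt, i.e. the same annual dynamics run unobserved.

Emigration modes: **random** constrains γ′ = γ″ (off-grid probability is
independent of the previous state), **Markovian** frees both, **none** fixes
γ″ = 0, γ′ = 1 (no temporary emigration; the model then reduces exactly to a
Cormack–Jolly–Seber survival model when K = 1).

### Emissions and conditioning

Within a primary with K secondary occasions the population is assumed closed,
and detection is an independent Bernoulli(p) per occasion for on-grid
animals; off-grid and dead animals produce the all-zero history. Because p is
constant within a primary, the within-primary emission depends only on the
detection *count* d: p^d (1−p)^(K−d).

The likelihood is **conditional on first capture** (Huggins-style): for an
individual first detected in primary f, the first-primary contribution is the
emission probability divided by p\*_f = 1 − (1 − p_f)^K (the probability of
at least one detection given presence), and the individual is known to be in
state A at f. Subsequent primaries are handled by the standard hidden-Markov
forward algorithm with the transition and emission terms above. No
entry/recruitment parameters are estimated; abundance is derived (below).

Detection may vary by sex, by camera era (e.g. film vs digital equipment
generations), and by year within an era; survival may vary by sex and/or
year; emigration by mode and time. Model structures are named with a small
DSL (see the README) and mapped to a minimal coefficient vector on the logit
scale.

### Derived abundance

For each sex and primary, N̂ = n / p\*, with n the number of distinct
individuals of that sex detected in the primary. The variance combines the
binomial component n(1 − p\*)/p\*² with the detection-parameter uncertainty
by the delta method through p\* (logit-scale coefficient variance from the
inverse observed information). Sexes with n = 0 in a year are reported as not
estimable rather than N̂ = 0.

### Model selection and averaging

AICc = −2ℓ + 2K + 2K(K+1)/(n_eff − K − 1), with the effective sample size
n_eff = Σ_i (T − f_i) (per-individual primaries from first capture to the end
of the study; a documented convention — AICc sample size for capture-recapture
data has no unique definition). Akaike weights are w_m ∝ exp(−Δ_m/2).
Model-averaged real-scale estimates use the Burnham–Anderson unconditional
standard error: SE = Σ_m w_m √(var_m + (θ̂_m − θ̄)²).

## 3. Derived demography

From a tidy abundance table (sex × year, with estimability flags):

- **Annual rate of change** λ_t = N̂_{t+1}/N̂_t, computed only across
  one-year intervals (never across monitoring gaps). If one sex is not
  estimable, the total is computed with that sex as 0 and flagged `partial`;
  the per-sex λ is left undefined.
- **Geometric mean growth** over the λ series, with the sample variance of
  the λ values reported alongside.
- **Recruits** B_t = N̂_{t+1} − φ_t N̂_t, floored at 0 by default (a negative
  point estimate is sampling noise); raw values are retained in `_raw`
  columns. Sexes not estimable at t contribute 0 to that year, matching the
  published-table convention the reference dataset reproduces.
- **Minimum age** = (last − first detection year) + 2, assuming an animal is
  at least 2 years old (independent adult) at first detection.
- **Entry cohorts** from the yearly detection matrix; individuals first seen
  in the first surveyed year after a monitoring gap get a merged cohort label
  (e.g. "2009/2011") since their true entry year is censored by the gap.

## 4. Population structure

- **Residency**: an individual is a *local resident* in an evaluation window
  if detected in ≥ 3 consecutive *surveyed* years (gaps in monitoring are
  bridged, not counted as absences); one buffer survey year on each side of
  the window is used so edge runs are judged fairly. Everyone else detected
  in the window is a *transient with respect to the grid* — the grid is much
  smaller than a home range, so "transient" is an observational, not a
  biological, category.
- **Two-group comparisons** use a Monte-Carlo permutation test on the
  difference of means (add-one p-value convention, (1 + c)/(B + 1)), plus
  exact small-sample Wilcoxon signed-rank (V = sum of positive signed ranks)
  and Mann–Whitney tests via scipy.
- **Detection-span regression**: per-sex OLS of span (last − first year) on
  the number of years detected. Perfectly consecutive detection histories
  give slope 1; every-other-year histories give slope 2. The sex difference
  in slopes is the interaction term of a pooled model.
- **Quarterly subsampling** splits a year-long continuous survey into four
  contiguous quarters and reports, per quarter and sex, the fraction of the
  year's detected individuals seen — a design probe for how much a short
  seasonal survey misses.

## 5. Synthetic-data generator

The generator produces *event-level* records with a complete truth ledger, so
every pipeline stage (parsing, independence filtering, binning, fitting) can
be validated end to end.

Scope and mechanics:

- Yearly dynamics over every calendar year the design spans (including
  monitoring-gap years): survive with probability φ, then move between
  on-/off-grid per the emigration mode; Poisson per-capita recruitment on the
  living resident population; an optional transient stream (enter on-grid,
  dwell 1–2 years, leave permanently, detected at half the resident rate).
- Detection: per secondary occasion, Bernoulli with sex- and era-specific p
  (year-specific within the digital era in the default preset).
- Event timing: each individual has a fixed daily "passage hour"; a detected
  occasion yields one event at that hour on a random day of the week-window,
  plus a Poisson number of clustered duplicates within the next six hours.
  This caricature of trail-patrolling behaviour guarantees the 24-hour filter
  reproduces the true week-level detection matrix exactly, making the ledger
  an exact oracle.
- Randomness: a single seed spawns separate demography and detection
  sub-streams (`numpy` `SeedSequence`), so runs are reproducible and
  components re-runnable.

The default preset (`paper_preset`) mirrors a real monitoring program's
scale: 12 annual primaries (7 film-era, 5 digital-era, a two-year gap), 10–14
weekly secondaries, 19 stations, φ = 0.78, random emigration γ = 0.20,
film-era detection 0.36 (males) / 0.07 (females), year-specific digital
detection, balanced true sex ratio with 16 initial animals per sex and
per-capita recruitment 0.22. The detected sex ratio under this preset is
male-biased (~2:1) purely through detectability — an emergent property, not
an input. The transient stream is off by default: transients leave
permanently, so including them deliberately depresses pooled apparent
survival below the resident rate; enable it (`transients=True`) for
structure-analysis experiments.

Out of scope: spatially explicit movement (stations are drawn uniformly),
individual detection heterogeneity beyond the resident/transient dichotomy,
and cub dynamics.

## 6. Numerical choices

- Coefficients live on the logit scale, bounded in [−15, 15] for L-BFGS-B;
  |β| > 10 flags a boundary estimate (e.g. p̂ → 1 under perfect detection).
- Multi-start optimisation: first start at β = 0 (all probabilities 0.5),
  further starts logit-uniform on (0.05, 0.95). The replicated recovery
  experiment uses a single start with a dispersed-restart fallback on
  non-convergence, which is sufficient for this well-behaved likelihood and
  keeps 200 replicates within minutes.
- The likelihood is vectorised over individuals by collapsing identical
  (sex, per-primary-count) histories with multiplicity weights; the forward
  recursion renormalises each step to avoid underflow.
- The covariance is the pseudo-inverse of the numerically differentiated
  observed information (symmetrised); non-positive diagonal entries are
  reported as missing rather than clipped.
- Real-scale standard errors use the delta method through the logistic link.

## 7. Validation

- **Exactness oracles**: exhaustive enumeration (all histories at T = 3,
  K = 2, including a multi-year gap, sum to probability 1 over 50 random
  parameter draws); closed-form M0 at T = 1; an inline Cormack–Jolly–Seber
  oracle at K = 1 with no emigration; brute-force re-implementations of the
  independence filter, run-length residency rule and cohort counts; exact
  enumeration nulls for the permutation and rank tests.
- **Recovery**: 200 end-to-end replicates at the preset scale, fitted with
  the top-ranked structure, recover φ and γ with |mean bias| < 0.03 and 95%
  Wald coverage between 90% and 99% (see `tests/test_acceptance.py` and
  `scripts/acceptance.py`).

## 8. Limitations

- Apparent survival confounds death with permanent emigration; φ is a lower
  bound on true survival.
- The derived abundance is conditional on the fitted detection model; it
  inherits any misspecification of p (e.g. unmodelled individual
  heterogeneity biases N̂ low).
- The closure assumption within primaries is approximate for long seasons;
  the week-level binning does not test it.
- Random-emigration γ is only identifiable through its joint effect with p
  on between-year detection patterns; sparse female data can leave γ poorly
  determined in sex-stratified fits.
- The AICc effective-sample-size convention (Σ(T − f_i)) is one of several
  defensible choices; rankings can shift slightly under alternatives.
- The generator is not spatially explicit; analyses that depend on station
  geometry (spacing, home-range coverage) cannot be validated with it.
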
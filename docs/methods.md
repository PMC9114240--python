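# Methods

## Model

A TDS record is a categorical time series at 1-second resolution: which of
J attributes a panelist perceives as dominant at each second, ending when
the panelist clicks finish.  `tdsmc` treats each record as a realization
of a semi-Markov chain (SMC):

1. the first dominant attribute is drawn from an initial distribution
   over the J attributes;
2. each dominance spell lasts an integer number of seconds drawn from a
   sojourn distribution that may depend on the attribute and the
   panelist;
3. when a spell ends, the next attribute (or the terminal STOP state) is
   drawn from the embedded transition matrix; self-transitions are
   structurally impossible, because a spell only ends when the dominant
   attribute changes.

The likelihood factorizes as initial × sojourn durations × embedded
transitions × the terminal STOP transition, with durations independent of
the destination state.  The final spell is treated as fully observed, not
right-censored: the finish click is interpreted as the end of the last
dominance, which is the natural reading of the protocol.  Initial and
transition probabilities are estimated by relative frequencies (their
MLE); a dedicated test confirms on small instances that the frequency
estimates maximize the transition part of the likelihood over a dense
grid of candidate matrices.

Sojourns are modeled by negative binomial (NB) distributions with mean mu
and shape kappa,

    f(y; mu, kappa) = Gamma(y+kappa) / (Gamma(y+1) Gamma(kappa))
                      (mu/(mu+kappa))^y (kappa/(mu+kappa))^kappa,

so kappa = 1 recovers the geometric sojourns implied by a first-order
Markov chain and kappa -> infinity the Poisson.  Under negative binomial
regression (NBR) the mean follows a log link in the panelist's covariates,
mu = exp(beta' [1, x_i]), and attributes are partitioned into G groups
whose members share one coefficient vector beta_g and one shape kappa_g.
Five nested families (G, N, Ng, R, Rg — see the README table) are compared
by AIC over the duration component only; initial/transition probabilities
are common to all five families and are excluded from the parameter
counts, consistent with the counts 1, 2, 2G, M+2, (M+2)G.

### Support shift

Observed durations are >= 1 s while the NB support starts at 0.  By
default the models describe y − 1 (`support_shift=True` on `ModelSpec`).
This keeps the kappa = 1 case exactly the geometric on {1, 2, ...} of a
Markov chain, so the G ⊂ N ⊂ ... nesting is exact.  A flag fits the raw
durations instead; which convention an external analysis used is usually
not stated, so both are exposed and the shift is the documented default.
The simulator samples on the shifted support to match.

## Fitting

Maximum likelihood over (beta, log kappa), by L-BFGS-B with analytic
gradients of the log-space NB log-likelihood (all terms are evaluated via
`logaddexp`, so extreme means cannot overflow).  Numerical choices:

- multistart over log kappa in {−1, 0, 2}; intercept started at
  log(mean shifted duration + 0.1), other coefficients at 0; the best of
  the three solutions is kept;
- coefficients bounded at ±30 (a degenerate all-zero-duration block then
  converges to the boundary with log-likelihood ≈ 0, the correct
  degenerate-geometric limit, instead of diverging);
- kappa bounded in [1e−4, 1e6]; a solution at the upper cap is flagged
  `boundary` and should be read as "Poisson limit, shape not identified";
- tolerances ftol 1e−12 / projected-gradient 1e−8; a run that L-BFGS-B
  labels an abnormal line-search termination is still accepted as
  converged when the projected gradient is below 1e−5 relative to the
  objective, since that is a property of the line search, not of the
  solution;
- the grouped families (Ng, Rg) factor into independent per-group blocks
  and are fitted block by block — the optimum is identical and the
  conditioning better;  a group with no observed spell raises a named
  error rather than silently dropping a block.

Model G fixes kappa = 1 and optimizes the single mean; its MLE equals the
sample mean of the shifted durations, which the tests verify, along with
agreement of the R-family fit with an independent NB regression
implementation (statsmodels) to ~1e−4 in log-likelihood.

## Covariate selection

Candidate subsets are compared by AIC with the same subset applied to
every group in Rg.  The default strategy is exhaustive enumeration (2^K
fits, capped at K = 15; the 11-covariate design of a real panel costs
2048 fits, well within desk scale); greedy forward selection is the
fallback for larger candidate sets.  Ties are broken toward fewer
parameters, then lexicographic variable order.  Fits that fail to
converge are recorded in the ranking with a warning and excluded from the
choice of best subset.

## Curves

Standardized time maps second s of a length-L record to t = s/L; the
lookup is right-continuous and 1-based: the attribute at t is the one at
second min(L, floor(t·L) + 1).  The default grid has 101 points and no
smoothing (an optional centered moving-average window is available; it
preserves the unit column sums).  The chance level is P0 = 1/J and the
significance limit is the one-sided normal approximation
P0 + z_{1−alpha} sqrt(P0(1−P0)/n) at alpha = 0.05 — the conventional
threshold for TDS curves; the exact formula behind any given published
figure is rarely printed, so this is the package's documented convention.

## Covariate preprocessing

Panelists with any missing value among the selected covariates are
omitted, and each retained column is z-scored with the sample (n−1)
standard deviation.  Binary covariates are z-scored too by default
(a `scale_binary=False` flag passes them through untouched); whether a
given published analysis standardized its binaries is typically unstated,
so the symmetric choice is the default.  The missingness screen applies
only to the covariate families R/Rg — curves, transition estimation and
Models G/N/Ng use the full panel.

## Simulator

`simulate_panel` draws, per panelist: a covariate vector (binary or
continuous specs; 1–5 questionnaire scales are emulated as rounded,
clipped normals), a first attribute, then alternately a duration
1 + NB(mu, kappa_g) — with mu evaluated on the panel-z-scored covariates,
matching what `preprocess_covariates` produces downstream, so fitted
coefficients are directly comparable to the generating ones — and a next
state from the transition row, until STOP or the `max_length` truncation
cap (default 300 s, recorded per sequence so analyses can exclude
truncated records).

Preset configurations:

- `chocolate_like_config` — the default study conditions: 54 panelists,
  9 attributes in 4 groups (bitterness, sweetness, mouthfeel, richness),
  11 covariates mixing binaries, an age-like variable and 1–5 scales,
  group intercepts 2.0–2.45 on the log scale and per-run stop probability
  0.13, which puts the mean record length in the low-to-mid 80 s — the
  scale of real chocolate panels.  Covariate effects are small
  (|beta| <= 0.15) and shapes moderately overdispersed (kappa ≈ 2–3,
  consistent with a pooled fitted shape near 2.1).  Near-Poisson shapes,
  though they do occur as point estimates in small real groups, are not
  used as generator defaults because kappa is weakly identified there.
- `recovery_config` — 5 covariates, effects up to ±0.3 with
  group-specific signs, kappa in 1.5–3.0; used for parameter-recovery
  experiments at panel sizes 50–800.
- `ranking_config` — 3 covariates: one strong effect nearly uniform
  across groups, two flipping sign between groups, plus distinct
  intercepts and shapes per group; under these conditions the AIC order
  Rg < R < Ng < N < G is essentially deterministic at 400 panelists.

What the simulator does *not* emulate: panelist learning or fatigue,
replicate tastings, time-inhomogeneous transitions, and the run-count
distribution of real panels — with a constant stop probability the number
of spells per record is geometric, so simulated record lengths are more
dispersed (SD ≈ 79 s at the default) than real panels (~24 s).  Passing
tests therefore demonstrate correctness of the estimators under the
model, not that the model captures every feature of real sensory data.

## Validation experiments and problem sizes

The statistical test suite (tests/test_acceptance.py) runs, entirely from
simulated ground truth:

- pmf normalization to 1e−9 and geometric/Poisson reductions to 1e−6;
- likelihood optimality of every family on 20 random ≤30-duration
  instances against a 1000-draw random-parameter oracle and a dense
  (mu, kappa) grid, both evaluated through scipy's independent NB pmf;
- the loglik nesting Rg >= R >= N >= G and Ng >= N on every dataset;
- parameter recovery from `recovery_config` at 800 panelists (every
  coefficient within ±0.1, every shape within 25%) and monotone RMSE
  decay over panel sizes 50 → 200 → 800 (three replicates each);
- AIC ranking Rg < R < Ng < N < G in at least 8 of 10 replicate
  400-panelist panels from `ranking_config`;
- the worked duration-table example (spells of 2, 3, 3 s give C = 3,
  Y = (2, 3, 3));
- empirical initial/transition frequencies over >= 10,000 simulated
  spells within 3 binomial standard errors of the truth per cell (the
  truncation cap is raised to 2 000 s there so forced stops do not
  contaminate the STOP frequencies).

These sizes keep the full suite under a minute on one CPU while leaving
each check's statistical power comfortably above its tolerance.

## Known limitations

- Transition probabilities are time-homogeneous; splitting the tasting
  into phases (or regressing transitions on covariates) is out of scope.
- kappa is constant within a group; no zero-inflation or
  covariate-dependent dispersion.
- The AIC comparison covers the duration component only; adding the
  (family-independent) transition likelihood would shift all AICs by the
  same constant and leave the ranking unchanged.
- Sub-second acquisition and vendor export formats are not parsed; input
  is plain CSV in the two documented dialects.
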
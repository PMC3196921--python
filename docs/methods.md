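# Statistical methods

This document records the model definitions, numerical conventions and
known limitations of `starnma`. Notation: trials are indexed by `i`, drugs
by `t`; `r/n` are event counts and arm sizes; all treatment effects are
odds ratios (OR) of fracture, so OR < 1 is protective.

## Evidence structure

Every trial is a two-arm randomized placebo-controlled trial of one drug
for one fracture outcome (non-vertebral, vertebral, hip, wrist). The
network for an outcome is therefore a star with placebo at the hub. There
are no head-to-head trials and no closed loops, which has two standing
consequences:

- all drug-vs-drug comparisons are indirect (through placebo), and
- consistency between direct and indirect evidence cannot be tested from
  the data; concordance is instead assessed *between methods* (classical
  vs Bayesian vs Bucher) on the same data.

## Per-trial effect and classical pooling

The per-trial log odds ratio is `ln[(r_d/(n_d−r_d)) / (r_p/(n_p−r_p))]`
with standard error `sqrt(Σ 1/cell)`. A continuity correction (default
0.5) is added to every cell of a trial **only** when that trial has a zero
cell. Trials with zero or all events in *both* arms carry no OR
information and are excluded with a warning.

Fixed-effect pooling is inverse-variance. Random effects use
DerSimonian–Laird: `τ² = max(0, (Q − df) / (Σw − Σw²/Σw))` with
fixed-effect weights `w = 1/se²`, then re-weighting by `1/(se² + τ²)`.
Heterogeneity: Cochran's `Q = Σ w (y − ŷ)²`, `I² = max(0, 100 (Q − df)/Q)`.

**Classification convention:** I² ≥ 50% is "moderate", ≥ 70%
"considerable", below 50% "none/low". The boundaries are deliberately
*inclusive*: an I² of exactly 50% classifies as moderate. Between-drug
(subgroup) heterogeneity applies the same Q to the per-drug pooled
estimates.

Sensitivity analysis re-pools after excluding named trials and reports
heterogeneity before and after. Forest data (per-trial rows, per-drug
pooled rows, all-drug pooled row, percentage weights) are exported as a
data frame; plotting is intentionally out of scope.

## Bucher adjusted indirect comparison

For drugs A and C each compared with placebo B:
`ln OR(A,C) = ln OR(A,B) − ln OR(C,B)`, `se² = se²_AB + se²_CB`.
The league table computes every ordered pair from the per-drug pooled
estimates; a drug absent from an outcome yields NR cells. Cells are exactly
reciprocal and transitive by construction. The key assumption is
transitivity — that trial populations are similar enough across spokes for
the placebo arms to be exchangeable; the covariate machinery below exists
to probe that assumption.

## Bayesian network model

Arm-level binomial likelihood with logit link:

- placebo arm of trial `i`: `r ~ Binomial(n, expit(mu_i))`
- drug arm (drug `t`): `r ~ Binomial(n, expit(mu_i + d_t))`
- priors: `mu_i ~ Normal(0, precision 0.001)`, `d_t ~ Normal(0,
  precision 0.001)` — vague on the log-odds scale (SD ≈ 31.6).

The model is *fixed effect* in `d_t` (one parameter per drug per outcome),
matching the sparse star (most drugs have 1–8 trials). Defaults: 2 chains
× 100,000 iterations with 50,000 burn-in.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs over the `S + K` scalar
parameters. Each coordinate has its own Gaussian proposal whose log step
size is adapted by Robbins–Monro (`gamma_t = (t+1)^-0.6`) toward a 0.44
acceptance rate **during burn-in only**; after burn-in the kernels are
fixed, so the retained draws come from a valid time-homogeneous chain.
Per-coordinate updates evaluate only the local likelihood terms (the one
binomial for `mu_i`, the drug's trials for `d_t`). Chains start from crude
empirical logits with per-chain offsets, and each chain draws from an
independent seeded substream.

### Summaries

- **Point estimate:** the geometric-mean odds ratio `exp(E[d_t])` — the
  exponential of the posterior mean log OR. The arithmetic mean of
  `exp(d_t)` draws sits a factor `≈ exp(Var[d]/2)` higher (Jensen's
  inequality) at *any* chain length, which would manufacture spurious
  disagreement with classical pooling (up to ~2% for wide single-trial
  posteriors). With the geometric convention, league-table cells
  `exp(E[d_A − d_C])` are exactly reciprocal and transitive.
- **Credible intervals:** empirical 2.5/97.5 percentiles of the OR draws.
- **P(best):** per-iteration share of draws in which the drug has the
  lowest `d_t` (most protective), with exact ties split equally; sums to 1
  by construction.
- **Effect size:** `(1/OR)/SD(OR)`; when only a published interval is
  available, `SD` is approximated by `(CrI_high − CrI_low)/3.92`.
- **NNT:** with comparator risk `p_C`, `risk_A = expit(logit(p_C) + ln
  OR)` and `NNT = 1/(p_C − risk_A)`; OR = 1 returns none (reported NR);
  negative values mean the comparator is favoured. The default `p_C` is
  the pooled placebo rate of the outcome's trials. NNT output is
  informational — published NNT values are not reproducible from any
  simple formula and are not used as a validation surface.
- **Display rounding:** ORs and probabilities to 2 decimals, effect sizes
  to 1, NNTs to the nearest integer.

### Exact-quadrature oracle

For a one-drug, one-trial network the posterior has two parameters, so it
is integrated on a dense 2-D grid (801² points, ±10 crude-SEs, log-domain
normalization) using scipy densities only — a sampler-independent gold
standard. The sampler is required to reproduce the exact posterior mean
and SD of `d` within 2% at 2 × 20,000 iterations.

### Convergence diagnostics

Implemented from their definitions, not wrapped from another package:
Gelman–Rubin potential scale reduction (pass < 1.1); Geweke first-10% vs
last-50% z-score with Bartlett-window spectral variances (pass |z| <
2.576); Heidelberger–Welch Cramér-von Mises stationarity test (critical
value 0.461 at α = 0.05) with iterative 10% front truncation plus the
relative half-width check (ε = 0.1); Raftery–Lewis run-length estimate for
the 2.5% quantile (r = 0.005, s = 0.95, `nmin` = 3,746) with BIC-based
thinning of the dichotomized chain. A parameter passes only if
Gelman–Rubin, Geweke and Heidelberger–Welch all ran and passed;
Raftery–Lewis is advisory (it sizes the run rather than judging it).

## Meta-regression

Weighted linear model on per-trial log ORs: intercept + drug dummies
(reference drug = first alphabetically, configurable) + selected
study-level covariates (mean age, years since menopause, hip BMD, %
prior vertebral fracture, follow-up years). `τ²` by REML (bounded scalar
optimization of the restricted log-likelihood; verified against an
independent REML implementation to ~1e-8) or by the method-of-moments
generalization of DerSimonian–Laird, which reduces exactly to DL for the
intercept-only model. Trials missing a selected covariate are dropped
listwise and reported. Residual degrees of freedom are enforced
(`InsufficientStudiesError` otherwise) — a real constraint on a star
network with single-trial drugs.

Collinearity diagnostics target the characteristic failure of covariate
adjustment in star networks (covariates aliasing drug identity): a term is
flagged when its CI width exceeds 10× its reference width (the drug's
unadjusted pooled CI width when available, else the median term width), or
when the weighted, column-normalized design has condition number > 10³ and
the term loads (>0.1) on a near-null singular direction.

## Synthetic evidence generator

Seeded generator used for oracle-based validation:

- per-(drug, trial-index) independent substreams
  (`SeedSequence([seed, crc32(drug), j])`), so adding or removing a drug
  never perturbs other drugs' simulated trials;
- per-trial baseline logit `~ Normal(mean, sd)`, drug effect `d_t + τ·z`
  (τ = 0 means a homogeneous truth), binomial arm counts;
- study covariates uniform over the published ranges (age 51.2–78.0 y,
  years since menopause 2.7–43.7, hip BMD 0.25–1.08 g/cm², prior
  vertebral fracture 0–100%, follow-up 1–4 y), with optional linear
  covariate effects (slopes centred at range midpoints) to plant
  explainable heterogeneity;
- validity guard: configurations whose 6-SD baseline range leaves the
  representable logit window are rejected.

The *paperlike* scenario emulates the published evidence base: trials per
drug {alendronate 6, denosumab 1, etidronate 8, ibandronate 4, raloxifene
1, risedronate 6, strontium 2, teriparatide 1, zoledronic 1}, 1,000
patients per arm (≈ the published 59,209 patients over 30 vertebral
trials), per-outcome placebo rates and true ORs set to the published
values, and the published missingness pattern (no hip data for
ibandronate; no wrist data for denosumab, ibandronate, zoledronic acid).
Oracles derived from a configuration: the true league table, the true best
drug, and a planted-winner transform that lowers one drug's effect a given
number of pooled SEs below every other drug.

Emulation scope: the generator matches the published *network shape,
effect profile and scale*, not individual historical trials — arm sizes
are uniform, covariates are independent draws, and baselines are
exchangeable across drugs. It is an oracle harness, not a re-creation of
the source trials.

## Validation problem sizes

The package's own end-to-end checks (also recomputed by
`scripts/acceptance.py`) use: the 2 × 20,000-iteration quadrature
comparison; the paperlike vertebral network at 2 × 10,000 iterations
(5,000 burn-in) for truth recovery, rank probabilities and
classical-vs-Bayesian concordance; the full 2 × 100,000 schedule for
Bucher-vs-Bayesian league equivalence (at the reduced length, Monte Carlo
error on contrasts between single-trial drugs is itself ~0.01 on the OR
scale); and 2,000 simulated 5-trial meta-analyses for Q-test calibration
at α = 0.10.

## Limitations

- Posterior means of log odds differences differ from classical MLEs by
  `O(1/events)` for single-trial drugs (the `ψ(e) − ln e ≈ −1/(2e)` skew
  offset per arm). On the OR scale the gap grows with the magnitude of the
  contrast: a single-trial drug with ~20 events shifts its posterior mean
  ~0.02 on the log scale, which a reciprocal contrast near 3.5 amplifies
  to ~0.07 in absolute OR units, even with arbitrarily long chains. For
  generated networks the Bucher-vs-Bayesian league gap therefore ranges
  from ~0.015 to ~0.08 depending on how few events the single-trial strong
  drugs happen to draw. This is a property of comparing Bayesian posterior
  means with frequentist point estimates, not a sampler defect.
- The Bayesian model is fixed-effect; between-trial heterogeneity within a
  drug is surfaced by the classical I² and the meta-regression `τ²`, not
  by the network model itself.
- Transitivity is an assumption, not a testable property, on a star.
- Published summary tables are transcribed as printed; two malformed
  classical hip cells (strontium, zoledronic acid) are omitted, and
  probabilities printed as "<0.01" are stored verbatim and parsed as
  missing rather than given an invented numeric value.
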
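# Methods

## The problem and the latent-history representation

With two identification channels that cannot be matched across individuals
(mark type 1 and mark type 2), a survey yields three sets of recorded
encounter histories: type-1 histories over {0,1}, type-2 histories over
{0,2}, and — when both marks were recorded simultaneously at least once, or
the identity was otherwise confirmed — fully "known" histories.  The true
per-individual history over `T` occasions uses codes 0 (undetected),
1 (type 1 only), 2 (type 2 only), 3 (both, non-simultaneous), 4 (both,
simultaneous) and is indexed by `j = 1 + Σₜ yₜ·5^(T−t)`.  Data types:
"never" forbids code 4 (α = 0), "always" forbids code 3 (α = 1),
"sometimes" allows both (0 < α < 1), where α is the conditional probability
that a both-type detection is simultaneous.

A single individual projects onto at most one type-1 and one type-2 record
(codes {1,3} → 1, codes {2,3} → 2), or onto a single known record if any
code is 4.  Conversely, every *unknown* admissible latent history is the
merge of at most one observed type-1 class and one type-2 class (overlap
occasions becoming code 3; under "always" overlapping merges are excluded
because co-detection would have been simultaneous and hence known).  This
conditioning on the observed record classes keeps the state space small:
with `n₁c`/`n₂c` distinct type-1/type-2 classes there are at most
`n₁c + n₂c + n₁c·n₂c` unknown latent histories plus the known ones, rather
than `5^T`.  The all-zero history is excluded — undetected individuals are
handled by the abundance parameter, not by the latent frequency vector.
Known records pin their own latent history's frequency.

The 0/1 matrix `A` (one row per admissible latent history, one column per
observed record class) links latent frequencies to record counts via
`Aᵀx = counts`.  Because each unknown history touches at most one class of
each type, the integer kernel of `Aᵀ` is generated *exactly* by the merge
moves `e₍a,b₎ − e₍a,·₎ − e₍·,b₎` (one per full pair): subtracting the pair
coordinates of any kernel vector leaves a vector supported on singleton
histories whose `Aᵀ` columns are distinct unit vectors, hence zero.  No
Hermite-normal-form computation is needed and the basis generates the full
integer lattice, so the feasible set is connected under signed basis moves.

## Sampling the feasible set

The latent state is a pool of individual "slots" (history index plus any
individual random effects).  A move draws `K ~ Uniform{1..maxnumbasis}`
signed basis vectors sequentially, each uniform over the moves that keep
the partially updated frequency vector nonnegative — proposals are
nonnegative by construction and require no tuning.  The Hastings ratio
multiplies the admissible-set sizes along the forward path against the
path-matched reverse (same K, negated vectors in reverse order); a mid-path
dead end aborts the proposal.

The acceptance ratio combines (i) the per-individual complete-data cell
probabilities of the individuals removed and created (with alive states
marginalized by backward recursion and random effects of new individuals
proposed from their prior, so prior densities cancel), (ii) counting
factors: the target over configurations carries the multinomial
multiplicity `n!/∏ⱼxⱼ!`, the proposal removes a uniformly chosen subset of
the `xⱼ` duplicates and creates additions as unordered batches, and
everything collapses to falling factorials
`log n'! − log n! + Σⱼ log[xⱼ!/(xⱼ−dⱼ)!] − Σⱼ log[x'ⱼ!/(x'ⱼ−aⱼ)!]`, and
(iii) for the closed model, `C(N,n)(1−p*)^{N−n}` evaluated at the proposed
number of detected individuals.  These factors were derived analytically
and verified against brute-force enumeration oracles, including instances
with duplicate records and multi-step (K = 2, 3) moves; the test suite
repeats those checks.  Default `maxnumbasis = 1`; one latent update is
interleaved per parameter sweep.

## Open-population (CJS) model

Conditional on first capture `C_i`, occasions `t = C_i+1..T` contribute
`(1−p_it)φ_{i,t−1}` (alive, undetected), `(1−φ_{i,t−1})` at death, 1 once
dead, and `p_it·τ(y)·φ_{i,t−1}` for detections, where
`τ = δ₁, δ₂, (1−δ₁−δ₂)(1−α), (1−δ₁−δ₂)α` for codes 1–4.  The encounter
type observed at the first capture is a free draw from the same
distribution and is included in the sampler's complete-data target, so
histories first encountered on the last occasion still inform δ and α (the
`cjs_cell_logprob` function exposes the conditional product alone;
`cjs_history_logprob` adds the first-capture type factor).

Detection and survival use probit links,
`Φ⁻¹(p_it) = x_t^{p′}β^p + z_i^p`, with zero-mean normal individual effects
when the formula includes `~h`.  One sweep: an exact categorical draw of
each individual's death time after its last detection (alive states are
sampled, not marginalized, preserving conjugacy); truncated-normal
utilities for every realized detection/survival Bernoulli; multivariate
normal draws for `β` (prior N(0, 1.75) per coordinate, the variance as
printed for the reference analyses); normal draws for the individual
effects; conjugate updates of their variances; a Dirichlet draw for
`(δ₁, δ₂, 1−δ₁−δ₂)` given the encounter-type counts (or, for the shared
model δ₁ = δ₂ = δ, a Beta draw of u = 2δ); a Beta draw for α given the
simultaneous/non-simultaneous both-type counts (fixed at 0/1 for
never/always); and the latent-frequency update.

### Prior for the CJS heterogeneity variances

Survival heterogeneity is only weakly identified in CJS data: on the probit
scale an enormous effect variance turns `φ_i` into an immortal/instant-death
mixture that fits "seen-throughout" versus "never-seen-again" patterns
almost as well as moderate survival does.  Quadrature oracles (individual
effects integrated by Gauss–Hermite on a log-spaced variance grid) show the
marginal likelihood in `σ²_zφ` is flat to mildly *rising* out to σ² ≈ 5, so
any heavy-tailed scale prior — half-Cauchy(25) included — pushes most
posterior mass into the degenerate large-variance regime, dragging the
survival intercept down and α up.  The reference two-mark CJS analyses this
package reproduces clearly operate in the moderate-variance regime, so the
CJS individual-effect variances default to a weakly informative conjugate
Inverse-Gamma(shape 2, scale 0.1) prior (prior mean 0.1), keeping the sweep
fully Gibbs.  This is a deliberate design choice of this package;
`Priors(sigma2_shape=..., sigma2_rate=...)` exposes it.  The closed model's
detection heterogeneity, which capture frequencies identify much more
strongly, keeps the half-Cauchy(25) scale prior (sampled via its
inverse-gamma mixture representation).

## Closed-population model

The semicomplete-data likelihood conditions the `n` detected individuals on
detection (`(p*)^{-n}` with `p* = P(detected at least once)`) and
multiplies by `Binomial(n; N, p*)`.  Cells multiply `1−p` or `p·τ(y)` over
all occasions.  Detection uses the logit link; `p*` is the closed-form
product when `σ²_zp = 0` and otherwise a one-dimensional integral over the
effect distribution (`compute_pstar`: adaptive quadrature, relative
tolerance 1e−8; samplers use a 50-node Gauss–Hermite rule that agrees to
~1e−10).  Updates: joint Gaussian random-walk Metropolis for `β^p` with
Robbins–Monro scale adaptation toward ≈ 0.33 acceptance *during burn-in
only*; componentwise random walks for the individual effects and log σ²
(adapted toward 0.44); conjugate δ/α draws; and an exact draw of `N` — under
the scale prior 1/N the full conditional of `N − n` is negative binomial
with `n` successes and success probability `p*`, since `C(N,n)/N =
C(N−1,n−1)/n`.  `N` is re-drawn after every latent update so its
conditional stays exact.  The behavioral term `c` is defined with respect
to the *latent* individual's first capture and such designs are rebuilt
whenever latent first captures change.

## Multimodel inference

Models are fitted one at a time with every parameter monitored (including
the latent configuration and individual effects; at save time the effects
of currently inactive slots are refreshed from their prior so stored draws
are a proper joint sample).  A Gibbs sampler on the product space then
alternates: draw the current model's parameters — together with the shared
block (latent configuration, and `N` for closed models) — from its stored
posterior; draw every other model's specific parameters from its
pseudoprior (independent moment-matched normals on transformed scales:
logit for probabilities, log for variances, a logit-of-2δ transform for the
shared-δ parameter); draw the model indicator from its full conditional,
each model scored by
`log prior(m) + complete-data loglik + log prior(spec) − log pseudoprior(spec)`
with a log-sum-exp.  Priors shared by all models (the latent multiplicity,
1/N) cancel and are omitted from the scores.  Indicator visit frequencies
estimate posterior model probabilities (summing to one by construction);
monitored common parameters are collected from the visited model per
iteration, and `summarize_mm` reports model-averaged modes (Gaussian-KDE
maximizer with Silverman bandwidth for continuous parameters, most frequent
value for integer `N`) and shortest empirical HPD intervals.
User-specified proposal distributions can override the default pseudopriors
(`ModelEntry(override_pseudoprior=...)`).

## Simulators

`simdata_cjs` / `simdata_closed` generate the study conditions: every
individual enters at occasion 1 (the open-population design specifies no
staggered-entry schedule, so none is simulated); survival is Bernoulli(φ)
per interval and detection Bernoulli(p) while alive; each detection is type
1 / type 2 / both with probabilities (δ₁, δ₂, 1−δ₁−δ₂), and a both-type
detection is simultaneous with probability α.  CJS simulation uses the
probit link (matching the fitted model), closed simulation the logit link.
Scalar `pbeta`/`phibeta` are link-scale intercepts; per-occasion vectors
are accepted.  Observed matrices are the projected records with all-zero
rows dropped; with δ₁ = 1, δ₂ = 0 the output is conventional single-mark
data.  Simulations emulate independent detections given alive status and
effect values; they do not emulate misidentification, spatial structure,
partial overlap of sampling periods for the two mark types, or more than
two mark types (all outside this package's scope), so passing recovery
tests demonstrate correctness of the inference under the model, not
robustness to those violations.

## Numerical choices and test scales

Cell probabilities are floored at 1e−300 before logs; truncated-normal
utilities clip the uniform CDF argument to [1e−12, 1−1e−12]; the model
indicator conditional and all enumeration oracles work in log space.
Occasions are 1-based everywhere; `Time` is coded 0..T−1 (uncentered);
`time`, `age` and `cohort` use treatment coding with the first level (or
the bin containing it) as reference.  Ties in the no-match initialization
are resolved by assigning each observed record its own latent individual,
which is always feasible.

Test and acceptance runs use deliberately modest problem sizes chosen for
tight Monte Carlo turnaround: enumeration checks use T ≤ 3 with ≤ 6
records; recovery studies use 20 replicates at the stated study conditions
(closed: N = 75, T = 5, p = 0.3, δ₁ = δ₂ = 0.4, "never"; open: N = 100,
T = 5, two-mark "sometimes") with single chains of 4000–5000 iterations,
which ESS diagnostics show is ample for interval coverage; the worked-example
reproduction uses the full published protocol (two chains of 45 000
iterations) in `scripts/acceptance.py` and a 2 × 12 000 version in the test
suite.  The bobcat re-analyses in the test suite run at ~10⁵ iterations per
model rather than the original 2 × 2 × 10⁶; they require the original
encounter matrix at `data/bobcat.csv`.

## Known limitations

- Survival-heterogeneity variance and the survival intercept are jointly
  weakly identified (above); under heavy-tailed variance priors the
  posterior is genuinely bimodal between moderate and degenerate regimes.
- The CJS latent-frequency weights use the first-capture-conditional
  likelihood, so the implied posterior over merges is the standard
  conditional-CJS one, not the full joint over entry processes.
- Pseudopriors are independent normals; strongly correlated or multimodal
  within-model posteriors would make the indicator chain mix more slowly
  (the exactness of the probabilities is unaffected, being a Gibbs
  conditional, but Monte Carlo error grows).
- `p*` assumes the capture (pre-first-detection) design for undetected
  individuals; time-varying covariates must be supplied for all occasions.
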
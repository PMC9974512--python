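# Methods

## The model

The package computes Bayes factors directly from classical test statistics.
For each of the four supported families the statistic's null distribution is
the usual central one, and its alternative distribution depends on the data
only through a scalar noncentrality parameter λ:

| family | H0 | H1 |
|---|---|---|
| z | N(0, 1) | z \| λ ~ N(λ, 1), λ ~ J(0, τ²) |
| t | t(ν) | t \| λ ~ t(ν, λ), λ ~ J(0, τ²) |
| χ² | χ²(k) | h \| λ ~ χ²(k, λ), λ ~ Gamma(k/2 + 1, 1/(2τ²)) |
| F | F(k, m) | f \| λ ~ F(k, m, λ), λ ~ Gamma(k/2 + 1, 1/(2τ²)) |

The alternative prior on λ is *nonlocal*: its density is exactly zero at the
null value λ = 0. The normal-moment prior J(μ₀, τ²) has density
(x − μ₀)²/(√(2π)τ³)·exp(−(x − μ₀)²/(2τ²)) and modes at μ₀ ± √2·τ; the gamma
prior has shape k/2 + 1 > 1 (a scaled χ²_{k+2}), hence zero density at the
origin, mode k·τ², and coefficient of variation √(2/(k+2)) irrespective of
τ². Shapes below 3/2 would give χ²-like priors that are positive at the
origin and hence local; the k/2 + 1 choice keeps the family nonlocal for all
k ≥ 1. Nonlocality is what allows the Bayes factor to accumulate evidence
*for* a true null at a useful rate, not only against it.

The Bayes factor BF₁₀(x | τ²) is the prior-averaged noncentral density of
the observed statistic divided by its central density. All four marginal
integrals reduce to closed forms; for example the z family gives

    BF₁₀(z | τ²) = (τ²+1)^(−3/2) · (1 + τ²z²/(τ²+1)) · exp(τ²z²/(2(τ²+1))),

and analogous expressions hold for t, χ², and F (the F form uses
v = m(τ²+1)). Two identities tie the families together and are enforced in
tests to 1e−12 relative: the z and χ²₁ = z² forms agree, as do the t and
F₁,ν = t² forms, at any common τ². An adaptive-quadrature oracle
(`quadrature_bf10`) integrates the scipy noncentral densities against the
prior and must agree with each closed form to 1e−6 relative; it exists only
for validation and is additionally cross-checked against a fixed-grid
Simpson rule in the tests.

## Effect-size indexing (the BFF)

τ² has no direct scientific meaning and its interpretation changes across
tests, so curves are indexed by a standardized effect size ω instead. Each
design maps ω to the noncentrality λ(ω); τ²_ω is then defined by *mode
matching* — it is the τ² that places the prior's mode(s) exactly at λ(ω):

| design | τ²_ω | λ(ω) |
|---|---|---|
| one-sample z/t | nω²/2 | √n·ω |
| two-sample z/t | n₁n₂ω²/(2(n₁+n₂)) | √(n₁n₂/(n₁+n₂))·ω |
| multinomial/Poisson χ² | nω̃² | nkω̃² |
| likelihood-ratio χ² | nω̃² | nkω̃² |
| linear-model F | nω̃²/2 | nkω̃²/2 |

For multi-degree-of-freedom tests the effect is a vector ω; τ² depends on it
only through ω′ω, so vectors are collapsed to the root mean square effect
size ω̃ = √(ω′ω/k) and curves are always over a scalar axis. n always means
the *total* sample size (85 and 140 in the replication example, not
per-group counts). Note the tabulated factor-of-two difference between the
χ²-design and F-design mappings; it is applied exactly as tabulated, and
mixing the two design kinds on one ω̃ axis triggers a warning. The
linear-model standardized effect L⁻¹(Aβ−a)/σ is documentation-level only:
the package consumes (n, k, ω̃) and never design matrices.

The Bayes factor function (BFF) is the curve ω ↦ BF₁₀(x | τ²_ω). Its
maximum is the strongest support for the alternative obtainable within the
prior family (a data-dependent selection, and interpreted conditionally on
it); its crossings of 1 separate effect sizes the data support from those
they contradict. Effect sizes are labeled very small (0, 0.1), small
(0.1, 0.35], medium (0.35, 0.65], large above — boundary values go to the
larger category, a deterministic completion of the open intervals.

A pointwise likelihood-ratio curve (`likelihood_ratio_curve`) — the
noncentral density at λ(ω) over the central density, with no prior
averaging — is also available. Its peak upper-bounds any prior-averaged
maximum, overstates the attainable evidence, and can never favor the null;
it is exported as a reference curve only.

## Evidence combination

For S independent studies sharing a common ω̃, the marginal densities
factor, so the combined Bayes factor is the product of per-study Bayes
factors, each evaluated at its own τ²_s(ω̃) derived from that study's sample
size. The implementation sums per-study log Bayes factors; additivity at
every grid point is asserted to 1e−12 absolute. Independence is assumed,
not checked, and no heterogeneity (random-effects) model is offered: the
shared ω̃ axis encodes the belief that the standardized effect is common
across studies. Mixed statistic families are permitted because the
factorization needs only independence.

## Numerical choices

- All closed forms are computed in log space (`log1p`, explicit
  `exp(a·log b)` powers), so degrees of freedom up to 10⁶ and statistics up
  to 50 stay finite; tests assert this.
- τ² = 0 returns exactly 1 by short-circuit; it is the exact limit and the
  prior degenerates there, so density evaluation at τ² = 0 is disallowed in
  the prior classes. Curves exclude ω = 0 for the same reason (the BF → 1
  limit is documented, not evaluated).
- z and t enter the formulas only through their squares; negative values are
  accepted and squared (the J(0, τ²) prior is symmetric, i.e. two-sided).
- Default grid ω ∈ [0.01, 1.0] step 0.005: standardized effects above 1 are
  rare on the Cohen scale. The curve is a pointwise function of ω — values
  are invariant to the grid step, which only controls resolution of the
  summary brackets.
- The argmax is refined off-grid inside its bracketing cell with scipy's
  bounded derivative-free minimizer; threshold crossings use bracketed root
  finding (`brentq`) on log BF₁₀ minus the log threshold. Both run to
  |Δω| ≤ 1e−6. These are scipy's Brent-type routines rather than literal
  golden-section/bisection loops — the same derivative-free class with
  guaranteed bracketing, without hand-rolling an optimizer. The refined
  maximum is never reported below the best grid value, and every reported
  root is asserted to reproduce its threshold within tolerance. A curve can
  cross a threshold several times in principle; all roots are reported in
  increasing ω (rising-then-falling curves give the usual 0 or 2).
- The quadrature oracle truncates the prior's support 12 standard deviations
  beyond its mean (the J(0, τ²) variance is 3τ²) and raises with diagnostics
  if the integral fails to converge. scipy's noncentral χ²/F densities are
  unstable at noncentrality ≈ 0, where the central density is substituted.
- Curve CSV export prints 17 significant digits and re-imports with
  pandas' round-trip parser, so Bayes factors survive a round trip bit for
  bit. Presentation layers round to 2 decimals; internal precision is full
  double throughout.

## The simulator and what tests do (and do not) show

`simulate_statistic` draws statistics under the exact null or hierarchical
alternative models above, from a seeded `numpy` Generator. Noncentral χ² and
F use the Generator's native samplers (central draws are routed through
`chisquare`, since the native sampler rejects a noncentrality of zero);
noncentral t is composed from primitives as N(λ,1)/√(χ²ν/ν); normal-moment
draws use μ₀ + τ·s·√W with W ~ χ²₃ and a random sign s, which is exact.
Stochastic tests fix seeds and use wide (≥4 SE) tolerance bands.

The simulator emulates the sampling models the statistics are *assumed* to
follow. It does not emulate finite-sample departures from those asymptotic
distributions, model misspecification, dependent studies, selection or
publication bias. Passing tests therefore certify the internal mathematics
(closed forms, mappings, combination rules) and the qualitative
evidence-accumulation behavior — e.g. that under a true null the median
BF₁₀ at a fixed alternative effect size falls as n grows over {25, 100,
400} (2000 replicates per n) — not the calibration of the method on real,
possibly misspecified data.

## Worked-example reproduction sizes

The shipped examples are desk-scale and deterministic: the z example uses
the default grid; the contingency example uses ω̃ ∈ [0.005, 0.5] step 0.001
(its maximum sits near ω̃ = 0.035, below the default grid's floor
resolution); the replication example uses the default grid. Each completes
in well under a second. Reported quantities follow the method's convention
of operating on *reported* statistics: the contingency χ² is computed from
the count table, reported at two decimals (12.65), and the BFF is evaluated
at that reported value. Headline numbers (maximum 2.90 at ω = 0.15 with
implied τ² = 1.125; 3.07 at ω̃ = 0.035 with the 1:1 crossing at 0.068;
combined 5.75 at ω̃ = 0.14 with 2:1 support on ≈(0.05, 0.26) and no support
above ≈0.31) are recomputed by `scripts/acceptance.py` and asserted in
`tests/test_acceptance.py`; the refined argmax of the z example is
ω* ≈ 0.153, which presentation rounding reports as 0.15 (hence τ² = 1.125).

## Known limitations

- Only the five tabulated designs are wired to the effect-size mapping;
  unequal-variance two-sample tests and general design-matrix algebra are
  out of scope.
- One-sided alternatives are not supported (the priors are symmetric or
  nonnegative by construction).
- Bayes factors are computed from test statistics, never from raw-data
  likelihoods; the package trusts the asymptotic distribution of whatever
  statistic it is given.
- The multinomial goodness-of-fit path covers the s = 0 and independence
  cases end to end; general fitted-parameter counts are the caller's
  responsibility via df1.
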
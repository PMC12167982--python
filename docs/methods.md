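# Methods

## The confounding problem

Longitudinal records in which some units reliably score higher than others
admit two readings: a *heterogeneity* model, where observations are
conditionally i.i.d. given a fixed latent trait drawn once per unit, and a
*reinforcement* model, where each observation is a measurable function of
the unit's own past observations plus fresh i.i.d. noise and no latent
variable exists. The package implements three concrete pairs in which the
two readings are not merely similar but have *identical joint distributions*
over entire trajectories, plus the machinery to verify that equality and to
probe the one restriction a stationary heterogeneity model does place on
data: exchangeability of the within-unit observation order.

## Models and exact likelihoods

**Binary pair.** The Pólya urn (start 1 black / 1 red; a drawn ball is
returned with a copy) has conditional law
`P(Y_n = 1 | history) = (1 + Σ_{k<n} Y_k)/(n + 1)`. Its twin draws
`p ~ U[0,1]` once and then i.i.d. Bernoulli(p). `polya_log_prob`
deliberately multiplies the urn conditionals sequentially while
`mixture_log_prob` evaluates `log B(k+1, n−k+1)` via log-gamma; the routes
share no code, so their agreement (machine precision, exhaustive to length
8, randomized to length 200) is a genuine cross-check, not a tautology. A
generalized `(a, b)` urn start with Beta(a, b) twin is exposed but the
(1, 1) default is the canonical case. All probability arithmetic is in log
space; a length-10⁴ sequence scores without underflow.

**Gaussian pair.** The latent-talent model `Y_n = T + X_n` has joint law
`N(μ_T·1, σ_T²·J + σ_X²·I)`; `q_log_pdf` evaluates exactly this
multivariate normal (scipy). The twin's conditional law

    μ_{n+1} = (c·a + Σ_k y_k)/(n + c),   σ²_{n+1} = b·(1 + 1/(n + c))

is precisely the conjugate-normal posterior predictive of the latent-trait
model under `a = μ_T`, `b = σ_X²`, `c = σ_X²/σ_T²`: the prior precision of
the trait is `c/b`, each observation adds precision `1/b`, so every past
observation is equally informative and the predictive variance falls
monotonically from `b + b/c` to `b`. `twin_log_pdf` sums the conditional
normal densities by the chain rule — again an independent route from the
joint-normal evaluation. The first draw comes directly from `N(a, b + b/c)`
(the `n = 0` boundary of the same formula) rather than a special case.

The unit-variance specialization `(0, 1, 1)` yields
`y'_n = ((n−1)/n)·ȳ'_{n−1} + √(1 + 1/n)·v_n`. The noise coefficient is
`√(1 + 1/n)`: this is forced by consistency with the conditional variance
formula at `b = c = 1`, and `sdm_twin_step` reproduces the general twin
exactly when fed the same innovations (tested). Innovations are
caller-supplied precisely so that identity can be checked deterministically.

**Event pair.** The frailty model draws `κ ~ Gamma(shape α, scale 1/α)` —
the mean-one convention, so `κ` is an identifiable multiplicative frailty
with variance `1/α` — and runs a pure-birth process with rates `κ·π_j`.
Marginalizing `κ` gives the closed form

    L = (Π_j π_j) · α^α · Γ(m+α)/Γ(α) · (α + Σ_j π_j τ_{j+1} + π_m (T − t_m))^{−(m+α)},

re-derived by hand and verified against adaptive quadrature over `κ`
(agreement ~1e−13 across random parameter/trajectory pairs; the quadrature
shifts by the integrand's log at the posterior mode to stay scaled). The
twin's intensity denominator is evaluated through the running normalization
`A_m = α + Σ_{j<m} π_j (t_{j+1} − t_j)`, to which the published form
telescopes by Abel summation (tested numerically); `A_m` is positive by
construction, and the simulator asserts it stays so. The twin likelihood is
the standard `Σ log λ(t_i) − ∫_0^T λ` with the integral in closed form; one
can show analytically that it telescopes to the same expression as the
frailty marginal — the code keeps both derivations and the test-suite holds
them to 1e−8 on simulated trajectories.

Twin simulation uses the time change `τ_{k+1} = s_{k+1}(z)` with
`s_{k+1}(z) = A_k (e^{z/(k+α)} − 1)/π_k` and `z ~ Exp(1)`; correctness is
established two ways: quadrature of the intensity over `(t_k, t_k + s(z)]`
recovers `z` to ~1e−15, and an independent Ogata thinning sampler (valid
because the intensity decreases between events, so its left limit
dominates) matches the time-change sampler in distribution (two-sample KS
on first-event times and total counts).

The π-rule is a user-supplied callable with the built-in power-law family
`π_0` free, `π_j = scale·j^ρ` (defaults α = 1, π_0 = 0.25, scale = 0.25,
ρ = 0.5 — the package's reference contact-process scenario); values are
cached per state. Tied event times are rejected at construction (they have
probability zero under the model and usually indicate a data error).

## Equivalence suite

`likelihood_equality_check` reports the maximum relative log-likelihood
discrepancy over a trajectory set; true twins sit at float noise (≤1e−12
binary, ≤1e−8 Gaussian/event), while perturbing one parameter by 10% moves
the statistic by orders of magnitude — the suite includes those perturbation
tests so the checks cannot pass vacuously. `marginal_compare` runs
two-sample KS (continuous) or chi-square with tail pooling (counts) per
index with Holm adjustment at family level 1%: distribution-free control of
the suite's false-alarm rate without assuming anything about the marginals.
`cross_moment_compare` compares mean vectors and cross-time covariance
matrices within 3 combined standard errors, with covariance-entry SEs
estimated from fourth moments. Stochastic checks take explicit seeds and
record sample sizes in the report so failures are reproducible.
`mixture_model` draws each unit's whole trajectory from component A with
probability `q`, else B, and scores with log-sum-exp; mixing a model with
its twin leaves the law unchanged for every `q`.

## Runs test

Each unit's record is dichotomized at its own median. Values exactly at the
median are **dropped** by default: that is the only policy that uses
strictly the two categories "below" and "above"; `assign-low`/`assign-high`
are available as alternatives since the choice is a genuine judgment call.
The minimum-length filter (default 3, the shortest record whose run count a
shuffle can change) applies after dropping. The observed statistic is the
pooled run count; each of `n_perm` permuted datasets independently
reshuffles every retained record, one substream per record with the
`n_perm` shuffles vectorized inside it. With `x` the share of permuted sums
strictly below the observed, the two-sided p-value is `2·min{x, 1−x}`;
when the observed statistic falls outside the whole permutation sample the
result is reported as the bound `2/n_perm` with `p_is_bound` set, since the
permutation resolution is exhausted. An add-one-smoothed `x` is available
but non-default.

Under within-unit exchangeability the test is exact, and the type-I
calibration experiment (500 panels of 30 units × 20 observations from the
binary heterogeneity twin, 1,000 permutations, nominal 0.05) measures a
rejection rate of ~0.05–0.06, inside [0.03, 0.08]. A subtlety worth
stating: the Pólya urn, although a reinforcement model, generates
*exchangeable* sequences, so the runs test is calibrated — not powered —
against it; the test-suite asserts exactly that. The test detects
non-exchangeable order structure (trends, streaks, regime changes), not
reinforcement per se. The strictly-below convention makes the lower tail
very slightly anticonservative in the presence of ties in the discrete
pooled statistic; with ~30 units this is within the calibration band.

`conditional_variance_profile` complements the runs test: it tabulates, per
history length `n`, the cross-unit variance of `Y_{n+1}` around the twin's
conditional mean next to the predicted `b(1 + 1/(n + c))`. On data from the
twin (or its heterogeneity twin) the profile tracks the curve; on data with
constant innovation variance it is flat, flagging that the specific
variance-decay rate — the property that makes the stationary heterogeneity
reading look "natural" — does not hold.

## Synthetic scenarios and what passing tests show

`generate_fixtures` provides the reference scenarios used throughout:
30 units × 10 observations of the citation pair at (μ_T = 0, σ_T² = 0.2,
σ_X² = 1) ↦ (a = 0, b = 1, c = 5); 10 units of the unit-variance
belief pair; 30 event trajectories to horizon 10 at (α = 1, π_0 = 0.25,
π_j = 0.25·j^0.5); binary panels from either member of the urn pair. These
generators produce exactly the laws the models assert — no contamination,
no missingness, no measurement error, no cross-unit dependence. Passing
tests therefore certify the mathematics (the twin equalities, the
calibration of the test under a true exchangeable null), not robustness of
the runs test to the messiness of real panels; real data additionally
involve unequal record lengths, attrition correlated with outcomes, and
discreteness far coarser than the models'.

## Numerical choices and problem sizes

Everything probabilistic is computed in log space (log-gamma, log1p/expm1);
the event-likelihood normalization is carried as a running `A_m` rather
than the alternating published sum. Randomness follows a seed +
named-substream contract (numpy `SeedSequence` spawn keys): one substream
per unit, so panels are reproducible regardless of simulation order, and
distinct named substreams for independent experiment arms. Monte-Carlo
checks use 10⁵ units for moment comparisons (3-SE bands), 2×10⁴ draws for
KS comparisons at the 1% level, and 500 replicates × 1,000 permutations for
the calibration experiment — sizes chosen so each distributional claim is
tested at useful power while the whole suite runs in about a minute.
Degenerate inputs have explicit policies: empty event trajectories are
valid (pure survival likelihood), all-tied records dichotomize to empty and
are filtered, a constant panel yields the bounded p-value, and zero counts
under `--log-transform` are an error rather than a silent pseudo-count.

## Limitations

No estimation: parameters are inputs, and fitting (maximum likelihood over
careers, frailty-model estimation from survey data) is out of scope.
Equivalence checking is direct likelihood/moment comparison, not formal
equivalence testing (no TOST) and not Bayesian model comparison. The runs
test addresses within-unit order only; it has no power against alternatives
that preserve exchangeability (the Pólya urn being the canonical example),
and nonstationary heterogeneity models can fail it while still being
heterogeneity models. Multi-colour urns and innovation schemes
(new-category processes) are not implemented.
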
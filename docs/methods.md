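# Methods

## Setting and model

A two-stage adaptive seamless trial compares a control with an
experimental treatment in a full population F that contains a
pre-specified subpopulation S (prevalence `p_S`); the remainder is S^c.
Patient outcomes are normal with known common standard deviation `sigma`,
and randomisation is stratified 1:1, so a mean treatment difference based
on `m` patients has variance `4 sigma^2 / m`. Stage 1 recruits `n1`
patients from F; with `s_X` of them in S, the observed stage-1
differences are

    X ~ N(theta_S,  4 sigma^2 / s_X),    Y ~ N(theta_Sc, 4 sigma^2 / (n1 - s_X)),

independent, with pooled full-population difference
`Z = p_hat X + (1 - p_hat) Y`, `p_hat = s_X / n1`. The trial continues
with S iff `x > z + b`, equivalently `x > y + b / (1 - p_hat)` (ties go
to F, since the F rule is stated with "<="); otherwise with F. Stage 2
recruits `n2` patients from the selected population and yields `U` (S
selected) or `V`, `W` with stratum split `s_V` (F selected). The
estimand is `theta_S` when S is selected and
`theta_F = p_S theta_S + (1 - p_S) theta_Sc` when F is selected.

## Naive estimators and their conditional bias

The naive estimators are the ordinary two-stage pooled means, e.g.
`D_S,N = t_S X + (1 - t_S) U` with `t_S = s_X / (s_X + n2)`. Because
selection is data-driven, they are biased conditional on the selection
event. The bias of `D_S,N` given S selected is
`t_S (E[X 1(X > Y*)] / Pr(X > Y*) - theta_S)` with
`Y* = Y + b/(1-p_S)`; the probability and the truncated moment are 1-D
integrals of a normal density times a normal CDF. `bias_analytic`
evaluates them with adaptive quadrature (`scipy.integrate.quad`,
absolute/relative tolerance 1e-12, standardised integration variable on
a ±13-SD window where the truncation error is below 1e-30; an estimated
quadrature error above 1e-10 raises). The complementary X-moment is
taken as `theta_S - E[X 1(X > Y*)]` rather than re-integrated.

Consequences carried by the code and verified by tests: the bias depends
on `(theta_S, theta_Sc)` only through their difference; a margin `b`
shifts the curves rigidly by `b/(1-p_S)`; under proportional allocation
(`s_X = p_S n1`, `s_V = p_S n2`) the prevalence-weighted component biases
cancel, so the combined naive estimator of `theta_F` is conditionally
unbiased; and the conditional bias is reported as an error (not zero)
when the conditioning probability underflows below 1e-12.

Normalisers: F-branch quantities are divided by
`SE_F = sqrt(4 sigma^2/(n1+n2))`. For the S branch the default is
`SE_S = sqrt(4 sigma^2/(p_S n1 + n2))`, the exact standard error of the
pooled two-stage mean in S; the alternative reading
`sqrt(4 sigma^2/(p_S (n1+n2)))` is available via `se_mode="printed"`.
The default is the one under which the standardised null bias at
`p_S = 0.3`, `n1 = n2 = 200`, `sigma = 1` equals 0.32.

## Conditionally unbiased (UMVUE) estimators

Conditional on the selection event, the stage-2 mean is unbiased for its
stratum effect; Rao-Blackwellising it on the complete sufficient
statistic (the complementary stage-1 mean together with
`Z_S = (tau_U/sigma_X) X + (sigma_X/tau_U) U`, and analogously on the F
branch) gives closed forms:

    D_S,U    = D_S,N    - tau_U^2/sqrt(sigma_X^2+tau_U^2) * phi(f_U)/Phi(f_U)
    D_S,U^F  = D_S,N^F  + tau_V^2/sqrt(sigma_X^2+tau_V^2) * phi(f_V)/Phi(f_V)
    D_Sc,U^F = D_Sc,N^F - tau_W^2/sqrt(sigma_Y^2+tau_W^2) * phi(f_W)/Phi(f_W)

where each `f` is the standardised signed distance between the naive
estimate and the selection threshold (`f_U` uses `y + b/(1-p_hat)`,
`f_V` its negation on the F branch, `f_W` uses `x - b/(1-p_hat)` — the
threshold implied by the selection region `X <= Y + b/(1-p_hat)`). The
margin term always uses the observed `s_X/n1`, so the same expressions
serve known and estimated prevalence; with proportional counts the two
modes coincide exactly. With unknown prevalence the UMVUE components are
combined with `p_hat = s_X/n1` (which keeps the combination unbiased for
`theta_F`), while the naive combination uses the pooled estimate
`p_hat* = (s_X+s_V)/(n1+n2)`.

The Mills ratio `phi(f)/Phi(f)` is computed as
`exp(log phi(f) - log_ndtr(f))`; naive division returns 0/0 below
`f ~ -38`, while the log-CDF form is accurate over the whole real line.

## Futility variants

With a futility bound B the trial continues only if `max(x, z) >= B`.
Continuation modifies the truncation regions (known prevalence only;
unknown prevalence plus futility raises "unsupported"):

- S branch: the threshold inside `f_U` becomes
  `max(B, y + b/(1-p_S))` — unchanged form otherwise.
- F branch, S component: given Y, X is truncated to the interval
  `((B - (1-p_S) y)/p_S, y + b/(1-p_S))`; the correction becomes the
  doubly-truncated-normal form
  `+ tau_V^2/sqrt(sigma_X^2+tau_V^2) * (phi(f_V)-phi(f_V_B))/(Phi(f_V)-Phi(f_V_B))`.
  The positive sign is the one consistent with the B -> -inf limit
  (which must recover the single-truncation form) and with the
  quadrature oracle; an empty truncation interval (`f_V_B >= f_V`,
  i.e. data outside the continuation region) raises.
- F branch, S^c component: the threshold inside `f_W` becomes
  `max(x - b/(1-p_S), (B - p_S x)/(1-p_S))`.

With a futility rule the combined naive estimator of `theta_F` loses its
unbiasedness; the package still reports the combined adjusted estimate
but flags it with a warning, since no unbiasedness claim is made for the
combination under futility.

## Brute-force oracle

`simulation` ships a quadrature oracle that recomputes each
Rao-Blackwell expectation directly: along the slice `Z = z` the stage-1
mean is an affine (decreasing) function of the stage-2 mean, so the
truncation of the stage-1 mean maps to an interval for the stage-2 mean
and the conditional expectation is a ratio of two 1-D integrals of the
joint normal weight. The integrand is centred and scaled at its
analytic mode before integration (tolerances 1e-13), and its value must
be invariant to the probe effect placed in the integrand — the
sufficiency property, asserted in tests. The oracle agrees with the
closed forms to ~1e-14 across grids, including the futility variants and
nonzero margins; it is an independent check, never the estimator.

## Monte Carlo engine

`run_mc_study` simulates at the summary-statistic level (the means are
drawn directly from their sampling distributions; patient-level
generation exists as a separate, distributionally identical path used
for round-trip validation). All noise for all replicates is drawn up
front from one seeded `numpy` Generator, so results are bitwise
reproducible and branch-conditional summaries do not depend on
evaluation order. In unknown-prevalence mode `s_X ~ Binomial(n1, p_S)`
and `s_V ~ Binomial(n2, p_S)`; degenerate draws (0 or n, an empty
stratum) are resampled with a logged count — at `n = 200` and
`p_S in [0.3, 0.7]` the event has probability below 1e-30, so this
cannot distort results measurably. Branch-conditional bias, MSE,
root-MSE/SE and their Monte Carlo standard errors are reported per
estimator; an empty branch is reported absent, not zero. All simulation
test tolerances are stated in multiples of the Monte Carlo standard
error, so reduced-replication runs remain valid tests; the default
checks use 2x10^5 replications per configuration, which bounds the MC
standard error of a conditional bias at roughly 4x10^-4 SD units while
keeping a full study under a second.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| `n1`, `n2` | — (200 in the reference configuration) | patients per stage |
| `sigma` | — (13.2 for the SIB-score example, 1.0 in bias studies) | known outcome SD |
| `p_S` | — | prevalence of S; `"unknown"` switches to binomial stratum counts |
| `b` | 0 | selection margin on the x-vs-z scale |
| `B` | none | futility bound on `max(x, z)` |
| `se_mode` | `pooled` | S-branch SE normaliser (see above) |

## What the generator does and does not emulate

The generator reproduces the model exactly: normal outcomes, known
common variance, stratified 1:1 allocation, fixed stage-2 sample size,
pre-specified subpopulation and selection rule. It does not emulate
unknown or unequal variances, arm imbalance, non-normal outcomes,
data-dependent stage-2 sizes, more than two strata, or post-stage-2
selection — so passing tests certify the estimators under the stated
model, not robustness to its violations. In particular, the separate
stratum estimates after selecting F are unbiased only if no further
selection is based on them.

## Known limitations

- Futility-adjusted estimation is implemented for known prevalence only.
- The combined adjusted estimator for `theta_F` is unbiased but is not
  claimed to be a UMVUE among combinations of unbiased components; under
  a futility rule no unbiasedness claim is made for any combined
  estimator of `theta_F`.
- Degenerate stratum counts (`s_X` or `s_V` equal to 0 or n) have no
  defined estimator and are rejected at the estimation layer.
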
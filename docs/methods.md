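# Methods note

This package infers directed ("Granger-causal") networks from
multivariate time series by comparing *description lengths* of nested
autoregressive models, and benchmarks the approach on synthetic systems
against a conventional two-stage Granger causality analysis (GCA)
baseline. This note records the model, the numerical choices, and the
places where behaviour is sensitive to design decisions.

## Causal decisions by code length

For a target series X and candidate source Y, two models are encoded:

- **restricted** — X regressed on its own history only;
- **unrestricted** — X regressed on its own history plus Y's history.

Writing `L(model)` for the description length of the data under a model,
the causal effect is

    F(Y -> X) = L(restricted) - L(unrestricted),

and an effect is declared iff `F > 0` (strict). Conditioning on a set Z
replaces the pair by `L(X+Z) - L(X+Y+Z)`. When several sources pass the
pairwise screen for one target, they are resolved jointly: candidates
are taken in order of increasing single-source length, and at each step
the joint model is kept only if

    min(L(current), L(single)) - L(joint) > 0,

otherwise the shorter of the two single models survives. This greedy
rule reproduces the exhaustive min-vs-joint comparison exactly for two
candidates; for more candidates it is a design decision that keeps the
number of fitted models linear in the candidate count.

All models of one target share a common response window of
`m = n - max_lag` observations so their lengths are comparable; mixing
windows is rejected at the API level. Per predictor block a single
shared lag is scanned over `1..max_lag` (default 5) and the minimum
length wins.

## Code-length schemes

Let a least-squares fit have `m` observations, `k` regressors, residual
sum of squares `RSS`, `tau = RSS/m`, and fitted energy
`R = beta' V'V beta / m`. Natural logarithms throughout.

**NML (default).** The normalized-maximum-likelihood length with a
Fisher-information parametric complexity evaluated at plug-in estimates:

    L = (m/2) ln(2 pi tau) + m/2
      + (k/2) ln(m/2) - ln Gamma(k/2) + (k/2) ln(R / tau) - 2 ln k

(the `-2 ln k` term applies for `k >= 2`). The first line is the
maximized Gaussian negative log-likelihood; the second is the
complexity of a parameter ball of squared radius `R` with noise floor
`tau`.

**Two-part code.** Likelihood term plus explicit parameter literals at
precision `delta = 1/n`:

    L = NLL + sum over parameters with |xi| >= delta of ln(|xi|/delta)
        + ln(k + 1),

where the parameter vector is `(tau, beta)`.

Implementation details: `RSS` is floored at `1e-12 * m * var(response)`
to keep logarithms finite on near-exact fits; rank-deficient designs
are fitted by `numpy.linalg.lstsq` (minimum-norm solution) with a
warning; under-determined candidates (`m <= k`) are skipped during the
lag scan. Both schemes were verified term by term against an
independent 60-digit arbitrary-precision oracle on frozen fixtures
(relative error <= 1e-9).

## Nonlinear design matrices

Nonlinearity is handled descriptively, by augmenting the linear lag
design in the spirit of a truncated Taylor expansion:

- linear lag columns for each predictor (target's own history first);
- powers `2..s` of every lag column (default `s = 2`);
- products of the target's and each other predictor's first-lag
  columns ("cross-terms", on by default).

The *linear* configuration (`s = 1`, no cross-terms) is the same code
path with the extra blocks disabled.

## Conventional GCA baseline

The baseline is the standard two-stage procedure on the same design
matrices: (1) per-model lag order by BIC (AIC available); (2) a nested
F-test of the restricted vs. unrestricted model at level alpha
(default 0.05), conditioning on **all** remaining nodes. If the
unrestricted model's selected lag falls below the restricted one's, it
is re-selected over lags >= the restricted lag so the models are truly
nested; a non-positive degrees-of-freedom difference is an error, and
the F statistic is floored at zero.

## Synthetic benchmark systems

Generator coefficients are the study conditions and are never tuned.

- **Three-node family** (linear / high-order / cross-term): a linear
  3-node vector autoregression with known edge set
  {X1->X2, X2->X1, X1->X3, X2->X3}, optionally augmented with squared
  lag-1 terms or with lag-1 cross products. The nonlinear variants are
  simulated as self-consistent recursions: the nonlinear terms are
  functions of the *generated* series' own lags.
- **Six-node system**: Gaussian-modulated AR self-terms
  (`y * exp(-y^2)`), `tanh` couplings and pairwise products, with the
  9-edge ground truth {Y2->Y1, Y1->Y2, Y1->Y3, Y2->Y4, Y5->Y4, Y2->Y5,
  Y4->Y5, Y3->Y6, Y5->Y6}. Least-squares regression on oracle designs
  recovers the printed generator coefficients within two standard
  errors (tested).

Realism choices: Gaussian innovations with configurable variance;
burn-in of 200 steps from `N(0, noise_var)` initial states; a
divergence guard (`|x| > 1e6`) with up to 20 seeded retries; and an
augmented Dickey-Fuller stationarity screen (5% level) that regenerates
non-stationary replicates. Seeding uses `numpy` `SeedSequence`
spawn-keys per (replicate, screening attempt, divergence attempt), so
ensembles are reproducible and replicates independent.

## Evaluation

Pooled true-positive rate (TPR) over true directed edges, true-negative
rate (TNR) over false ordered pairs, the exact-network
("ground-truth") rate, and per-edge detection accuracy; Jaccard
similarity between edge sets (defined as 1 for two empty networks);
in/out-degree profiles by node partition; and directed shortest-path
distributions (unreachable pairs counted separately).

## Known limitation: signal-free (white-noise) targets

The NML complexity above is evaluated at the plug-in estimates `R` and
`tau`. When the target carries **no** autoregressive signal, the fitted
energy is pure overfit, `R ~ (k/m) tau << tau`, so the term
`(k/2) ln(R/tau) ~ (k/2) ln(k/m)` is large and *negative* and nearly
cancels the `(k/2) ln(m/2)` dimension penalty. The net penalty is then
too weak, larger models get spuriously short codes, and pairwise false
positives on independent white-noise pairs are common (~86% measured at
n = 300). The effect fades as the target's own-history signal grows
(7.7% false positives for independent AR(1) pairs with coefficient 0.5;
0.5% per absent pair on the six-node benchmark, where `R >> tau`).

We deliberately do **not** patch the formula (e.g. by flooring `R` at
`tau`): the plug-in form is the method under study, and any floor would
also change code lengths at moderate signal-to-noise ratios. The
practical reading: the NML decision rule is trustworthy on series with
genuine temporal structure and must not be applied to series that fail
a signal screen; the test suite pins both regimes explicitly.

## Problem sizes and open design choices

The shipped experiments use 3- and 6-node networks at lengths 300-1000
with 100-300 Monte-Carlo replicates — minutes on one CPU. Design
choices not fixed by the problem statement and settled here: natural
logs everywhere; shared (not per-column) lag per predictor block;
common response window per target; greedy joint resolution beyond two
candidates; BIC as the default baseline criterion; strict positivity
for declarations. Conclusions could shift under per-column lag
selection, exhaustive subset resolution, or different stationarity
screens; none of these variants is explored here.
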
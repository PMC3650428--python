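# Methods

## Model

The observer infers the true positions x = (x_1, …, x_n) of a tap
sequence from noisy measurements x_m, combining a Gaussian likelihood
(per-tap sd σ_si) with a prior over how trajectories move. Both priors
offered here are Gaussian in the positions, so every posterior in the
package is Gaussian and the percept (posterior mode) equals the
posterior mean and solves a sparse linear system.

**Low-speed prior.** Each segment's average speed (x_{i+1} − x_i)/t_i is
penalized independently by a zero-mean Gaussian of sd σ_v. The MAP
cost is

    C(x) = Σ_i (x_i − x_im)²/(2σ_si²) + Σ_{i<n} (x_{i+1} − x_i)²/(2(σ_v t_i)²)

with a symmetric positive-definite tridiagonal Hessian, solved exactly
by `scipy.linalg.solveh_banded`; posterior sds come from the diagonal of
the exact dense inverse (n is at most a few dozen in any stimulus of
interest, so no approximation is used). The same percept is produced by
a Kalman filter over a random-walk position state (process variance
(σ_v t_i)² per step, diffuse initial state so the first update returns
the first measurement) followed by a Rauch–Tung–Striebel backward pass;
the two routes are cross-checked to 1e-8 in the tests, and both are
checked against a generic BFGS minimizer of C(x).

There is deliberately no prior over absolute position: only movement is
penalized, which makes percepts translation-equivariant (a property
test) and makes the single-tap percept veridical.

**Two-tap closed forms.** For n = 2 the mode gives the contraction
formula l* = l_m/(1 + 2(τ/t)²) with τ = σ_s/σ_v, its generalization with
the RMS of unequal σ_s1, σ_s2, and the midpoint-shift formula for
imbalanced spatial attention. The package treats these closed forms as
the primary API and verifies them against exhaustive two-stage grid
maximization of likelihood × prior (coarse 0.05-cm lattice, then a
0.001-cm lattice around the coarse argmax).

**Prediction/postdiction.** The joint inference decomposes exactly into
scalar inferences: project tap 1's likelihood forward in time (add
(σ_v t)² to its variance) to obtain a predicted prior over tap 2, and
symmetrically backward for a postdicted prior over tap 1; fuse each
likelihood with its projected prior by precision weighting. Equality
with the joint posterior's marginals (means and sds to 1e-10) is the
module's central theorem-by-test. Flat beliefs are represented by an
infinite-sd sentinel whose fusion is the identity; fusing two flat
beliefs is an error.

**Low-acceleration prior.** The rival observer penalizes the first
segment's velocity v_1 = (x_2 − x_1)/t_1 by N(0, σ_v²) and each
subsequent velocity increment v_i − v_{i−1} by N(0, σ_v²) with the same
scale, so both observers are parameterized by the single σ_v (hence the
single τ once σ_s is fixed). Whether the increments should instead scale
with interval duration is genuinely open; the constant-scale form was
chosen because it keeps the two observers comparable through one τ and
reproduces the characteristic endpoint under/overshoot on rapid
sequences. The cost is quadratic in x (pentadiagonal Hessian), solved
densely.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| σ_v | cm/s | 10 | sd of the speed expectation; smaller = stronger slow-motion belief |
| σ_s | cm | 1 | spatial measurement sd; ≈1 cm forearm, ≈0.1 cm fingertip |
| τ = σ_s/σ_v | s | 0.10 | time constant of contraction; l* = l_m/3 at t = τ |

Only the ratio τ is identified by two-tap percepts (scaling σ_s and σ_v
together leaves every percept unchanged, tested to 1e-12), so fitting
estimates τ alone, by bounded scalar least squares on [1e-4, 10] s.

## Generative simulation

`worldsim` draws trials from the world the prior assumes: x_1 uniform on
a 10-cm window, x_2 ~ N(x_1, (tσ_v)²), measurements with independent
N(0, σ_s²) noise, so l_m = l + ε with Var(ε) = 2σ_s². Defaults are the
standard forearm condition (t = 0.15 s, σ_v = 10 cm/s, σ_s = 1 cm, so
true lengths have sd 1.5 cm) with 10^6 trials and a recorded seed. The
conditional-variance closed forms

    Var(l_m | l) = 2σ_s²,
    Var(l | l_m) = 2σ_s² (σ_v t)² / (2σ_s² + (σ_v t)²)

were derived from the joint Gaussian of (l, l_m) and validated against
the Monte-Carlo conditional variances (within 5% at 10^6 trials) before
being trusted; Var(l | l*) equals Var(l | l_m) because the percept is a
deterministic function of the measurement. The simulation demonstrates
the estimator trade-off: the measurement is conditionally unbiased but
miscalibrated, the percept is biased toward zero but calibrated
(regressing truth on percept gives slope 1, intercept 0) and has
strictly smaller mean-squared error.

What the generator does *not* emulate: non-Gaussian likelihoods or
priors, trial-to-trial attention drift, lapses, response noise in human
reports, and any heavy-tailed structure of natural tactile statistics.
Passing tests therefore validate the inference machinery and its
internal consistency, not the claim that human forearm data follow the
model — that requires fitting real datasets, for which `fit_tau` accepts
user-supplied CSVs.

## Scenario conventions

Deterministic scenario predictions (tau-effect PSE curves, rabbit
percepts) feed the actual tap positions in as the measurements — the
expected measurement — matching how the contraction formula is fit to
actual stimulus lengths. The 15-tap rabbit preset is five taps at each
of 0, 5 and 10 cm with uniform ISI (configurable); per-region σ_s
profiles are assigned block-wise to the three five-tap groups.

The tau-effect PSE defaults to the pairwise closed form (apply the
contraction formula to each interval and equate). The alternative joint
mode runs full 3-tap inference and finds the root of l2*(x3) − l1*(x3)
with a bracketed root-finder (bracket [x_2 + 0.1 cm, 10·l_1], tolerance
1e-6 cm, diagnostic error reporting the endpoint differences when the
bracket holds no sign change). The two modes agree at t_2 = t_1 by
symmetry but diverge at small t_2, where the joint chain couples the
intervals and pushes the PSE far beyond the pairwise value; both are
exposed rather than silently picking one, and pairwise is the default
because it is the form under which τ is interpretable interval by
interval.

`fit_tau` requires at least two distinct inter-stimulus times: from a
single time, τ trades off against an overall length rescaling and is not
identifiable. Parameter recovery on synthetic fixtures is exact without
noise and within 10% (median over 100 seeds) at 0.3-cm report noise with
50 records.

## Numerical choices and degenerate inputs

- t ≤ 0 (coincident or out-of-order taps) is rejected everywhere rather
  than treated as a double tap: the speed prior's variance (σ_v t)²
  degenerates at t = 0.
- Negative lengths are allowed throughout (direction is sign); all
  closed forms are odd in l_m.
- σ_v → ∞ limits are handled by ordinary floating point (the percept
  tends to the measurements); the flat-belief sentinel exists only in
  the scalar fusion layer.
- Closed forms are evaluated directly; no iterative solver is used below
  n = 3, and the banded solves are exact.
- Problem sizes: property tests use 50–100 random instances with n ≤ 20;
  Monte-Carlo tests use 0.5–1 × 10^6 trials, which keeps conditional
  windows populated by several hundred trials while the whole suite runs
  in a few seconds.

## Limitations

Gaussian likelihoods and priors only; MAP (= posterior-mean) readout
only, no alternative loss functions; no streaming/online API; no
crossmodal cue combination; the package ships no human data — historical
datasets exist only as synthetic stand-ins generated from the model
itself, so τ values fitted to them are recoveries, not measurements.
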
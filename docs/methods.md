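# Methods

## Neuronal models

Four neuronal state equations share one structural specification
(`ModelSpec`: connection mask `A`, per-input modulation masks `B`,
driving mask `C`, with self-connections always present and modulation
allowed only on existing connections).

**Single-state bilinear** — `ż = (A + Σⱼ uⱼBʲ) z + C u`. The classical
first-order expansion of any neuronal dynamics around the resting fixed
point; `A`, `B`, `C` are in Hz. Convention: `A[i, j]` is the connection
*from* region `j` *to* region `i`.

**Single-state Wilson–Cowan** — `ż = −z + S(x)` with
`S(x) = 1/(1+e^{−αx}) − 1/2` and `x` the same linear drive. The sigmoid
is zero-centred so the origin stays a fixed point and states are
deviations from baseline (negative values = activity below baseline).
The relaxation time constant is fixed at 1 s: with BOLD sampled every
2 s, a free neuronal time constant is barely identifiable, so only the
nonlinearity is kept. The slope `α` is estimated per region on the log
scale (a shared-slope configuration is a trivial restriction of the
priors); at `α = 4`, `S′(0) = 1`, so the small-signal regime equals the
bilinear model with `A − I` (the Taylor remainder obeys
`|S(x) − x| ≤ 2|x|³`, the bound asserted in the tests). `S` is evaluated
as `tanh(αx/2)/2`, which cannot overflow.

**Two-state forms** — each region carries excitatory and inhibitory
sub-populations; inter-regional coupling runs only between excitatory
populations (`wEE`, per directed edge), with per-region intrinsic
weights `wSE, wSI, wIE, wEI`. `wEE` and `wIE` carry additive modulatory
parts analogous to `B`. All `w` magnitudes are estimated on the log
scale to enforce positivity; the equations carry the signs (inhibition
enters E negatively, E drives I positively). In the bilinear form the
excitatory self-term is a decay (−wSE·zE); in the Wilson–Cowan form the
printed equations place +wSE·zE inside the sigmoid argument (recurrent
self-excitation) with decay supplied by the leak, and we keep that sign
convention. Hemodynamics are driven by `z` (single-state) or `zE` only,
on the assumption that BOLD reflects excitatory/synaptic activity.

## Hemodynamics and observation

Per region, the balloon/windkessel cascade

    ṡ = z − κs − γ(f−1)
    ḟ = s
    v̇ = (f − v^{1/α_g})/τ_h
    q̇ = (f·E(f,ρ)/ρ − v^{1/α_g}·q/v)/τ_h,   E(f,ρ) = 1 − (1−ρ)^{1/f}

with rest point (0, 1, 1, 1), and BOLD (% signal change)

    y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v)).

Defaults (overridable): κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ_h = 2 s,
α_g = 0.32, ρ = 0.32, V₀ = 0.04, k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2
(classical 1.5 T coefficients). During inversion only per-region
log-scaling factors on κ and τ_h are estimated; the remaining constants
are fixed, keeping the parameter count small as in common DCM practice.
Note the model's physical envelope: inflow cannot reverse, so sustained
strongly negative neuronal drive (z ≲ −0.3 for many seconds) would push
`f` to zero; the neuronal models used here do not produce such drive.

## Forward integration

All states evolve on a microtime grid (default dt = TR/16; the heavier
test fixtures use TR/8, justified by the step-halving self-consistency
check, which shows sampled-BOLD changes < 1e−6 RMS under halving) with
fixed-step classical RK4 and inputs held piecewise-constant over each
step. Inputs are compiled from event lists (onset, duration, optional
amplitude; overlaps merge by maximum) or read as sampled arrays. BOLD is
sampled at t = 0, TR, 2TR, …  A state that becomes non-finite or leaves
the positive domain of (f, v, q) raises a divergence error carrying the
first bad microtime index — possible for unstable bilinear systems,
impossible in practice for Wilson–Cowan flows, whose state is confined
to (−1/2, 1/2) per component (plus initial-condition decay). Batched
integration (one RK4 loop advancing many parameter sets sharing a
timeline) underlies the finite-difference sensitivities and the
Levenberg–Marquardt candidate ladder below; per-step effective
connectivity matrices are precomputed per distinct input vector, which
is efficient for boxcar designs.

## Priors

Shrinkage priors in the classical style, over the full free-parameter
vector (structurally absent parameters simply do not appear):

| parameter | prior |
|---|---|
| A off-diagonal, B (allowed by masks) | N(0, 1/16) |
| C (allowed) | N(0, 1) |
| A diagonal | N(−0.5, 1/256) |
| log α (and log α_E, log α_I) | N(log 4, 1/16) |
| two-state log wEE | N(log 0.25, 1/16) |
| two-state log wSE/wSI/wIE/wEI | N(log 0.5, 1/16) |
| two-state modulatory parts | N(0, 1/16) |
| hemodynamic log-scalings (κ, τ_h) | N(0, 1/256) |
| per-region noise log-precision | N(6, 1/128) |

The log-slope prior mean log 4 makes the Wilson–Cowan small-signal
regime start bilinear-equivalent. The noise hyperprior (precision e⁶,
i.e. noise sd ≈ 0.05 in model units) is coherent with the amplitude of
BOLD this generator produces (~0.04 sd); it deliberately over-weights
accuracy when data are much noisier, which is what produces the
flat-line failure mode at very low SNR. Noise precision is per region; a
global precision is the obvious restriction but per-region is the
default.

## Variational-Laplace inversion

Confounds: per-region mean removal only (applied to data and to every
prediction before residuals). Each iteration:

1. **Sensitivities.** Forward finite differences (step 1e−4 on the
   unconstrained scale) of the sampled, demeaned prediction with respect
   to every free parameter, integrated as one batch. A perturbation
   whose integration diverges contributes a zero column (no
   information).
2. **E-step.** Gauss–Newton step toward the posterior mode of the
   Gaussian log-joint
   `O(θ, h) = Σ_r [T/2·(h_r − ln 2π) − e^{h_r}/2·‖e_r‖²]
   − ½(θ−θ₀)ᵀΠ₀(θ−θ₀) − ½Σ_r (h_r−h₀)²/σ_h²`,
   regularized by a Levenberg–Marquardt ladder: candidates for damping
   ν, 2ν, 4ν, … (start 1/8, 8 rungs) are integrated as one batch and the
   least-damped candidate that *increases* O is accepted (identical to
   the sequential try/double/retry rule); acceptance halves ν, total
   failure multiplies it by 2⁸. Candidates whose integration diverges
   are treated as rejected rungs. O does not depend on the local
   Jacobian, so it is comparable across iterations and the recorded
   trajectory is non-decreasing by construction.
3. **M-step.** Per-region Newton update of the noise log-precisions
   under their Gaussian hyperprior (a few guarded Newton steps); the
   posterior variance of each h_r is the inverse curvature.

Convergence: three consecutive iterations with gain < 1e−2 nats (or no
accepted step), capped at max_iter (default 128; fixtures use 32–64).
At the optimum the Laplace covariance Σ = (JᵀΛJ + Π₀)⁻¹ is formed and
the full free energy

    F = accuracy − KL[q(θ)‖p(θ)] − KL[q(h)‖p(h)]

is evaluated once, with the accuracy term the Gaussian log-likelihood of
the residuals at the posterior noise log-precisions. F is the
model-comparison currency. Reported alongside: the predicted response,
explained variance `100·(1 − var(e)/var(y))` pooled over regions after
demeaning (may be negative), and the flat-line flag
`var(pred) < 10⁻³·var(obs)` (strict), the signature of an inversion
collapsing to "noise explains everything". The posterior probability
that a coupling is nonzero with determinate sign,
`max(Pr(θ>0), Pr(θ<0))` under the Gaussian marginal, is the
edge-presence score used downstream.

A design note: an earlier formulation accepted steps on F itself,
recomputed each iteration from the current Jacobian. Because the
log-determinant complexity terms change with the expansion point, F
values at different iterates are not mutually consistent, and the scheme
could deadlock against a stale, optimistically-curved baseline
(particularly at the resting fixed point, where most sensitivities
vanish). Ascending the J-independent log-joint and reserving F for the
converged Laplace approximation avoids this while returning the same
posterior mode.

## Synthetic data

The ground-truth network is three regions with a driving input into
region 1, feedforward connections 1→2, 1→3 and 3→2, and a contextual
input modulating 1→3 and 3→2. Default values (configurable): self
connections −0.5 Hz, forward connections 0.4 Hz, modulations 0.2 Hz,
driving input 0.5 Hz, α = 4. Input design: a 20 s-on/20 s-off driving
boxcar and a 60 s-period (30 s-on/30 s-off) contextual boxcar; 6-minute
runs at TR = 2 s (the heavier sweep fixtures use 3-minute runs to keep
desk-scale runtimes). SNR is defined per region as
sd(clean signal)/sd(noise); noisy realizations add white Gaussian noise
with sd = sd(clean)/SNR, fully seeded. The generator produces none of
the structure of real fMRI noise — no autocorrelation, drift, motion or
physiological components — so passing recovery tests demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to real-data artifacts.

The "pure noise" fixture uses noise sd = 2.0 in model units: the clean
generator signal has sd ≈ 0.04, and an empirical SNR of about 0.02
(typical of event-related limbic/face-processing data) implies noise of
that magnitude.

## Model spaces

The full space over `l` regions and one modulatory input assigns each
directed inter-regional connection one of {absent, present,
present+modulated} and lets each region independently receive the
driving input: `3^{l(l−1)}·2^l` models (5,832 for l = 3).
Self-connections are never enumerated over and never modulated. The
hypothesis-constrained space fixes the driving input to one region and
keeps a model only if **every other region is reachable from the input
region through present connections** — the input must be able to
propagate through the whole network. For l = 3 this yields exactly 540
models. The published count comes without its derivation; reachability
is the inferred rule (weaker rules, e.g. "the input region has an
outgoing edge", give different counts), cross-checked in the tests by an
independent graph-library enumeration. Enumeration order is
lexicographic over edge states, so model indices are stable.

## Group-level model selection

- **FFX**: group log evidence = column sum of F across subjects;
  posterior model probabilities are a softmax; log group Bayes factors
  are column-sum differences, annotated as strong evidence at ≥ 3 nats.
- **RFX**: the variational Dirichlet scheme — iterate subject-wise
  responsibilities `u_{nk} ∝ exp(F_{nk} + ψ(α_k) − ψ(Σα))` and counts
  `α = α₀ + Σ_n u_n` to convergence (α change < 1e−6; flat prior
  α₀ = 1). Expected probabilities are α/Σα; exceedance probabilities
  `Pr(x_k = max)` are estimated from ≥ 1e5 seeded Dirichlet samples
  (cross-checked against the regularized incomplete beta function at
  K = 2).
- **Protected exceedance**: the Bayesian omnibus risk is the posterior
  probability of the null model in which all frequencies are fixed equal,
  `BOR = 1/(1 + e^{F₁−F₀})`, where F₀ = Σ_n[logsumexp_k F_{nk} − ln K]
  and F₁ is the evidence bound of the Dirichlet model; then
  `φ̃_k = φ_k(1−BOR) + BOR/K`. With perfectly uninformative data BOR is
  well above 1/2 but below 1 (the null wins only by its Occam factor,
  ≈ 0.79 at K = 2, N = 20), matching the behavior of the standard
  toolbox implementations.
- **Family level**: FFX re-normalizes the model prior so each family
  carries equal mass; RFX gives each model prior weight 1/|family| and
  sums posterior Dirichlet samples within families.
- **BMA**: parameter means are averaged over models weighted by
  posterior model probability; a model in which a parameter is absent
  contributes the value 0 with all mass at 0 (sign probability 0).
  Parameters with model-averaged sign probability > 0.95 are flagged.

## Evaluation harness

The SNR sweep generates data from the *bilinear* ground truth, then
inverts each realization under both neuronal variants using the
**saturated** structure (all six inter-regional connections present,
modulation and input masks unchanged), recording explained variance,
flat-line flags and per-edge presence scores. Scoring the saturated fit
avoids a 540-model refit per realization; this is a deliberate
desk-scale deviation from refitting the whole space. ROC curves sweep
the presence-probability threshold from strict to lenient with endpoints
(0,0) and (1,1); AUC is the trapezoidal area (cross-checked against
scikit-learn). Model recovery fits each of a small set of generating
models to each realization and counts which model attains maximal F.
All cells use deterministic child seeds, so tables reproduce
bit-identically.

## Known limitations

- **The Wilson–Cowan variant cannot imitate a strong bilinear
  generator.** Its state is confined to (−1/2, 1/2), so bilinear data
  with latent excursions beyond that amplitude are unreachable; and with
  the self-connection prior pinned near −0.5 inside the sigmoid, its
  effective linearized decay is at least 1.125 s⁻¹ — faster than the
  −0.5 s⁻¹ of the bilinear generator — so even amplitude-matched
  bilinear data are fit with a systematic shape deficit (~25 % of signal
  variance in our sweeps). Consequently, on bilinear-generated synthetic
  data the (correct) bilinear model attains higher explained variance at
  moderate SNR, and the two variants do not merge within error bars;
  this is reported as-is by the sweep test. Edge detection shows the
  opposite ordering: the sigmoid's saturation suppresses noise-chasing,
  and the Wilson–Cowan variant's connection AUC is consistently at least
  as high at low SNR, with comparable false-positive rates.
- **Flat-line rescue is optimizer-dependent.** The batched LM ladder
  explores eight damping levels per iteration and therefore recovers
  many bilinear inversions that a scheme with a single candidate step
  per iteration abandons at the prior (the flat-line collapse). Both
  variants still flat-line when data are overwhelmingly noise.
- Exceedance probabilities are Monte-Carlo estimates; equivalence with
  other implementations holds at the level of the defining formulas, not
  sampler details.
- Two-state inversions are supported but have roughly twice the
  parameter count and are correspondingly slower and less identifiable
  at these data sizes; the validation harness exercises the single-state
  models.
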
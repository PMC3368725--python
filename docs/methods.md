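# Methods

## The model

The spindle assembly checkpoint (SAC) delays anaphase until every
kinetochore is attached to spindle microtubules. The package models the
checkpoint and the subsequent anaphase onset as two continuous-time
Markov chains over molecule counts, small enough that concentration
(mass-action) kinetics is not valid: the relevant copy numbers are a
handful of free Cdc20 molecules and N ≈ 13 kinetochore targets.

**Inhibition phase (checkpoint up).** The state is the number k of free
Cdc20 molecules. Three reaction channels act on it:

| channel | transition | propensity |
|---|---|---|
| production (release from a pool of S complexes) | k → k+1 | λ(S−k) |
| inhibition/ubiquitylation by MCC | k → k−1 | k₋₁·k |
| premature APC/C activation (absorbing) | k → ∗ | μN·k |

Absorption models the event the checkpoint exists to prevent: one free
Cdc20 reaching one of the N APC/C targets. The survival probability
P(t) — no activation by time t, starting from k = 0 — has the closed
form

P(t) = [((λ+r₁)e^{−(λ+r₂)t} − (λ+r₂)e^{−(λ+r₁)t}) / (r₁−r₂)]^S,

where r₁ ≥ r₂ solve X² − (−λ+μN+k₋₁)X − k₋₁λ = 0. The closed form is
an exact consequence of the generating-function solution of the master
equation; the package does not re-derive it symbolically but proves it
numerically, on every tested parameter set, against direct stiff
integration of the truncated master equation (truncation at k = S is
exact because the pool bounds the count). P is non-increasing in t and
in λ, non-decreasing in k₋₁, and identically 1 when λ = 0 or μ = 0.

**Equilibrium.** Conditioned on survival, the absorption channel drops
out and the birth–death chain with rates λ(S−k) / k₋₁k has the binomial
stationary law B(S, λ/(λ+k₋₁)), mean S·λ/(λ+k₋₁) (≈ 0.0125 molecules at
the defaults — the checkpoint keeps free Cdc20 essentially at zero).
Detailed balance gives an exact residual check. The chain relaxes at
rate λ + k₋₁; `relaxation_time` exposes the scale (≈ 0.04 s at the
defaults) but no threshold is imposed on how long the checkpoint must
have been up — that is the user's modelling judgement.

**Activation phase (checkpoint lifted).** MCC production stops and k₋₁
is set to zero exactly; its only trace is the equilibrium binomial used
as the initial Cdc20 law. The state is (k, m): k Cdc20 produced (bound
ones included), m of N targets activated. Channels: production
k → k+1 at λ(S−k), and activation m → m+1 at μ(N−m)(k−m) (free Cdc20
= k−m). Both coordinates are non-decreasing, so the chain is acyclic
and the expected occupation times a(k,m) = ∫p_{k,m}(t)dt solve

out(k,m)·a(k,m) = init(k)·[m=0] + λ(S−k+1)·a(k−1,m)
                  + μ(N−m+1)(k−m+1)·a(k,m−1)

in a single topological sweep (no iteration). The mean anaphase-onset
time is τ = Σ_{m<N} Σ_k a(k,m).

**Constraint domain.** Two requirements bracket the rates: C1, the
survival over the congression window τ₁ = 1200 s stays ≥ 0.95; C2, the
mean activation time τ ≤ τ′ = 600 s. Ω is their intersection in the
(λS, k₋₁) plane; the scan is parameterized by λS because production
enters all large-S behaviour through that product. Monotonicity of both
evaluators in λ makes each fixed-k₋₁ slice of Ω an interval, and the
boundary level curves P(τ₁) = 0.95 and τ = τ′ are found by bisection.
The summary ratio ρ = k₋₁/(λS) is reported descriptively (ρ = 80 at the
defaults).

## Parameters and defaults

| symbol | meaning | default | unit | origin |
|---|---|---|---|---|
| λ | per-complex Cdc20 production rate | 1e-4 (λS = 0.3) | 1/s | reference operating point |
| k₋₁ | inhibition rate per free Cdc20 | 24 | 1/s | Smoluchowski 2πbD[MCC], rounded |
| μ | per-target arrival rate | 2e-4 | 1/s | tabulated reference value |
| N | chromosomes / APC/C targets | 13 | — | PTK2 karyotype |
| S | complex-pool size | 3000 | — | 50 nM in 100 µm³ |
| V, a, b, D | volume, target radius, binding-site radius, diffusivity | 100, 0.01, 0.002, 20 | µm³, µm, µm, µm²/s | flat PTK2 cell |

Two documented inconsistencies in the reference values are preserved
rather than resolved, because the headline numbers are only
reproducible with the tabulated figures:

- 4aD/V with the tabulated a, D, V gives μ = 8×10⁻³ 1/s, not the
  tabulated 2×10⁻⁴ 1/s. The package default is the tabulated value;
  `mu_from_geometry` computes the geometric one.
- 2πbD[MCC] at 10⁴ MCC copies gives 8π ≈ 25.13 1/s, commonly rounded
  to 24; the default is 24, the constructor returns 25.13.

Unit conversions use Avogadro's number exactly: 50 nM in 100 µm³ is
3011 molecules (quoted as 3000), 200 nM is 12044 (quoted as ~10⁴).

## Numerical choices

- **Survival in log space.** P = exp(S·log B); with S ≈ 3000, direct
  powering of B ≈ 1 loses precision. λ+r₂ is evaluated through the
  product identity (λ+r₁)(λ+r₂) = λμN to avoid cancellation, and the
  normalizing denominator is written (λ+r₁)−(λ+r₂) so that P(0) is
  exactly 1. Excursions outside [0,1] up to max(1e-12, 4·eps·S) are
  clamped as rounding noise; larger ones raise, to separate rounding
  from bugs. The degenerate double root (possible only when k₋₁λ = 0
  with −λ+μN+k₋₁ = 0) uses the analytic limit B = e^{−(λ+r)t}(1+(λ+r)t).
- **Master-equation oracles.** BDF with the exact sparse Jacobian,
  rtol 1e-10 / atol 1e-14; total probability is checked to drift less
  than the requested tolerance at every output point. The inhibition
  system has S+2 states; the activation system lives on the wedge
  m ≤ min(k, N).
- **Occupation sweep.** The a(k,m) table is stored dense, (S+1)×N
  (~300 kB at the defaults), with structural zeros for k < m; the sweep
  is O(S·N). States with zero outflow but positive inflow mean τ = ∞
  and raise `DivergentMeanTimeError` (e.g. λ = 0 with initial mass
  below k = N).
- **Bisection.** Plain interval halving to an absolute λS tolerance
  (default 1e-4), after an explicit sign-change check; an infinite τ
  inside the bracket is reported as a bracket error rather than treated
  as a sign.
- **SSA.** Direct method (one exponential waiting time plus one uniform
  channel choice per event) — with at most three channels nothing
  faster is warranted. Ensembles draw per-run generators from
  `SeedSequence(root, spawn_key=(i,))`, so a root seed reproduces the
  ensemble regardless of execution order.

## The simulator as synthetic-data generator

The SSA layer generates the only "data" this analysis consumes:
exponential-waiting-time event trajectories of the two reaction
networks at the study conditions (the defaults above; 10⁴ trajectories
for ensemble comparisons, the checkpoint horizon t = 1200 s). It
emulates exactly the stochastic structure the analytic layers assume —
well-mixed kinetics, constant MCC during the checkpoint, instantaneous
k₋₁ shutdown at anaphase onset. It deliberately does **not** emulate
features of real cells outside the model: spatial diffusion gradients
(space enters only through the scalar rates μ and k₋₁), gradual MCC
decay after attachment, per-kinetochore attachment dynamics (N is fixed
within each phase), or the downstream securin/separase cascade.
Agreement between simulation and the closed forms therefore validates
the mathematics and the implementation, not the biological completeness
of the model.

## Validation summary

Every analytic result has at least one independent check computed by
the test suite: closed-form survival vs. master-equation integration
(≤1e-6 absolute, reference point and 20 randomized parameter sets);
occupation sweep vs. dense fundamental-matrix solve vs. ODE quadrature
(≤1e-4 relative on small instances); binomial equilibrium vs.
stationarity residual (≤1e-10) and long-time integration (TV ≤ 1e-6);
and all three vs. 10⁴-trajectory Monte-Carlo ensembles (3 standard
errors). Unit tests use reduced systems (S ≤ 200) so the default suite
runs in well under a minute; the reference-scale comparisons (S = 3000)
run in the deeper end-to-end tests.

At the reference parameters the package computes P(1200 s) = 0.9618 and
τ = 345.04 s. The τ value is worth a remark: a figure of 239 s is
sometimes quoted for this parameter set. All three independent solvers
here (sweep, fundamental matrix, SSA with 10⁴ runs) agree on 345 s, and
239.5 s is obtained from this chain only by setting λ equal to μ =
2×10⁻⁴ 1/s (i.e. λS = 0.6). Both values satisfy the timing constraint
C2 (τ ≤ 600 s), so the constraint-domain conclusions are unaffected.

## Known limitations

- The model has no spatial resolution; cells with strong Cdc20 or MCC
  gradients violate the well-mixed assumption behind μ and k₋₁.
- MCC is held constant during the checkpoint and removed instantly at
  anaphase onset; a slow clearance would lengthen τ.
- The equilibrium initial condition for the activation phase assumes
  the checkpoint lasted ≫ 1/(λ+k₋₁); the diagnostic is exposed but not
  enforced.
- Ω is unbounded above in k₋₁ unless the user closes it with the
  Smoluchowski bound on [MCC]; the package reports the helper rate but
  adds no third constraint.
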
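# Methods

## The scientific question

Serum stimulation of starved fibroblasts produces a spike of the membrane
lipid PIP3 at about 2 minutes, but Akt phosphorylation at Thr308
(Aktp308) peaks only at 30–60 minutes before settling to a moderate
steady level — an "overshoot" an order of magnitude later than its
canonical driver.  The package asks which single non-canonical effect,
inserted into the canonical PIP3/PDK1/Akt cascade, can explain that
delay, and then excludes candidates with simulated intervention
experiments until one mechanism survives.

## Model family

All variants share the canonical core (concentrations in arbitrary units,
time in minutes):

```
PDK1      <-> PIP3:PDK1m      k1*[PIP3][PDK1]   /  k2*[PIP3:PDK1m]
Aktc       -> PIP3:Aktm       k3*[PIP3][Aktc]
PIP3:Aktm  -> Aktp308m        k4*[PIP3:PDK1m][PIP3:Aktm] / (k5 + [PIP3:Aktm])
Aktp308m   -> Aktp308c        k6*[Aktp308m]
Aktp308c   -> Aktc            k7*[Phosphatase][Aktp308c] / (k8 + [Aktp308c])
```

PIP3 is an *input*: a measured, piecewise-linear curve that appears as a
multiplier on the right-hand sides and is never itself integrated or
depleted.  Totals are conserved by construction (PDK1 pool, Akt pool, and
for M4 the phosphatase pool), which the test suite verifies along every
trajectory.  Dephosphorylation is cytosol-only, reflecting the absence of
the relevant phosphatase from membrane fractions in this cell type.

Each alternative hypothesis adds one pseudo-species — a latent
piecewise-linear curve v(t) knotted on the measurement grid
{0, 2, 5, 10, 30, 60, 120} min — coupled through one pseudo-reaction:

- **M1** multiplies the PIP3-dependent recruitment term (`k3*[PIP3]*v*[Aktc]`);
- **M2** adds a PIP3-independent recruitment flux (`k9*v*[Aktc]`);
- **M3** splits membrane phospho-Akt into free and trapped pools with
  trapping `k10*v*[Aktp308mf]` and release `k11*[Aktp308mt]` (membrane
  retention);
- **M4** reversibly sequesters the phosphatase
  (`k12*v*[Phosphatase]` forward, `k13*[InaccPhosphatase]` back).  The
  printed equations of this variant carry no spline variable, so the
  curve is coupled multiplicatively to the forward sequestration flux —
  a documented design choice that keeps M4 on the same pseudo-species
  scheme as the others (v = 0 recovers the canonical model exactly);
- **M5** multiplies the phosphorylation flux.

The knot at t = 0 is pinned to the neutral value (1 for multiplicative,
0 for additive couplings) so the pre-stimulation state is not perturbed;
a flag (`free_t0_knot`) releases it.

The phosphatase concentration is dynamic only in M4 and constant
elsewhere.  The source text is internally inconsistent on this point
(prose vs. equations); the equations win here.

## Simulation

`scipy.integrate.odeint` (LSODA) with rtol 1e-8 / atol 1e-10 by default
(1e-6 / 1e-8 inside the calibration loop, where speed matters and the
objective tolerates it); spline knot times are passed as critical points
so derivative kinks do not degrade the step controller.  Negative
excursions beyond −1e-9 raise; smaller ones clip to zero.  The default
output grid is 1-minute resolution over 0–120 min merged with the
measurement grid, which peak-feature extraction needs.

## Calibration

The objective is the weighted sum of squared residuals over every
(species, condition) series, with the time-independent inverted
mean-square weight w = n_t / Σ_t x(t)², which makes the objective
invariant to rescaling any single series — appropriate for arbitrary-unit
densitometry.  A quadratic penalty λ‖f(x₀, 0)‖² (λ = 10³ by default)
keeps the fitted rates consistent with an approximately steady starved
state; it can be disabled per problem (and is disabled for noiseless
self-consistency fits, where the generating parameters are the global
optimum of the plain SSE and the penalty would bias the solution away
from them).

Search runs in log10 space for rates (they span k8 ≈ 1.65 to
k5 = 68 000) and linear space for knot values; default bounds are rates ∈
[1e-3, 1e5], additive knots ∈ [0, 100], multiplicative knots ∈ [0, 50].
k4 and k5 stay at their literature values; k1–k3 and k6–k8 are free.

Each restart perturbs the base guess multiplicatively by
(1 − α) + α·Exp(1) per coordinate (α = 0.5) — an interpretation of
"exponential noise" chosen because the factor has unit mean for every α
and degenerates to a no-op as α → 0 — then runs a global-best particle
swarm (20 particles, 30 iterations, constriction coefficients
w = 0.7298, c1 = c2 = 1.49618) followed by Nelder–Mead refinement.
A failed integration returns a large sentinel value so the stochastic
search routes around stiff corners of the box.  All randomness derives
from one run seed; repeated runs are bit-identical.

The default budgets are desk-scale: 10 restarts per model rather than the
hundreds a full study would use (`FitConfig.full_scale()` restores the
larger budget).  The four-species refit of protocol stage 2 is the harder
search and gets an escalated budget (50 swarm iterations, 600 simplex
evaluations) — the scripted replacement for the interactive tuning such
fits traditionally receive.

## Peak scoring and gross violations

Because blot data carry relative, per-series scales, model–data agreement
is judged on shape features of each curve: peak time (argmax), peak width
(time above the final-time baseline plus half the prominence, crossings
interpolated), and peak amplitude (peak / final fold change).  A series
with amplitude below 1.15 whose maximum is interior counts as having no
overshoot.

A hypothesis is excluded only for a *gross* violation, with thresholds
calibrated once against the default synthetic protocol so that a
well-converged fit of the generating model sits well inside every bound:

- peak-time displacement > 15 min, measured as the argmax-to-window
  distance (each curve's argmax against the other's ≥90%-of-max window).
  Plain argmax differences are noise-fragile for plateau-shaped series
  such as total membrane Akt, where the maximum may sit anywhere on a
  broad shelf; the window distance tolerates that jitter while still
  flagging genuinely displaced peaks;
- amplitude disagreement beyond 4-fold;
- width disagreement beyond 2-fold;
- a decisive overshoot mismatch: one curve clearly declining (amplitude
  > 1.35) while the other clearly does not (< 1.15).  The dead band keeps
  borderline, noise-level declines from flipping verdicts.

The Σ(err) summary (sum of absolute peak-time errors over Aktp308,
PDK1m, TotMemAkt and Aktp308m) is reported alongside.  For dual-peaked
fits only the global maximum is scored.

## The four-stage exclusion protocol

1. **Aktp308 fit.**  All six variants are fit to the total-lysate Aktp308
   series; a model whose best fit grossly violates the overshoot is out.
   The canonical model fails here: with a PIP3 input that declines to a
   moderate plateau (rather than to baseline), the plateau dominates the
   input integral, so slow parameterizations relax monotonically and only
   fast ones peak — early, mirroring PIP3.  Neither produces a 30-minute
   peak followed by a real decline.
2. **Membrane time series.**  Survivors are refit (warm-started from
   stage 1) to the four-species dataset and scored on all four curves.
   The dephosphorylation and phosphorylation variants fail here: both
   must convert most Akt by 30 min to reach the Aktp308 peak, after which
   membrane occupancy collapses or the Aktp308 peak slides decades late —
   the irreconcilable trade the verdict detects as a peak-time or width
   violation.
3. **PIP3 clamp (PI3K inhibition).**  The PIP3 input is clamped at its
   unstimulated baseline with the serum-induced deviation maintained, and
   the predicted total membrane Akt is compared with the measured flat
   response; a model whose predicted rise differs from the observed rise
   by more than 2 a.u. (20% of the Akt pool) fails.  PIP3-independent
   recruitment accumulates membrane Akt regardless of the clamp and is
   excluded.
4. **Constitutive activation + shutdown.**  Each survivor is driven to a
   plateau with high constant PIP3 (deviation held at its fitted
   maximum), PIP3 is then clamped low, and persistence (level at 120 min
   post-clamp over the level at the clamp) is computed for membrane Akt
   and membrane PDK1.  The observed pattern is a *partial* decline of
   membrane Akt (persistence above the 30% present/absent threshold)
   with PDK1 vanishing.  A model fails if its classifications disagree —
   or if it predicts persistence more than 1.5× the observed one, i.e.
   no decline at all: a recruitment mechanism that parks Akt at the
   membrane indefinitely mismatches the experiment as surely as one that
   drains completely.

Failures propagate: an excluded model is not re-tested downstream
(`prior_fail`), and the canonical model is only subjected to the first
test.  On the default synthetic bundle the retention model is the sole
survivor.

## The synthetic-data generator

No public dataset accompanies the study, so the generator produces the
full bundle from a retention-model ground truth whose noiseless
observables land on the published shape anchors: PIP3 peaking at 2 min
and declining to a moderate plateau, Aktp308 peaking at 30 min before
declining to a lower steady level, total membrane Akt peaking at 5 min
and staying high through 30 min, membrane phospho-Akt rising and staying
high, membrane PDK1 mirroring PIP3, a flat membrane-Akt response under
the PIP3 clamp, and retained membrane Akt (but not PDK1) after
constitutive activation plus clamp.  Those anchors do not pin a unique
parameter set; the defaults were chosen once by constrained search over
rates and retention-knot values and then frozen.  The generating rates
(k1 = 2.4, k3 = 0.6, k6 = 0.83, k7 = 1.65, k10 = 3.3, k11 = 0.095,
with k2, k4, k5, k8 at the published canonical values)
deliberately produce deep phosphorylation (peak Aktp308 ≈ 0.8 of the Akt
pool) and a membrane pool dominated by trapped phospho-Akt at 30 min, so
that the fixed rescaling targets of the normalization chain (below) sit
in nearly uniform proportion to the native maxima.  The starved initial
state holds essentially all PDK1 and Akt cytosolic (membrane pools
0.001–0.004 a.u.), and the PIP3 baseline is the value that balances the
PDK1 shuttle there.

Replicate noise is multiplicative: one lognormal batch factor per
replicate series (σ = 0.15), an independent lognormal factor per
measurement (σ = 0.2), and a noisy constant loading control (σ = 0.05) —
mimicking blot variability in which within-batch trends are more
consistent than batch-to-batch scale.  Replicate counts follow the
study's design (4 lysate, 3 membrane phospho, 6 membrane total, 3
clamped).

The densitometry normalization chain follows the blot-processing recipe:
divide by the loading control, convert to fold-change from t = 0 (which
cancels batch factors by construction), difference into per-interval
increments, take the median increment across replicates, re-accumulate,
and rescale so the maxima are 10.0 (Aktp308, TotMemAkt), 5 (Aktp308m)
and 3.5 (PDK1m; no published target exists for this series, so a value
commensurate with a realistic membrane fraction was chosen), with
membrane phospho capped at the total-lysate series.  The chain is
end-to-end scale invariant, which the tests verify.

What the synthetic data do **not** emulate: saturation and
nonlinearities of film densitometry, correlated timepoint noise within a
blot, cytosolic-fraction measurements, and any biological variability in
the curve shapes themselves — the ground truth is one fixed mechanism.
Passing the protocol on this bundle therefore demonstrates that the
machinery discriminates the mechanisms *under the study's stated
conditions*, not that it would do so under every noise regime.

## Numerical choices and degenerate inputs

Spline evaluation clamps outside the knot span (simulations never leave
it in normal use; clamping avoids negative extrapolated abundances).
Interventions compose left-to-right and never mutate their input spec.
Michaelis constants must be positive; an all-zero data series has no
defined weight and is rejected; a monotone series featurizes with the
full span as width and the no-overshoot flag set; a shutdown test on a
model that never activates raises rather than dividing by zero.

## Identifiability and known limitations

The models are deliberately under-determined (the deviation knots plus
free rates exceed what seven-timepoint series can pin down), so fitted
knot values are not individually meaningful; only trajectories and
curve-shape features are interpreted, and the parameter-recovery test
accordingly checks trajectory RMSE and deviation-curve shape correlation
rather than parameter equality.  Two further structural facts matter
when reading results.  First, membrane-bound unphosphorylated Akt has no
dissociation reaction in the printed equations, so any variant can "park"
Akt at the membrane once recruited; the stage-4 over-retention guard
exists precisely because such parking predicts no post-clamp decline at
all.  Second, the published rescaling targets (Aktp308 max = 10 with an
Akt pool of 10, membrane maxima 10 and 5) are mutually inconsistent as
absolute concentrations — no state vector satisfies all of them at the
30-minute peak — so every fit carries an irreducible residual and
verdicts must rest on shape features, which is exactly why the scoring
layer is feature-based.

The verdict thresholds and the stage-3/stage-4 numeric criteria are this
package's formalization of judgments the source study made by
inspection; they are configurable, and the defaults are calibrated to
the synthetic protocol as described above.
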
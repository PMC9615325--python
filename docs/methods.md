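# Methods

## Model and assumptions

The package analyses a three-compartment rumor-diffusion model with constant
recruitment Λ of susceptibles, mass-action spreading βSI, uniform removal μ,
and conversion of spreaders by recovered individuals at rate αI·R(t−τ). The
delay τ models the lag between a debunking contact and the spreader actually
ceasing to propagate; it enters only the ±αI·R(t−τ) terms. A government
control removes spreaders at rate qI, switched on only above a spreader
threshold I_th. All parameters are strictly positive (τ ≥ 0); population
classes are nonnegative; the total N = S + I + R obeys dN/dt = Λ − μN
regardless of the control, since the control term moves mass from I to R.

The discontinuity at I = I_th is given meaning in the Filippov sense: off the
plane the appropriate smooth field acts; on the plane the admissible
velocities are the convex combinations of the two fields. A subsystem
equilibrium is regular when it lies in its own region of validity and virtual
otherwise; on the plane, motion can slide when both fields point toward it.

## Parameters

| name  | meaning                                   | typical value used here |
|-------|-------------------------------------------|-------------------------|
| Λ     | susceptible recruitment (individuals/time) | 0.5–0.8                |
| β     | susceptible–spreader contact rate          | 0.2–0.6                |
| μ     | removal rate of every class (1/time)       | 0.05–0.5               |
| α     | spreader–recovered contact rate            | 0.4                    |
| q     | control strength                           | 0.6–0.7                |
| τ     | debunking delay (time)                     | 0–50                   |
| I_th  | control threshold (spreader level)         | 0.1–0.4                |

The standard benchmark set used throughout the tests is
(α, β, Λ, μ, q) = (0.4, 0.6, 0.7, 0.1, 0.6), for which the free subsystem's
positive equilibrium is (2.8, 0.25, 3.95) and the controlled subsystem's is
(3.4306, 0.1734, 3.3960).

## Equilibria and classification

The free subsystem's equilibria are explicit. The controlled subsystem's
positive equilibrium solves the quadratic C₁R² + C₂R + C₃ = 0 with
C₁ = μα(α+β) > 0 and C₃ = q(μ² + qμ − Λβ); under the existence condition
Λβ > μ² + qμ we have C₃ < 0, so exactly one root is positive. The root is
evaluated in the cancellation-free form (−C₂ + √disc)/(2C₁) when C₂ ≤ 0 and
−2C₃/(C₂ + √disc) otherwise. Every equilibrium constructor verifies a drift
residual below 1e−10 with the delayed argument set equal to the instantaneous
one.

Classification compares I against I_th; an equilibrium within 1e−12 of the
plane is labelled `boundary` rather than arbitrarily regular/virtual. The
knife-edge boundary equilibria require exact parameter coincidences, so their
defining equalities are tested within a user tolerance (default 1e−9).

## Characteristic equation and Hopf crossings

Linearization at a positive equilibrium yields
λ³ + a₁λ² + a₂λ + a₃ + (a₄λ² + a₅λ + a₆)e^{−λτ} = 0. For the controlled
subsystem two conventions for a₆ circulate; symbolic expansion of the 3×3
characteristic determinant gives a₆ = αI[(αR+q)(βI+μ) − β²SI], which is the
package default (`convention="derived"`). The alternative without the leading
αI factor (`convention="printed"`) is retained behind a flag for comparison;
it fails the τ = 0 Routh–Hurwitz test at the benchmark set even though the
equilibrium is demonstrably stable there, and it fails the characteristic-
determinant residual oracle, so it is not used for conclusions. The test
suite validates the derived convention against a direct numerical determinant
of the delayed Jacobian at random complex arguments.

Imaginary-axis roots λ = iω require v = ω² to be a positive root of the
crossing cubic h(v) = v³ + B₁v² + B₂v + B₃ (B₁ = a₁²−2a₂−a₄²,
B₂ = a₂²−2a₁a₃+2a₄a₆−a₅², B₃ = a₃²−a₆²). Roots are taken from the companion
matrix with a 1e−9 realness/positivity tolerance. The critical delays are
obtained from the complex ratio e^{−iωτ} = −P(iω)/Q(iω): the principal angle
θ ∈ (0, 2π] is read off with atan2, which solves the sine and cosine
equations simultaneously and fixes the quadrant without any branch
bookkeeping; τ_j = (θ + 2πj)/ω. Note this is *not* the same as taking
arccos of the cosine expression with the sign it is sometimes quoted with;
the solved system requires the opposite sign of that expression, and every
returned (ω, τ_j) pair is verified against the full transcendental
characteristic function (residual < 1e−8 in the tests).

The crossing direction is the sign of h′(ω²) (the sign of Re(dλ/dτ)⁻¹ at the
crossing); |h′(ω²)| < 1e−10 raises a degenerate-crossing error rather than
guessing. Stability windows in τ are assembled by sorting all critical delays
on [0, τ_max] and accumulating right-half-plane root-pair counts (+1 at an
entering crossing, −1 at a leaving one), starting from 0 when the τ = 0 test
passes. At the benchmark set this reproduces stability on
[0, 1.3845) ∪ (5.9800, 12.5853) ∪ (22.9664, 23.7860) and permanent
instability afterwards: entries recur every 2π/ω₁ ≈ 11.20, exits only every
2π/ω₂ ≈ 16.99, so the count can never return to zero.

## Sliding dynamics

On the band μ ≤ βS − αR ≤ μ + q of the plane I = I_th, the equivalent control
ε = (βS − αR − μ)/q annihilates the I-component of the convex field.
Substituting εqI_th into the R-equation cancels the delayed terms exactly,
leaving the planar, delay-free flow dS/dt = Λ − βSI_th − μS,
dR/dt = I_th·βS − μR − μI_th (the `derived` variant, the default). A second
(`printed`) variant keeps the delay on the removal term,
dR/dt = I_th·βS − μR(t−τ) − μI_th; its rest point is the same but its
stability obeys the Hayes criterion μτ < π/2 instead of being unconditional.
Both are implemented; the simulator integrates the derived variant, and the
long-time simulation settling exactly on the derived rest point
R_p = I_th(βS_p − μ)/μ (S_p = Λ/(βI_th + μ)) is the adjudicating check, which
the acceptance tests perform to 1e−3. The pseudo-equilibrium is reported only
when ε(S_p, R_p) lies strictly inside (0, 1); boundary coincidences are the
business of the boundary-equilibrium routine instead.

## Simulator numerics

* Fixed-step classical RK4 with base step dt = 0.01 (method of steps: dt ≤ τ
  is enforced when τ > 0, so every stage's delayed argument lies in known
  history). τ = 0 uses the same stepper as a plain ODE.
* History lookups use cubic Hermite interpolation on the stored (t, R, dR)
  nodes; for t ≤ 0 the initial history function is evaluated directly. The
  default history is a constant state; tabulated/callable histories are
  accepted.
* Threshold crossings are located by bisection on H = I − I_th within the
  step, to event tolerance 1e−10 (in time), and the state is then projected
  exactly onto the plane. If both fields point toward the plane
  (F_G1·∇H > 0 > F_G2·∇H) the run switches to the sliding flow; otherwise it
  continues with the field on the far side.
* During sliding, I is held at I_th exactly (index-0 projection; no boundary
  layer, hence no chattering), and ε is monitored using the delayed R. The
  exit time where ε hits 0 or 1 is bisected; exit through 0 resumes the free
  field, through 1 the controlled field. Recorded ε values are clamped to
  [0, 1] when within 1e−8 (event round-off at exits).
* A round-off guard zeroes components in (−1e−9, 0); the exact flow preserves
  nonnegativity, so anything more negative indicates a genuine failure and is
  surfaced. Non-finite states raise a blow-up error with the offending time.
* Convergence: halving dt reduces the terminal error by ~2⁴ on smooth
  segments (tested), and the conservation identity
  N(t) = (N(0) − Λ/μ)e^{−μt} + Λ/μ holds to better than 1e−8 across regime
  switches on the horizons used.
* There is no randomness in the integrator; a seed only affects the optional
  randomized constant history.

## Study conditions and design choices

* The qualitative experiments use constant history (1.0, 0.5, 0.5), dt = 0.01
  and horizons of 100–500 time units: long enough for the slowest mode (rate
  μ = 0.1) to decay below the convergence tolerances, short enough that the
  full suite runs in seconds.
* Oscillation is declared when the peak-to-peak amplitude of I over the final
  20% of the horizon exceeds 1e−3; "finite-time convergence" means the state
  stays within 1e−6 of its terminal value from before 0.9·t_end onward.
* The control-comparison experiment (α, β, Λ, μ) = (0.4, 0.5, 0.6, 0.1) with
  saturated-control parameters β₁ = 0.7, α₁ = 0.4 uses q = 0.7 for the
  threshold policy. The comparison studies thresholds I_th = 0.145 and 0.15,
  and the point of the threshold policy is to pin the spreader level at I_th
  by sliding; that requires I*_S2 < I_th, which holds for q ≳ 0.67 at this
  base set (I*_S2 = 0.1437 at q = 0.7) but not at q = 0.6 (I*_S2 = 0.1555,
  in which case the run converges to the controlled equilibrium above both
  thresholds instead and the comparison degenerates). q = 0.7 was fixed once
  on that analysis.
* Region labels in the (α, I_th) scan use the three-way ordering taxonomy
  (controlled-regular / both-virtual-with-pseudo / free-regular) with the raw
  free-subsystem case index attached, rather than exposing the six raw cases
  as the primary output.

## What the experiments do and do not show

All inputs are parameter sets; there is no data generator and no measurement
noise. Passing tests demonstrate internal mathematical consistency (closed
forms against residual oracles, analysis against simulation) and reproduction
of the benchmark dynamics at the studied parameter sets. They say nothing
about how well the compartmental model itself describes real rumor
propagation: real cascades are network-structured, heterogeneous and
stochastic, and parameters are not identifiable from the model alone.

## Known limitations

* The direction/stability of the bifurcating periodic orbits (normal form,
  first Lyapunov coefficient) is not computed; crossings are classified only
  by transversality sign.
* Stability-interval bookkeeping assumes simple, non-coincident crossings;
  coincident critical delays from different frequencies raise an error rather
  than being resolved.
* When the τ = 0 polynomial is unstable, the initial right-half-plane count
  is taken from numerical roots of the cubic; a lone real unstable root is
  treated as one "pair" for bookkeeping (it cannot leave through ±iω).
* The integrator is fixed-step and non-stiff; extremely fast control rates or
  tiny thresholds may need a smaller dt.
* Boundary/tangent equilibria are detected only at knife-edge parameter
  coincidences within a tolerance; no continuation of them is attempted.
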
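# Methods

## Model and scaling

The package analyzes the planar tumor–immune system

    dx/dt = σ + ρxy/(η + y) − μxy − δx,
    dy/dt = αy(1 − βy) − xy,

a nondimensional reduction of a Kuznetsov-type kinetic scheme for cytotoxic
effector cells attacking an immunogenic tumor.  `x` and `y` are effector and
tumor densities in units of the scaling populations E₀ = T₀ = 10⁶ cells, and
time is scaled by the tumor-deactivation rate, τ = n·T₀·t.  The
dimensional→nondimensional conversion implemented is

    σ = s/(n·E₀·T₀), ρ = p/(n·T₀), η = g/T₀, μ = m/n,
    δ = d/(n·T₀), α = a/(n·T₀), β = b·T₀,

the unique scaling consistent with τ = n·T₀·t; β must carry inverse-cell
units before scaling, which fixes β = b·T₀.  Two presets ship: the ODE-run
set (ρ = 11.131) and the discrete-run set (ρ = 1.131), both with
σ = 0.1181 by default (σ overridable; some tabulations of the same source
data quote σ = 0.001181, reachable via the override), and
η = 20.19, μ = 0.00311, δ = 0.3743, α = 1.636, β = 0.002.

## Discretization

The NSFD (Mickens) scheme moves each loss term into the denominator of its
own update:

    x' = (x + h(σ + ρxy/(η+y))) / (1 + h(δ + μy)),
    y' = y(1 + hα) / (1 + h(x + αβy)),        h ∈ [0, 1).

Consequences, all exercised by the test suite:

- **positivity** is structural (positive numerators over denominators > 1);
- **equilibria are preserved exactly** for every h: the fixed-point algebra
  reduces to δx + μxy = σ + ρxy/(η+y) and x = α(1 − βy), identical to the
  ODE equilibrium conditions — note the effector balance keeps the factor x
  in the inactivation term μxy, so the eliminated equation in y is a genuine
  cubic (leading coefficient −μαβ ≠ 0); no quadratic reduction exists;
- the scheme is first-order consistent, and the one-step difference from
  explicit Euler is O(h²);
- when ρ < δ(1 + βη) the box (0, σ(1+βη)/(δ(1+βη)−ρ)] × (0, 1/β] is
  forward-invariant (the certificate reports the y-bound 1/β always and
  flags the x-bound inapplicable otherwise — a flag, not an error).

h = 0 is accepted by the step maps (identity) but excluded from bifurcation
searches, where J(0) = I makes it a spurious root of det J = 1.

## Fixed points

The boundary (tumor-free) point is (σ/δ, 0).  Interior candidates come from
the cubic's real roots filtered to 0 < y < 1/β (the boundedness window) and
x = α(1 − βy) > 0, each polished by a damped Newton iteration on the full
2-D residual (max 50 iterations, step halving on residual increase,
convergence below 1e−12).  All admissible roots are returned, sorted by
ascending y: the classical uniqueness conditions (ρ > δ plus two further
inequalities, evaluated as diagnostics by `existence_conditions`) fail at
the discrete preset, and the cubic there genuinely carries three admissible
equilibria (y ≈ 8.190, 267.80, 447.13).  The smallest-y, low-tumor point is
the one that is stable at small h and undergoes the Neimark–Sacker
bifurcation; analysis entry points default to it but accept an explicit
fixed point.

## Stability classification

Jacobians of the vector field and of all three step maps (NSFD, Euler,
hybrid-controlled) are derived symbolically from the defining expressions at
import time and lambdified; hand-written finite differences serve only as
independent test oracles and for user-supplied generic fields.  The ODE side
uses Routh–Hurwitz (sink iff T < 0 < D, saddle iff D < 0).  The map side
uses the Jury table on C(φ) = φ² − Tφ + D assuming C(1) > 0: sink iff
C(−1) > 0 and D < 1, source iff C(−1) > 0 and D > 1, saddle iff C(−1) < 0,
non-hyperbolic complex pair iff T² < 4D and D = 1.  When C(1) < 0 one real
multiplier exceeds +1 and the table does not apply; the classifier then
falls back to eigenvalue moduli (the boundary point at the discrete preset
with h = 0.5 is such a saddle) and flags the report.  Non-hyperbolicity
tolerance is 1e−9 throughout, and every Jury verdict is cross-checked
against the moduli.

Two structural identities are used as invariants: at any interior
equilibrium the ODE Jacobian satisfies J₁₁ = −σ/x\* and J₂₂ = −αβy\*, so
T = −σ/x\* − αβy\* < 0 for all positive parameters — the interior
equilibrium of the ODE can never lose stability through a Hopf crossing.
And for the NSFD map C(−1) > 0 over all sampled admissible parameters and
steps, ruling out period-doubling.

## Hopf machinery

Because the tumor model itself admits no Hopf point, `hopf_scan` is written
against a `PlanarField` protocol: it tracks the equilibrium over the scanned
parameter (for the tumor adapter, by continuation to the nearest interior
point), brackets the zero of the leading eigenvalue real part, and reports
crossing location, frequency, transversality (central difference, step
1e−6·(1+|a₀|)) and the first Lyapunov coefficient.  `hopf_l1` translates the
equilibrium to the origin, maps the field by the real eigenbasis
Q = [Re q, −Im q] (normalized to unit determinant so the radial normal form
ẋ = −y + a·x·r², ẏ = x + a·y·r² returns exactly L1 = a) into rotation form,
and evaluates the classical planar formula

    L1 = (fxxx + fxyy + gxxy + gyyy)/16
       + [fxy(fxx + fyy) − gxy(gxx + gyy) − fxx·gxx + fyy·gyy]/(16ω)

with 4th-order central differences (default step 1e−2, exact for the
polynomial nonlinearities used in validation).  Synthetic registered fields
(`SyntheticHopfField`, `RadialNormalFormField`) provide planted crossings
with known location, frequency and criticality.

## Neimark–Sacker analysis

`ns_critical_h` root-finds det J(h) − 1 on [1e−3, 1 − 1e−6] (grid scan of
256 points plus Brent refinement to machine precision), then verifies the
multiplier pair is complex (T² < 4D) and leaves the unit disk with positive
speed (central-difference modulus derivative).  Low-order resonances
λᵐ = 1, m = 1..4 correspond to T ∈ {2, −2, −1, 0} and are excluded at
tolerance 1e−9.

The normal-form coefficient is computed from the map's own exact second and
third derivative tensors (symbolically derived), not from transcribed
closed forms: translate the fixed point to the origin, transform by the real
eigenbasis [[J₁₂, 0], [λ − J₁₁, −ω]] with λ = T/2, ω = √(4D − T²)/2, contract
the derivative tensors into the transformed quadratic/cubic coefficients
ξ₂₀, ξ₁₁, ξ₀₂, ξ₂₁, and assemble

    coeff = −Re[(1 − 2m)m̄²/(1 − m) · ξ₂₀ξ₁₁] − |ξ₁₁|²/2 − |ξ₀₂|² + Re(m̄ξ₂₁),

with m = λ + iω the critical multiplier.  The sign convention was fixed
against the delayed-logistic map (x, y) → (y, r·y(1 − x)) at r = 2, the
classical supercritical example, where the implementation returns −0.5 and
a simulation shows the attracting curve; an affine map returns exactly 0.
At the discrete preset the coefficient is ≈ −1.33e−6 < 0: supercritical, an
attracting invariant closed curve for h just above h\* ≈ 0.49148 — confirmed
by simulation (orbits at h\* + 0.02 settle on a curve at finite distance
from the point; at h\* − 0.02 they spiral in below 1e−6).

## Hybrid control

The controlled map is sin(b)·NSFD + (1 − sin(b))·identity, b ∈ (0, 1], so
its Jacobian is Jc = (1 − sin b)I + sin b·J and its multipliers move along
chords of the unit disk toward 1.  Stability is decided by the full Jury
pair |Tr Jc| < 1 + det Jc < 2 — the absolute value is kept even though the
flip side cannot occur here, because the one-sided predicate misclassifies
flip-type exits on general maps — and cross-checked against the spectral
radius at every grid point.  At h = 0.6 (uncontrolled spectral radius
1.0027) every gain in (0, 1] stabilizes the point, since sin(b) < 1 strictly
contracts the chord.

## Diagnostics

The MLE iterates the map and its tangent map together, renormalizing every
step and averaging natural-log growth (natural-log convention throughout);
for linear maps it reproduces ln of the spectral radius to 1e−3 by 5e3
iterations.  Bifurcation sweeps default to 10³ transient plus 10⁵
measurement iterations per grid point, starting 1e−3 from the interior fixed
point; convergence means the last 200 recorded states stay within 1e−6 of
the point, and the onset is the first grid value failing that.  The
measurement window matters: with only 10⁴ iterations a stable orbit
contracting at ~1e−4 per step cannot pass the 1e−6 threshold from a 1e−3
offset, and the onset would report transient slowness rather than lost
stability; 10⁵ iterations resolve every stable grid point of the preset
sweep, putting the onset at 0.49 — in the same grid cell as both the
computed h\* = 0.4915 and the MLE zero crossing.  Divergence (any component
beyond 1e12, a guard that keeps Euler blow-up demonstrations finite) flags
the grid point and the sweep continues.

Randomized property tests draw parameters log-uniformly within a factor of
3 of the discrete-preset magnitudes (seeded `numpy` generator; rejection
filters for ρ > δ, the boundedness hypothesis ρ < δ(1 + βη), or interior
existence, capped at 1e5 attempts).  This band keeps draws in the
biologically plausible regime the presets describe; it does not probe
extreme stiffness ratios, so the property results speak to that regime
only.

## What the synthetic conditions do and do not show

All experiments are self-generated: the model presets and seeded parameter
draws *are* the study conditions, and there is no external data.  Passing
tests therefore demonstrate internal dynamical consistency (scheme
properties, classification correctness against eigenvalue and simulation
oracles, reproducibility of the critical step size and sweep onset), not
fidelity of the model itself to tumor biology.  Known limitations: no
center-manifold analysis at degenerate (non-NS) boundaries, no continuation
of the invariant curve or resonance tongues, first-order accuracy of the
scheme, and Hopf analysis validated only on synthetic fields since the
model itself admits no crossing.
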
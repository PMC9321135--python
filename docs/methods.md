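# Methods

`mfsim` simulates pressure-driven, channel-based microfluidic devices at
three abstraction levels — closed-form / semi-analytic 1D models, and 2D/3D
lattice-Boltzmann (LBM) solvers — for three canonical use cases: shear-
thinning (blood) flow through a straight channel, passive mixing of two
miscible streams, and droplet transport through a T-junction. This note
records the models, the numerical choices, and the places where the design
was genuinely open.

## 1D models

**Rectangular duct flow.** The volumetric flow rate of a duct of width w,
height h, length l under a pressure drop Δp is

    Q = (w h³ Δp)/(12 μ l) · [1 − (h/w)(192/π⁵) Σ_{n odd} tanh(nπw/2h)/n⁵].

The odd-n series converges extremely fast; two terms carry a relative
truncation error of order 10⁻⁴ for a square duct and below 10⁻³ for all
aspect ratios h/w ∈ [0.1, 1] (asserted in the tests against a 200-term
evaluation). Hydraulic resistance is R_H = Δp/Q; networks of channels are
solved by nodal analysis (Kirchhoff current balance in the unknown junction
pressures, fixed-pressure boundary nodes, fixed-flow inlets as source
terms). For comparisons against the *2D* lattice solver, plate resistances
R'_H = 12 μ l / w³ (per unit depth) are used instead of the duct form, so
that both levels describe the same physics.

**Shear-thinning profile.** Blood is modelled with the five-parameter
Carreau–Yasuda law

    μ_eff(γ̇) = μ∞ + (μ0 − μ∞)(1 + (λγ̇)^a)^((n−1)/a),

with μ0 = 22 mPa·s, μ∞ = 2.2 mPa·s, λ = 0.110 s, a = 0.644, n = 0.392 and
ρ = 1060 kg/m³ (whole-blood literature fit). Between parallel plates the
stress balance gives τ_s(z) = (Δp/l)(w/2 − z), zero on the centerline; the
local shear rate solves γ̇ μ_eff(γ̇) = τ_s(z), which is strictly monotone
in γ̇ and therefore has a unique root. (A published variant of this
balance reads τ_s = z·Δp/l with z measured from the wall — that places zero
stress *at* the wall and maximal stress on the centerline, which
contradicts both the Newtonian limit and the flat-centered profile it is
meant to produce; it is available behind `literal=True` for inspection but
never used.) The root is found per point by damped Newton iteration
(start γ̇₀ = τ_s/μ0, residual tolerance 10⁻¹⁰ relative to τ_s, ≤100
iterations) with a guaranteed-bracket bisection fallback on
[0, τ_s/μ∞]. The velocity profile follows by composite Simpson
quadrature of γ̇ from the wall to the centerline (1001 points across the
width by default) and mirroring. Driving by a prescribed mean inlet
velocity inverts the monotone Δp ↦ ū map with Brent's method, bracketed by
the Newtonian pressure drops at μ0 and μ∞.

**Mixing.** With uniform advection u along x and diffusion D across the
width, the depth-averaged concentration obeys ∂²c/∂y² = Pe ∂c/∂x̃ with
Pe = u w/D and x̃ = x/w. Measuring y from the channel centerline
(y ∈ [−½, ½], inlet interface at y = 0) the solution is

    c = ½ + (2/π) Σ_{k odd} exp(−π²k² x̃/Pe) sin(πk y)/k,

whose odd-k sine modes have zero flux at the walls. The nondimensional
convention (which length scales x̃ and Pe, and where the interface sits)
is not uniquely fixed by the problem statement; it is exposed as explicit
parameters, and the default above is the one that reproduces the published
1D mixing-index value for the straight-channel case. The series is summed
until the next term's amplitude falls below 10⁻¹² (hard cap 10⁵ odd
terms; at x̃ = 0 exactly, the square-wave series converges only like 1/k,
so a residual of order 10⁻⁶ remains — irrelevant at any x̃ > 0).

**Droplet kinematics.** The droplet is a slug of length dl whose trailing
edge moves along the center path at u_d = α·Q/A of the segment containing
it, where α = 1.28 is the empirical slip factor; corners are taken at
constant speed, and the branch taken is the one carrying the larger
outward flow (tie → top, logged). Deformation, splitting and stability are
out of scope at this level.

## Lattice-Boltzmann solvers

**Discretization.** D2Q9 / D3Q19 stencils with the standard weights and
cs² = ⅓ (validated against the moment identities at construction), BGK
collision `f → f − (f − f_eq)/τ`, second-order truncated Maxwellian
equilibrium, and pull-free streaming by array shifts. SI ↔ lattice
conversion goes through (dx, dt, ρ_ref); ν = cs²(τ − ½) is the single
source of truth linking viscosity and relaxation time. Guards: lattice
inlet speed < 0.1 (weak compressibility), τ ∈ (0.5, 3].

**Boundaries.** Link-wise half-way bounce-back at walls (second order, wall
plane mid-link, so a channel of width w contains exactly w/dx fluid
cells); velocity inlets by bounce-back with the momentum correction
2wᵢρ(cᵢ·u_in)/cs²; pressure outlets by anti-bounce-back on the density
with the second-order velocity terms taken from the adjacent fluid cell.
The inlet profile is a uniform plug (the development length is well
upstream of every measurement line used). Geometry masks carry a one-cell
boundary ring; every population crossing the fluid boundary is rewritten
by exactly one rule, which makes mass conservation in closed domains exact
to machine precision.

**Shear-thinning coupling.** The local strain rate comes from the
non-equilibrium populations,
S = −(1/2ρcs²τ) Σᵢ cᵢcᵢ (fᵢ − f_eqᵢ), γ̇ = √(2 S:S), with no finite
differences; each step the τ field is refreshed from μ_eff(γ̇) and clamped
to (0.5+10⁻⁶, 3]. The time step is chosen so the *largest* viscosity (μ0)
maps to τ = 1.8, which puts μ∞ at τ ≈ 0.63.

**Two-component (Shan–Chen) model.** Each component carries its own
population set; the inter-component pseudopotential force
F_σ = −G ψ_σ Σᵢ wᵢ ψ_σ̄(x+cᵢ) cᵢ with ψ = ρ (linear, inter-component
coupling only) enters through the original velocity-shift forcing: both
components relax toward equilibria at the common velocity
u' = (Σ j_σ/τ_σ)/(Σ ρ_σ/τ_σ) plus τ_σ F_σ/ρ_σ; reported velocities carry
the half-force correction. "Pure" regions keep a minority floor (2% of the
reference density) — hard 0/1 initialization is not stable in this model —
and composition steps are initialized with a one-cell tanh ramp for the
same reason. Walls are neutral-wetting: the force stencil reads boundary
cells filled with the weighted average of their fluid neighbours.
Pressure outlets invert the full mixture equation of state
p = cs²(ρ + G ρ_a ρ_b α-wise) for the ghost density, so mixed and pure
cells on the same outlet face see the same *total* pressure (imposing the
ideal-gas density alone drives a spurious jet at the interface row).

**Mutual diffusivity and the choice of τ for the mixing case.** Linear
response about the symmetric mixture (verified numerically by the decay of
a sinusoidal concentration perturbation, which the package can measure)
gives

    D(α) = cs²[(τ − ½) − 2 τ G ρ_tot α(1−α)],

so the coupling *suppresses* interdiffusion, most strongly at α = ½, and
demixes the pair below τ_c = 1/(2 − Gρ_tot). Two consequences shape the
mixing use case. First, the physical pair (D = 90 μm²/s at the shipped
scales, i.e. D_lat ≈ 4.5·10⁻⁴, Schmidt number ≈ 10³) cannot be reached by
a stable subcritical pair: it needs τ − ½ ≈ 10⁻³, far below the stability
floor for sharp composition fronts. Second, in the *weakly supercritical*
regime the coupling itself throttles transport across the interface while
the dilute wings stay diffusive — qualitatively the regime the published
runs operated in (their G = 0.8 was hand-tuned, and their 2D concentration
profile differs visibly from the exact solution while its mixing index is
close). The shipped mixing configuration therefore runs both components at
τ = 0.65 with G = 0.8 (quench ratio Gρ/[2(τ−½)/τ] ≈ 1.7): the smallest
relaxation time at which a square composition wave remains free of over-
and undershoot in a periodic stress test. The resulting interface is
sharp with slowly eroding shoulders; the measured effective diffusivity is
reported alongside the mixing index rather than asserted.

**Droplet case.** Both components at τ = 0.7 with G = 1.1 (quench ratio
≈ 1.9) give near-pure bulk phases (α ≈ 0.99/0.01) and a ~4-cell interface;
at τ = 1 the same G is a weak quench whose plateaus sit at 0.77/0.23 and a
200-μm slug slowly dissolves. dt maps the carrier viscosity
(ν = 1.004·10⁻⁶ m²/s) to ν_lat = cs²·0.2. The carrier flow is first
converged single-phase and used as the droplet run's initial velocity
field (a stagnant start launches pressure waves that destroy the slug).
The slug is initialized 10 cells downstream of the inlet with a one-cell
carrier film at each wall. Surface tension is *measured*, not assumed:
static droplets of radius 15–30 cells give the pressure jump vs curvature
line whose slope is the numerical surface tension (R² > 0.99); at the
shipped scales it maps to ≈ 2·10⁻³ N/m versus the physical 5·10⁻³ N/m, so
a warning notes the mismatch (G is kept at the published value; the
capillary number stays ≪ 1 either way, which is the regime that matters
for integrity).

**Convergence control.** Steady runs monitor the windowed mean kinetic
energy (window 1000 steps, relative change < 10⁻⁵); the mixing run
monitors the concentration field's second moment the same way. Transient
droplet runs instead stop when the trailing edge passes the branch
midpoint.

## Comparison metrics

**Absolute mixing index.** For concentration samples αᵢ across the width
with mean ⟨α⟩, the package default is

    AMI = sqrt( (1/N) Σ (αᵢ − ⟨α⟩)² / ⟨α⟩ ),

which is 0 for a uniform profile and 1/√2 for a perfect half/half step.
The published rendering of this formula is typographically ambiguous; of
the candidate readings (mean absolute deviation over mean, relative
standard deviation, and the form above), only the form above reproduces
the published straight-channel 1D value (0.654) under the physical series
convention, so it is the calibrated default; `method="mad"` and
`method="rms"` select the other two. Sampling is at cell centers across
the width at the measurement line (N = width cells).

**Droplet tracking.** The droplet phase is α ≥ 0.5; connected components
by face adjacency; the trailing edge is the minimum arc-length coordinate
of the phase along the center path (inlet axis → junction center → branch
axis; cells of the opposite branch are excluded).

## Shipped study conditions

| case | domain (grid) | key parameters |
|---|---|---|
| flow | 500×100 μm, dx = 1 μm (tests/examples run dx = 2.5–10 μm) | blood CY fit, u_in = 10 mm/s, line m at 400 μm |
| mix | 600×40 μm, dx = 1 μm (600×40 cells) | D = 90 μm²/s, u_in = 10 mm/s, G = 0.8, τ = 0.65, line m at 500 μm |
| droplet | l = 500, k = 250, w = 100 μm, dx = 5 μm | water-like pair, γ = 5 mN/m, G = 1.1, τ = 0.7, dl = 200 μm, α = 1.28, Δp_out = 2.5 Pa |

Two droplet parameters deviate deliberately from the printed setup, whose
numbers are internally inconsistent (both outlets carry the same label;
the stated density of 1 kg/m³ and viscosity "1.004 μm²/s" do not recover
the stated branch flows). The fluids are taken as water-like
(ρ = 1000 kg/m³, ν = 1.004·10⁻⁶ m²/s), and the outlet
differential is 2.5 Pa — the largest round value below the 2D
flow-reversal threshold (≈3 Pa for the plate network). Above that
threshold the high-pressure outlet back-feeds the junction and the
stretched slug capillary-pins in the branch; near an even split the slug
physically splits at the T (classical low-capillary-number slug
splitting). 2.5 Pa gives a ~92/8 outward split that routes the droplet
into the low-pressure branch intact, which is the behavior the study
describes. The printed branch flows are treated as a directional check
only (favored branch carries more flow; branch flows sum to the inlet
flow).

The 3D solver is exercised on reduced grids (e.g. 50×10×10 for the
four-wall confinement check); full-resolution 3D runs (500×100×100) are
supported by the same code path but are multi-hour jobs and not part of
the test surface.

## What the tests do and do not show

The lattice solvers are validated against closed forms (plane Poiseuille
to second order in the grid, Laplace's law, moment identities, exact mass
conservation) and against the 1D models where those are exact (blood
profile within ~1% away from walls). The mixing comparison shows
method-level agreement of the *index*, not of the profile: the Shan–Chen
pair at the published G is a supercritical surrogate for a miscible pair
and its concentration profile is qualitatively different from the exact
solution (sharp interface instead of an erf ramp) — the same caveat the
original study raises for this method. The 2D droplet slug advects at
about the mean carrier speed, ~25% slower than the 1D model's empirical
slip factor of 1.28 predicts (that factor reflects three-dimensional
droplets riding the channel core); the corresponding acceptance assertion
is expected to fail and documents the genuine 1D/2D discrepancy. Nothing
here validates against laboratory data; all references are the published
simulation study's printed values and standard closed forms.
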
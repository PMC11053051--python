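# Methods

`dcbsim` simulates the transfer of sirolimus from an inflated drug-coated
balloon (DCB) into a two-dimensional cross-section of a diseased arterial
wall, and the subsequent redistribution, binding and clearance of the
drug. This note records the model, its discretisation, the parameter
values and units, the choices made where the problem is genuinely open,
and the limits of what the synthetic test geometries can show.

## Computational domain

The wall cross-section is a pixel grid in which every pixel carries one
label: lumen, healthy tissue (HT), fibrous (FI), fibrofatty (FF),
necrotic core (NC), dense calcium (DC), or perivascular exterior. Each
pixel is a square control volume of side `pixel_size` (default
8.48 × 10⁻³ mm, the side length of the source imaging grid, so one pixel
covers 7.19 × 10⁻⁷ cm²). The tissue pixels form the transport domain
Ω_T; its inner boundary Γ^I is the lumen–tissue interface, its outer
boundary Γ^A the adventitial rim.

Grids come from two sources:

* **Segmentation** of an RGB cross-section image in the VH-IVUS display
  convention. Pixels are clustered in RGB space (k-means, k-means++
  initialisation, 10 restarts, seeded) and each cluster takes the label
  of the nearest reference palette color (gray HT, dark green FI, light
  green FF, red NC, white DC). Exact palette RGB values are a documented
  package choice (`dcbsim.DEFAULT_PALETTE`), since the convention fixes
  color names, not coordinates. Lumen and perivascular background are
  both dark; they are separated spatially: non-tissue regions connected
  to the image border become exterior, the enclosed cavity becomes the
  lumen. Segmenting a noiseless rendering of a label grid returns the
  grid exactly.
* **Phantom generators.** A circular single-label annulus; a *scattered*
  phantom that assigns labels to tissue pixels by a seeded shuffle with
  exact (largest-remainder) target counts; and a *clustered* phantom
  whose DC∪NC pixels form a band whose inner edge sits a prescribed
  number of pixel layers (4-connected graph distance) from Γ^I — offset
  0 covers the interface completely. Identical specs (including seed)
  produce bitwise-identical grids.

Boundary curves are traced with sub-pixel marching squares
(`skimage.measure.find_contours`), ordered counter-clockwise; normals
come from central differences of a lightly smoothed copy of the polyline
(the raw half-pixel staircase would alias into the normals) and point
out of the tissue. A point is classified against a curve by the sign of
p·n at the nearest vertex (p·n ≤ 0 is the tissue side). RMSND — the
root-mean-square distance of DC and NC pixel centers to the nearest
inner-curve vertex — summarises how close the hard plaque components sit
to the lumen.

## Interstitial flow

Plasma filters through the wall, treated as a rigid porous medium. The
velocity **w** and pressure P obey the Brinkman equations with
continuity,

    ρ_t (∂w/∂t + (w·∇)w) = −∇P + μ_t ∇²w − (μ_t/K) w,   ∇·w = 0,

with a prescribed filtration speed V along the inward normal on Γ^I and
zero normal velocity gradient on Γ^A. With the baseline permeability the
Darcy drag dominates viscosity by ~nine orders, so the solution is
Darcy-like; the Brinkman form is retained as written.

Discretisation is a marker-and-cell (MAC) staggered grid: u on vertical
faces, v on horizontal faces, P at cell centers, each pixel one control
volume. Interface conditions are imposed by direct forcing at the
boundary faces: each lumen-interface face receives the component of
V·n̂ matching its orientation, where the unit interface normal n̂ is
estimated from the gradient of a Gaussian-smoothed lumen indicator. The
smoothing length is fixed in *physical* units (0.16 mm, floor of two
pixels) so that the normal field — and with it the discrete interface
flux, which equals V·(interface length) up to staircase quadrature —
converges under grid refinement. Adventitial faces copy their interior
neighbour (discrete zero normal gradient).

The steady state is found by a pseudo-transient march. The Darcy drag
term is integrated pointwise-implicitly — its relaxation time
ρ_t K/μ_t ≈ 3 × 10⁻¹³ s makes a fully explicit treatment unusable —
while pressure, viscous and convective terms (hybrid central /
second-order-upwind differencing, switching at cell Péclet 2) are
explicit with the viscous pseudo-step bound ρ_t h²/(4 μ_t). Each
pseudo-step ends in a pressure–velocity projection: the pressure-
correction Poisson system is solved by red–black SOR with
over-relaxation factor ω = 1.2 (warm-started, by default, from a sparse
direct factorisation computed once per geometry), followed by SOLA
cell-wise corrections until the maximum absolute cell divergence is at
most 10⁻¹². Adventitial faces enter the projection as free outflow
degrees of freedom (ghost pressure 0), which makes the system
non-singular and lets the outflow balance the forced inflow exactly;
global mass balance closes to better than 10⁻⁸ relative. The march
stops when the relative maximum velocity change per pseudo-step falls
below 10⁻¹⁰; the converged field carries its divergence certificate
(`FlowField.div_max`). The pressure level is pinned to zero mean over
tissue cells.

## Drug transport and binding

Free sirolimus (volume-averaged concentration c_t, mol/mm³) obeys

    ∂c_t/∂t + (w·∇)c_t = D^l ∇²c_t − ∂b_R/∂t − ∂b_E/∂t,

with label-dependent diffusivity D^l, and the receptor-bound (b_R) and
extracellular-matrix-bound (b_E) phases follow saturable reversible
kinetics

    ∂b/∂t = k_a (B_m − b) c_t − k_d b        (one equation per phase).

All concentrations start at zero. The adventitial boundary is a perfect
sink (c_t = 0) at all times.

**Spatial scheme.** Conservative finite volumes on the pixel grid. Face
diffusivities are harmonic means of the two adjacent cells (flux
continuity across tissue-type junctions). Advection uses first-order
upwind with a minmod-limited second-order correction; slopes touching
non-tissue cells fall back to first order. In one dimension the scheme
is TVD at the time steps used; the unsplit two-dimensional corner
coupling admits only a small bounded overshoot (≲2% in stress tests).
Boundary conditions enter as face fluxes: a Dirichlet face value c_f
contributes 2 D (c_f − c)/h through the half-cell, a no-flux face
contributes nothing diffusively.

**Time stepping.** Forward Euler with an adaptive step: the minimum of
the convective bound h/|u|_max, the diffusive bound min_cells h²/(4 D^l)
(safety 0.8), and a positivity bound 0.9 / max_cells Σ(outgoing flux
coefficients) that accounts for boundary-coupled cells. The viscous
bound ρ_t h²/(4 μ_t) belongs to the momentum march; flow is solved to
steady state once and frozen for transport (the filtration speed is
time-independent), so it does not constrain the transport step.

**Binding integration.** Each binding ODE is linear in b for frozen c_t
and is advanced by its exact exponential solution over the step; this
preserves 0 ≤ b ≤ B_m unconditionally and is exact whenever c_t is
constant. The moles gained by b_R + b_E are debited from c_t; if a step
would overdraw the free drug (possible at low c_t with empty sites),
the step is recursively halved rather than clipped. With the sirolimus
constants the binding rates (k_Ra c_t ~ 10³ s⁻¹ near the interface) are
far stiffer than transport; the exponential update integrates them
stably at the transport step, tracking the quasi-equilibrium they relax
to.

**Balloon release.** The coating releases the areal mass
M_b(t) = a₁(1 − e^{−k₁ t}) during inflation (t ≤ t₀ = 30 s). The
default coupling is a per-face *contact-film reservoir*: each interface
face holds an areal reservoir m(t) fed by the release kinetic (exact
per-step increments, so the discrete budget closes identically) and
drained into its tissue cell through a Dirichlet film concentration
c_I = m/ℓ_c, by diffusion and by the filtration inflow. The film
thickness ℓ_c = 5 µm is the one parameter of the coupling, set to a
typical DCB coating film. The reservoir ODE is integrated exactly per
step with the cell concentration frozen. Uptake is therefore limited by
the local tissue diffusivity: fibrous/fibrofatty interfaces drain the
film almost completely within the inflation, a calcified interface
leaves most of the dose stranded — which is what makes the soft ≥
healthy ≥ hard uptake ordering possible at all. (A uniform
prescribed-flux coupling, `coupling="flux"`, is also available; it
forces identical delivered mass into every geometry and therefore
cannot differentiate compositions.) Film drug remaining at deflation is
discarded from the system and tracked in the budget.

**Post-deflation interface.** Two extremes and their blend on Γ^I:
*sink* (c_t = 0 at the interface; the streaming blood syphons off mural
drug), *no-flux* (zero diffusive flux through a mirrored ghost value,
with the advective term still active, so the filtration stream
re-entrains near-wall drug — this is what lets convection amplify the
retained dose), and *hybrid(θ)*, the linear blend with θ = 0 ≡ no-flux,
θ = 1 ≡ sink. With convection disabled the advective term is removed
from the transport equation only.

**Stopping.** A run ends at t_end or when the transport residual — the
maximum |Δc_t|/Δt per step, normalised by its value at the first
post-deflation step — has fallen by 10⁻⁶.

**Budget.** At every output time, released mass equals tissue content
(free + bound) + film reservoir + discarded film + cumulative boundary
outflow, to round-off (~10⁻¹⁵ relative); the suite enforces 10⁻⁶.

## Summary metrics

Tissue content C^tissue = D_MW/(ρ_t A) ∬(c_t + b_R + b_E) dA (g drug
per g tissue), fractional effects FE^R = ⟨b_R/B_Rm⟩ and
FE^E = ⟨b_E/B_Em⟩ (area-averaged site occupancies), and the per-area
mean concentrations. Integrals are midpoint sums over pixel centers;
cut cells count as full pixels, consistent with the label-grid area
definition. Percent declines are measured against the value at
deflation (the concentration peak) with linear interpolation between
samples; the reference instant is a parameter.

## Parameters (baseline sirolimus set)

| quantity | symbol | value | unit |
|---|---|---|---|
| tissue density | ρ_t | 0.983 (9.83 × 10⁻⁴ internally) | g/ml (g/mm³) |
| plasma viscosity | μ_t | 5 × 10⁻³ | g/(mm s) |
| Darcy permeability | K | 1.43 × 10⁻¹² | mm² |
| filtration speed | V | 5.8 × 10⁻⁵ | mm/s |
| diffusivity FI, FF | D¹,D² | 1.0 × 10⁻⁴ | mm²/s |
| diffusivity NC, DC | D³,D⁴ | 8.42 × 10⁻⁷ | mm²/s |
| diffusivity HT | D⁵ | 8.42 × 10⁻⁵ | mm²/s |
| receptor capacity | B_Rm | 3.3 × 10⁻¹² | mol/mm³ |
| ECM capacity | B_Em | 3.6 × 10⁻¹⁰ | mol/mm³ |
| receptor on/off | k_Ra, k_Rd | 8 × 10¹¹, 1.6 × 10⁻⁴ | (mol mm⁻³ s)⁻¹, s⁻¹ |
| ECM on/off | k_Ea, k_Ed | 2 × 10⁹, 5.2 × 10⁻³ | (mol mm⁻³ s)⁻¹, s⁻¹ |
| release rate / capacity | k₁, a₁ | 0.1135, 1.4618 | s⁻¹, µg/mm² |
| inflation time | t₀ | 30 | s |
| molecular weight | D_MW | 914.2 | g/mol |
| contact-film thickness | ℓ_c | 5 × 10⁻³ | mm |

Everything runs in the internal mm–s–g–mol system; the density is
converted from g/ml at load time. FI/FF and NC/DC share diffusivities
for lack of separate data. The permeability is uniform across labels.

## Shipped study conditions

* **Circular validation vessel**: lumen radius 1.5 mm, wall thickness
  0.3 mm, healthy tissue only. The dimensions are this package's
  documented choice of a typical healthy human coronary lumen and
  intima+media thickness (the prior circular model this configuration
  mirrors does not print its dimensions). Interface: no-flux with
  convection on — a sink interface empties the thin post-inflation
  boundary layer almost immediately and cannot produce the reported
  accelerating decline shape. On this geometry at pixel size 0.02 mm
  the averaged free drug falls ≈37% five minutes after deflation and
  ≈92% at twenty minutes, and both binding-site populations saturate
  within minutes.
* **Composition phantoms** (annulus, lumen radius 1.5 mm, wall 0.5 mm):
  reference (HT 27.4 / FI 31.9 / FF 9.2 / NC 22.4 / DC 9.1%), hard
  (HT 27.4 / NC+DC 72.6%), soft (HT 27.4 / FI+FF 72.6%), healthy
  (HT 100%), scattered with a fixed seed.
* **Clustered phantoms**: HT 37 / FI+FF 44.8 / NC+DC 18.2%, band
  offsets 0, 1, 2 and 4 pixels from the interface.
* **Sensitivity ranges**: V ∈ {2.8 × 10⁻⁵, 5.8 × 10⁻⁵, 1.1 × 10⁻⁴} mm/s
  and K ∈ {1.43 × 10⁻¹³…10⁻¹¹} mm², evaluated at 4 h.

Default problem sizes (pixel 0.02 mm for the validation vessel,
0.04–0.05 mm for the phantom comparisons) were chosen so that every
shipped scenario completes in seconds to a couple of minutes on one
core while keeping the wall ≥ 10 pixels thick; halving the pixel size
changes the validation declines by well under a percentage point.

## What the synthetic geometries do and do not show

The phantoms emulate the *area fractions* and *radial placement* of
plaque components on an idealised annulus. They do not reproduce a real
lesion's asymmetric lumen, its connected anatomical plaque bodies (the
scattered mode mixes single pixels), speckle or palette noise in real
VH-IVUS frames, or 3-D axial transport. Passing the suite therefore
demonstrates correct physics and numerics under controlled geometry,
not patient-level predictions; patient-specific numbers (e.g. receptor
occupancy in an actual cross-section) require the corresponding image.

## Numerical and design notes

* The divergence certificate (10⁻¹²) is absolute, in 1/s, as is the
  SOLA stopping rule; SOR failure to reach it raises, never silently.
* Ties in the cluster→palette mapping break toward the lowest label
  code with a logged warning.
* `stable_dt` exposes `include_viscous=True` restoring the three-way
  minimum (viscous/convective/diffusive) for coupled marching; the
  transport driver uses the convective/diffusive pair plus the
  positivity bound, since flow is frozen at its steady state.
* The interface length used to convert areal release into total mass is
  the staircase face-length measure of Γ^I; the budget uses the same
  measure, so closure is exact by construction.
* Degenerate inputs fail loudly: walls thinner than three pixels,
  multiple lumen components, unattainable phantom fractions, hybrid
  interface without θ, zero-diffusivity/zero-velocity step bounds.
* Runs are bit-reproducible for identical inputs; phantom generation is
  deterministic in its seed.

## Known limitations

Rigid wall (no poroelasticity or balloon-induced deformation); no
luminal hemodynamics beyond the sink/no-flux/hybrid abstraction; no
coating micro-mechanics (the film model lumps adhesion, dissolution and
transfer into ℓ_c and the release kinetic); uniform permeability across
plaque types; first-order time accuracy; 2-D cross-section only.
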
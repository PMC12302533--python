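# Methods

## Scope and model structure

`nanoyap` models a single adherent cell on a nanopillar substrate as four
well-mixed compartments — plasma membrane (PM), cytosol, nuclear envelope
(NE) and nucleoplasm — coupled through surface reactions on analytic
geometry patches. A surface reaction on a patch of area `A` contributes to a
volume species at rate `(A/V_compartment) ×` (per-area rate law), which is
what makes the signaling state sensitive to substrate geometry: nanopillars
change both the amount of substrate-contact membrane and its curvature
distribution. Spatial PDE transport (lateral diffusion between patches, and
the confinement effect in the thin gap between NE and apical PM) is
deliberately out of scope; the model's steady states are the well-mixed
limit of the corresponding reaction-transport system, and the closed-form
nucleocytoplasmic ratio expressions in `transport.py` are exact steady
states of the dynamical system (verified to 1% in the test suite).

## Substrate and PM geometry

The substrate is a square lattice of pillars (radius `r_np`, height `h_np`,
pitch `p_np`, top-edge rounding `r_tip`) with one pillar on the axis of a
circular contact region. The PM conforms at a 50-nm offset and meets the
floor through a 200-nm fillet. All patch areas and mean curvatures are
closed forms (cylinder, sphere/torus zones, plane), with the sign convention
that curvature is positive when the membrane bends toward the cytosol; the
base fillet is a valley and carries negative tube curvature, which the
integrin-endocytosis law treats by its `H < 0` branch (no depletion). A
numeric second-fundamental-form oracle on the parametric surfaces of
revolution cross-checks every closed form in the tests.

Per-substrate contact radii default to 15 µm (flat), 13 µm (pitch 5.0) and
11 µm (pitch 2.5): cells spread less on denser arrays, and this measured
geometric input is part of what orders the steady-state YAP/TAZ N/C across
substrates. The free (non-contact) membrane closes the cell surface as a
squat cylinder of volume `V_cyto + V_nuc` over the contact disk and is flat
for reaction purposes.

## Nucleus and indentation

The reference nucleus is an oblate spheroid with aspect ratio 2.21:1 and
volume 550 µm³ (U2OS scale; cytosol 2300 µm³). When a vertical envelope is
imposed, the vertical semi-axis shrinks to fit and the equatorial semi-axis
grows to conserve volume.

Indentation displaces lower-NE material points purely vertically. The
deformed lower NE is a height field: the smooth-max (log-sum-exp, rounding
scale `β = transition_width/2`) of the reference spheroid surface against
each pillar's obstacle profile — the pillar offset surface (offset =
NE-pillar standoff, default 0.2 µm) continued outward by a steep conical
skirt of lateral width `transition_width` (default: the pillar tip radius).
The construction conforms wherever a pillar would penetrate the reference,
is C¹-smooth, and never intersects a pillar. Volume is conserved by
rescaling the equatorial semi-axis with bisection (relative tolerance 1e-6,
measured with the same grid quadrature on both sides, so the reported
conservation is quadrature-consistent). The default grid step is 20 nm; the
sweeps use 50-80 nm, where the aggregate NE quantities (areas, mean stretch)
are converged at the few-percent level.

The area-stretch ratio is the kinematic identity for vertical displacement,
`α = sqrt(1+|∇z|²)/sqrt(1+|∇z₀|²)`, interpreted as lamina (not lipid)
stretch and therefore uncapped. Patches are labeled `deformed` where
`|α − 1| > 1e-3`. Two behaviors worth noting: (i) over a flat pillar top the
NE translates rigidly and stays unstretched, with the highest stretch on the
steep flanks beside the pillars; (ii) where the NE flattens over *outboard*
pillar tops against the sloped spheroid flank, slopes can decrease and
`α < 1` — genuine surface compression, which the stretch-gated import law
handles by design (`α < 1` reduces import). A blanket `α ≥ 1` holds only
over the near-flat central region.

### NE curvature readouts

`ne_mean_curvature` returns the standard graph-surface mean curvature
`H = (κ₁+κ₂)/2`, positive toward the nucleoplasm (hemispherical bump of
radius R → `1/R` at the apex). The *indented-region summary* used to
compare with confocal reslice measurements
(`IndentedNucleus.central_indent_mean_curvature`) averages the **total
bending curvature** `κ₁+κ₂` over the membrane in contact with the central
pillar (conforming cap plus rim collar; the transition annulus and skirt are
excluded). Rationale: reslice quantification reads a single tangent-circle
curvature `1/R` at the pit apex, where the surface is locally spherical and
`κ₁ ≈ κ₂ ≈ 1/R`; the matching 3-D surface functional on the strongly
anisotropic collar (tube curvature ≫ azimuthal curvature) is the curvature
sum, the quantity membrane-bending mechanics is written in. Averaged over
any vertical-displacement construction, the plain H-mean over the whole
deformed region is instead dominated by the large-area, low-curvature skirt
and lands near 1 µm⁻¹ regardless of profile shape, which cannot reproduce
measured indentation curvatures of 2.5-4.5 µm⁻¹. With defaults, the
tall-pillar geometry (r 0.5 µm, h 3 µm, pitch 3.5 µm, tip 0.2 µm, depth
2.8 µm, standoff 0.2 µm) gives 3.3 µm⁻¹.

## Signaling network

The activation chain and its parameter table (`data/params_v1.yaml`) follow
the established well-mixed YAP/TAZ mechanotransduction ODE models:
stiffness- and integrin-gated FAK phosphorylation; highly cooperative
(fifth-power) FAK-dependent RhoA activation; RhoA-driven ROCK and mDia
activation at the PM (scaled by total PM area over cytosolic volume, so
cells with less membrane activate less); ROCK-dependent myosin and LIMK
activation; LIMK-catalyzed cofilin phosphorylation (Michaelis-Menten);
actin turnover with mDia- and N-WASP-assisted polymerization and
cofilin-assisted depolymerization; stiffness-driven lamin A
dephosphorylation (half-saturation 5 kPa of cytosolic stiffness
`E_cyto = 0.22·[F]^2.6` kPa); NPC opening cooperative in lamin A and stress
fibers; and stress-fiber-driven YAP/TAZ dephosphorylation against constant
rephosphorylation. Every activation pair conserves its total, so actin,
lamin, NPC and YAP/TAZ pools are conserved exactly by construction; the
volume-weighted YAP/TAZ budget across cytosol and nucleoplasm is also
checked numerically (< 0.1% drift over 10,000 s).

Units: volume species in µM, surface species in µm⁻². The FAK and
ROCK/mDia surface activations use a membrane-proximal reaction depth
`ell_pm = 3 µm` to convert the catalog's s⁻¹ rates into per-area
velocities; it is a fixed property of the parameter table, chosen so the
flat-reference geometry reproduces the catalog kinetics, not a per-geometry
fit. The table is validated against a required-key manifest at load time; a
missing key raises an error naming it.

The initial condition is a resting state (minimal cytoskeletal activation,
N/C ≈ 0.74 < 1). Integration uses BDF with `rtol 1e-8 / atol 1e-10`,
initial step 0.01 s, to t = 10,000 s (the conventional steady-state time),
stopping early when every relative rate falls below 1e-8 s⁻¹. The dynamics
are deterministic; no seeds are involved.

## Nuclear transport and rupture

NPC import is stretch-gated per NE patch; export removes total nuclear
YAP/TAZ. The rupture pore is aggregated to one NE patch of area
`π σ_NER²` with permeability evaluated at the pore center (the Gaussian
tail beyond the patch is dropped), opening with time constant `t₀ = 1 s`;
pore repair is not modeled. The free cytosolic fraction `φ_free` is the
dephosphorylated share of cytosolic YAP/TAZ from the converged signaling
state, not a free parameter (an override to 1 exists for limit checks).
One subtlety: "rupture raises N/C iff the retention ratio υ exceeds the
no-rupture N/C" is exact when the cytosolic pool is fully free; with
`φ_free < 1` the exact threshold is `N/C / φ_free`. Both statements are
tested in their exact form.

## Synthetic imaging

The generator voxelizes the cell and the (possibly indented) nucleus at
confocal-like resolution (0.175 µm z-steps) and assigns channel intensities
so nuclear/cytosolic ratios are exact before optional Gaussian blur
(σx = σy = 0.2 µm, σz = 0.4 µm — a deliberately simple stand-in for a
microscope PSF) and seeded Gaussian read noise. It emulates intensity
ratios, indentation geometry and channel bleed from blur; it does *not*
emulate photon statistics, background gradients, depth-dependent
aberrations or segmentation-confounding clutter, so round-trip tests
validate the quantification pipeline, not robustness to real micrograph
artifacts. Quantification uses an Otsu threshold on the nuclear-marker
channel (pluggable; the study's exact DAPI threshold rule is unspecified),
the generator's cell border as the cell mask (no cell segmentation is
claimed), a strict `> 0.16` Ku-80 cytosolic/nuclear cutoff for rupture
calls, and an ellipse fit (algebraic seed + Sampson-distance geometric
refinement, replacing manual ellipse placement) whose top tangent circle
`R = a²/b` yields indentation curvature `b/a²` and depth `b`. The
field-projection operator evaluates the Gaussian-kernel integral by
midpoint quadrature on the supplied sample points; with sampling at or
below half the kernel width it is exact to ~0.1% (point-mass and
constant-field tests).

## Known limitations

- The prior-network rate constants are a reconstruction in the published
  models' structure, not a transcription of a specific table; absolute
  steady-state values (e.g. N/C = 2.32 on flat) are indicative, while the
  orderings and closed-form consistencies are the tested claims.
- The height-field representation cannot express overhangs; near-vertical
  NE sleeves appear as steep slopes, so extreme local α values depend on
  the skirt width (exposed as `transition_width`).
- No mechanics: membrane and nuclear shapes are prescribed, not solved from
  force balance; lamina elasticity enters only kinematically through α.
- Cytosolic confinement between NE and apical PM (which amplifies local
  activation in full spatial simulations) is not represented.
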
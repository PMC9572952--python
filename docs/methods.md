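# Methods

`mcaspine` models the L4–L5 spinal motion segment as an ensemble of equal-size
bonded discrete elements ("movable cellular automata") whose pair interactions
reproduce an isotropic linear-elastic continuum, coupled to an interstitial
fluid through Biot effective stress and Darcy filtration on the element-centre
network. This note records the model, the numerical design decisions, and what
the verification suite does and does not establish.

## Solid kernel

Elements of size `d` sit on an fcc (default) or simple-cubic lattice and are
bonded to their initial contacts (no bond breaking, no new contacts: the
compression regime studied here never separates or collides bodies). Each
bonded pair carries

* a normal force, updated incrementally from the pair strain increments;
* a tangential force vector, from the relative tangential displacement at the
  contact (including rotation), kept in the plane normal to the bond;
* a rotational-resistance torque `K_ij = G_pair S q Δθ_rel` against relative
  rotation (dimensionally consistent bonded-DEM practice; only weakly
  exercised under axial compression).

The incremental normal law per unit interaction area is

    dF_n / S = 2 G_i dξ_ij + D_i dσ̄_i + A_i dσ̄_j,      D = 1 − 2G/K,  A = 4G/(3K),

where `σ̄` is the element's mean *effective* (skeleton) stress obtained by
moment homogenization of the bond forces, `σ̄_αβ = (1/V) Σ q sym(n_α F_β)`.
The split between the element's own coefficient `D` and the neighbour
coefficient `A` (the "volume-dependent" many-body term, folded into the bond
so Newton's third law holds exactly per pair) is fixed by requiring the affine
lattice response to reproduce the macroscopic moduli: on fcc and sc lattices
the homogenized response equals isotropic Hooke elasticity exactly when
`D + A = 1 − 2G/(3K)`. With `A = D` or similar readings the emergent bulk
modulus is wrong by a large factor; the modulus-recovery tests gate this
calibration.

For dissimilar materials the strain increment splits by a 2×2 solve that
equalizes the two sides' force (`2G_i dξ_i + h_i = 2G_j dξ_j + h_j`,
`dξ_i + dξ_j = 2 dr/d`), so the softer element takes proportionally more
strain and the reaction forces are equal and opposite by construction.

Two numerical restrictions were found to be load-bearing:

1. **Volumetric cross-terms act within material regions only.** The `D/A`
   terms form a lagged fixed-point iteration on the mean stress whose loop
   gain exceeds unity across bonds joining materials of very different
   stiffness (cortical bone vs cartilage: contrast ~10³). The iteration then
   diverges for *any* time step (a real eigenvalue > 1 is immune to
   under-relaxation). Across region boundaries the bond therefore uses the
   pure pair stiffness; the error is confined to one-element-thick interface
   layers and does not affect the homogeneous-region moduli.
2. **The homogenized mean stress that feeds `D/A` excludes the pore force.**
   Hooke's law acts on the effective stress; feeding the total (pore-loaded)
   stress back into the volumetric terms couples the enormous pore stiffness
   into a lagged loop and diverges.

Time integration is explicit velocity Verlet. The step is the acoustic limit
`d/c_p` times a safety factor (default 0.2) times a per-material margin
`(2G/3K)^(1/2)` (dry) or `(2G/3K)^(3/4) × 0.5` (saturated), calibrated on
homogeneous and bimaterial lattices; high-Poisson tissues (endplate cartilage,
ν = 0.46) have the highest volumetric loop gain and demand the smallest steps.
Quasi-static loading uses non-viscous local damping (a fraction α, default
0.1–0.3, of the out-of-balance force opposing the velocity, never applied to
boundary particles whose force sum is the measured reaction), and optionally
*quasi-static mass scaling*: the inertia of the materials with the smallest
stable step is inflated until all materials share the most permissive one
(~15× for bone at segment scale, ~3.8× faster wall-clock). Mass scaling leaves
equilibrium response unchanged but makes transients non-physical; it is off in
every wave-speed and free-vibration test and on in the segment experiments.

## Fluid model

Each element carries a pore fluid with linear equation of state
`ρ(P) = ρ0 (1 + (P − P0)/K_fl)` (salt water: ρ0 = 1000 kg/m³,
K_fl = 2.4 GPa, η = 1 mPa·s, P0 = 0 gauge). The conserved state is the fluid
mass; it changes only by pairwise antisymmetric Darcy transfer

    dm_ij = K_fl (k_harm/η) (S/r_ij) (ρ_j − ρ_i) dt,

with harmonic-mean interface permeability, an explicit-diffusion subcycling
limit, and no transfer out of an element at or below the equilibrium density
(`ρ ≤ ρ0`). Porosity follows solid-volume conservation
`φ = 1 − (1 − φ0)/(1 + ε_vol)` and permeability the channel law
`k = φ d_ch²` with `d_ch = sqrt(k0/φ0)`.

The element's volumetric strain is *geometric*: three times the mean of its
accumulated bond strains, with the pair strain split by shear moduli alone.
(Using the constitutive strain partition instead feeds mean-stress noise into
the pore pressure with gain `K_fl/(2K φ0)` ≈ 10³ for nucleus tissue — an
instructive way to destroy a simulation.) Pore-volume change recompresses the
resident fluid exactly (`ρ ∝ 1/(φ0 + ε_vol)`), and the pore pressure pushes
back on the skeleton through a bond-level force derived from the fluid
compression energy,

    dF_pore = −(a_i dP_i c_i + a_j dP_j c_j),   c_side = 6 V w_side /(nb_side d),

with `w` the same shear-modulus shares that feed the strain split and `nb` the
element's bond count. In a full-coordination bulk this reduces to
`−S·mean(a dP)` and homogenizes to exactly the Biot reduction `−a dP` on the
diagonal of the total stress; the energy-consistent weights matter at free
surfaces and interfaces, where a non-symmetric force law pumps energy. The
pore force is evaluated *within* the step (elastic pass → fluid update from
current strains → pore pass): the pore stiffness `K_fl/φ` dwarfs the
soft-tissue moduli, so a one-step lag is explosively unstable.

Fluid boundary conditions default to no-flux everywhere (loading lasts
milliseconds; exterior drainage is negligible at tissue permeabilities of
10⁻¹⁶–10⁻¹⁹ m²); per-element "drained" pinning (`ρ = ρ0`) supports the
consolidation benchmark.

### Effective poroelastic behaviour

Under constant total stress the model realizes a pressure diffusion with
consolidation coefficient `c_v = k/(η S_storage)`. The storage combines fluid
compressibility with the skeleton's effective-stress compliance and depends on
coordination because the energy-consistent pore force scales with `1/nb`: for
the 1×1×n verification column `S = φ0/K_fl + 9a/(2G)`, for a bulk
`S = φ0/K_fl + a/K`. The Terzaghi benchmark (drained-top column with uniform
initial excess pressure, compared to the classical series solution using the
model's own c_v) agrees to RMS ≈ 1% at Fourier times 0.1–1.0.

## Geometry

The parametric segment stacks two waisted elliptic-cylinder vertebral bodies
(cortical shell around a cancellous core) and a three-part disc: cartilaginous
endplates above and below a core of nucleus pulposus (an ellipse holding 40%
of the disc area, its centroid 2 mm posterior of the disc centroid) inside the
annulus fibrosus ring. Degeneration reduces the total disc height from 10 mm
(healthy) to 8 mm (first degree) and 5 mm (second degree) with endplate
thickness held constant, and/or replaces the AF/NP poroelastic parameters with
the stage values (stiffer, less porous, less permeable). Coordinates: X
lateral, Y anterior(+)/posterior(−), Z axial; "dorsal" ≡ −Y.

Region tagging is by membership of the lattice-site centre; a feature thinner
than about half a lattice plane captures no sites and raises a resolution
error. Defaults used in the reduced-resolution (d = 2 mm) experiments thicken
the cortical shell and endplates to 2 mm and 1.5 mm so every region resolves.

## Experiments

Loading drives the top particle layer down at a linearly ramped velocity and
holds it constant; the bottom layer is fixed. The run stops when the smoothed
*transmitted* force (the fixed-plate sum) reaches the stop force — with mass
scaling the driven-layer sum also carries the scaled inertial overburden, so
the transmitted channel is the physically comparable one (both are recorded
and agree in the quasi-static limit). Stiffness is the least-squares slope of
the final 20% of the force–displacement curve, in N/mm.

Problem sizes are the package's own reductions of the study conditions:

* Verification cubes: 10×10×10 mm, d = 1 mm (~1.4×10³ elements).
* Segment (acceptance script): anatomical cross-section 48×35 mm, shortened
  vertebral bodies (8 mm), disc 10 mm, d = 2 mm (~5.7×10³ elements), so
  force/area quantities (intradiscal pressure at 500/1000 N, stiffness) are
  directly comparable with the full segment.
* Study matrices (convergence, degeneration): a narrower 24×18 mm variant
  with stop forces scaled by cross-sectional area (identical mean axial
  stress), d ∈ {2.0, 1.5} mm.

Intradiscal pressure is the compression-positive hydrostatic stress over
disc-tagged elements (min/max/p95 all reported; the pore-fluid pressure field
is reported separately). The dorsal-shift metric is the posterior offset of
the Y-centroid of the top-decile pressure elements relative to the whole-disc
centroid; because this centroid statistic flips sign with the elastic ringing
phase at the stop instant, it is evaluated on fields averaged over 0.2 ms of
continued loading (one ringing period, ~2% extra force). Pressure statistics
and the pore-maximum region use the instantaneous loaded state.

## Known limitations

* The degeneration *directions* reproduce at reduced resolution — stage-1
  property loss raises the peak intradiscal pressure and moves the
  pore-pressure maximum from the endplates into the nucleus; stage-2 geometry
  change moves the stress maxima dorsally of the healthy pattern — but the
  *absolute* dorsal-shift sign does not: the simplified parametric geometry
  has an anteriorly biased healthy baseline (~+1.6 mm) and the ~1 mm relative
  dorsal migration stays below one automaton size at d = 2 mm. Whole-segment
  runs at d = 0.5 mm (~10⁶ elements) would be needed to resolve it.
* At loading speeds of 0.1–1.0 m/s the Darcy timescales of these tissues
  (consolidation times of 10⁴–10⁵ s) are ~10⁸ slower than the loading; the
  loading-rate sensitivity of the saturated model is therefore a
  dynamic-poroelastic effect (undrained stiffening plus wave impedance), not
  drainage. A dry soft-tissue specimen has no quasi-static regime at 1 m/s at
  all (the loading outruns its shear-wave relaxation, ratio `ε_f c_s/v < 1`),
  so the "rate-insensitive dry control" is unattainable in this regime for
  any dynamic model.
* The synthetic geometry omits posterior vertebral elements, facet joints,
  ligaments, osteophytes and wedge angles; whole-segment quantitative values
  carry that geometry uncertainty. Temperature dependence, damage/fracture,
  bond breaking and new contact detection are out of scope.
* Interaction areas are fixed at their lattice values (small-strain regime);
  bonded topology is fixed at setup.
* The free-surface softening of the fcc packing biases uniaxial moduli about
  −8% at 10 elements per edge, shrinking with refinement; all
  modulus-recovery checks pass within 10% at that size.
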
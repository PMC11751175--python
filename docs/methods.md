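# Methods

## Model overview and assumptions

The model computes the steady vestibular stimulus produced by a static
magnetic field acting on the inner ear's standing ionic currents, in four
one-way coupled stages:

1. **Electrodynamics.**  The magnetic Reynolds number of endolymph flow,
   Re_m = σ_e μ₀ U L ≈ 2×10⁻¹³ (σ_e = 1.67 S/m, μ₀ = 1.26×10⁻⁶ H/m,
   U = 10⁻⁴ m/s, L = 10⁻³ m), is so small that the moving fluid does not
   perturb the field: the electric problem is quasi-static and solved once.
   The potential obeys ∇·(σ∇φ) = 0 in the endolymph and cupulae
   (σ_e = σ_c = 1.67 S/m by default; their ratio is configurable).  The
   sensory hair-cell patches (three cristae and the utricular macula) are
   held at 0.01 V; the secretory dark-cell patches inject a total current
   with uniform density over their area (i.e., split across patches in
   proportion to area); every other boundary is insulating.  Then
   J = −σ∇φ and f = J × B per cell.
2. **Endolymph flow.**  At these forces the flow Reynolds number is ≪ 1 and
   the flow equilibrates within a second, so the momentum balance is steady
   incompressible Stokes flow with body force f, rigid no-slip walls, and
   the cupulae treated as sealed rigid walls (one-way coupling; their actual
   deflections are sub-micrometre).  The compressible-density closure used
   by general-purpose solvers is dropped: the Mach number is ~10⁻⁷.
3. **Cupula mechanics.**  Each cupula is a thin clamped circular plate
   (E = 4.26 Pa, ν = 0.48, radius R = ampulla radius, thickness h).  The
   effective load is the transcupular pressure (area-weighted mean pressure
   on the ampullar minus the utricular face) plus the direct Lorentz load on
   the cupula volume (mean utriculopetal force density × h).  Center
   deflection w₀ = q R⁴/(64D) with D = E h³/(12(1−ν²)); the reported crista
   strain is the rim bending strain ε = 4 w₀ h / R², signed positive for
   utriculopetal deflection.  Temporally ε relaxes as a first-order system
   with the canal long time constant τ (default 4.2 s); the plateau time is
   the first t at which the rim shear-stress increment
   G·|ε_ss| e^(−t/τ)(1 − e^(−w/τ)), G = E/(2(1+ν)) ≈ 1.44 Pa, falls below
   the criterion threshold (1 µPa over a w = 2 s window).  The µPa criterion
   is read as a *stress* increment — the minimal unit-consistent
   interpretation of a threshold quoted in pascals against a strain trace.
4. **VOR synthesis.**  Utriculopetal deflection excites the horizontal
   crista and inhibits the superior/posterior ones.  With signed stimuli
   (positive = excitation) the excitatory/inhibitory pathway bookkeeping of
   the VOR reduces to `spv_hor = s_LH − s_RH`,
   `spv_ver = s_LS + s_RS − s_LP − s_RP`,
   `spv_tor = s_LS − s_RS + s_LP − s_RP`, with unit gain and linear
   summation (valid at the very low frequencies of this stimulus).  Positive
   SPV means rightward / upward / counterclockwise.

World frame: right-handed with X posterior→anterior, Y right→left,
Z feet→head.  The scanner bore axis is Z; a "head-to-feet" field is
B = (0, 0, −|B|).  Ear-to-shoulder roll is a rotation about X (negative =
right ear down); flexion-extension pitch about Y (negative = flexion); the
supine posture carries a +20° pitch offset so the utricle plane sits above
the axial plane, as it does in a supine subject.  The right labyrinth is the
mirror image of the left through the sagittal plane.

## Idealized labyrinth

The geometry is an implicit solid, voxelized and split into tetrahedra with
the Kuhn 6-tet decomposition (conforming and watertight by construction):

* utricle: ellipsoid with semi-axes 1.5 × 0.75 × 0.5 mm;
* three torus canals (major radius 3.2 mm, duct radius 0.16 mm) in mutually
  orthogonal planes, each ring passing through the utricle so the canal
  opens into it twice;
* one spherical ampulla (radius 0.6 mm) per canal just outside the utricle,
  sealed by a cupula disk (thickness 0.3 mm) perpendicular to the local
  canal axis — removal of the cupula cells reopens the ampulla–utricle
  passage, and with them in place the only path is around the canal;
* patches: the exposed rim of each cupula disk is its crista; a narrow
  (0.15 mm) secretory band sits beside each crista on the canal side; the
  macula occupies the anterior floor of the utricle; dark-cell bands lie on
  the posterior utricle wall and on the superior canal's posterior limb
  (standing in for the common crus — the idealization attaches all three
  canals directly to the utricle rather than merging two of them into a
  shared crus).

Two placement choices matter for the sign structure and follow anatomy:
the **lateral canal chord crosses the utricle obliquely** (ampullated end
antero-lateral, non-ampullated end postero-medial, as in the human
labyrinth), and the **macula is anterior**.  The supine Lorentz force points
toward the left ear in both labyrinths and peaks in the utricle, creating a
lateral high-pressure / medial low-pressure dipole with two counter-rotating
vortices (the anterior one stronger and clockwise seen from above).  With
the lateral canal sampling that dipole across the utricle, its cupula is
pushed away from the utricle on the left side and toward it on the right,
while both vertical canals deflect the opposite way — the observed pattern
(left: H inhibited, S and P excited; right mirrored).  The ampullary
secretory bands are kept narrow so the dominant current into each crista
arrives through the canal from the utricular and common-crus dark regions;
wide local bands would inject azimuthally asymmetric forces right at the
cupula whose sign is a discretization artifact rather than physics.

Default voxel size is 0.1 mm (≈55k cells, ≈3–4 duct cells across); this
resolves the sign and linear structure of the problem, which is the model's
acceptance surface, but not boundary layers in the 0.16 mm ducts.  All
dimensions and patch extents are configuration, not anatomical claims.

## Numerics

* P1 tetrahedral FEM throughout; per-cell gradients; sparse direct solves
  (SuperLU) with deterministic ordering, so identical configurations
  reproduce bit-identical results.
* Stokes: equal-order P1–P1 velocity/pressure with Brezzi–Pitkäranta
  stabilization (α h²/μ ∇p·∇q, α = 0.05), one pinned pressure DOF and a
  zero-mean pressure gauge.  Validated against Poiseuille flow in a
  body-fitted cylinder (centerline speed within 5 %, mesh-convergent) and a
  hydrostatic closed-box balance.
* Conduction: validated against the parallel-plate (exact linear, < 10⁻⁸)
  and concentric-sphere (a + b/r, < 2 % relative L2 at the default shell
  resolution, converging under refinement) solutions.
* Current streamlines are integrated through the per-cell J field with
  tangential sliding along staircase walls; exits are attributed to the
  nearest boundary patch, preferring a sensory/secretory patch within 1.5
  voxels of the exit point because insulating walls cannot terminate current
  in the continuum.
* Degenerate inputs: a uniform Dirichlet problem returns the constant
  potential; zero force returns exactly zero flow; an identically-zero sweep
  component is reported as "null everywhere" rather than fit; a peak summary
  built from fewer than ten slow phases is flagged as insufficient.

## The free scale and its calibration

The boundary-condition data behind the dark-cell drive are not published, so
the total injected current is the model's one free constant.  With
`drive="auto"` it is calibrated once so that the supine 7 T run reaches a
peak utricular endolymph speed of 134 µm/s — the headline utricular vortex
speed, and the only absolute velocity anchor available (the calibrated drive
comes out at ≈6.5 µA, a physiologically plausible labyrinthine current).
Every *normalized* output (sweep shapes, null points, field-strength ratios,
sign patterns) is independent of this constant; the absolute strains, and
through the logarithm the plateau time, inherit it.  The plateau time is
insensitive in practice: it varies only as τ·ln(drive).

## Surrogate orientation sweeps

Full-physics sweeps cost one pipeline run per angle, so the sweep machinery
also offers a surrogate mode in which each crista responds sinusoidally in
the sweep angle.  For ear-to-shoulder roll the null angles are ±12° (H),
±19° (P) and ±42° (S), mirrored between ears (s_R(θ) = −s_L(−θ)); for
flexion-extension they are −27°/153° (H), −71°/109° (P) and −42°/138° (S),
identical in both ears with opposite sign.  Both templates reproduce the
supine sign pattern at 0°.  Amplitudes default to 1 per canal pair; in the
ETS sweep the horizontal/torsional SPV nulls sit at exactly ±90° for *any*
mirrored amplitudes (a trigonometric identity), while the FE torsional null
depends on the superior:posterior amplitude ratio —
`fe_torsional_amplitude_ratio` inverts that choice for a requested null
(e.g. a −50° null needs A_S/A_P ≈ 2.57).  The "180-degree wavelength" of the
response is implemented as zeros 180° apart on a 360°-periodic sinusoid;
fits therefore use the 360° period, which is the reading consistent with the
tabulated null spacing.

One caveat on the surrogate defaults: the ETS vertical component is the
difference of two nearly cancelling pair sums, so its *sign* (though not its
nulls at 0°/180° or its 90° phase offset from the horizontal component)
depends on the superior:posterior amplitude ratio.  With equal default
amplitudes the surrogate's vertical SPV points downward for left
ear-to-shoulder tilt, whereas the full-physics sweep on the idealized
labyrinth — like supine subjects tilted in a scanner — produces an upward
drift for left tilt; a ratio A_S/A_P > cos19°/cos42° ≈ 1.27 brings the
surrogate in line.  Cross-checks between the two modes therefore compare the
horizontal and torsional components.

## Synthetic eye traces and quantification

The generator emulates 100 Hz three-channel video-oculography: linear
slow-phase drift at the injected SPV (plus an optional baseline drift
standing in for inherent nystagmus in darkness), single-sample quick phases
at a Poisson rate (default 2 s⁻¹) that reset the eye beyond the recentre
point so position stays bounded for any SPV, blink gaps (mask false,
position held), and additive Gaussian position noise (default 0.05°).  It
does **not** model video artifacts, torsion template matching, smooth
pursuit, or the central adaptation that makes real SPV decay over minutes —
so passing recovery tests demonstrate the quantification arithmetic, not
robustness to real-world recording pathologies.

Quantification cuts the trace where the central-difference velocity exceeds
30 °/s (with a 3-sample debounce that merges chattering crossings) or where
the validity mask is false, discards segments shorter than 100 ms, fits
least-squares slopes per segment, summarizes the mean of the ten
highest-|SPV| points (error bar = half the range of those ten — the
published "standard error from the max and min" is under-specified, so the
half-range convention is isolated in one function), subtracts the
Earth-field baseline in quadrature, sign-inverts caudocephalic-field
recordings, and normalizes groups with the vertical component scaled by the
horizontal peak.  Known floor: when *all* injected components are below
≈0.5 °/s the resetting quick phases are themselves sub-threshold and
detection degrades; recovery is validated for beats driven by a dominant
component ≥2 °/s, the regime of interest.

## Known limitations

* The labyrinth is an idealization: orthogonal planar canals, no common
  crus duct, no left/right anatomical asymmetry; absolute strain magnitudes
  and region-to-region speed ratios are geometry-specific and should be read
  only through normalized comparisons.
* One-way fluid–cupula coupling assumes the sign of the steady transcupular
  pressure is unchanged by cupula compliance.
* Voxel resolution limits duct hydrodynamics; cross-section fluxes of the
  sealed canals are verified to be near zero rather than resolved.
* The utricular macula's afferent pathway is not modeled: currents to the
  macula are computed (they shape the force field) but produce no eye
  movement in the VOR synthesis.
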
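# Methods

## Scene model

A cell is a piecewise-constant 3D refractive-index field: an ordered set of
homogeneous geometric parts (ellipsoids/spheres, half-ellipsoid pairs,
biconcave discs, swept tubes) in a medium of index `n_m`.  Each part has a
priority; at any point the index is that of the highest-priority containing
part, so a nucleus (priority 2) overrides cytoplasm (priority 1) overrides
medium.  Lengths are micrometres; the frame is right-handed with origin at
the cell centre and z along the optical axis of the first view.

Documented presets: the two-half-ellipsoid monocyte carries nucleus
semi-axes 3.40/3.70/3.00 μm at centre (0, 0, 3.00) μm, indices
n₁ = 1.37 (cytoplasm), n₂ = 1.39 (nucleus), n_m = 1.003, λ = 488 nm; the
RBC is a biconcave disc of diameter 7.7 μm with centre/edge thickness
1.0/2.0 μm; the five white-cell models share a 12.0 μm membrane sphere.
**Assumptions** (values not fixed by the source material, all overridable):
the RBC interior index (1.40), the WBC nucleus/cytoplasm indices (1.39/1.37,
mirroring the monocyte), lymphocyte nucleus radius 4.5 μm at (0, 0, 1),
eosinophil/neutrophil spheroid semi-axes 2.5/2.0/2.0 μm, U-tube arc radius
3.0 μm with tube radius 1.5 μm, basophil S-arcs of radius 2.0 μm, and the
monocyte membrane half-ellipsoids a = b = 6.0, c_top = 6.5,
c_bottom = 3.5 μm.  c_top must exceed 6.0 μm for the preset nucleus
(top at z = 6.0 μm) to fit inside the membrane; 6.5 μm keeps the 12 μm
equatorial diameter while containing the nucleus with modest clearance.

The biconcave profile is a cosine sum
`h(ρ) = A0 + A1·cos(πρ) + A2·cos(2πρ)`, ρ = r/R, with the three
coefficients fixed in closed form by h(0) = centre thickness, h(1) = 0 and
max h = edge thickness at an interior radius.  Any smooth axisymmetric
profile meeting those three constraints yields the same qualitative ring
pattern; the cosine sum was chosen for its closed-form constraint solve.

## Forward phase model

Phase is the straight-ray projection integral
`φ(u,v) = (2π/λ)∫(n(s)−n_m)ds`; diffraction is deliberately out of scope.
Chords are closed-form for quadrics (ellipsoids, half-ellipsoid pairs,
axial rays through the disc); swept tubes and lateral disc rays use a
coarse membership scan (default 0.02 μm) whose bracketed boundary crossings
are bisection-refined to ~1e-12 μm, so sampled parts carry no first-order
step error.  Overlaps resolve by priority level: the chord credited to a
level is the union chord of its parts minus the union of all
higher-priority parts, which reproduces the composition
`φ₁ = (2π/λ)[(n₁−n_m)h₁ + (n₂−n₁)h₂]` exactly for a nucleus inside a
membrane.  An independent oracle (`brute_force_phase`) integrates the same
ray using only point membership of the assembled scene, also with
bisection-refined boundaries under a fixed evaluation budget: a plain
10⁴-sample Riemann sum of a discontinuous integrand would have
boundary-placement error ≈ k·Δn·step/2 ≈ 3×10⁻³ rad per crossing, larger
than the 10⁻³ rad agreement the oracle is meant to certify, so refinement
is required for the check to be meaningful.

Wrapping maps to the interferometric principal interval (−π, π].

## Phase unwrapping

Two methods: `itoh` line-scans wrapped differences (first column, then each
row) and is exact whenever neighbouring true phases differ by less than π;
it computes the 2×2-loop residues first and raises rather than guess when
any are non-zero.  `quality` (default) is the Herráez reliability-sorted
region-merging algorithm (scikit-image implementation).  The global 2π·k
offset is fixed by zeroing the median of a 5-pixel background border.

**Sampling limit.**  A sphere-like silhouette has chord `2√(2Rδ)` at depth
δ, so the rim phase step between adjacent pixels of size h can reach
`2kΔn√(2Rh)`.  For the 12 μm membranes at Δn = 0.367 this exceeds π for any
h > (π/(2kΔn√(2R)))² ≈ 0.009 μm: at the default 0.0625 μm grid a thin rim
band is aliased for *every* unwrapping algorithm — each rim pixel's four
neighbour differences all exceed π, so the information is genuinely lost,
not merely hard to recover.  Round-trip tests therefore run the
sphere-membrane models at 1792² over a 14 μm field (h ≈ 0.0078 μm), where
the Itoh condition holds everywhere and both methods are exact; the RBC's
cosine profile has zero rim slope and round-trips at the default grid.
The reconstruction pipeline itself consumes unwrapped maps (or wrapped maps
the caller knows to be Nyquist-sampled) and is unaffected.

## Inflexion-curve boundary extraction

For piecewise-constant scenes each projected interface makes the chord —
hence the phase — kink like `A·√(depth)`.  The response field is the second
directional derivative of the Gaussian-smoothed phase along the local
gradient,

    f = (φ_xx g_x² + 2 φ_xy g_x g_y + φ_yy g_y²) / (g_x² + g_y²),

whose negative lobes ridge along the interfaces (the surface-of-revolution
curvature locus; an algebraically garbled printed variant of this
expression with inconsistent `1 + y'²` factors admits the same reading for
surfaces of revolution, which is the implemented one).  Default smoothing
σ = 2 pixels.

Detection: non-maximum suppression of W = −f along the principal Hessian
direction yields one-pixel crest skeletons; connected components that
surround their own centroid (≥ 90% angular coverage) are accepted as closed
interface loops and resampled at uniform angles about the centroid.  The
approach assumes interfaces are star-shaped about their centroid — true for
the convex compartments this method targets (U/S-shaped nuclei are rendered
and wrapped correctly by the forward model but their outlines are not
extracted; the lobed neutrophil nuclei extract per-lobe).

Sub-pixel localisation: after Gaussian smoothing the √ edge's second
derivative has a negative lobe inside, a positive lobe outside, a zero
crossing ≈ 0.77 σ inside the edge and a positive peak ≈ 0.55 σ outside it —
offsets that are amplitude-independent by scale invariance and are
calibrated against the *discrete* operator chain (so grid effects are
included).  Each resampled point moves to the nearest crest of W
(quadratic fit across the ridge), marches outward to the response zero
crossing and shifts outward by the calibrated offset.  Two corrections
handle real maps: (i) a smooth background level b (from the membrane's own
curvature) shifts the crossing by b/slope; b is estimated by linear
extrapolation from two samples beyond the positive lobe and subtracted,
clamped to ±2 px and skipped when a stronger neighbouring interface
dominates the samples; (ii) where an adjacent stronger interface suppresses
the zero crossing entirely (overlapping lobes), the surviving local maximum
— the positive-lobe peak — is used as the landmark with its own calibrated
offset.  A zero-crossing extraction mode is retained for graded-index
inputs.

Phase centres: the centroid rule takes the area centroid of the closed
nucleus contour; the extremum rule takes the argmax of the *unwrapped*
phase restricted inside the innermost contour (the extremum of a wrapped
map is ill-defined once |φ| > π), ties broken by the centroid of the argmax
set.  The two orthogonal views share the x axis; their x estimates must
agree within 0.2 μm (default) or the detection is rejected as "no
consistent nucleus".  The pipeline's 3D centre uses the centroid rule: in
an x-z view of an off-centre nucleus the phase maximum is dominated by the
membrane chord (largest at the equator), so the extremum z tracks the
optical-path maximum rather than the nucleus centre; the extremum centre is
still computed and reported.

## Reconstruction and reporting

`rotate_outline` revolves a closed outline 180° about an in-plane axis
(mirror symmetry supplies the rest), rejecting outlines that cross the axis
more than twice.  `merge_orthogonal` (pipeline default) lofts, at each
shared-axis station, an ellipse whose semi-axes are the half-widths of the
two outlines, centred at their mid-lines; it reduces to the revolution when
the outlines are congruent and uses the information of both views.
Stations are cosine-spaced so the closed poles are well resolved; meshes
are watertight by construction.  The axis-aligned ellipsoid fit is linear
in the inverse squared semi-axes and is solved by least squares about the
reconciled centre; the report carries the semi-axes, equivalent volume
(4/3)π·a·b·c, the ellipsoidal degree — defined here as the pairwise ratios
(b/a, c/a, c/b) plus the mean geometric fit residual, separating
departure-from-sphericity from departure-from-ellipsoidality — and the mesh
volume alongside.  A residual above 10% of the mean semi-axis warns
"non-ellipsoidal nucleus".  Arbitrary-orientation fits are out of scope
(the models are axis-aligned).

Nucleus thickness maps are rasterised from the watertight mesh by the
divergence identity (signed sum of triangle heights over each pixel);
`outer_surface_thickness` inverts the phase composition for
`h₁ = [λφ₁/(2π) − (n₂−n₁)h₂]/(n₁−n_m)`, clipped at zero.  `assemble_cell`
lofts the membrane from the two cell outlines (or from the silhouettes of a
thickness-map pair), verifies nucleus containment with a rasterised
z-extent test (exact for the two-crossing membrane shapes; ~1 px
quantisation) and reports the maximum violation distance on failure.

## Synthetic study conditions

The randomised recovery sweep draws nucleus semi-axes U(2, 4) μm and
centres uniform in ±2 μm per coordinate, rejection-sampled so the nucleus
keeps ≥ 1.1 μm clearance inside the default membrane.  The clearance
encodes a genuine limitation of curvature-based boundary analysis: two
interfaces closer than roughly the lobe width of the smoothed response
(≈ 8σ ≈ 1 μm at default settings) produce merged curvature signatures that
no two-view method can separate, so such configurations are outside the
method's stated domain rather than failures of the implementation.  Under
these conditions the pipeline recovers, noise-free at the default 256²
grid, every centre coordinate within 0.1 μm and every semi-axis within
0.15 μm (the test suite checks 25 random draws), and the preset monocyte to
within a few hundredths of a micrometre.

What the generator does *not* emulate about real data: diffraction and
finite numerical aperture, detector and shot noise (only additive Gaussian
phase noise is available), graded intracellular refractive indices,
non-axis-aligned or asymmetric nuclei, and acquisition artefacts of real
interferograms.  Passing tests therefore certify the geometry-processing
chain under the projection approximation, not performance on experimental
holograms.

## Numerical choices and limitations

* Default grid 256² over a 16 μm field (0.0625 μm pixels): sub-2%
  discretisation on the reported quantities at interactive runtimes.
* Quadrature: 0.02 μm coarse scan + bisection for sampled parts (the
  tube-model round-trip tests relax the scan to 0.1 μm at 1792², which can
  miss grazing chords shorter than the scan step — a ≤ 0.03 rad effect,
  irrelevant to unwrapping consistency).
* Ridge floor 2% of the map's peak response; loops below 1 μm² or with
  < 16 points are discarded.
* Meshes: 160 stations × 120 angular steps (merge), 180 × 180 (literal
  revolution), volumes within 1% of closed forms.
* Two views constrain only surfaces of revolution per x-station: genuinely
  asymmetric nuclei (and lobe identities of multi-lobed nuclei) need more
  views; symmetric specimens are a stated assumption of the method.
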
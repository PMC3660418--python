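# Methods

`acinomorph` re-creates, on fully synthetic data, the quantitative
imaging chain used to measure terminal branching units — a "mother"
terminal bronchiole and its two "daughter" alveolar sacs — in
phase-contrast synchrotron CT of a mouse lung: tomographic
reconstruction, edge-based air–tissue segmentation, 3D morphometry, and
branching-asymmetry statistics.  This note records the models, the
parameters that matter, and the choices made where the design was
genuinely open.

## The phantom model

A terminal branching unit is idealised as:

* **mother**: a cylinder of radius `mother_radius_um` along +z, ending
  at a bifurcation;
* **necks**: two short cylinders (length `neck_length_um`, default
  10 µm) whose radii equal the mouth radii, diverging from the
  bifurcation at `bifurcation_angle_deg` (default 90°) in the x–z plane;
* **daughter sacs**: ellipsoids whose long axes continue the neck
  directions.  Each mouth plane is perpendicular to the sac's long axis
  and placed so that its intersection with the ellipsoid is exactly the
  circle of the stated mouth radius — mouth diameters therefore have
  closed-form ground truth (geometric mean of two equal axes = the
  diameter), while the sac interior begins strictly distal of the plane.

Alveolated walls with ambiguous borders are emulated, not resolved:
sac surfaces are perturbed radially by a smooth seeded noise field
(white noise low-pass filtered at `bump_correlation_um`, default 9 µm,
max-abs normalised), with absolute amplitude `wall_bumpiness` × smallest
semiaxis.  Bumps taper to zero within `mouth_taper_um` of the mouth
plane so the mouth circle — the sac's firm baseline — stays analytic.
Individual alveoli are deliberately not modelled; the default
`wall_bumpiness = 0.1` gives ±3–4 µm wall texture at the default scale.

Where the two sacs approach each other, a tissue septum of
`septum_gap_um` (default 6 µm, ≈3–4 voxels — the scale of real
interalveolar septa) is kept between the lumens: each sac cedes any
voxel within half a septum of the other sac's inflated boundary on the
wrong side of the bisector plane.  Sacs that interpenetrate beyond the
mouth region are rejected as invalid geometry.

Voxel membership is by centre inclusion on a 0-based (z, y, x) grid with
voxel centres at `index × voxel_size_um`; default 1.74 µm isotropic
voxels on a 128³ grid.  Default dimensions put the unit at real mouse
scale (d₀ = 72 µm, mouth diameters 50/42 µm, sac volumes 0.25/0.17 nL),
inside the observed ranges of the bundled reference table.

**Ground-truth oracle.** Diameters are analytic.  Sac volumes and
surface areas are computed by voxelizing the *same* continuous geometry
(shared code path, same interpolated bump field) at 4× finer resolution
and applying the same estimators used on measurements — voxel counting
and 6-neighbour face counting — then scaling.  The face-counting bias
(see below) is thereby reproduced, not corrected, on both sides of every
comparison.  4× and 8× refinement agree within 2% (tested).

## Beam simulation

Synchrotron beams are near-parallel, so projections are straight-ray
line integrals, computed per angle by bilinear rotation of the volume
about z and summation along rows (exactly mass-conserving; equivalent in
accuracy to explicit ray sampling).  The phantom is projected as a
density map: tissue 1, air 0, with the tissue block confined to a
cylinder inscribed in the slice so the object stays inside the
parallel-beam field of view.

Propagation-based phase contrast appears in the data as a bright/dark
double fringe along every air–tissue boundary.  It is emulated
phenomenologically — a transport-of-intensity-style stand-in, not wave
optics: each projection image `p` becomes `p − strength·∇²p` (discrete
Laplacian over the slice and detector axes).  No quantitative fringe
amplitude is available for the real instrument; the default
`strength = 0.3` makes the fringe pair ≈30% of the air–tissue step,
which is visually comparable and leaves the mid-step gradient (the edge
detector's target) strongly enhanced.  Acquisition metadata (22 keV mean
energy, ΔE/E = 0.62, 18 cm propagation, 5× magnification) is carried in
sidecars as description only.

Photon noise: detected intensity `I = N₀·exp(−κL)` with
`κ = attenuation_per_unit` (default 0.002 per density·µm, i.e. ~30%
attenuation through 180 µm of tissue-equivalent path), Poisson-sampled
and log-transformed back to line-integral scale.  Default
`N₀ = 10⁶ photons/pixel` gives ≈0.2% RMS sinogram noise — a clean
synchrotron acquisition; the Canny thresholds below tolerate far worse.

## Reconstruction

Standard parallel-beam filtered back projection, written against the
discrete band-limited ramp (1/4 at lag zero, −1/(πn)² at odd lags) so
the DC response vanishes exactly; optional Shepp–Logan apodisation.
Rows are zero-padded to the next power of two ≥ 2× the detector length.
Backprojection uses linear interpolation and the π/(2·n_angles) scaling;
pixels outside the inscribed circle are zeroed.  These are the standard
choices — the reference workflow used closed-source software that
published none of them.  The implementation is cross-checked in tests
against `skimage.transform.iradon` on identical sinograms and against
analytic disk profiles (RMSE ≤ 5% of density inside 90% of a disk's
radius at 500 angles; fewer angles reconstruct measurably worse).

## Segmentation

Each slice is binarized with a Canny detector (boundary = 1, everything
else = 0): Gaussian smoothing (`gaussian_sigma_px`, default 2.0 — wide
enough that the fringe pair presents a single gradient maximum at the
true interface rather than three), Sobel gradient, non-maximum
suppression, 8-connected hysteresis, followed by morphological thinning
so the boundary is one voxel thick even when both fringes fire.
Hysteresis thresholds default to the 80th/95th percentiles of the
nonzero gradient magnitudes per slice (no published absolute values
exist); an absolute mode is provided for reproducibility experiments.

Detection is strictly 2D per slice along z by default, matching a
slice-wise workflow.  Where the 3D surface runs parallel to the slices
(sac caps) the in-plane gradient vanishes and the stacked mask has
pinholes; `segment_stack(axes=(0, 1, 2))` optionally sweeps all three
axes for applications needing a watertight surface.  The measurement
pipeline instead stays robust through the intensity gate described next.

## Unit extraction

Unit identification is annotation-driven (seed voxels plus cap/mouth
planes in JSON), mirroring manual selection; no automatic bifurcation
detection.  Interiors are recovered by 6-connected flood fill over
non-boundary voxels — consistent with the 6-neighbour surface estimator
— truncated by cap planes: voxels on the far side of a plane or with
centres within 0.5 voxel of it are blocked.  A fill that reaches the
volume border raises a "leak" error naming the exit face (regions that
legitimately touch the border can opt out).

When the reconstructed volume is supplied, two refinements use it:

* the fill traverses only air-like voxels (below the air–tissue
  midpoint), so mask pinholes cannot leak the fill into tissue;
* boundary-mask voxels that are air-like are iteratively reassigned to
  the adjacent lumen.  The detected 1-voxel edge shell straddles the
  true interface, so roughly half of it is morphologically air;
  excluding it would bite ~half a voxel out of the lumen everywhere
  (a 3h/2r ≈ 5–7% volume deficit at sac scale).  The reconstructed
  intensity at those voxels — below the midpoint on the air side, above
  on the tissue side, with the fringes reinforcing the split — decides
  their side to sub-voxel effect.

Daughters are ordered major/minor by mouth diameter, ties broken by
volume, then by annotation order.

**Mouth rings.** A mouth ring is traced as the face centres between
wall voxels and the adjacent *mother/neck* lumen within 1.5 voxels of
the mouth plane, anchored to within 3 voxels of the daughter region,
projected onto the plane, and reduced to the innermost contour (minimal
radius per 4° azimuth bin).  The proximal side is used because it sits
at the mouth's defining radius, whereas wall contacts on the daughter
side lie on the flaring sac base at least half a voxel distal of the
plane and inflate a maximal-chord axis by 5–14% at default scale.  The
mother diameter d₀ uses the same machinery at the mother cap plane
(where along the bronchiole d₀ is taken is otherwise unspecified; the
cap plane is the reproducible choice).

## Morphometry

* **Diameter** = geometric mean √(long × short) of a ring's long axis
  (maximal pairwise chord) and short axis (extent along the in-plane
  direction perpendicular to that chord).  The chord convention is
  parameter-free and brute-force checkable; fitted-ellipse axes would be
  an equally defensible reading of "longer axis/shorter axis".
* **Surface area** = exposed 6-neighbour faces × voxel face area,
  counting faces against boundary-mask voxels and the array border as
  exposed.  On smooth surfaces this estimator converges to 3/2 × the
  true area (the face count estimates ∫(|n_x|+|n_y|+|n_z|)dA and the
  spherical mean of that integrand is 3/2); digitized spheres with
  r ≥ 20 voxels stay within [1.40, 1.60] of 4πr².  The bias is kept so
  that measured values remain comparable with face-counted references.
* **Volume** = voxel count × voxel volume, reported in nL
  (1 nL = 10⁶ µm³).

Exports round to 3 significant figures; all internal arithmetic is
unrounded.

## Asymmetry statistics

Per unit: d₁/d₀ (diameter reduction), d₁/(d₁+d₂), S₁/(S₁+S₂),
V₁/(V₁+V₂).  The diameter ratio is ≥ 0.5 by the major/minor ordering;
area and volume ratios may fall below 0.5 (the wider-mouthed sac is not
always the larger one — true for 4 of the 16 reference units).
Box summaries: median (even n: mean of the two central order
statistics), quartiles by linear interpolation of order statistics
(configurable — plotting packages differ and no quartile values are
published to pin the convention), whiskers at the extremes.  Reported
medians are rounded half-up to 2 decimals.

The bundled 16-unit reference table reproduces, exactly, medians
0.82 / 0.55 / 0.57 / 0.60 and extremes d₀ ∈ [52.5, 123] µm, mouth
diameter ∈ [29, 92] µm, sac surface ∈ [8 510, 97 700] µm², sac volume
∈ [0.0305, 0.920] nL.  One known inconsistency in the source: the
printed d₁/d₀ range "0.58 to 1.05" does not follow from the printed
table, whose direct quotients span ≈0.68–1.05; the table is taken as
authoritative and the range is recomputed, not copied.

## What the synthetic data does and does not show

The phantoms share the real data's geometry scale, voxel size,
double-fringe boundary signature, closed thin walls and Poisson noise,
so passing tests demonstrate that the chain — reconstruction,
edge-based binarization, fill, estimators — is implemented correctly
and recovers known truth (d, V within 5%; S within 10% of the
same-estimator oracle on a 128³ unit; sub-2% typical).  They do not
contain true Fresnel fringes, polychromatic or detector effects, ring
artifacts, sample motion, or the anatomical ambiguity of real alveolated
surfaces, so they cannot validate parameter choices against real
beamline data — only the internal consistency and correctness of the
method.

## Problem sizes and numerics

Default study conditions are used throughout: 128³ voxels at 1.74 µm,
500 projections over 180°.  Property tests use 64³–96³ phantoms and
2D slices where the property is dimension-independent.  Ties and
degeneracies: voxels exactly on a cap plane are blocked from the fill;
rings need ≥ 3 non-collinear points (else an error); constant images
segment to empty masks; equal mouth diameters fall back to volume, then
annotation order.  All randomness flows from explicit seeds (phantom
bumps and photon noise are the only stochastic stages), and every stage
is bit-reproducible given its inputs and seed.

## Known limitations

* The sac model (ellipsoid + smooth bumps + circular mouths) is an
  idealisation chosen for oracle-computability; no claim is made that it
  matches alveolar-sac shape statistics.
* Per-slice 2D Canny leaves pinholes at surface caps; watertightness
  comes from the intensity gate (or the 3-axis sweep), not the mask
  alone.
* The edge-enhancement operator is phenomenological; fringe shapes and
  amplitudes are not radiometrically calibrated.
* Mother-region morphometry is limited to d₀; mother surface/volume are
  not defined quantities here.
* At paper scale the mouth-diameter ground-truth recovery is accurate to
  ≈1–2% (ring digitization); claims below that resolution are outside
  the package's precision.
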
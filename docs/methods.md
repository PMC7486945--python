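# Methods

## Scope and model

`coroalign` measures the transmural organization of two oriented tissue
components in the embryonic ventricular wall: the coronary microvascular
network (a 3D centreline skeleton) and the cardiomyocyte nuclei field (a
z-stack of 2D images).  Both are reduced to *axial* orientation angles —
directions without sense, period 180° — as a function of depth below the
epicardial surface, and the two depth profiles are compared.

### Surface-anchored frame

Every vessel segment gets one local orthonormal frame, anchored at its
arc-length midpoint:

* **g₁** — unit vector from the midpoint toward the nearest point of the
  epicardial surface cloud; the distance itself is the segment's depth.
  Nearest-point queries run through a k-d tree and match exhaustive
  search exactly; distance ties are resolved toward the lowest
  surface-point index for determinism.
* **g₂** = g₁ × (V_AB × g₁), normalized — the apex→base unit axis V_AB
  (two user-supplied points; in practice identified manually on the
  specimen) with its g₁ component removed.
* **g₃** = g₂ × g₁ — circumferential.  The operand order fixes the frame
  handedness and therefore the *sign* of helical angles; it is applied
  verbatim everywhere so signs are self-consistent across the pipeline.

Degenerate configurations — zero depth, or g₁ parallel to V_AB — have no
defined frame.  Such segments are excluded from all statistics and their
counts logged; silently propagating NaNs would corrupt circular means.

The frame is exact only insofar as the surface cloud is dense: the
nearest cloud point sits up to half a sampling pitch away from the true
foot point, tilting g₁ by up to atan(pitch/2 / depth).  The induced
helical-angle error is second order in that tilt and averages out over
segments; the phantom generator samples its surfaces at a 3 μm pitch so
this term stays well below the angular dispersion being measured.

### Vessel angles

For the vessel-vector V_v joining a segment's start and end nodes:

* helical angle α_H = 90° − arccos(V_v·g₂/|V_v|) ∈ [−90°, +90°]
  (0° circumferential, +90° apex→base).  Segment node order is
  arbitrary, so V_v is first mapped onto the hemisphere with
  non-negative g₃ component (non-negative g₂ component on its boundary);
  the elevation of an undirected line is then single-valued and exactly
  invariant under direction reversal.
* projection angle: V_p = g₁ × (V_v × g₁) removes the radial component;
  the angle of V_p is computed as atan2(V_p·g₂, V_p·g₃) and folded to
  (−90°, 90°].  The unsigned arccos(V_p·g₃/|V_p|) form cannot
  distinguish +45° from −45°; the atan2 form agrees with it up to the
  axial sign and keeps the slab identity α_P = α_H valid for negative
  angles, which matters when correlating against signed nuclei
  orientations.  Segments running along g₁ (|V_p|/|V_v| < 10⁻⁶) have no
  tangent projection and are excluded.

### Depth profiles

The moving-window profile evaluates, every 5 μm from the shallowest to
the deepest segment, the axial circular mean, fitted κ and standard
uncertainty u over all segments whose *midpoint depth* lies within
±15 μm (both defaults configurable).  5 μm is far below the window
width, so the curve is effectively continuous.  Bins with fewer than
n_min = 10 segments are reported with NaN statistics, never
interpolated: κ fits on fewer axial samples are unstable.  Segments
count once each by default; an optional length-weighted mode exists.
No radius-based exclusion of large vessels is applied by default; an
optional cutoff is provided.

A per-segment local mean-angle field (for color-coded rendering) uses an
axis-aligned window of 136 × 136 × 175 μm centred on each segment
midpoint, aligned to the image axes.  Depth normalization maps the
min–max segment depth affinely onto [0, 1] (epicardium → endocardium) so
walls of different thickness can be overlaid.

### Nuclei orientation

Each slice is mean-subtracted, multiplied by a 2D Hann window (hard image
borders otherwise leak a ±45° cross into the spectrum), and transformed
with the FFT.  Spectral power is summed under wedge masks of half-width
2.5° centred every 5° from 0° to 180°; the wedges partition the
half-plane (boundary ties to the lower angle) so the wedge sums add up
to the total power.  Two further choices:

* only frequency bins inside the inscribed disc (k ≤ 0.5 cycles/px) are
  used; the corners of a square spectrum would otherwise give diagonal
  wedges systematically more bins and bias isotropic images toward ±45°;
* a 90° rotation converts spectral orientation to spatial orientation
  (stripes at angle θ concentrate power at θ + 90°), so all reported
  angles are image-space orientations.

A(θᵢ) is normalized to minimum zero and unit trapezoidal area over θ in
radians (the grid is closed periodically with A(180°) = A(0°));
normalization is idempotent.  The slice summary is the A-weighted axial
circular mean, the least-squares κ, and u.  Nuclei analysis is strictly
2D per slice; 3D nuclei orientation is out of scope.

**Noise floor of κ.**  The min-zero normalization rescales any
*near-flat* spectrum into an O(1)-contrast shape, whatever the image
size, so the fitted κ of a perfectly isotropic image does not go to 0
but plateaus around κ ≈ 0.5–1.5.  Concentrations in that range should be
read as "no detectable orientation"; oriented textures sit orders of
magnitude higher.

### Axial circular statistics

* **Mean.** Angles are doubled, unit phasors averaged (optionally
  weighted), and the mean is half the argument of the resultant, folded
  to (−90°, 90°].  A resultant length below 10⁻¹² (antipodal or uniform
  data) leaves the mean undefined and flagged.
* **Density model.** The bimodal von Mises density
  pdf(θ) = [e^{κcos(θ−μ)} + e^{κcos(θ+π−μ)}]/(2πI₀(κ)) integrates to 1
  over any axial half-period — it is the proper density for axial data
  on 180° (and integrates to 2 over the full circle).  It is evaluated
  in exponent-shifted form via the scaled Bessel function, stable for
  arbitrary κ.
* **κ fit.** κ is the bounded least-squares minimizer of
  Σᵢ (dᵢ − pdf(θᵢ; μ, κ))² with μ fixed at the axial mean, over
  κ ∈ [0, 10⁴].  The input density — a 5°-binned empirical histogram for
  samples, or the normalized A(θᵢ) for spectra — is first rescaled to
  unit half-period integral so a discretized pdf self-fits exactly.
  Because the objective stops being unimodal once the mode is narrower
  than the grid step, the minimizer scans a log-spaced κ grid first and
  refines locally; solutions at the upper bound are flagged.  Sample and
  spectrum fits share the one 5° discretization.
* **Standard uncertainty.** u is the half-width with
  P(−u < θ < u) = 0.68 under the pdf centred at its mode and restricted
  to the axial half-period (−90°, 90°], found by bracketing to 10⁻⁶ rad.
  The restriction is what makes u well defined at small κ: at κ = 0 the
  axial density is uniform and u = 0.68·90° = 61.2°; for large κ, u
  approaches the Gaussian standard deviation 1/√κ.  u is strictly
  decreasing in κ.

### Density and comparison

Volume fraction is foreground/total voxels in the ROI box.  Length
density sums centreline polyline lengths clipped to the ROI (parametric
slab clipping, so partial segments contribute exactly their inside
fraction) and divides by ROI volume; lengths are carried in μm and
converted to mm-based units (mm⁻²) exactly once, at this reporting step.

Profile correlation restricts both mean-angle series to their
overlapping depth range, unwraps axial jumps larger than 90° by ±180°
continuation (profiles genuinely pass through ±90°, and the wrap
discontinuity would otherwise corrupt ρ), resamples both onto 200 evenly
spaced depths by linear interpolation, and reports Pearson's ρ.
Constant series leave ρ undefined and flagged.

Group comparison runs a one-tailed F-test (larger variance in the
numerator) for equality of variances followed by a two-tailed Welch
T-test on the means; p-values are reported at machine precision with no
multiple-testing correction.

## Synthetic phantoms

The generators define the validation conditions; they are deliberately
simple enough to have exact ground truth.

**Wall phantom.**  Two geometries: a slab (analytic frames, exact
expected angles) and a hemispherical shell (curvature, exercises the
nearest-surface machinery; outer radius 1000 μm by default).  Default
wall thicknesses 550 μm and 900 μm mirror the embryonic stages of
interest (ED9-like and ED13-like; the ED13 preset widens the outer
radius to 1400 μm).  Straight segments (length ~ N(50, 15) μm, floored
at 5 μm; radius 5 μm) are placed with midpoints uniform in the wall
below a 15 μm epicardial margin; each segment's in-tangent-plane
orientation is drawn from the bimodal von Mises law around
mean_profile(depth fraction) — default linear −30° → +80° — with
concentration κ(depth) (default constant 8; a two-level high-epi/low-endo
preset exists).  Sampling is exact: a unimodal von Mises draw flipped by
180° with probability ½.  Segments are independent; network branching
topology is not emulated (orientation statistics do not depend on it).
An optional out-of-plane tilt (default 0°) is available, since real
penetrating-vessel statistics are only qualitatively known.  A
target-length-density mode accumulates boundary-clipped segment length
until the requested mm⁻² is met.  The truth table records each segment's
depth, drawn in-plane angle, and exact helical angle.  Surfaces are
sampled at 3 μm pitch (regular grid for slabs, Fibonacci lattice for
shells, kept slightly past the equator so rim effects do not bias
near-equator queries).  Masks are rasterized separately as unions of
flat-ended cylinders so the voxelized volume of non-overlapping segments
converges to the analytic πr²L.

**Nuclei phantom.**  Per slice, 250 anti-aliased ellipses (semi-axes
6 × 1.5 μm, aspect 4:1) at orientations drawn from the bimodal law
around a depth profile (default linear −40° → +79° across the stack),
composited by maximum, plus additive Gaussian noise (σ = 0.05).  Images
are 256 × 256 px at 1.4 μm/px — an ~360 μm field of view matching the
analysis-image scale, at a resolution that keeps the FFT cheap while
leaving nuclei ~4 px wide.  The truth table records the profile value
and the realized circular mean of the drawn angles per slice.

What the phantoms do **not** emulate: branching topology, vessel
curvature, radius variation along vessels, confocal image formation
(depth-dependent attenuation, anisotropic PSF), nuclei clustering, and
any correlation between vessel and nuclei placement.  Passing the
end-to-end recovery tests therefore shows that the *measurement chain*
is correct under the assumed statistical model, not that the model
captures every property of real cleared-heart images.

All generator randomness flows from one `numpy` Generator seeded per
call; identical specs and seeds reproduce outputs bit-for-bit.

## Validation problem sizes

End-to-end checks run at desk scale: 2,000 segments on the shell phantom
(≈110 depth bins with n ≥ 30, recovered within 0.5° of the realized
window truth), 24-slice nuclei stacks (per-slice error ≤ 6°, profile
correlation ≥ 0.98), κ recovery over 100 replicates of n = 500 draws for
κ ∈ {2, 8, 32} (median within 25%), and 1,000-replicate Welch-test
calibration at n = 4 per group.  The recovery tolerance for moving-window
means is checked against the circular mean of the *realized* drawn
angles inside each window rather than the analytic profile, so the check
isolates measurement error from the phantom's own sampling noise.

## Known limitations

* The helical-angle hemisphere convention makes exactly-circumferential
  boundaries (g₃ component zero) depend on the g₂ sign tie-break; this
  affects a measure-zero set of directions.
* κ fitted from min-zero-normalized spectra has the isotropic noise
  floor described above; κ from binned samples does not subtract a
  minimum and is unaffected.
* The moving-window profile assigns whole segments to bins by midpoint
  depth; long segments spanning several windows are not apportioned.
* Wall "layers" are not segmented automatically: κ(depth) is exported
  and layer identification is left to the user.
* The surface is a point cloud, not a fitted mesh; g₁ accuracy is set by
  cloud density as described above.
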
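# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know. No number in this note
is an empirical claim beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Synthetic atrium

The geometry generator builds a parametric stand-in for a segmented left
atrium: an ellipsoidal chamber (default semi-axes 30 × 25 × 24 mm, ~75 mL —
a mildly dilated AF atrium), four pulmonary-vein tubes (radius 6 mm, length
30 mm) opening on the posterior wall, a tapered closed appendage pouch on
the anterolateral roof, and a circular mitral orifice (radius 13 mm). The
construction is mesh surgery on an icosphere: a hole is cut per feature and
a tube of morphing rings is stitched to the directed boundary loop, which
preserves orientation and manifoldness by construction. The result is
genus 0 with exactly five boundary loops (V − E + F = −3), and every
anatomical label class (six body-wall sectors plus generic body, appendage,
four PVs, mitral rim) is populated at every supported resolution
(target edge length 1–3.5 mm; finer grids first).

Standardization follows image-based CFD practice:

* **Flow extensions** — every open orifice is extruded along its mean
  outward plane normal by 10 equivalent diameters, d_eq = √(4A/π) with A
  the loop area projected on its best-fit plane. The hydraulic-diameter
  convention is an interpretation: "equivalent diameter" has no unique
  definition for non-circular orifices, and this is the standard one.
* **PV clipping** — each vein is truncated where its geodesic distance
  (multi-source Dijkstra over the PV edge subgraph, sourced at the ostium
  curve) from the ostium reaches 10 mm, accurate to one edge length.

## Mitral waveform and A-wave removal

The transmitral velocity fixture is a sum of periodic Gaussian bumps
(E-wave at 0.30 T, width 0.07 T; A-wave at 0.75 T, width 0.06 T), exactly
periodic in value and slope. AF simulations use the E-wave only: the
A-wave is spliced out by keeping every sample up to diastasis (the minimum
between the peaks) and replacing the rest of the cycle with a cubic Hermite
branch matching values and slopes at both splice points, so the waveform
stays C1 and periodic. When the single cubic would go negative or leave a
residual hump — which happens when the sampled diastasis sits on a slope,
as it does for small A-waves — the branch is rebuilt as descend/flat/rise
Hermite segments whose lengths keep each sloped segment inside the
Fritsch–Carlson monotone regime. Local maxima of a waveform are counted
with a prominence floor of 1% of the range: physiological E- and A-waves
have prominences of several percent at minimum, while splice ripple stays
well below one percent, so the floor separates them robustly.

## Flow surrogate and blood age

The Navier–Stokes stage of a patient pipeline is deliberately out of scope;
transport of a blood-age scalar needs a divergence-free, waveform-driven
velocity field, which a quasi-static potential flow provides. The capped
chamber is voxelized (interior by vertical-ray crossing parity, one ray per
grid column, jittered off vertices), PV caps become inlets (equal quarters
of the flux by default, configurable) and the mitral cap the outlet. One
discrete Laplace problem with unit outlet speed is solved directly; because
the field is linear in the driving velocity, the unit solution is scaled by
the waveform value at each time sample. Flux balance is exact by
construction and interior divergence is at direct-solver precision
(~1e-13 of the mean face speed).

Blood age solves ∂a/∂t + **u**·∇a = D∇²a + 1 by finite volumes: first-order
upwind advection, central diffusion, implicit backward Euler (the matrices
scale with the waveform, so factorizations are cached per distinct sample
value). Boundary conditions: a = 0 at inlets (Dirichlet through a half-cell
ghost), zero-gradient at the outlet, no-flux walls. These conditions and
the diffusivity are interpretations — the age-transport literature states
the source term but not D; the default D = 1 mm²/s is numerically gentle
and configurable, and is recorded in the result metadata. The scheme is
monotone, so 0 ≤ a ≤ elapsed time holds everywhere. Verified limits: pure
source integration is exact; steady 1D plug flow recovers a = x/u to the
half-cell offset (first-order upwind); the pure-diffusion steady state
matches x(L−x)/(2D) to well under 5%. The near-wall sample is a trilinear
interpolation at vertex − 1 mm × outward normal, with nearest-interior
fallback for probes that exit the interior (counted in metadata).

Desk-scale defaults for the pipeline presets are voxel spacing 3 mm, time
step 2 ms and 16 waveform samples per cycle over six cycles; the solver
operation itself defaults to the conventional 0.25 ms step and accepts any
grid. The presets are a fidelity/turnaround choice — backward Euler is
unconditionally stable, so the step size only controls temporal accuracy.

## Traction and shear indices

Two traction sources exist. The synthetic generator prescribes per-vertex
tangential square-wave signals: magnitude equal to a target TAWSS field
(exact under any periodic quadrature) and a sign pattern whose positive
fraction encodes a target OSI (oscillation/2, to 1/n_samples). The
finite-difference surrogate reads the tangential velocity one offset inside
the wall and forms τ ≈ μ u_t/δ — a first-order viscous estimate, documented
as such, not a CFD traction.

Indices use periodic trapezoidal quadrature with the first sample closing
the period. The OSI numerator uses the time-averaged mean-traction
magnitude, which makes OSI dimensionless in [0, ½] and consistent with the
RRT identity RRT · TAWSS · (1 − 2 OSI) = 1; the printed form of the
oscillatory index without the 1/T normalization is dimensionally
inconsistent and the time-averaged reading is the standard one. Vertices
with zero mean traction report RRT and ECAP as +inf behind a defined-mask:
downstream statistics must exclude them, not cap them. The WSSG operator is
read as the projection (dot product) of the surface gradient of ‖τ‖ onto
the instantaneous unit traction direction, time-averaged; a cross product
would produce a vector and contradicts a scalar, flow-aligned gradient
index. A `mode="mean-direction"` switch projects onto the time-averaged
direction instead, since the operator is genuinely ambiguous. The surface
gradient uses exact per-face linear-shape-function gradients, area-averaged
to vertices; it is exact for linear fields on flat patches and first-order
convergent on curved surfaces.

## Synthetic clinical fields and mapping

BV and IIR are generated from the TAWSS field with a calibrated copula:
standardized TAWSS values are mixed with a spatially smooth Gaussian noise
field (random Fourier features, correlation length 8 mm — clinical voltage
and enhancement maps vary over millimetres to centimetres, not per vertex)
and pushed through the empirical CDF onto the clinical ranges (BV 0.1–5 mV,
IIR 0.8–1.6), so the marginal is exactly uniform on the range. The mixing
weight is root-found so the realized correlation equals the prescribed ρ
for that realization, not merely in expectation (defaults ρ(TAWSS,BV) =
−0.4, ρ(TAWSS,IIR) = +0.3, matching the negative-BV/positive-IIR coupling
reported clinically). Using TAWSS values rather than ranks inside the mix
matters: rank transforms amplify spatial noise wherever the TAWSS marginal
concentrates, producing fields no realistic sampling density could carry.

The electroanatomical cloud samples the surface uniformly by area, carries
barycentric BV values, adds isotropic Gaussian positional jitter (default
SD 0.5 mm — catheter localization error) and applies a stored rigid pose
that registration must recover. Alignment is point-to-point ICP (SVD/Kabsch
per iteration, nearest-neighbor correspondence); transfer is RBF
interpolation with an affine polynomial tail (thin-plate default, λ = 1e-8,
seeded subsampling above 4,000 sites for cubic-cost control). Kernel and
smoothing defaults are conventions, not reproductions of any particular
clinical pipeline.

A known systematic of this chain: resampling and interpolation attenuate
the fine-scale (noise) component of a field slightly more than the
large-scale (signal) component, so the post-mapping |correlation| runs a
few hundredths above the injected ρ. At the standard problem size
(~16k vertices, 8k points) the effect stays within the parameter-recovery
tolerance; it is the main reason recovered correlations sit slightly above
their targets in magnitude.

## Unfolding and the 24-region template

After clipping, the atrium is a disk with holes. The unfolding is a
harmonic parameterization with mean-value weights: positive weights plus a
convex fixed boundary give a flip-free embedding in the classical
Tutte/Floater setting; here only the mitral rim is pinned (arc-length
proportional positions on the template perimeter, anchored at the rim
vertex nearest the septal wall, following the rim's face-induced
orientation) while PV rims and the appendage remain free natural holes.
Flip-free behavior is therefore asserted, not guaranteed, and holds on
every fixture; triangles whose 2D area is below 1e-12 of the largest
(collinear slivers on free-hole rims) are reported as degenerate rather
than flipped. Matching the template radius to mitral-rim-length/2π
demonstrably reduces area distortion and is available via
`build_template(radius=...)`.

The 24-region template is an explicit stand-in — published atlas region
outlines are not reproduced here. It is anchor-driven: one disk and one
ostial ring per PV (in the fitted variant, the convex hull of the unfolded
rim with a margin, with rings grown until they capture peri-ostial
vertices), one appendage region, and 15 body sectors (roof ×3 in the
center, a middle ring of posterior ×3 / anterior ×3 / lateral ×2 /
septal ×2, floor ×2 against the mitral perimeter). Regions are made
disjoint by sequential difference in region order, and assignment tests
regions in the same order, so shared boundaries resolve deterministically;
uncovered vertices (numerical slivers) snap to the nearest region with a
logged count. Templates serialize to JSON (WKT geometries) and are
user-replaceable.

Atlas registration is similarity ICP (Umeyama scale estimate, seeded by the
RMS-radius ratio so pure-similarity pairs resolve exactly) followed by
label-wise landmark matching of the PV ostia, appendage and mitral rim.

## Statistics

Per-case Pearson correlations (pairwise deletion of non-finite entries,
with counts), TAWSS quartiles at the empirical 25/50/75 percentiles with
boundary values assigned to the lower quartile, Kruskal–Wallis across
quartiles, fibrosis (IIR ≥ 1.2, inclusive) and scar (BV < 0.5 mV, strict)
classification, a 4×2 pooled chi-square without continuity correction, and
Fisher-z (atanh) transformation of correlation coefficients compared across
groups by Welch's two-sample t test — the comparison method is a
documented choice, as the z-transform alone does not define one. Test
selection follows the normality-driven tree: Shapiro–Wilk per group at
α = 0.05, then Levene, then ANOVA / Welch ANOVA / Kruskal–Wallis, with the
decision trail returned. Significance is two-sided 0.05 with no
multiplicity correction. Treating vertices as observations pseudo-replicates
heavily within a case; the per-case p-values should be read as descriptive,
which is why the package also reports regional summaries.

## What the synthetic data do not show

The generator fixes the correlation structure, smoothness and ranges of
the clinical fields by construction; passing recovery tests therefore
demonstrates that the pipeline preserves injected structure, not that real
atria exhibit it. The potential-flow surrogate has no inertia, no vortices
and no valve dynamics, so blood-age patterns reflect washout geometry only;
the synthetic traction prescribes its own TAWSS rather than deriving it
from flow, and the TAWSS–blood-age correlation arises solely from the
shared PV/appendage geography built into both. Wall motion is absent
(rigid-wall assumption), and the idealized geometry lacks patient-specific
features (common ostia, accessory veins, appendage lobes) that stress
registration and unfolding in practice.
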
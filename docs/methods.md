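# Methods

This note documents the models, numerical choices and limitations behind
`cectkit`, in the order data flow through the pipeline.

## Synthetic phantom

The phantom voxelizes a cylindrical osteochondral plug (default 4.0 mm
diameter; 2.0 mm cartilage on 1.0 mm bone; 40 μm isotropic voxels) in air or
fluid. The articular surface is an analytically tilted plane evaluated at
voxel centres — tilt never involves resampling, so the truth geometry is
exact and the cartilage voxel count is conserved under tilt up to a single
boundary layer. The surface plane is deliberately placed half a voxel above
the first cartilage voxel centre, the generic registration of a plane in a
voxel grid; an integer-aligned surface is a degenerate case that would hide
half-voxel depth-registration errors.

Attenuation is linear in partition,

    HU(z, t) = HU_cartilage + (A_bath / 100) · P(z, t),
    P(z, t)  = P_max · w(z) · [1 − exp(−t/τ)],

which makes the phantom the exact inverse of the pipeline's
division-by-bath partition definition. The depthwise weight `w(z)` defaults
to constant 1: only bulk uptake kinetics are reported for real tissue, and
the depth profile of nanoparticle uptake is not established, so a uniform
profile is the assumption-free choice; `w` is a free function for users who
want depth structure. Default kinetics are the cationic-particle cohort
values (P_max = 56.49 %, τ = 62.85 h); the default palette (air −1000,
fluid 0, cartilage 100, bone 2000, bath 1200 HU) is a plausible 150 kVp μCT
palette and fully configurable. Noise is additive i.i.d. Gaussian per voxel,
drawn fresh per time point from seeds spawned deterministically off the
phantom seed and recorded in the truth record.

Lesions are vertical cuts from the surface to a fraction of cartilage depth
(default 2/3): `sharp_cut` keeps its width (0.1 mm default) to full lesion
depth, `v_cut` narrows linearly from ≈0.5 mm at the surface to zero. Lesion
voxels carry fluid/bath attenuation.

What the phantom does **not** emulate: X-ray projection physics (beam
hardening, scatter, rings), partial-volume averaging beyond voxel-centre
sampling, anatomical curvature, depth-dependent native cartilage
attenuation, or spatially correlated noise. Passing tests therefore
demonstrate correctness of the analysis chain under a known forward model,
not robustness to every scanner artifact.

## Diffusion pipeline

*Surface detection.* Per image column, the first crossing of the
background/cartilage threshold (sub-voxel refined by linear interpolation)
gives a surface depth; a plane is fitted by least squares. The fit is
restricted to the central 75 % of the crossing footprint — columns near the
plug side wall cross far too deep and would otherwise dominate — followed by
one trimmed refit dropping residuals above 1.5 voxels. Detection requires
≥50 % of columns to cross and rejects fitted tilts above 45°.

*Alignment.* The volume is rotated by the estimated angles (trilinear
interpolation about the volume centre, out-of-field voxels filled with the
medium attenuation). Aligning an already-aligned volume is the exact
identity. The two small-angle rotations are composed in a fixed order; the
non-commutativity error is O(θxθy), negligible below 5°.

*Segmentation.* Three-way thresholding (background/cartilage,
cartilage/bone), then a per-column contiguity cleanup: cartilage is the run
between the first tissue voxel and the first bone voxel, and only the
largest connected cartilage component is kept. Thresholds are explicit
configuration; the phantom-palette defaults are (−500, 1000) HU.
Fluid-immersed scans in a bright contrast bath invert the fluid–cartilage
ordering and are not threshold-segmentable; the contrast measurement
accepts an externally supplied mask for that case (mirroring the manual
segmentation such scans receive in practice).

*Profiles.* The ROI is a 1.2 mm disk centred on the in-plane cartilage
centroid ("middle of the sample" made precise). Depth is normalized by the
mean cartilage thickness of the ROI columns; the per-slice ROI means are
linearly interpolated onto the fixed grid 0.5 %, 1.5 %, …, 99.5 % (always
exactly 100 points), clamped at the ends rather than extrapolated.
Subtracting the 0 h profile removes native attenuation; dividing by the
bath attenuation yields percent partition. Negative partitions are
preserved — an excluded agent plus noise legitimately produces them.

*Bulk partition* is the unweighted mean of the 100 points. Whether a bulk
figure should average the full depth or a sub-range is a reporting choice;
the full-depth mean is this package's documented convention.

Numerical behaviour on phantoms: noiseless and untilted, recovered bulk
partitions match the saturation formula to ≪0.1 % absolute (voxelization
only); with 3° tilt and 10 HU noise at 40 μm the error stays below 1 %
absolute at every time point, dominated by interpolation blending in the
one to two slices nearest the surface.

## Uptake kinetics

`P(t) = P_max[1 − exp(−t/τ)]` is fitted per sample by trust-region
nonlinear least squares (plain, unweighted loss). Initialization: `P_max`
from the last observation, τ from the first time the series exceeds 63.2 %
of it (fallback: half the window), plus two staggered restarts; τ is
bounded below at 10⁻³ h, `P_max` is unbounded in both signs. A fit with
τ > 3× the last observation time is flagged degenerate but reported
verbatim — an agent that does not enter the tissue genuinely produces such
fits, and constraining them would manufacture plausible-looking numbers.
Cohort kinetics are arithmetic means of the per-sample parameters with
t-distribution 95 % CIs (parameter averaging, not pooled fitting; the CI
method is t-based by choice, swappable for a bootstrap).

## Indentation biomechanics

All moduli use the flat-punch bonded-layer correction
`E = P(1−ν²)/(2aκw)` with ν = 0.2 for equilibrium and ν = 0.5 for
instantaneous/dynamic quantities. κ(a/h, ν) is computed, not transcribed:
the surface compliance of an elastic layer bonded to a rigid substrate,

    W(y) = [2k·sinh 2y − 4y] / [2k·cosh 2y + 4y² + k² + 1],  k = 3 − 4ν,

is exact in both limits (half-space as y→∞, confined uniaxial compression
as y→0); splitting W = 1 + G and Abel-inverting the punch's dual integral
equations gives a Fredholm equation of the second kind solved by 48-node
Gauss–Legendre Nyström quadrature, with the kernel's cosine transform
integrated to y = 30 (G decays like e^(−2y)). The resulting table
(a/h ∈ [0, 2] step 0.1; ν ∈ {0.2, 0.3, 0.4, 0.5}) is cached at first use
and queried by bilinear interpolation with no extrapolation. κ(0, ν) = 1
exactly; the thin-layer asymptote κ → (π/2)(a/h)(1−ν)²/(1−2ν) is approached
from above.

Strain bookkeeping follows the protocol: each step is 4 % of the thickness
remaining at its start, so per-step strains are 0.04 by construction and
applied strain after step i is 0.04·i. Per step, the equilibrium force is
the mean of the final 5 s of the 600 s hold (a drift of >2 % of the
equilibrium force over the last minute flags the hold as unrelaxed);
`E_eq` is the slope of equilibrium stress on strain over steps 2–4.
`E_inst` per step is the incremental ramp-end stress over the step strain,
with its strain dependence the least-squares line over steps 2–4. The
stretched exponential is fitted in the force domain per hold — with the
decay clock starting at the ramp-end peak — and (α, β) averaged over steps
2–4; β is constrained to (0, 1] and flagged when pinned at a bound. The
default generator truth (α = 60 s, β = 0.8) makes the 600 s hold ten
relaxation times long, so the final-window equilibrium read-out is
unbiased; slower materials trip the unrelaxed-hold flag instead of silently
biasing `E_eq`. Sinusoid amplitude and phase are estimated by least-squares
regression at the known drive frequency over the last 3 of 4 cycles —
four-cycle records make FFT peak-picking leakage-prone — and the phase
shift is wrapped to [0°, 90°). The 40 kPa prestress appears as a constant
force offset, removed via the pre-ramp baseline before analysis.

## Densitometry

Gray → OD is a plain linear least-squares map through the imaged filter set
(OD 0.0, 0.15, 0.3, 0.6, 1.3, 1.6, 2.0, 2.3, 2.6, 3.0), exactly as the
acquisition intends; the calibration residual is reported so users can
detect camera nonlinearity rather than having it silently absorbed. Section
rows (surface at top) are averaged, converted, standardized to the shared
100-point grid, and the three replicate sections averaged (fewer warns but
proceeds). Bulk = mean of points 1–100, superficial = mean of points 1–30;
"1–100 %" is read as grid points 1–100 inclusive, the natural
interpretation on a bin-centre grid.

## Statistics

Spearman ρ uses average ranks. The p value is exact for n ≤ 9 (full
enumeration of all permutations) and t-approximate otherwise; at the study
cohort size n = 27 the approximation operates at its nominal level (type-I
rate 0.05 ± 0.02 over 2000 replicates, verified in the test suite). CIs use
the Fisher z transform with variance 1.06/(n−3), the standard correction
for rank correlations; the construction is isolated so a bootstrap can be
substituted. Missing values are removed pairwise. No multiple-testing
correction is applied; the table reports raw p values and flags p < 0.05.

The cohort generator couples superficial/bulk PG OD, `E_eq`, `P_max`, τ and
(negatively) phase shift through a latent PG level, with coupling strengths
fixed a priori to produce rank correlations of magnitude ≈0.4–0.65 at
n = 27 — the regime the real structure–function analysis operates in. With
noise disabled every coupled pair reaches |ρ| = 1, which pins the coupling
signs independently of noise calibration.

## Pipeline and reproducibility

The CLI demo runs at 80 μm voxels to stay interactive; the acceptance
script and the end-to-end tests use the full 40 μm study resolution. Every
random draw descends from the run seed via spawned `SeedSequence`s;
identical config + seed reproduces every CSV byte for byte. Config files
are validated field by field with errors naming the dotted path; the bath
attenuation has no default because the partition definition is meaningless
without the measured value.

## Known limitations

- The phantom's forward model is the pipeline's inverse by construction;
  agreement validates the implementation, not the physical model of any
  scanner.
- Depthwise uptake truth is user-supplied; no diffusion PDE is solved, and
  no depth-resolved kinetics are fitted (bulk only).
- The lesion reading is contrast-based; no 3D lesion segmentation is
  provided.
- Hayes κ assumes a frictionless rigid punch on an isotropic elastic layer
  bonded to a rigid substrate; poroelastic or fibril-reinforced behaviour
  is outside its scope, entering only through the lumped (α, β) relaxation.
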
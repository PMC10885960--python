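# Methods

This note records the model, the numerical choices, and the calibration
behind the `xlct` package, in the spirit of a methods section: what is
computed, under which assumptions, and what the in-silico results do and
do not demonstrate.

## Forward model

Photon transport in the visible/NIR window of soft tissue is modelled by
the diffusion approximation: valid when scattering dominates absorption
(here μs′ = 10 cm⁻¹ ≫ μₐ = 0.02 cm⁻¹) and at distances beyond about one
transport length (1/μs′ = 1 mm) from sources and boundaries.  The Robin
boundary condition Φ + 2κD(ν·∇Φ) = 0 models the refractive-index mismatch
at the tissue/air interface; κ defaults to 2.52, a standard soft-tissue
value, and enters the FEM system as a boundary mass term with coefficient
1/(2κ).

The X-ray excitation is a cone-beam point source with Beer–Lambert
attenuation along the in-medium path (default μₜ = 0.2 cm⁻¹, uniform; a
nodal μₜ field is integrated numerically).  No inverse-square falloff is
applied by default (`XRayConfig.inverse_square` enables it); at the
source distances used (20 cm) the differential falloff across a 3 cm
phantom is ≈ 1.3 % and is swallowed by the normalization of the
reconstruction, which is scale-invariant throughout.  The light yield η
and source flux X(r₀) default to 1 for the same reason.

Discretization is P1 (linear) tetrahedral FEM.  The mesher is a
deterministic structured one — a ring-pattern disk triangulation extruded
in z, prisms split into three tetrahedra with index-consistent diagonals
— so identical inputs give byte-identical meshes; externally generated
meshes can be read from Gmsh MSH v2 or legacy VTK ASCII.  The sensitivity
matrix H = K⁻¹FηA is never formed by inverting K: its detector rows are
computed by one sparse adjoint solve per detector (K is symmetric), and a
column-wise construction is kept as a cross-check.

Two known P1 artifacts are documented rather than hidden: (i) nodal
fluence exactly on the boundary is a small Robin-derivative-scale
quantity and carries a few-percent mesh-pattern noise; (ii) adjoint
point-source solutions undershoot slightly (≤ ~1 % of the row maximum)
near the detector node, so H may contain small negative entries.  The
camera band excludes the end-face rim nodes (`z_margin`), whose corner
elements are the worst offenders.

## Depth compensation

Single-view measurements are hypersensitive to nodes near the camera.
Two diagonal weights counteract this:

* **W_d = diag(max(Ñ, floor)^q)** carries a rough prior Ñ, the standard
  Tikhonov reconstruction of the same data (regularized normal
  equations; α defaults to 10⁻³·tr(HᵀH)/n).  The exponent q trades data
  fit against stability; entries are floored at 10⁻⁴ of the prior
  maximum so W_d stays invertible where the prior is zero or negative.
* **W_m** is built per column from β_j = 1/|max(H_j) − min(H_j)| (levels
  the within-column dynamic range) and ‖H_j‖₂⁻¹ (levels the overall
  column strength).

A genuinely open design point is on which side of the operator W_m acts.
The pipeline applies it as a multiplicative column **gain**,
H_t = H·W_d·W_m with recovery ρ = W_d·W_m·χ — the direction in which the
weights *level* the depth falloff: on a depth-stratified sensitivity
matrix whose deep columns are ~100× weaker, the coefficient of variation
of column norms strictly decreases (the acceptance suite measures this).
The printed-formula alternative (division by W_m, selectable via
`CompensationParams.wm_role='literal'`) suppresses deep columns twice
over — once through their own small norms and once through the weight —
and demonstrably drives the solver into the near-surface shell; it is
retained only for comparison.  Both recovery conventions
(`recovery_mode='consistent'|'literal'`) are implemented; the default is
the substitution under which H·ρ = H_t·χ holds exactly.

Crucially, the weights are **recomputed on the column-reduced system at
every outer restart**.  As junk columns are pruned the Tikhonov prior
becomes better posed and W_d sharpens; with weights frozen at round 1 the
support reliably collapses to the detector-side surface.  This per-round
re-weighting is what "alleviating the ill-posedness at every outer
iteration" means operationally in this implementation.

## The restarted FPGD solver

Inner loop: accelerated proximal gradient on
f(χ) = ‖H_t χ − Φ‖² + λ‖χ‖₀ with step s = 1/(2σ_max²) (power iteration,
100 steps), Nesterov momentum t_{k+1} = (1+√(1+4t_k²))/2 started at the
t₁ = 1 convention (the t₀ = 0 extrapolation coefficient is undefined),
the hard-threshold prox (keep v_i iff v_i² ≥ 2sλ; the measure-zero tie is
kept), and a support projection of the extrapolated point.  Two readings
of the support projection are implemented: projection onto the support of
the current iterate (`support_mode='iterate'`), and a **monotone**
permissible set that shrinks as entries are thresholded and is reset at
each restart (`'monotone'`, the default).  The monotone reading is what
makes the all-ones initialization meaningful, as follows.

With χ₀ = 1 the iterate starts on a flat floor.  The transformed system
is scaled so that ‖H_t·1‖ = `floor_scale`·‖Φ‖ (default 0.2): the floor is
a mild underfit, and entries grow out of it in proportion to how much
they explain the data.  The hard threshold is anchored **at the floor**:
`threshold_floor` sets √(2sλ) in floor units, so the very first prox
removes every entry the data do not support and the survivors are
refined by the remaining iterations.  This floor-anchored λ
(λ_eff = thr²/2s) replaces an absolute λ because the measurement scale is
arbitrary; the generic `restart_outer` (fixed matrix, no re-weighting)
keeps the conventional λ·‖H_tᵀΦ‖∞ auto-scale, which is appropriate for
unit-scale systems and is what the exhaustive-search oracle tests
exercise.  Inner stopping: relative iterate change < 10⁻⁵ or 3000
iterations.  Outer loop: clamp negatives, drop zero columns, stop at
≥ 95 % zeros (counted on the full-length solution) or when a round prunes
nothing; a collapsed support raises an error suggesting a smaller
threshold.

Parameter calibration (frozen after a development study on the EED
0.23 cm scenario across seeds, before the acceptance runs): phantom
scenarios use q = 0.4, `threshold_floor` = 1.5, `floor_scale` = 0.2 —
the most robust point in its neighbourhood, prioritizing resolution (SPI
≥ 0.99 with no missed tubes across seeds).  Compact-tumour scenarios
(`make_simulation_scenario`) use q = 0.6 and `threshold_floor` = 1.05:
at 0.1–0.3 cm separations a single merged atom fits the data within the
20 dB noise, so culling must be gentler to keep both targets.  Tuning
q per study is inherent to the method (the data weight exponent is an
empirical knob by construction).

## In-silico studies

`make_two_tube_scenario(eed_cm)` builds the two-tube phantom: a 3.0 cm
diameter cylinder restricted to the 2.6 cm investigated band, μₐ = 0.02
cm⁻¹, μs′ = 10 cm⁻¹, two 0.4 cm tubes (uniform concentration 0.1,
arbitrary units) symmetric about the axis at mid-height, camera azimuth
30°, X-ray source orthogonal to the camera, white Gaussian noise at
20 dB power SNR on the boundary fluence.  Forward data are generated on
a fine mesh (edge 0.18 cm, ≈ 4300 nodes) and inverted on a coarse one
(edge 0.28 cm, ≈ 1400 nodes, the few-thousand-node scale typical of XLCT
work); the pipeline refuses identical meshes unless
`allow_inverse_crime=True`, and fine-mesh detector readings are remapped
to nearest coarse boundary nodes with averaging.
`make_simulation_scenario(eed_cm)` is the homogeneous-cylinder analog of
a small-animal study: two compact 4 mm ⌀ × 3 mm targets, same
acquisition.  It is an *analog*, not a replication — the animal anatomy
and organ-specific optical properties are external data.

Evaluation follows the tomographic-slice convention in which such
results are reported: LE in-plane on the evaluation slice, DICE between
2-D areas (reconstruction thresholded at 10 % of its maximum — a common
choice that is insensitive for near-binary L0 solutions — on a 0.025 cm
grid), SPI along the chord through the two reconstructed centers
extended to the boundary (on the closed inter-center segment the global
minimum would always equal the valley and SPI would degenerate to 1).
Full 3-D variants of all three metrics are available
(`evaluate_reconstruction`).

## What the tests show — and what they cannot

The synthetic studies emulate the acquisition geometry, optics, noise
level and discretization scale of a bench experiment, with inverse-crime
protection.  They do not emulate camera physics (lens coupling, pixel
PSF, EM gain), free-space propagation from surface to camera, real
phosphor photochemistry, or anatomical heterogeneity.  Two quantitative
consequences:

* **LE is quantized by the inverse mesh.**  Reconstructed peaks live on
  coarse-mesh nodes (spacing ≈ 2.5–2.9 mm), so sub-millimeter LE values
  are only reachable when a node happens to sit at the target center;
  the typical in-silico LE of one node offset (≈ 0.7–3 mm) is the
  resolution floor of this discretization, not of the method.
* **DICE of a sparse nodal solution is bounded well below 1.**  A
  handful of nodal hat functions cannot tile a 4 mm tube exactly; with
  the 10 % threshold the in-silico DICE plateaus around 0.15–0.6
  depending on how many in-tube nodes survive.  Physical-camera
  reconstructions with dense surface sampling can score higher.

SPI, by contrast, transfers well: the L0 solution is exactly zero
between separated targets, so resolution (SPI ≈ 1 at EED 0.23 cm, and
≥ 0.67 down to EED 0.1 cm for the compact analog) is the robust headline
result, matching the method's claim of resolving adjacent targets from a
single view.

## Numerical details and edge cases

* Tetrahedra are stored with positive signed volume; boundary faces are
  wound so right-hand normals point outward; point location uses a
  cell-bin index with ties on shared faces resolved to the lowest
  tetrahedron index.
* Degenerate W_m columns (zero range) get the median of valid entries,
  with a warning; an all-zero measurement raises immediately; a
  non-factorizable K raises rather than falling back.
* The SNR definition is the power ratio of the noiseless measurement
  vector: noise variance = mean(signal²)/10^(SNR/10).
* All randomness flows from a single scenario seed, split
  deterministically per stage (CRC-keyed `SeedSequence`), so runs are
  byte-reproducible.
* Problem sizes ship at the scale the studies were designed for
  (≈ 4300-node forward mesh, ≈ 1400-node inverse mesh, ~120 detectors);
  a full simulate–reconstruct–evaluate cycle takes a few seconds on one
  CPU.

## Known limitations

* Single-view physics: targets far from the camera (beyond the visible
  half-space or outside the detector band) are unreliable — the
  end-to-end recovery property is therefore stated for targets in the
  camera-facing band, where the recovery rate is ≥ 90 %.
* The depth compensation corrects moderate depth differences; it does
  not recover targets at extreme depth asymmetry (e.g. one target
  directly behind the other relative to the camera).
* The homogeneous-medium assumption: organ-level heterogeneity would
  require per-region optical coefficients (supported by the assembly
  only through a uniform `OpticalTissue` at present).
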
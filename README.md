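# xlct — single-view cone-beam X-ray luminescence computed tomography

Cone-beam X-ray luminescence CT (CB-XLCT) excites nanophosphor particles
inside tissue with a cone of X-rays and images the emitted visible/NIR
light with a camera, then reconstructs the 3-D phosphor distribution.
With only **one** camera view the inverse problem is severely
underdetermined and detection sensitivity drops nonlinearly with depth,
so reconstructions collapse toward the surface facing the camera.  This
package implements a reconstruction pipeline that tackles both problems
— **depth-compensated, L0-regularized, automatically restarted fast
proximal gradient descent (re-DC-FPGD)** — together with the finite-element
forward model, image-quality metrics, and an in-silico phantom generator,
so the whole chain can be exercised and tested without any measurement
hardware.

It is intended for researchers in optical/hybrid tomographic imaging who
want a self-contained, reproducible reference implementation of
single-view CB-XLCT reconstruction.

## The model

**Forward.** X-rays attenuate along lines, X(r) = X(r₀)·exp(−∫μₜ dτ);
phosphors at concentration ρ emit light S = η·X·ρ.  Light transport
follows the diffusion equation with a Robin boundary condition,

    −∇·(D∇Φ) + μₐΦ = S in Ω,   Φ + 2κD(ν·∇Φ) = 0 on ∂Ω,

with D = 1/(3(μₐ + μs′)).  P1 finite elements on a tetrahedral mesh give
K Φ = F η A ρ (K: stiffness + absorption + boundary, F: mass, A = diag of
the nodal X-ray field), and the sensitivity matrix H = K⁻¹FηA restricted
to the camera-visible boundary nodes maps concentration to the surface
measurement Φ_meas.

**Inverse.** The sparse reconstruction solves

    min ‖H W_d W χ − Φ_meas‖² + λ‖χ‖₀,

where W_d = diag(Ñ^q) carries a Tikhonov prior estimate Ñ (exponent
q ∈ [0.4, 0.8]) and the model weight built from β_j = 1/|max H_j − min H_j|
and ‖H_j‖₂⁻¹ levels the depth falloff of the sensitivity columns.  The
L0 problem is solved by FPGD — accelerated proximal gradient with
Nesterov momentum, a support projection, and the elementwise
hard-threshold prox — from an all-ones start, inside an automated
restarting loop: after each inner solve, negative entries are clamped,
the columns of zero entries are removed, the weights are recomputed on
the reduced system, and the loop stops once ≥ 95 % of the solution is
zero.

**Metrics.** Localization error LE = ‖p_r − p_t‖₂ (mm), DICE overlap
2|ROI_r ∩ ROI_t|/(|ROI_r| + |ROI_t|) on the evaluation slice, and the
spatial-resolution index SPI = (ρ_max − ρ_valley)/(ρ_max − ρ_min) along
the chord through the two reconstructed centers (1 = fully resolved,
0 = merged).

## Worked example

Two 0.4 cm phosphor tubes, 0.23 cm edge-to-edge, in a 3.0 cm scattering
cylinder (μₐ = 0.02 cm⁻¹, μs′ = 10 cm⁻¹), one 30° view, 20 dB noise;
forward data on a fine mesh, inversion on a coarser one:

```python
from xlct import make_two_tube_scenario, run_forward, run_reconstruction

scenario = make_two_tube_scenario(eed_cm=0.23, rng_seed=1)
forward = run_forward(scenario)
recon, report = run_reconstruction(scenario, forward.measurement, forward.fine_mesh)
print(recon.results.summary())
for name in ("tube1", "tube2"):
    print(f"{name}: LE = {report.le_mm[name]:.2f} mm, DICE = {report.dice[name]:.2f}")
print(f"SPI = {report.spi['tube1|tube2']:.2f}")
```

prints

```
XLCT depth-compensated re-FPGD reconstruction
==============================================
detectors (observations)                  117
unknown nodes                            1397
compensation exponent q                 0.400
hard-threshold level                      1.5
outer rounds                                1
support size                               16
sparsity (zero fraction)               0.9885
residual l2                        3.9725e-03
----------------------------------------------
round   inner   support     residual
    1    3000        16   3.9725e-03

tube1: LE = 2.88 mm, DICE = 0.15
tube2: LE = 0.65 mm, DICE = 0.53
SPI = 1.00
```

The solver keeps 16 of 1397 nodes (98.9 % zeros).  SPI = 1.00 means the
two tubes are fully separated along the chord between them; the
localization errors (0.65 and 2.88 mm) are at the scale of the inverse
mesh's node spacing (≈ 2.5 mm), i.e. each tube is recovered at or next to
the mesh node nearest its true center.  DICE compares the thresholded
reconstruction area with the true tube cross-section on the evaluation
slice; sparse nodal solutions cover the 4 mm tubes only partially, which
bounds DICE well below 1 (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
xlct pipeline scenario.yaml --outdir runs/   # simulate + reconstruct + evaluate
xlct describe scenario.yaml                  # resolved geometry
```

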
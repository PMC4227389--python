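# Methods

## Model

`tdcsim` simulates transcranial direct current stimulation (tDCS) with a
multiscale model that couples the bidomain description of excitable brain
tissue to a passive volume conductor for the rest of the head.

Inside the brain region Ω_B (grey and white matter) the intracellular and
extracellular spaces coexist as interpenetrating continua, coupled through
the cell membrane. With transmembrane voltage v = Φ_i − Φ_e and writing Φ
for the extracellular potential:

    ∇·(M_i ∇v) + ∇·(M_i ∇Φ) = χ C_m ∂v/∂t + χ I_ion        in Ω_B
    ∇·(M_i ∇v) + ∇·((M_i + M_e) ∇Φ) = 0                    in Ω_B
    ∇·(M_e ∇Φ) = 0                                          in Ω \ Ω_B

M_i and M_e are the intracellular and extracellular conductivity tensors
(M_i ≡ 0 outside the brain, which confines intracellular current to Ω_B —
the no-outflow condition n·M_i∇(v+Φ) = 0 on ∂Ω_B holds automatically in
the weak form because the intracellular integrals extend over Ω_B only).
χ is the membrane area per unit tissue volume and C_m the membrane
capacitance per unit area. Φ and the normal extracellular current are
continuous across ∂Ω_B, which a single conforming Φ field provides for
free.

Electrodes enter through scalp boundary conditions: the anode is an
inhomogeneous Neumann flux n·M∇Φ = I(x) (a uniform inward current density
summing to the electrode current; any edge concentration of current is an
outcome of the solution, not of the load), the cathode a grounded
homogeneous Dirichlet patch, and every other scalp point is insulated,
n·M∇Φ = 0.

Membrane kinetics are FitzHugh–Nagumo with physical voltages:

    ∂v/∂t = c1/v_amp² (v − v_rest)(v − v_th)(v_peak − v) − c2 w + I_app
    ∂w/∂t = b (v − v_rest − c3 w)

with v_amp = v_peak − v_rest and v_th = v_rest + a·v_amp. The cubic is
kept literally in this form (explicit 1/v_amp² prefactor) so the
coefficient values below can be read off directly. (v_rest, 0) is an exact
fixed point; the rest state is therefore preserved by the full simulator
to round-off.

The validation reference is the classical volume-conductor model of tDCS:
∇·(M∇Φ) = 0 over the whole head with the same electrode boundary
conditions and extracellular conductivities only (`laplace_ref`). Once the
coupled model's transient settles, the membrane's interior adjusts so that
intracellular gradients nearly vanish, and the coupled Φ converges to this
single-field solution; `compare_fields` reports the relative L2 difference
using P1 mass-matrix inner products.

## Numerics

Time stepping is Godunov operator splitting. Each global step Δt:

1. **Reaction.** The membrane ODEs are advanced nodewise over Δt with
   Heun's method (explicit trapezoid, order 2) in substeps Δt_ODE,
   producing the partial solution ṽ. Convergence of the integrator is
   verified empirically at slope 2.0 ± 0.2 against a fine classical
   Runge–Kutta reference.
2. **Diffusion.** One implicit-Euler step of the coupled PDEs, discretized
   in space with P1 (linear) simplicial finite elements. With
   β = Δt/(χ C_m) the symmetric block system is

        [ A  B ] [ v ]   [ α ]        A = M_B + β K_i,   B = β K_i,
        [ Bᵀ C ] [ Φ ] = [ g ],       C = β (K_i + K_e),  α = M_B ṽ,

   where M_B is the consistent mass matrix over Ω_B, K_i the stiffness
   matrix of M_i over Ω_B, K_e the stiffness of M_e over the whole domain,
   and g the β-scaled anode load. v-degrees of freedom live on nodes of
   brain elements (including interface nodes); Φ on all nodes. All
   integrals are exact for P1 (constant gradients, order-2 mass rule), so
   no quadrature tolerance exists anywhere. Element stiffness matrices are
   explicitly symmetrized (half-sum with their transpose) so the assembled
   operator is symmetric to the last bit. The recovery variable w is
   frozen through the diffusion substep.

The block system is solved with conjugate gradients under the relative
residual monitor ‖r_k‖/‖r_0‖ at tolerance 1e-8, preconditioned with the
block-diagonal operator diag(Ã⁻¹, C̃⁻¹) where each block is a relaxed
ILU(0) factorization: fill outside the sparsity pattern is dropped and ω
times the dropped value is lumped onto the diagonal (ω = 0 plain ILU(0),
ω = 1 modified ILU; default ω = 0.5). On the 10,000-element phantom the
preconditioner cuts iteration counts by roughly an order of magnitude
(e.g. 38 versus several hundred unpreconditioned); correctness of every
solve is checked against dense direct factorization on ≤500-element
meshes (relative error < 1e-6, both with and without electrodes).

Numerical safeguards and conventions:

* **Warm starts.** Each step starts CG from the previous solution. The
  convergence monitor then references ‖b‖ rather than the (near zero)
  initial residual — otherwise the relative criterion would demand
  round-off beyond machine precision. A cold start reproduces the strict
  ‖r⁰‖ definition and is used in the solver tests.
* **Singular pure-Neumann runs.** Without electrodes Φ is defined only up
  to a constant. The rhs is compatible (its Φ-block sums to zero), CG
  converges in the range space, and the reported Φ is gauged to zero
  area-weighted mean. A pivot in the incomplete factorization smaller
  than 1e-13 of its row norm is replaced by the row norm; a fully zero
  row (true breakdown) drops that block to Jacobi with a warning.
* **Dirichlet elimination.** Cathode constraints are applied by symmetric
  row/column elimination with unit diagonal, preserving exact symmetry
  (‖K − Kᵀ‖ = 0), as CG requires.
* **Degenerate inputs.** Zero-area elements, non-SPD conductivity
  tensors, non-increasing phantom radii, missing tissue entries, an anode
  without a cathode, probes that never cross threshold — all rejected
  with specific errors before any compute.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| a | 0.13 | – | threshold position: v_th = v_rest + a·v_amp = −55.7 mV |
| b | 13.0 | 1/s | recovery rate (τ_w ≈ 77 ms) |
| c1 | 260.0 | 1/s | cubic prefactor (used as c1/v_amp²) |
| c2 | 100.0 | 1/s | recovery feedback strength |
| c3 | 1.0 | – | recovery saturation |
| v_rest, v_peak | −0.070, 0.040 | V | resting / peak membrane voltage |
| χ | 1.26e5 | 1/m | membrane area per tissue volume |
| C_m | 1.0e-4 | F/m² | membrane capacitance per area |
| Δt, Δt_ODE | 1.0, 0.5 | ms | global / reaction substep |
| σ_e (skin, skull, CSF, GM, WM) | 0.465, 0.010, 1.654, 0.276, 0.126 | S/m | extracellular conductivities |
| σ_i (GM, WM) | 0.1 | S/m | intracellular conductivity |
| CG tolerance | 1e-8 | – | relative residual |
| ω | 0.5 | – | ILU relaxation |
| anode current | 1.0 | mA | per meter of depth (2D slab convention) |

2D meshes are treated as unit-depth slabs, so "1 mA" means 1 mA per meter
depth spread uniformly over the electrode arc. All coordinates are stored
in meters and all physics is SI.

## The phantom generator

`build_annulus_phantom` emulates the layered anatomy of the head as
concentric annuli: a 40 mm white-matter disc, then grey matter, CSF,
skull and scalp annuli with outer radii 50, 70, 90, 100 mm, plus a 10 mm
horizontal CSF strip through the brain that emulates CSF interwoven with
the cortex (confined to the cerebral region, radius ≤ 50 mm; the radius
is configurable). Nodes are placed on concentric rings snapped to the
tissue interfaces and triangulated with Delaunay; per-ring node counts
are kept even and ring phases alternate by half a step, which preserves
exact mirror symmetry about both axes — the property behind the
symmetric electric-potential traces at (±100, 0) mm. Ring spacing is
iterated so the element count lands within 20% of the target (default
10,000).

What the phantom does *not* emulate: real cortical geometry and folding,
anisotropic white-matter conductivity (supported by the assembly if
per-element tensors are supplied, but not generated), electrode–skin
contact impedance, and any 3D effect. The strip is tagged by element
centroid, so its boundary is staircase-shaped at mesh resolution; annulus
areas converge at better than 1% per doubling of the element budget, but
strip-adjacent tissue areas carry an O(h) tagging error. Passing tests on
this phantom show the numerics and the coupling are right; they do not
certify predictions on anatomical head models.

## Stimulus calibration and the velocity protocol

The applied current that initiates an action potential is not part of the
model proper and must be chosen. Two defaults exist:

* **Single-cell demonstration:** 5 V/s for 10 ms is the smallest round
  amplitude that drives one full-height AP (max v > 0 V) in the isolated
  membrane model.
* **Tissue experiment:** 100 V/s for 10 ms inside the 2.5 mm stimulus
  disc — the smallest 1-2-5-series value for which the surrounding tissue
  ignites and both default velocity probes register threshold crossings
  at both the quarter-scale and full-scale mesh. The isolated-cell value
  is far too weak in tissue because diffusion drains the small disc.

Conduction velocity is measured between two probes along the propagation
direction: distance divided by the difference of first *upward* threshold
crossings, each crossing time linearly interpolated between the bracketing
samples (needed for sub-sample accuracy at Δt = 1 ms). The default pair
sits at (0, −30) and (0, −35) mm — 5 and 10 mm from the stimulus center,
inside the brain, below the CSF strip. The strip severs the intracellular
continuum, so an AP started at (0, −25) mm can never reach the upper
brain half; probes must lie on the stimulated side.

## Findings and known limitations

* **Conduction is decremental under the default kinetics.** The effective
  monodomain diffusivity is D = σ/(χ C_m) ≈ 4–8×10⁻³ m²/s, and the exact
  planar bistable-front speed for this cubic, √(2 c1 D)(1/2 − a), is at
  most ≈ 0.75 m/s. With the full recovery dynamics (b = 13 /s,
  c2 = 100 /s) the pulse is not even sustained: an independent 1D
  splitting model shows it dies after ~50 mm, and on the phantom the
  excited region collapses ~11 mm from the stimulus disc once the drive
  ends (the disc is below the critical nucleation radius ~D/c). The
  default two-probe measurement reports ≈ 0.64 m/s at the full 10,000-
  element resolution. Apparent speeds up to ~2 m/s occur only within a
  few mm of the disc during the stimulus window, where spread is
  diffusion-dominated (the instantaneous diffusive spreading rate
  √(D/t) passes 2 m/s near t ≈ 2 ms). Biological conduction velocities
  of ~2 m/s therefore require either faster upstroke kinetics or a
  larger σ_i/(χ C_m) than these defaults provide; both knobs are exposed.
* **tDCS quasi-statics.** With electrodes active and no AP, Φ stabilizes
  within ~1 ms and drifts by < 0.1% of its peak thereafter; the coupled
  model's Φ agrees with the stationary volume-conductor solution to
  ~0.13% relative L2 (threshold for acceptance: 5%). Current shunts the
  resistive skull, concentrates at electrode edges, and favors the
  conductive CSF — the classical forward-model picture.
* **Scalp potentials.** AP-generated scalp potentials are ~200× weaker
  than tDCS-generated ones at full resolution (~0.1 mV vs ~20 mV); on
  very coarse meshes the lumped stimulus exaggerates the AP's far field
  and the contrast shrinks.
* The splitting is first order in Δt (measured step-halving error ratios
  1.6 → 1.9 approaching 2); Strang splitting or adaptive Δt would be the
  natural upgrades. Simulations are serial; the 1.1M-element scale of
  realistic 3D heads would want a compiled assembly path and parallel CG.
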
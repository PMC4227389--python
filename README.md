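# tdcsim

Multiscale simulation of transcranial direct current stimulation (tDCS):
the bidomain equations of excitable brain tissue, coupled to
FitzHugh–Nagumo membrane dynamics, solved together with a passive
volume-conductor model of the head — so that a single simulation yields
both the tDCS electric field *and* its effect on neuronal transmembrane
voltage.

Classical tDCS forward models solve ∇·(M∇Φ) = 0 for the head and stop at
the electric field; they cannot say what the field does to neurons. This
package targets researchers who want that missing cellular layer: inside
the brain region Ω_B the intracellular and extracellular continua coexist,

    ∇·(M_i∇v) + ∇·(M_i∇Φ)        = χC_m ∂v/∂t + χI_ion     in Ω_B,
    ∇·(M_i∇v) + ∇·((M_i+M_e)∇Φ)  = 0                        in Ω_B,
    ∇·(M_e∇Φ)                     = 0                        elsewhere,

with membrane kinetics

    ∂v/∂t = c1/v_amp² (v−v_rest)(v−v_th)(v_peak−v) − c2 w + I_app,
    ∂w/∂t = b (v − v_rest − c3 w),

anode current injection as a Neumann flux, a grounded cathode, and an
insulated scalp elsewhere. Time integration is Godunov operator splitting
(Heun reaction substeps + implicit-Euler P1 finite-element diffusion);
each step solves a symmetric 2×2 block system by conjugate gradients with
a relaxed-ILU(0) block preconditioner. Experiments run on a generated 2D
five-tissue head phantom (skin, skull, CSF, grey and white matter, with a
CSF strip through the cortex), or on any user-supplied tagged simplicial
mesh in Gmsh MSH 2.2 text format. The stationary volume-conductor model
is included as the validation reference. See `docs/methods.md` for the
full model, discretization and parameter documentation.

## Worked example

Run the first tDCS electrode configuration (anode at (−100, 0) mm,
cathode at (70.7, 70.7) mm, 10 mm electrodes, 1 mA, 100 ms) on the
10,000-element phantom, with the paired volume-conductor comparison:

```sh
tdcsim experiments run tdcs-1 --out runs/tdcs-1
```

```json
{
  "name": "tdcs-1",
  "n_elements": 10030,
  "n_nodes": 5141,
  "t_end": 0.1,
  "cg_iterations_mean": 38.16,
  "phi_max_V": 0.0200840382175256,
  "phi_min_V": 0.0,
  "ap_sensitivity_max_pct": 0.346558875192861,
  "laplace_rel_l2_final": 0.00141260982638456,
  "laplace_rel_l2_t1ms": 0.0016890370769367042,
  "laplace_rel_l2_t25ms": 0.00126474447365983,
  "laplace_rel_l2_t100ms": 0.00141260982638456
}
```

Reading the numbers: the scalp potential peaks at 20.1 mV under the
anode (the cathode is the 0 V reference); the coupled model's potential
agrees with the stationary volume-conductor solution to 0.13% relative L2
at t = 25 ms (`laplace_rel_l2_t25ms`), confirming that adding membrane
dynamics does not distort the classical tDCS field; and tDCS depolarizes
brain tissue by up to 0.35% of the rest-to-threshold distance
(`ap_sensitivity_max_pct`, the statistic
(v_rest − v)/(v_rest − v_th) × 100%). The artifact directory holds VTK
snapshots of Φ, E, |J|, v and sensitivity, probe CSVs, the config copy
and this summary.

The AP-conduction experiment (`tdcsim experiments run ap-conduction`)
initiates an action potential in a 2.5 mm disc at (0, −25) mm and reports
`conduction_velocity_m_per_s` measured between two probes 5 mm apart
along the propagation path, plus the (sub-millivolt) potentials the AP
projects to the scalp — roughly 200× weaker than the tDCS potentials.

From Python, the same machinery is explicit:

```python
import numpy as np, tdcsim as t

mesh = t.build_annulus_phantom(target_element_count=10_000)
anode = t.place_electrode(mesh, "anode", np.pi, 0.010, total_current=1e-3)
cathode = t.place_electrode(mesh, "cathode", np.pi / 4, 0.010)
res = t.run_simulation(mesh, [anode, cathode],
                       config=t.SolverConfig(t_end=0.100),
                       probes=[t.ProbeSpec("center", (0.0, 0.0), "phi")])
sens = t.ap_sensitivity(res.state.cell.v, t.FHNParams())
```

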
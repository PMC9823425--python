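# csifem

Quantitative microwave imaging for brain-stroke diagnostics: contrast
source inversion (CSI) on a curl-conforming finite-element forward model.

Microwave tomography probes the head with a ring of antennas at ~1 GHz and
reconstructs the complex permittivity `eps = eps_r - j sigma/(omega eps0)`
inside it; a haemorrhagic stroke shows up as a blood-like region
(`eps_r = 64.41`, `sigma = 1.58 S/m` at 1 GHz) against the average head
background (`eps_r = 45.37`, `sigma = 0.77 S/m`). CSI solves this
nonlinear inverse scattering problem by alternately updating the contrast
`chi = (eps - eps_b)/eps_b` and the contrast sources `w_t = chi E_t^tot`
to minimize

    F_CSI = sum_t ||d_t - G_S w_t||^2 / sum_t ||d_t||^2
          + sum_t ||chi E_t^inc - w_t + chi G_D w_t||^2 / sum_t ||chi E_t^inc||^2

where `G_D` solves the FEM-discretized wave equation
`(U - V - A) E^sct = R w` and `G_S` maps the result to the antenna data.

The package implements two discretizations of the contrast source:

* **standard** — one vector coefficient per tetrahedron,
  `w_t,i = chi(r_i) E_t(r_i)` (field frozen at the cell barycenter);
* **edge basis** — scalar coefficients on the same Whitney edge functions
  that carry the field, `w_t,(e,i) = E_t,e chi_i`. This representation is
  exactly consistent with the discretized wave equation
  (`R w_exact = (V_target - V_b) E_tot` to machine precision), so its
  wave-equation residual and exact-point cost sit at the forward-solver
  floor, orders of magnitude below the standard scheme's discretization
  error — and the inversion focuses the stroke better.

Also included: a structured tetrahedral mesher (Kuhn subdivision) with
closed-form Whitney element integrals, a first-order absorbing boundary,
dipole and TEM coaxial-port acquisition models with S-parameter algebra, a
synthetic layered-phantom scenario generator that avoids the inverse crime
(data and inversion meshes differ), residual/cost/region-statistics
diagnostics, and a sparse-LU / FFT-preconditioned-GMRES forward solver
pair (the latter handles 160k-edge structured meshes on one CPU).

## Worked example

```python
import csifem as cf

# synthetic stroke scenario: 80 mm head sphere in a 120 mm box, blood-like
# inclusion, 6 antennas; data simulated on a finer mesh than the inversion
phantom = cf.PhantomSpec(
    layers=[cf.Layer((0.06, 0.06, 0.06), (0.04, 0.04, 0.04), 45.37, 0.77)],
    domain=(0.12, 0.12, 0.12))
stroke = cf.StrokeSpec(center=(0.072, 0.06, 0.06),
                       semi_axes=(0.014, 0.012, 0.012))
acq = cf.AcquisitionSpec(n_antennas=6, ring_radius=0.05,
                         ring_center=(0.06, 0.06, 0.06),
                         data_h=0.009, inversion_h=0.012)
ds = cf.generate_dataset(phantom, stroke, acq, seed=7)

res = cf.ContrastSourceInversion(ds, variant="edge").fit(n_iter=60)
print(res.summary())
```

```
Contrast Source Inversion Results
=================================================
discretization              edge (linear)
antennas                    6
mesh cells / edges          6000 / 7930
DoI cells                   936
iterations                  60
final F_S                   4.9743e-02
final F_D                   1.3900e-02
final F_CSI                 6.3643e-02
max eps_r in DoI            46.66
max sigma in DoI (S/m)      0.835
=================================================
```

`F_S` and `F_D` are the data- and object-equation mismatch terms of the
cost functional (dimensionless, 1.0 means "as wrong as a zero source");
their monotone decrease is the convergence diagnostic
(`res.plot_convergence()`). `res.eps_r` / `res.sigma` are the per-cell
reconstructed permittivity and conductivity;
`res.region_stats(region_mask)` summarizes them inside a target region
with the detection-threshold percentages used for stroke localization.
`res.to_vtk("recon.vtk")` exports the volume for ParaView.

The same pipeline is scriptable from the shell:

```bash
csifem write-default-config --out run.yaml
csifem simulate --config run.yaml --out dataset.npz
csifem invert --config run.yaml --dataset dataset.npz --out-dir out/
csifem compare-discretizations --h 0.01 --antennas 4
```

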
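# tdcsim

Forward modeling of transcranial direct current stimulation (tDCS) on
voxelized multi-tissue head phantoms.

tDCS pushes ~1 mA of direct current through scalp electrodes; how much
electric field that induces in any given cortex — and how much it varies
between people and between electrode montages — is not measurable
directly and must be computed.  `tdcsim` is a compact, fully testable
pipeline for that computation, aimed at people studying stimulation
*dose*: solver developers who want an oracle-validated reference, and
modelers exploring how head anatomy (size, skull thickness, CSF, gyral
folding) and montage design (large pads vs a 4×1 high-definition ring)
shape the cortical field.

At its core it solves the quasi-static volume-conduction equation

    ∇·(σ∇V) = 0,   E = −∇V

on a 3-D voxel grid with a 7-point finite-volume stencil
(harmonic-mean face conductances), Jacobi-preconditioned conjugate
gradients to a relative residual of 1e−6, total injected current applied
at the anode, ground at the cathode(s), and insulated external surfaces.
Around the solver sit: parametric head phantoms (layered and gyrated
spheres with skin/skull/CSF/gray/white/air at literature conductivities),
electrode montage presets and rasterization, cortical-surface field maps
with signed inward/outward normal components, comparison metrics (peak
cortical EF, fold variation, ring containment), dose normalization by
current rescaling, and an independent multilayer-sphere Legendre-series
solution used as an analytic oracle.

## Worked example

```python
import tdcsim as t

# a head phantom: 80 mm outer radius; skin 6, skull 5, CSF 3, gray 4 mm
spec = t.SphereSpec(80, {"skin": 6, "skull": 5, "csf": 3, "gray": 4}, voxel_mm=2.0)
head = t.make_layered_sphere_phantom(spec)

# two 50x50 mm sponge pads (motor-cortex anode, supraorbital cathode), 1 mA
montage = t.preset_pad_m1_so(head)
potential, report, raster, sigma = t.solve_montage(head, montage)
print(report.per_electrode_current_A)

efield = t.gradient_to_efield(potential, head)
cmap = t.normal_component_map(efield, t.extract_cortical_surface(head))
peak = t.peak_cortical_ef(cmap)
print(peak.peak_V_per_m)
```

which prints (electrode current audit, then peak cortical field):

```
{'anode_m1': 0.0009999999802145789, 'cathode_so': -0.0009999999802892214}
0.35720833854849143
```

The audit recovers the injected ±1 mA to ~1e−8 relative — current is
conserved through the solve — and the peak cortical field magnitude is
0.357 V/m, the right physiological scale for 1 mA tDCS (published
subject-specific models put it at a few tenths of a V/m, varying
~1.5–3-fold between individuals).  `examples/` contains one short script
per capability: phantom construction, the pad solve above, pad-vs-ring
focality, oracle validation, and a three-subject dose-normalization
study.

## What the pieces are

| module | contents |
| --- | --- |
| `tdcsim.phantoms` | layered/gyrated sphere and slab label volumes |
| `tdcsim.conductivity` | tissue conductivity table, label→σ volumes |
| `tdcsim.montage` | electrode presets (pad, 4×1 ring), scalp rasterization |
| `tdcsim.solver` | finite-volume assembly, CG solve, current audit |
| `tdcsim.fields` | E = −∇V, cortical surface, normal-component maps |
| `tdcsim.metrics` | peak EF, fold variation, containment, dose normalization |
| `tdcsim.oracle` | analytic N-layer sphere series solution |
| `tdcsim.validation` | solver-vs-oracle comparison runner |
| `tdcsim.study` | multi-subject × multi-montage driver with caching |
| `tdcsim.nifti_io` | NIfTI-1 I/O with label-code sidecars |

See `docs/methods.md` for the model, the numerical choices (including
the conductor-conductivity cap and the measured staircase discretization
bias of voxel grids against the analytic sphere), and what phantom
results do and do not say about real heads.

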
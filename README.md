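# porespeed

Through-transmission ultrasound velocimetry in skull-mimicking porous
digital phantoms.

Transcranial focused ultrasound must focus a beam through bone whose
microstructure — marrow pores below the resolution of clinical CT — changes
the effective speed of sound.  `porespeed` provides a tested, desk-scale
pipeline to quantify that effect: it generates digital phantoms of cortical
bone with randomly placed overlapping spherical marrow pores (single pore
diameter, uniform porosity), propagates pulsed or continuous plane waves
through them with a first-order k-space pseudospectral solver for
heterogeneous lossy fluids, and estimates the composite velocity a
through-transmission measurement would report.

The velocity estimate is the substitution method: a transmitted signal is
compared against a water-only reference over the same path and the delay
Δt converts to velocity via

    V = C_w / (1 + C_w Δt / d)

with water speed C_w = 1500 m/s and phantom thickness d = 8 mm.  Δt comes
from the envelope cross-correlation peak (group velocity V_g), from the
unwrapped Fourier phase difference at the carrier (phase velocity V_P), or
from post-transient peak timing of a continuous wave (steady-state phase
ϕ_s).  An independent analytic transfer-matrix model of layered lossy
fluids cross-checks the solver and estimators on transversely uniform
problems.

## Worked example

Group velocity through a scaled 2-D phantom (0.3 mm pores, 25 % porosity)
at 500 kHz:

```python
from porespeed import (PhantomSpec, generate_phantom, assign_properties,
                       run_case, velocity_field)

phantom = generate_phantom(PhantomSpec(
    pore_diameter=0.3, target_porosity=0.25, extent=(3.2, 8.0),
    rng_seed=1, porosity_tolerance=0.02))
medium = assign_properties(phantom, 500e3)
record, reference, time = run_case(medium, 500e3, duration=16e-6)
ref_trace = reference.pressure.reshape(-1, reference.pressure.shape[-1])[0]
field = velocity_field(record.pressure, ref_trace, record.dt, 500e3,
                       method="group")
print(f"V_g = {field.mean:.0f} +/- {field.std:.0f} m/s")
```

prints

```
V_g = 2330 +/- 50 m/s
```

— the plane-averaged group velocity and its spatial standard deviation over
the measurement plane.  Repeating with 0.1 mm pores at the same porosity
gives `V_g = 2839 +/- 18 m/s`: finer microstructure transmits faster and
more uniformly, which is the package's central observable.  The same
`record` yields the phase velocity with `method="phase"`, and continuous
runs (`kind="continuous"`) yield the steady-state phase.

A CLI mirrors the library (`porespeed phantom`, `sim`, `measure`, `sweep`,
`converge`, `report`); see `porespeed --help`.

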
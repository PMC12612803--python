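# Methods

## Problem and model

`porespeed` simulates through-transmission ultrasound measurements through
digital phantoms of porous cranial bone and estimates the composite sound
speed a measurement would report.  The phantoms are blocks of cortical bone
containing spherical red-marrow pores of a single diameter, placed at
uniformly random positions (overlap allowed) until a target marrow volume
fraction — the porosity — is reached.  Wave propagation is linear acoustics
in a heterogeneous lossy fluid; shear waves, mode conversion, poroelastic
coupling and nonlinearity are deliberately out of scope, which is a
reasonable approximation for normally incident plane waves on fluid-like
marrow/bone mixtures and keeps the microstructural signal isolated.

The measurement emulated is the substitution method: a plane wave is
transmitted along z through 0.5 mm of water, the 8 mm phantom, and 2.3 mm of
water; the pressure time series is recorded at every pixel of the last
transverse plane and compared against a water-only reference over the same
path.  The arrival-time difference Δt converts to a composite velocity via

    V = C_w / (1 + C_w Δt / d),

with C_w = 1500 m/s and d = 8 mm.  Three estimators of Δt are provided:

* **Group delay** — lag of the peak of the normalized cross-correlation
  between the Hilbert envelopes of signal and reference.  Robust to waveform
  distortion; the peak value itself quantifies envelope distortion.
* **Phase delay** — both records are zero-padded to 4x their length, Fourier
  transformed, and the per-bin phase of `reference x conj(signal)` is
  unwrapped outward by accumulating adjacent-bin increments wrapped into
  (−π, π].  Δt = Δφ(f_c)/(2π f_c) at the discrete bin nearest the carrier.
* **Steady-state phase** — for continuous sources, the timing of the first
  signal peak after 90 % of the run duration relative to the reference peak,
  expressed in radians and wrapped to [0, 2π).

All estimators use the full recorded signal, never a windowed ballistic
portion.  Reflections from pores and from the slab faces therefore
contribute to the estimates; this is intentional and is why even a
homogeneous bone-only slab yields frequency-dependent phase velocities
(3280–3583 m/s over 250 kHz–1 MHz) below the material speed of 3514 m/s.

## Materials

| material      | c (m/s) | attenuation at 1 MHz (Np/m) | ρ (kg/m³) |
|---------------|---------|------------------------------|-----------|
| water         | 1500    | 0                            | 1000      |
| red marrow    | 1450    | 12.55                        | 1029      |
| cortical bone | 3514    | 54.55                        | 1908      |

Absorption follows a frequency power law with the exponent fixed at 2, the
single value at which the Kramers–Kronig dispersion term vanishes, making
every constituent dispersionless (any dispersion that appears is then an
emergent effect of the microstructure).  The tabulated values are treated as
linear-law coefficients defined at 1 MHz; the quadratic pre-factor is
re-anchored per run by dividing by the source center frequency in MHz, so
the two laws agree exactly at the carrier.

## Numerical scheme

The solver integrates the first-order linear equations (momentum, mass,
pressure with the exponent-2 loss term) with spectral spatial derivatives on
staggered grids, the k-space temporal correction `sinc(c_ref |k| Δt/2)`
evaluated at the reference speed c_ref = 1450 m/s (the slowest material,
minimizing numerical dispersion), and leapfrog time stepping.  Key choices:

* **Grid** — 0.05 mm isotropic voxels; z is the propagation axis; transverse
  axes are periodic so a uniform plane source stays planar.  At 1 MHz this
  gives 29 points per wavelength in the slowest material.
* **Time step** — Δt = CFL·Δx/c_max with c_max the cortical speed
  (3514 m/s), since the stability bound is governed by the fastest medium.
  The CFL per source frequency is 0.024 / 0.035 / 0.06 / 0.08 for 250 / 500 /
  750 / 1000 kHz; halving it changes measured velocities by well under 0.01 %
  in the audited cases.
* **PML** — 20 voxels at each z end, 2.0 Np/voxel at the outer edge,
  split-field exponential damping with a quartic ramp (the ramp shape is a
  design choice; the convergence and uniformity contracts bound its
  influence).
* **Smoothing** — property maps and the source plane are low-passed by
  multiplying their spectra with a separable Blackman window whose value is
  exactly 1 at DC (mean-preserving) and 0 at Nyquist.  Medium maps are
  smoothed without peak restoration; the source apodization with it.
* **Source** — additive mass-rate injection at one z plane, scaled by
  Δt so the emitted amplitude is discretization-independent; amplitude is
  arbitrary in this linear setting and cancels in all estimators because the
  signal and reference share the injection dialect.
* **Durations** — 20 µs for single-cycle pulses (covers the slowest
  arrivals), 80 µs for continuous sources (steady state; doubling it moves
  the steady-state phase by ≤ 0.01 % in the audited 1-D case).

The same stepping code serves 1-D/2-D/3-D.  At transverse spatial frequency
zero every operator reduces to its 1-D form, so a transversely uniform 3-D
problem reproduces the 1-D run to near machine precision — verified at
1e-6 relative tolerance and used to run transverse-uniform cases (bone-only
slabs, water references) in 1-D.

The discrete energy pairing successive pressures with the staggered
velocity, E = Σ pⁿpⁿ⁺¹/(2ρ₀c²) + Σ ½ρ₀u², is conserved to machine precision
in lossless periodic runs, and a continuous plane wave in a homogeneous
lossy medium decays as exp(−α(f)z) to better than 1 %.

## Analytic cross-check

An independent transfer-matrix model computes normal-incidence transmission
through planar layered fluids between water half-spaces, with the same
exponent-2 complex wavenumber and the same water-path referencing as the
substitution method.  It is implemented by the recursive (Airy) formulation,
which uses only decaying exponentials and therefore remains finite for
arbitrarily lossy layers.  Discretizing a solver run's smoothed 1-D property
profile into thin layers lets the analytic model consume the *identical*
medium; on the bone-only slab the two pathways agree within 0.2 % at all
four frequencies.

## Phantom generator

Pore centers are drawn uniformly over the phantom extent from a seeded,
per-phantom random stream; spheres are voxelized by strict inequality on
voxel centers, clipped at the faces (no wrap-around), and carved until the
marrow fraction first reaches the target.  Porosity is always recomputable
as the marrow voxel count over the total.  The attainable precision is set
by the single-pore volume quantum: the default tolerance of 0.005 suits the
full 12.8 × 12.8 × 8 mm phantom, while the scaled 2-D domains used in the
test suite (2.4–3.2 mm transverse) need ~0.02–0.03 for the largest
(0.6 mm) pores.  What the generator does *not* emulate: depth-dependent
porosity, distinct cortical tables and diploë, anisotropy, and polydisperse
or non-spherical pores — so agreement on these phantoms demonstrates
microstructure sensitivity of the measurement, not fidelity to any real
skull.

## Problem sizes

Full-scale 3-D runs (256 × 256 × 216 voxels, ~40 000 steps) are supported
but take hours per case on one core; the package's own test and acceptance
profiles use the equivalences above instead: bone-only and water cases in
1-D (identical to transverse-uniform 3-D), and microstructure trends on 2-D
phantoms with 2.4 mm transverse extent, 12–20 µs records, and three seeds
per cell.  2-D pores are disks, not spheres, so 2-D magnitudes are not
comparable to 3-D ones; the monotone trends (velocity decreasing with
porosity, non-increasing with pore diameter) are the scaled observables.

## Numerical details and edge cases

* Phase unwrapping is anchored at the first non-DC bin: a small rectified
  offset in a recorded trace flips the DC angle to π and would otherwise
  shift the whole unwrapped curve by π.
* Steady-state peaks are refined by three-point parabolic interpolation (a
  sinusoid's peak is locally parabolic).  The correlation lag uses the
  discrete argmax by default: at Δt ≈ 0.5 ns sampling the quantization is a
  sub-0.1 % effect, while the envelope correlation peak is flat enough that
  parabolic refinement mostly amplifies envelope-tail asymmetry; refinement
  remains switchable on both.
* Plane statistics use the population (n) denominator.
* The carrier bin is the nearest discrete frequency after 4x padding; with
  20 µs records the padded resolution is 12.5 kHz and every study frequency
  falls exactly on a bin.
* Smoothed absorption maps are clipped at zero (Blackman ringing must not
  create gain).
* The steady-state phase histogram uses 2π/16 bins; the Goodman criterion
  is recorded as passed when ≥ 95 % of the probability mass falls within
  two adjacent bins (2π/8).

## Known limitations

Fluid-only physics (no shear or Biot waves), normal incidence only,
single-diameter overlapping spheres, uniform porosity, no CT-derived
property mapping.  The phase-velocity estimator's sensitivity to reflections
means its absolute values are method-specific; comparisons should use a
consistent estimator, as done throughout.
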
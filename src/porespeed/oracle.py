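"""Analytic transmission through planar layered lossy fluids.

Independent forward model used to validate the wave solver and the
velocimetry estimators on transversely uniform problems: normal-incidence
transmission through a stack of homogeneous fluid layers between water
half-spaces, computed with the standard 2x2 acoustic transfer-matrix method.

Each layer carries a complex wavenumber ``k = 2 pi f / c - i alpha(f)`` with
the same exponent-2 absorption law as the solver (``alpha = a0 * f_MHz**2``),
and time convention ``exp(+i w t)`` so forward propagation over x multiplies
a spectrum by ``exp(-i k x)``.  Transmission is referenced against an
all-water path of the same total length — exactly the reference convention of
the substitution method — so synthesized signals can be compared directly
against a water-only reference trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .medium import WATER, MaterialProps

__all__ = ["Layer", "layered_transmission", "layered_reflection",
           "synthesize_received_signal", "oracle_signal_pair",
           "layers_from_profile"]


@dataclass(frozen=True)
class Layer:
    """One homogeneous fluid layer of a planar stack."""

    sound_speed: float  # m/s
    density: float  # kg/m^3
    absorption_prefactor: float  # Np/m/MHz^2
    thickness: float  # m

    def __post_init__(self) -> None:
        if min(self.sound_speed, self.density, self.thickness) <= 0:
            raise ValueError("sound_speed, density and thickness must be positive")
        if self.absorption_prefactor < 0:
            raise ValueError("absorption_prefactor must be non-negative")

    @classmethod
    def from_material(cls, material: MaterialProps, thickness: float,
                      center_frequency: float) -> "Layer":
        from .medium import absorption_prefactor as _pref
        return cls(material.sound_speed, material.density,
                   _pref(material.attenuation_at_1mhz, center_frequency),
                   thickness)


def _transfer(layers: tuple[Layer, ...], frequency: np.ndarray):
    """Complex pressure transmission and reflection between water half-spaces.

    Vectorized over frequency; transmission is *relative to an equal-length
    all-water path* and T(0) = 1 by convention.  Computed by the recursive
    (Airy summation) formulation, which involves only decaying exponentials
    ``exp(-i k d)`` and therefore stays finite for arbitrarily lossy layers,
    unlike the naive cos/sin transfer-matrix product.
    """
    f = np.atleast_1d(np.asarray(frequency, dtype=float))
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    w = 2 * np.pi * f
    z_w = WATER.density * WATER.sound_speed
    # per-layer impedance and one-way propagation factor (|phi| <= 1)
    zs = [z_w] + [lay.density * lay.sound_speed for lay in layers] + [z_w]
    phis = []
    total_d = 0.0
    for lay in layers:
        alpha = lay.absorption_prefactor * (f / 1e6) ** 2  # Np/m
        k = w / lay.sound_speed - 1j * alpha
        phis.append(np.exp(-1j * k * lay.thickness))
        total_d += lay.thickness
    # recurse from the back half-space toward the front face
    R = np.zeros_like(f, dtype=complex)  # looking into the back water
    T = np.ones_like(f, dtype=complex)
    for j in range(len(layers), -1, -1):
        za, zb = zs[j], zs[j + 1]
        r_ab = (zb - za) / (zb + za)
        t_ab, t_ba = 1 + r_ab, 1 - r_ab
        if j < len(layers):  # response seen across layer j+1's thickness
            phi = phis[j]
            R = R * phi * phi
            T = T * phi
        denom = 1 + r_ab * R  # r_ba = -r_ab
        R = r_ab + t_ab * t_ba * R / denom
        T = t_ab * T / denom
    t_abs, r = T, R
    k_w = w / WATER.sound_speed
    t_rel = t_abs * np.exp(1j * k_w * total_d)  # reference: equal water path
    zero = f == 0.0
    t_rel[zero] = 1.0
    r[zero] = 0.0
    return t_rel, r


def layered_transmission(layers, frequency):
    """Pressure transmission coefficient(s), water-path referenced.

    Scalar in, scalar out; array in, array out.
    """
    layers = tuple(layers)
    t, _ = _transfer(layers, frequency)
    if np.isscalar(frequency) or np.ndim(frequency) == 0:
        return complex(t[0])
    return t


def layered_reflection(layers, frequency):
    """Pressure reflection coefficient(s) at the front face."""
    layers = tuple(layers)
    _, r = _transfer(layers, frequency)
    if np.isscalar(frequency) or np.ndim(frequency) == 0:
        return complex(r[0])
    return r


def synthesize_received_signal(source: np.ndarray, dt: float, layers) -> np.ndarray:
    """Analytic received trace: source filtered by the stack's transmission.

    Multiplies the source's (real-input) spectrum by the water-referenced
    transmission per frequency bin and inverse-transforms, yielding the
    signal a through-transmission measurement would record relative to the
    water-only reference, for a transversely uniform problem.  The source
    series is used at its own length (callers pad if they need room for
    slower-than-water arrivals).
    """
    source = np.asarray(source, dtype=float)
    n = source.shape[-1]
    f = sfft.rfftfreq(n, d=dt)
    t_rel, _ = _transfer(tuple(layers), f)
    return sfft.irfft(sfft.rfft(source) * t_rel, n=n)


def layers_from_profile(sound_speed: np.ndarray, density: np.ndarray,
                        absorption_prefactor: np.ndarray,
                        voxel_size: float) -> list[Layer]:
    """One thin layer per voxel of a 1-D property profile along z.

    Lets the analytic model consume the *same* (for example Blackman
    smoothed) property profile a solver run uses, so the two transmission
    pathways model identical media.
    """
    return [Layer(float(c), float(rho), max(float(a), 0.0), voxel_size)
            for c, rho, a in zip(np.asarray(sound_speed, float).ravel(),
                                 np.asarray(density, float).ravel(),
                                 np.asarray(absorption_prefactor, float).ravel())]


def oracle_signal_pair(
    source: np.ndarray, dt: float, layers, pre_delay: float
) -> tuple[np.ndarray, np.ndarray]:
    """(received, reference) pair mimicking a through-transmission record.

    The reference is the source delayed by ``pre_delay`` seconds (an exact
    spectral delay, emulating the water travel time to the measurement
    plane); the received trace is that reference filtered by the stack's
    water-referenced transmission.  ``pre_delay`` must exceed the largest
    arrival-time advance through the stack so that faster-than-water signals
    do not wrap around the circular time window.
    """
    source = np.asarray(source, dtype=float)
    n = source.shape[-1]
    f = sfft.rfftfreq(n, d=dt)
    shift = np.exp(-2j * np.pi * f * pre_delay)
    ref_spec = sfft.rfft(source) * shift
    t_rel, _ = _transfer(tuple(layers), f)
    return sfft.irfft(ref_spec * t_rel, n=n), sfft.irfft(ref_spec, n=n)
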
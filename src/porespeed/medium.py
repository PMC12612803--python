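"""Acoustic property maps for the through-transmission geometry.

Turns a labeled phantom into co-registered grids of sound speed, density and
power-law absorption pre-factor, embedded between a front and a back water
layer along the propagation (z) axis.  The absorption convention is a
frequency power law with exponent fixed at 2,

    alpha(f) = a0 * f_MHz**2   [Np/m],

which makes every constituent material dispersionless (the power-law
dispersion term required by the Kramers-Kronig relation vanishes at exponent
2).  Because the tabulated attenuation values are linear-in-frequency numbers
defined at 1 MHz, the pre-factor is re-anchored at each source center
frequency by dividing by that frequency in MHz, so the quadratic law agrees
with the linear law exactly at the carrier.

Property grids are optionally smoothed by multiplying their discrete Fourier
spectrum with a separable Blackman window, the standard anti-aliasing step
for pseudospectral propagation through staircased media.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .phantoms import CORTICAL, MARROW, PhantomVolume

__all__ = [
    "MaterialProps",
    "WATER",
    "RED_MARROW",
    "CORTICAL_BONE",
    "MediumMaps",
    "absorption_prefactor",
    "assign_properties",
    "smooth_field",
    "NP_TO_DB",
]

#: Conversion constant, dB per neper (interoperability only).
NP_TO_DB = 8.685889638065035


@dataclass(frozen=True)
class MaterialProps:
    """Bulk acoustic constants of one constituent material.

    ``attenuation_at_1mhz`` is the linear-law attenuation coefficient in Np/m
    at 1 MHz.
    """

    name: str
    sound_speed: float  # m/s
    attenuation_at_1mhz: float  # Np/m
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound speed and density must be positive")
        if self.attenuation_at_1mhz < 0:
            raise ValueError("attenuation must be non-negative")


WATER = MaterialProps("water", 1500.0, 0.0, 1000.0)
RED_MARROW = MaterialProps("red_marrow", 1450.0, 12.55, 1029.0)
CORTICAL_BONE = MaterialProps("cortical_bone", 3514.0, 54.55, 1908.0)

#: Exponent of the absorption power law.  Only 2 is supported: it is the one
#: value at which the materials are dispersion-free.
POWER_LAW_EXPONENT = 2.0


@dataclass
class MediumMaps:
    """Co-registered acoustic property grids on the simulation interior.

    The z (propagation) axis is the last array axis.  ``absorption_prefactor``
    is in Np * m^-1 * MHz^-2 (exponent-2 convention, anchored at the source
    center frequency).
    """

    sound_speed: np.ndarray  # m/s
    density: np.ndarray  # kg/m^3
    absorption_prefactor: np.ndarray  # Np/m/MHz^2
    voxel_size: float  # m
    power_law_exponent: float = POWER_LAW_EXPONENT

    def __post_init__(self) -> None:
        if not (self.sound_speed.shape == self.density.shape
                == self.absorption_prefactor.shape):
            raise ValueError("property maps must share one grid")

    @property
    def c_min(self) -> float:
        return float(self.sound_speed.min())

    @property
    def c_max(self) -> float:
        return float(self.sound_speed.max())

    @property
    def ndim(self) -> int:
        return self.sound_speed.ndim

    def smoothed(self) -> "MediumMaps":
        """All three property maps Blackman-smoothed (peak not restored)."""
        return MediumMaps(
            sound_speed=smooth_field(self.sound_speed),
            density=smooth_field(self.density),
            absorption_prefactor=smooth_field(self.absorption_prefactor),
            voxel_size=self.voxel_size,
            power_law_exponent=self.power_law_exponent,
        )


def absorption_prefactor(
    attenuation_at_1mhz: float,
    center_frequency: float,
    exponent: float = POWER_LAW_EXPONENT,
) -> float:
    """Exponent-2 power-law pre-factor anchored at the carrier frequency.

    Returns ``a0`` such that ``a0 * f_MHz**2`` equals the linear law
    ``attenuation_at_1mhz * f_MHz`` exactly at ``f = center_frequency``;
    i.e. ``a0 = attenuation_at_1mhz / f_c[MHz]``.
    """
    if exponent != POWER_LAW_EXPONENT:
        raise ValueError("only the dispersionless exponent y = 2 is supported")
    if center_frequency <= 0:
        raise ValueError("center frequency must be positive")
    return attenuation_at_1mhz / (center_frequency / 1e6)


def assign_properties(
    phantom: PhantomVolume,
    center_frequency: float,
    front_water: float = 0.5e-3,
    back_water: float = 2.3e-3,
    pore_material: MaterialProps = RED_MARROW,
    background_material: MaterialProps = CORTICAL_BONE,
    water: MaterialProps = WATER,
) -> MediumMaps:
    """Embed a phantom between water layers and assign material constants.

    ``front_water`` and ``back_water`` are thicknesses in meters along z.
    The default geometry (0.5 mm front, 8 mm phantom, 2.3 mm back at 0.05 mm
    voxels) yields a 216-voxel propagation axis with the phantom occupying
    z-indices [10, 170).  Before any smoothing every voxel carries exactly
    one material's constants.
    """
    dx = phantom.spec.voxel_size * 1e-3  # mm -> m
    n_front = front_water / dx
    n_back = back_water / dx
    if abs(n_front - round(n_front)) > 1e-9 or abs(n_back - round(n_back)) > 1e-9:
        raise ValueError("water layer thickness must be an integer number of voxels")
    n_front, n_back = int(round(n_front)), int(round(n_back))

    labels = phantom.labels
    nz = labels.shape[-1] + n_front + n_back
    shape = labels.shape[:-1] + (nz,)
    mats = (water, background_material, pore_material)
    pre = {m.name: absorption_prefactor(m.attenuation_at_1mhz, center_frequency)
           for m in mats}

    c = np.full(shape, water.sound_speed)
    rho = np.full(shape, water.density)
    a0 = np.full(shape, pre[water.name])
    sl = (Ellipsis, slice(n_front, n_front + labels.shape[-1]))
    bone = labels == CORTICAL
    marrow = labels == MARROW
    c[sl] = np.where(bone, background_material.sound_speed,
                     np.where(marrow, pore_material.sound_speed, water.sound_speed))
    rho[sl] = np.where(bone, background_material.density,
                       np.where(marrow, pore_material.density, water.density))
    a0[sl] = np.where(bone, pre[background_material.name],
                      np.where(marrow, pre[pore_material.name], pre[water.name]))
    return MediumMaps(c, rho, a0, voxel_size=dx)


def _blackman_spectral_window(n: int) -> np.ndarray:
    """Blackman taper as a function of (signed) DFT frequency index.

    Exactly 1 at DC and 0 at the Nyquist frequency, so smoothing preserves
    the grid mean.
    """
    if n == 1:
        return np.ones(1)
    x = sfft.fftfreq(n) * 2.0  # in [-1, 1)
    return 0.42 + 0.5 * np.cos(np.pi * x) + 0.08 * np.cos(2 * np.pi * x)


def smooth_field(grid: np.ndarray, restore_peak: bool = False) -> np.ndarray:
    """Low-pass a grid by Blackman-windowing its Fourier spectrum.

    The window is separable (one Blackman factor per axis) and centered on
    DC, so a constant grid is left unchanged and the mean is conserved.  With
    ``restore_peak`` the output is rescaled so its maximum magnitude matches
    the input's (used for source planes, where amplitude matters).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    spec = sfft.fftn(grid)
    for ax, n in enumerate(grid.shape):
        w = _blackman_spectral_window(n)
        spec *= w.reshape([-1 if a == ax else 1 for a in range(grid.ndim)])
    out = sfft.ifftn(spec).real
    if restore_peak:
        peak_in = np.abs(grid).max()
        peak_out = np.abs(out).max()
        if peak_out > 0:
            out *= peak_in / peak_out
    return out
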
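"""First-order k-space pseudospectral solver for linear lossy acoustics.

Integrates the coupled first-order equations of linear acoustics in a
heterogeneous fluid,

    du/dt   = -(1/rho0) grad p            (momentum)
    drho/dt = -rho0 div u                 (mass)
    p       = c0^2 (rho + tau drho/dt)    (pressure, exponent-2 absorption)

with spectral spatial gradients on staggered grids and the k-space temporal
correction ``sinc(c_ref |k| dt / 2)`` evaluated at a fixed reference sound
speed.  The absorption power-law exponent is fixed at 2, for which the
fractional-Laplacian loss operator reduces to a plain time derivative
(``tau = 2 a0 c0`` with ``a0`` in Np s^2 / m) and the dispersion term is
identically zero, so the constituent materials are dispersion-free.

Geometry convention: the propagation (z) axis is the *last* array axis.  A
split-field PML with a quartic absorption ramp caps both z ends; transverse
axes are periodic, so a uniform plane source remains a plane wave.  The same
stepping code serves 1-D, 2-D and 3-D grids, and a transversely uniform 3-D
problem reproduces the corresponding 1-D run exactly (at transverse spatial
frequency zero every operator reduces to its 1-D form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .medium import WATER, MediumMaps, smooth_field

__all__ = [
    "SimGrid",
    "SourceSpec",
    "TimeParams",
    "FieldRecord",
    "derive_time_params",
    "make_source_signal",
    "water_medium",
    "run_simulation",
    "run_reference",
    "KSpaceSimulation",
]

#: Reference sound speed for the k-space correction: the slowest constituent
#: (red marrow), which minimizes non-physical numerical dispersion.
DEFAULT_C_REF = 1450.0


@dataclass(frozen=True)
class SimGrid:
    """Simulation grid: interior voxel counts plus PML configuration.

    ``dims`` are the *interior* per-axis voxel counts (z last).  The PML is
    added externally to both z ends; transverse axes are periodic and carry
    no PML.
    """

    voxel_size: float  # m
    dims: tuple[int, ...]
    pml_thickness: int = 20  # voxels, each z end
    pml_absorption: float = 2.0  # Np per voxel at the outer edge

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.dims) not in (1, 2, 3):
            raise ValueError("1-D, 2-D or 3-D grids only")
        if self.pml_thickness < 0:
            raise ValueError("pml_thickness must be non-negative")

    @property
    def ndim(self) -> int:
        return len(self.dims)


@dataclass(frozen=True)
class SourceSpec:
    """Plane-wave excitation injected at one interior z plane."""

    kind: str  # "single_cycle_pulse" | "continuous"
    center_frequency: float  # Hz
    source_plane_index: int = 0  # interior z index
    amplitude: float = 1.0  # Pa, arbitrary in the linear regime

    def __post_init__(self) -> None:
        if self.kind not in ("single_cycle_pulse", "continuous"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")


@dataclass(frozen=True)
class TimeParams:
    """Time discretization derived from a CFL number."""

    cfl: float
    dt: float  # s
    n_steps: int
    duration: float  # s
    reference_sound_speed: float = DEFAULT_C_REF


@dataclass
class FieldRecord:
    """Pressure time series over the measurement plane.

    ``pressure`` has shape ``transverse_dims + (n_steps,)`` — a single trace
    in 1-D, a line of traces in 2-D, a full plane in 3-D.
    """

    pressure: np.ndarray
    dt: float
    center_frequency: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.pressure.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def derive_time_params(
    cfl: float,
    voxel_size: float,
    c_max: float,
    duration: float,
    reference_sound_speed: float = DEFAULT_C_REF,
) -> TimeParams:
    """Time step from the CFL condition against the fastest medium.

    ``dt = cfl * dx / c_max`` and ``n_steps = ceil(duration / dt)``.
    """
    if not 0 < cfl < 1:
        raise ValueError(f"CFL must lie in (0, 1) for stability, got {cfl}")
    if c_max <= 0 or voxel_size <= 0 or duration <= 0:
        raise ValueError("voxel_size, c_max and duration must be positive")
    dt = cfl * voxel_size / c_max
    return TimeParams(
        cfl=cfl,
        dt=dt,
        n_steps=math.ceil(duration / dt),
        duration=duration,
        reference_sound_speed=reference_sound_speed,
    )


def make_source_signal(kind: str, center_frequency: float, time: TimeParams) -> np.ndarray:
    """Unit-amplitude source waveform sampled on the simulation time grid.

    ``single_cycle_pulse`` is exactly one period of ``sin(2 pi f t)`` followed
    by zeros; ``continuous`` is the sinusoid over the whole duration.
    """
    t = np.arange(time.n_steps) * time.dt
    s = np.sin(2 * np.pi * center_frequency * t)
    if kind == "single_cycle_pulse":
        s[t >= 1.0 / center_frequency] = 0.0
    elif kind != "continuous":
        raise ValueError(f"unknown source kind {kind!r}")
    return s


def water_medium(dims: tuple[int, ...], voxel_size: float) -> MediumMaps:
    """Homogeneous water property maps on the given interior grid."""
    shape = tuple(dims)
    return MediumMaps(
        sound_speed=np.full(shape, WATER.sound_speed),
        density=np.full(shape, WATER.density),
        absorption_prefactor=np.zeros(shape),
        voxel_size=voxel_size,
    )


class InstabilityError(RuntimeError):
    """Raised when the field becomes non-finite during time stepping."""


def _quartic_pml_profile(nz_total: int, pml: int, pml_np_per_voxel: float,
                         c_ref: float, dx: float, staggered: bool) -> np.ndarray:
    """Absorption rate sigma(z) in 1/s: quartic ramp over each z-end PML.

    Scaled so a wave crossing the layer at ``c_ref`` accumulates
    ``pml_np_per_voxel`` nepers per voxel at the outer edge.
    """
    sigma = np.zeros(nz_total)
    if pml == 0:
        return sigma
    z = np.arange(nz_total) + (0.5 if staggered else 0.0)
    left = pml - z  # depth into the left PML, in voxels
    right = z - (nz_total - 1 - pml)
    depth = np.maximum.reduce([left, right, np.zeros(nz_total)])
    sigma = pml_np_per_voxel * c_ref / dx * (depth / pml) ** 4
    return sigma


class KSpaceSimulation:
    """Stateful k-space time stepper; drive via :meth:`step` or :meth:`run`.

    Exposes the instantaneous split-field state (``p``, ``u``, ``rho``) for
    diagnostics such as energy audits.  ``medium`` holds the *interior* maps;
    the PML region is filled by edge replication along z.
    """

    def __init__(
        self,
        medium: MediumMaps,
        grid: SimGrid,
        time: TimeParams,
        source: SourceSpec | None = None,
        source_signal: np.ndarray | None = None,
        smooth_medium: bool = True,
        smooth_source: bool = True,
        initial_pressure: np.ndarray | None = None,
    ):
        if medium.sound_speed.shape != tuple(grid.dims):
            raise ValueError("medium maps do not match grid dims")
        self.grid = grid
        self.time = time
        self.source = source
        ndim = grid.ndim
        pml = grid.pml_thickness
        dx = grid.voxel_size
        dt = time.dt

        maps = medium.smoothed() if smooth_medium else medium
        pad = [(0, 0)] * (ndim - 1) + [(pml, pml)]
        c0 = np.pad(maps.sound_speed, pad, mode="edge")
        rho0 = np.pad(maps.density, pad, mode="edge")
        a_pref = np.pad(maps.absorption_prefactor, pad, mode="edge")
        a_pref = np.clip(a_pref, 0.0, None)  # smoothing ringing must not gain

        self.shape = c0.shape
        self.c0sq = c0 ** 2
        self.rho0 = rho0
        # absorption: p = c0^2 rho + c0^2 tau drho/dt, tau = 2 a0 c0,
        # a0 in Np s^2/m (power-law prefactor converted from per-MHz^2)
        a0_si = a_pref / (2 * np.pi * 1e6) ** 2
        self._loss = 2.0 * a0_si * c0 ** 3 * rho0
        self._lossless = not np.any(self._loss)

        # staggered densities (forward average; periodic wrap is benign:
        # both z ends sit in water)
        self.rho0_sg = [0.5 * (rho0 + np.roll(rho0, -1, axis=ax))
                        for ax in range(ndim)]

        # spectral operators on the rfft half-spectrum (real z-last layout)
        ks = [2 * np.pi * sfft.fftfreq(n, d=dx) for n in self.shape[:-1]]
        ks.append(2 * np.pi * sfft.rfftfreq(self.shape[-1], d=dx))
        kgrids = np.meshgrid(*ks, indexing="ij", sparse=True)
        k_mag = np.sqrt(sum(kg ** 2 for kg in kgrids))
        c_ref = time.reference_sound_speed
        kappa = np.sinc(c_ref * k_mag * dt / (2 * np.pi))
        self._grad_op = []
        self._div_op = []
        for ax in range(ndim):
            kax = kgrids[ax]
            shift = np.exp(1j * kax * dx / 2.0)
            self._grad_op.append(kappa * (1j * kax) * shift)
            self._div_op.append(kappa * (1j * kax) / shift)

        # PML damping factors (z axis only), applied twice per update
        nz = self.shape[-1]
        sig = _quartic_pml_profile(nz, pml, grid.pml_absorption, c_ref, dx, False)
        sig_sg = _quartic_pml_profile(nz, pml, grid.pml_absorption, c_ref, dx, True)
        bshape = (1,) * (ndim - 1) + (nz,)
        self._pml = np.exp(-sig * dt / 2).reshape(bshape)
        self._pml_sg = np.exp(-sig_sg * dt / 2).reshape(bshape)
        self._has_pml = pml > 0

        # state
        self.u = [np.zeros(self.shape) for _ in range(ndim)]
        self.rho = [np.zeros(self.shape) for _ in range(ndim)]
        if initial_pressure is not None:
            p0 = np.asarray(initial_pressure, dtype=float)
            if p0.shape != tuple(grid.dims):
                raise ValueError("initial_pressure does not match grid dims")
            p0 = np.pad(p0, pad, mode="constant")
            for ax in range(ndim):
                self.rho[ax] += p0 / (ndim * self.c0sq)
        self.p = sum(self.rho) * self.c0sq

        # source bookkeeping
        self._signal = None
        if source is not None:
            if source_signal is None:
                source_signal = make_source_signal(
                    source.kind, source.center_frequency, time)
            self._signal = source.amplitude * np.asarray(source_signal, float)
            if not 0 <= source.source_plane_index < grid.dims[-1]:
                raise ValueError("source plane outside interior grid")
            self._src_z = pml + source.source_plane_index
            # transverse apodization of the plane source (uniform by default,
            # smoothed with peak restoration; a constant plane is unchanged)
            apod = np.ones(self.shape[:-1]) if ndim > 1 else np.array(1.0)
            if smooth_source and ndim > 1:
                apod = smooth_field(apod, restore_peak=True)
            csq_plane = self.c0sq[..., self._src_z]
            # mass-rate injection: pressure added per step ~ s(t)*c_ref*dt/dx,
            # independent of dt in the continuum limit
            self._src_scale = apod * (c_ref * dt / dx) / (ndim * csq_plane)

        self._measure_z = pml + grid.dims[-1] - 1
        self._step_index = 0

    @property
    def measurement_plane_index(self) -> int:
        """Total-grid z index of the last interior transverse plane."""
        return self._measure_z

    def step(self) -> None:
        """Advance the field state by one time step."""
        dt = self.time.dt
        ndim = len(self.shape)
        P = sfft.rfftn(self.p)
        zax = ndim - 1
        for ax in range(ndim):
            dp = sfft.irfftn(self._grad_op[ax] * P, s=self.shape)
            if ax == zax and self._has_pml:
                self.u[ax] = self._pml_sg * (
                    self._pml_sg * self.u[ax] - dt / self.rho0_sg[ax] * dp)
            else:
                self.u[ax] -= dt / self.rho0_sg[ax] * dp
        div = None
        for ax in range(ndim):
            du = sfft.irfftn(self._div_op[ax] * sfft.rfftn(self.u[ax]),
                             s=self.shape)
            if ax == zax and self._has_pml:
                self.rho[ax] = self._pml * (
                    self._pml * self.rho[ax] - dt * self.rho0 * du)
            else:
                self.rho[ax] -= dt * self.rho0 * du
            div = du if div is None else div + du
        n = self._step_index
        if self._signal is not None and n < self._signal.shape[0]:
            inject = self._src_scale * self._signal[n]
            for ax in range(ndim):
                self.rho[ax][..., self._src_z] += inject
        self.p = self.c0sq * sum(self.rho)
        if not self._lossless:
            self.p -= self._loss * div
        self._step_index += 1
        if self._step_index % 2000 == 0 and not np.isfinite(
                self.p[..., self._measure_z]).all():
            raise InstabilityError(
                f"non-finite pressure at step {self._step_index}")

    def run(self, record_plane: bool = True) -> np.ndarray | None:
        """Step through ``n_steps``, recording the measurement plane."""
        n_steps = self.time.n_steps
        if not record_plane:
            for _ in range(n_steps):
                self.step()
            return None
        out = np.empty(self.shape[:-1] + (n_steps,))
        for i in range(n_steps):
            self.step()
            out[..., i] = self.p[..., self._measure_z]
        if not np.isfinite(out[..., -1]).all():
            raise InstabilityError(f"non-finite pressure at step {n_steps}")
        return out


def run_simulation(
    medium: MediumMaps,
    grid: SimGrid,
    source: SourceSpec,
    time: TimeParams,
    smooth_medium: bool = True,
    smooth_source: bool = True,
    metadata: dict | None = None,
) -> FieldRecord:
    """Propagate a plane source through ``medium`` and record the last plane.

    The pressure time series is recorded at every pixel of the last interior
    transverse plane (just before the back PML).  Fully deterministic.
    """
    sim = KSpaceSimulation(
        medium, grid, time, source,
        smooth_medium=smooth_medium, smooth_source=smooth_source,
    )
    pressure = sim.run()
    meta = {"cfl": time.cfl, "kind": source.kind,
            "n_steps": time.n_steps, "dims": tuple(grid.dims)}
    if metadata:
        meta.update(metadata)
    return FieldRecord(
        pressure=pressure,
        dt=time.dt,
        center_frequency=source.center_frequency,
        metadata=meta,
    )


def run_reference(
    grid: SimGrid,
    source: SourceSpec,
    time: TimeParams,
    smooth_source: bool = True,
) -> FieldRecord:
    """Water-only reference run on the same grid, source and time stepping.

    For a plane source in water the recorded pressure is spatially uniform
    across the plane, so the reference reduces to a single trace usable at
    every pixel.
    """
    medium = water_medium(grid.dims, grid.voxel_size)
    rec = run_simulation(medium, grid, source, time,
                         smooth_medium=False, smooth_source=smooth_source,
                         metadata={"reference": True})
    return rec
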
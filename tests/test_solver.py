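"""k-space solver: discretization contracts, physics oracles, reductions."""

import dataclasses

import numpy as np
import pytest

from porespeed.medium import MediumMaps
from porespeed.solver import (KSpaceSimulation, SimGrid, SourceSpec,
                              derive_time_params, make_source_signal,
                              run_reference, run_simulation, water_medium)

DX = 0.05e-3


class TestTimeParams:
    def test_dt_from_cfl(self):
        t = derive_time_params(0.035, DX, 3514.0, 20e-6)
        assert t.dt == pytest.approx(0.035 * DX / 3514.0)
        assert t.dt == pytest.approx(4.98e-10, rel=1e-3)
        assert t.n_steps == int(np.ceil(20e-6 / t.dt))
        assert t.n_steps * t.dt >= 20e-6

    @pytest.mark.parametrize("cfl", [1.0, 1.5, 0.0, -0.1])
    def test_unstable_cfl_rejected(self, cfl):
        with pytest.raises(ValueError):
            derive_time_params(cfl, DX, 3514.0, 20e-6)


class TestSourceSignal:
    def test_single_cycle_support(self):
        t = derive_time_params(0.1, DX, 1500.0, 5e-6)
        s = make_source_signal("single_cycle_pulse", 5e5, t)
        times = np.arange(t.n_steps) * t.dt
        assert np.all(s[times >= 2e-6] == 0.0)
        assert np.any(s[times < 2e-6] != 0.0)

    def test_continuous_quarter_period_value(self):
        # dt chosen so t = 0.5 us falls on a sample
        t = dataclasses.replace(
            derive_time_params(0.1, DX, 1500.0, 5e-6),
            dt=0.05e-6, n_steps=100)
        s = make_source_signal("continuous", 5e5, t)
        assert s[10] == pytest.approx(np.sin(np.pi / 2))

    def test_single_cycle_integrates_to_zero(self):
        t = derive_time_params(0.1, DX, 1500.0, 5e-6)
        s = make_source_signal("single_cycle_pulse", 5e5, t)
        assert abs(np.sum(s) / np.max(np.abs(s))) < 1e-8


@pytest.fixture(scope="module")
def short_time():
    return derive_time_params(0.2, DX, 3514.0, 1.2e-6)


class TestRunSimulation:
    def test_linearity_in_source_amplitude(self, slab_profile_1d, short_time):
        grid = SimGrid(DX, slab_profile_1d.sound_speed.shape,
                       pml_thickness=10)
        rec1 = run_simulation(slab_profile_1d, grid,
                              SourceSpec("single_cycle_pulse", 1e6),
                              short_time)
        rec2 = run_simulation(slab_profile_1d, grid,
                              SourceSpec("single_cycle_pulse", 1e6,
                                         amplitude=2.0),
                              short_time)
        np.testing.assert_allclose(rec2.pressure, 2.0 * rec1.pressure,
                                   rtol=1e-12)

    def test_3d_transverse_uniform_reduces_to_1d(self, slab_profile_1d,
                                                 short_time):
        m1 = slab_profile_1d
        nz = m1.sound_speed.shape[0]
        m3 = MediumMaps(
            np.broadcast_to(m1.sound_speed, (16, 16, nz)).copy(),
            np.broadcast_to(m1.density, (16, 16, nz)).copy(),
            np.broadcast_to(m1.absorption_prefactor, (16, 16, nz)).copy(),
            voxel_size=DX)
        src = SourceSpec("single_cycle_pulse", 1e6)
        r1 = run_simulation(m1, SimGrid(DX, (nz,), pml_thickness=10),
                            src, short_time)
        r3 = run_simulation(m3, SimGrid(DX, (16, 16, nz), pml_thickness=10),
                            src, short_time)
        scale = np.abs(r1.pressure).max()
        err = np.abs(r3.pressure - r1.pressure[None, None, :]).max() / scale
        assert err < 1e-6

    def test_water_propagation_speed(self):
        # two grid lengths; envelope-lag difference isolates 10 mm of water
        from porespeed.velocimetry import group_delay

        src = SourceSpec("single_cycle_pulse", 5e5)
        t = derive_time_params(0.035, DX, 3514.0, 18e-6)
        recs = {n: run_reference(SimGrid(DX, (n,)), src, t)
                for n in (216, 416)}
        lag = group_delay(recs[416].pressure, recs[216].pressure, t.dt).delta_t
        c = 200 * DX / lag
        assert abs(c - 1500.0) / 1500.0 < 1e-3


class TestRunReference:
    def test_plane_uniformity(self):
        t = derive_time_params(0.06, DX, 3514.0, 2e-6)
        rec = run_reference(SimGrid(DX, (24, 64)),
                            SourceSpec("single_cycle_pulse", 7.5e5), t)
        peak = np.abs(rec.pressure).max()
        assert rec.pressure.std(axis=0).max() <= 1e-10 * peak

    def test_frequency_changes_reference(self):
        t = derive_time_params(0.06, DX, 3514.0, 2e-6)
        grid = SimGrid(DX, (64,))
        a = run_reference(grid, SourceSpec("single_cycle_pulse", 2.5e5), t)
        b = run_reference(grid, SourceSpec("single_cycle_pulse", 5e5), t)
        assert not np.allclose(a.pressure, b.pressure)


class TestPhysicsInvariants:
    def test_energy_conservation_lossless_periodic(self):
        # discrete energy (p^n p^{n+1} pairing, staggered u) is conserved
        n = 128
        medium = water_medium((n,), DX)
        grid = SimGrid(DX, (n,), pml_thickness=0)
        t = dataclasses.replace(
            derive_time_params(0.3, DX, 1500.0, 1e-9,
                               reference_sound_speed=1500.0),
            n_steps=1000)
        z = (np.arange(n) + 0.5) * DX
        p0 = np.exp(-(((z - n / 2 * DX) / (6 * DX)) ** 2))
        sim = KSpaceSimulation(medium, grid, t, initial_pressure=p0,
                               smooth_medium=False)
        rho0, c2 = sim.rho0, sim.c0sq
        p_prev = sim.p.copy()
        energies = []
        for _ in range(1000):
            sim.step()
            kin = sum(np.sum(0.5 * r0 * u * u)
                      for r0, u in zip(sim.rho0_sg, sim.u))
            energies.append(np.sum(p_prev * sim.p / (2 * rho0 * c2)) + kin)
            p_prev = sim.p.copy()
        energies = np.asarray(energies)
        assert np.ptp(energies) / energies[0] < 1e-3

    def test_plane_wave_attenuation_matches_power_law(self):
        # continuous wave in a homogeneous lossy medium decays as exp(-alpha z)
        n, pml = 400, 20
        a_pref = 50.0  # Np/m/MHz^2 -> 12.5 Np/m at 500 kHz
        medium = MediumMaps(np.full(n, 1500.0), np.full(n, 1000.0),
                            np.full(n, a_pref), voxel_size=DX)
        grid = SimGrid(DX, (n,), pml_thickness=pml)
        t = derive_time_params(0.1, DX, 1500.0, 25e-6,
                               reference_sound_speed=1500.0)
        sim = KSpaceSimulation(medium, grid, t,
                               SourceSpec("continuous", 5e5),
                               smooth_medium=False)
        sim.run(record_plane=False)
        n_period = int(round(1 / 5e5 / t.dt))
        amps = np.zeros((n_period, n))
        for i in range(n_period):
            sim.step()
            amps[i] = sim.p[pml:-pml]
        profile = amps.max(axis=0)
        i0, i1 = 100, 300
        alpha = -np.polyfit(np.arange(i0, i1) * DX,
                            np.log(profile[i0:i1]), 1)[0]
        expected = a_pref * 0.5 ** 2
        assert abs(alpha - expected) / expected < 0.01


def test_mismatched_medium_and_grid_rejected(slab_profile_1d, short_time):
    with pytest.raises(ValueError):
        run_simulation(slab_profile_1d, SimGrid(DX, (32,)),
                       SourceSpec("single_cycle_pulse", 1e6), short_time)
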
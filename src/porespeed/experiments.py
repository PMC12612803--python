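"""Experiment orchestration: sweeps, convergence tests and reports.

Drives the full factorial study — pore diameters x porosities x frequencies
x source kinds — through the phantom generator, medium builder, solver and
velocimetry, producing one tidy result row per (phantom, frequency, method).
Water-only references are cached per (frequency, kind, grid) since they are
independent of the phantom.  Completed cells are skipped on re-runs by a
content hash recorded next to the result table.

Also implements the two numerical convergence audits used to qualify the
solver settings: halving the CFL number (time-step refinement) and doubling
the continuous-source duration (steady-state attainment).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .medium import CORTICAL_BONE, MediumMaps, assign_properties
from .phantoms import PhantomSpec, generate_phantom
from .solver import (DEFAULT_C_REF, FieldRecord, SimGrid, SourceSpec,
                     TimeParams, derive_time_params, run_reference,
                     run_simulation)
from .velocimetry import (PhaseField, phase_histogram, steady_state_phase,
                          velocity_field)

__all__ = [
    "CFL_BY_FREQUENCY",
    "SweepConfig",
    "run_case",
    "run_sweep",
    "bone_slab_medium",
    "bone_only_velocity",
    "cfl_convergence_test",
    "duration_convergence_test",
    "make_report",
]

#: Stability-qualified CFL number per source center frequency.
CFL_BY_FREQUENCY = {250e3: 0.024, 500e3: 0.035, 750e3: 0.06, 1e6: 0.08}

#: Simulation durations per source kind (s).
DURATION_BY_KIND = {"single_cycle_pulse": 20e-6, "continuous": 80e-6}

PHANTOM_THICKNESS = 8e-3  # m
FRONT_WATER = 0.5e-3  # m
BACK_WATER = 2.3e-3  # m


def default_cfl(frequency: float) -> float:
    try:
        return CFL_BY_FREQUENCY[frequency]
    except KeyError:
        raise KeyError(
            f"no CFL configured for {frequency} Hz; supply one explicitly")


@dataclass
class SweepConfig:
    """Configuration of a factorial through-transmission sweep.

    Lengths are mm in the config (matching the phantom generator) and
    converted internally.  ``transverse_extent_mm`` applies per transverse
    axis; 1-D sweeps have none.
    """

    pore_diameters_mm: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.6)
    porosities: tuple[float, ...] = (0.025, 0.05, 0.1, 0.15, 0.2, 0.25,
                                     0.3, 0.4, 0.5, 0.65, 0.8)
    frequencies: tuple[float, ...] = (250e3, 500e3, 750e3, 1e6)
    source_kinds: tuple[str, ...] = ("single_cycle_pulse",)
    methods: tuple[str, ...] = ("group", "phase")
    dimensionality: int = 3
    transverse_extent_mm: float = 12.8
    voxel_size_mm: float = 0.05
    seeds: tuple[int, ...] = (0,)
    cfl_by_frequency: dict = field(default_factory=lambda: dict(CFL_BY_FREQUENCY))
    durations_by_kind: dict = field(default_factory=lambda: dict(DURATION_BY_KIND))
    porosity_tolerance: float = 0.005
    output_root: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("pore_diameters_mm", "porosities", "frequencies",
                    "source_kinds", "methods", "seeds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cfl_by_frequency" in raw:
            raw["cfl_by_frequency"] = {float(k): v for k, v
                                       in raw["cfl_by_frequency"].items()}
        if "durations_by_kind" in raw:
            raw["durations_by_kind"] = dict(raw["durations_by_kind"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def phantom_extent_mm(self) -> tuple[float, ...]:
        t = (self.transverse_extent_mm,) * (self.dimensionality - 1)
        return t + (PHANTOM_THICKNESS * 1e3,)


def make_grid(medium: MediumMaps, pml_thickness: int = 20,
              pml_absorption: float = 2.0) -> SimGrid:
    return SimGrid(voxel_size=medium.voxel_size,
                   dims=medium.sound_speed.shape,
                   pml_thickness=pml_thickness,
                   pml_absorption=pml_absorption)


def run_case(
    medium: MediumMaps,
    frequency: float,
    kind: str = "single_cycle_pulse",
    cfl: float | None = None,
    duration: float | None = None,
    reference: FieldRecord | None = None,
    pml_thickness: int = 20,
) -> tuple[FieldRecord, FieldRecord, TimeParams]:
    """One simulation plus (possibly cached) water reference.

    The time step is derived from the CFL against the *material* maximum
    sound speed (cortical bone when present); the water reference reuses the
    identical time stepping so the two records share ``dt``.
    """
    if cfl is None:
        cfl = default_cfl(frequency)
    if duration is None:
        duration = DURATION_BY_KIND[kind]
    grid = make_grid(medium, pml_thickness=pml_thickness)
    c_max = max(medium.c_max, CORTICAL_BONE.sound_speed)
    time = derive_time_params(cfl, medium.voxel_size, c_max, duration)
    source = SourceSpec(kind=kind, center_frequency=frequency)
    if reference is None:
        reference = run_reference(grid, source, time)
    elif reference.dt != time.dt or reference.n_samples != time.n_steps:
        raise ValueError("supplied reference has mismatched time stepping")
    record = run_simulation(medium, grid, source, time)
    return record, reference, time


def _reference_trace(reference: FieldRecord) -> np.ndarray:
    """Collapse a (uniform) reference record to a single trace."""
    press = reference.pressure
    return press.reshape(-1, press.shape[-1])[0]


def _measure_cell(record: FieldRecord, reference: FieldRecord,
                  method: str, frequency: float, duration: float) -> dict:
    ref = _reference_trace(reference)
    if method == "steady_state_phase":
        flat = record.pressure.reshape(-1, record.pressure.shape[-1])
        phases = np.array([
            steady_state_phase(tr, ref, record.dt, frequency, duration)
            for tr in flat])
        fld = PhaseField(values=phases.reshape(record.pressure.shape[:-1]),
                         center_frequency=frequency)
        return {"mean": fld.mean, "std": fld.std, "field": fld}
    fld = velocity_field(record.pressure, ref, record.dt, frequency,
                         method=method, thickness=PHANTOM_THICKNESS)
    row = {"mean": fld.mean, "std": fld.std, "field": fld}
    if method == "group":
        from .velocimetry import group_delay
        flat = record.pressure.reshape(-1, record.pressure.shape[-1])
        row["peak_correlation"] = float(np.mean(
            [group_delay(tr, ref, record.dt).peak_correlation for tr in flat]))
    return row


def run_sweep(config: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial sweep; returns one row per cell and method.

    With ``config.output_root`` set, rows are appended to
    ``results.csv`` as they complete and previously completed cells are
    skipped on re-runs (guarded by a config hash; resuming under a different
    configuration is refused).
    """
    out_dir = Path(config.output_root) if config.output_root else None
    done: set[tuple] = set()
    csv_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        hash_path = out_dir / "config_hash.txt"
        if hash_path.exists():
            if hash_path.read_text().strip() != config.config_hash():
                raise RuntimeError(
                    "output_root holds results for a different configuration")
        else:
            hash_path.write_text(config.config_hash())
        csv_path = out_dir / "results.csv"
        if csv_path.exists():
            prev = pd.read_csv(csv_path)
            done = {tuple(r) for r in prev[
                ["pore_diameter_mm", "porosity_target", "frequency",
                 "source_kind", "seed", "method"]].itertuples(index=False)}

    ref_cache: dict[tuple, FieldRecord] = {}
    rows: list[dict] = []
    for d_mm in config.pore_diameters_mm:
        for phi in config.porosities:
            for seed in config.seeds:
                spec = PhantomSpec(
                    pore_diameter=d_mm, target_porosity=phi,
                    extent=config.phantom_extent_mm(),
                    voxel_size=config.voxel_size_mm, rng_seed=seed,
                    porosity_tolerance=config.porosity_tolerance)
                phantom = None
                for freq in config.frequencies:
                    for kind in config.source_kinds:
                        methods = (config.methods
                                   if kind == "single_cycle_pulse"
                                   else ("steady_state_phase",))
                        todo = [m for m in methods
                                if (d_mm, phi, freq, kind, seed, m) not in done]
                        if not todo:
                            continue
                        if phantom is None:
                            phantom = generate_phantom(spec)
                        medium = assign_properties(
                            phantom, freq,
                            front_water=FRONT_WATER, back_water=BACK_WATER)
                        cfl = config.cfl_by_frequency[freq]
                        duration = config.durations_by_kind[kind]
                        ref_key = (freq, kind, cfl, duration,
                                   medium.sound_speed.shape)
                        record, reference, _ = run_case(
                            medium, freq, kind=kind, cfl=cfl,
                            duration=duration,
                            reference=ref_cache.get(ref_key))
                        ref_cache[ref_key] = reference
                        for method in todo:
                            m = _measure_cell(record, reference, method,
                                              freq, duration)
                            row = {
                                "pore_diameter_mm": d_mm,
                                "porosity_target": phi,
                                "porosity_achieved": phantom.achieved_porosity,
                                "frequency": freq,
                                "source_kind": kind,
                                "seed": seed,
                                "method": method,
                                "mean": m["mean"],
                                "std": m["std"],
                                "peak_correlation": m.get("peak_correlation"),
                            }
                            rows.append(row)
                            if csv_path is not None:
                                pd.DataFrame([row]).to_csv(
                                    csv_path, mode="a", index=False,
                                    header=not csv_path.exists())
                        if progress:
                            print(f"done d={d_mm} phi={phi} f={freq} "
                                  f"{kind} seed={seed}")
    table = pd.DataFrame(rows)
    if csv_path is not None and csv_path.exists():
        table = pd.read_csv(csv_path)
    return table


def bone_slab_medium(frequency: float, transverse_voxels: tuple[int, ...] = (),
                     voxel_size_mm: float = 0.05) -> MediumMaps:
    """All-cortical 8 mm slab with the standard water padding (0 % porosity)."""
    extent_mm = tuple(v * voxel_size_mm for v in transverse_voxels) + (
        PHANTOM_THICKNESS * 1e3,)
    spec = PhantomSpec(pore_diameter=2 * voxel_size_mm, target_porosity=0.0,
                       extent=extent_mm, voxel_size=voxel_size_mm)
    phantom = generate_phantom(spec)
    return assign_properties(phantom, frequency,
                             front_water=FRONT_WATER, back_water=BACK_WATER)


def bone_only_velocity(frequency: float, method: str = "phase",
                       cfl: float | None = None,
                       duration: float = 20e-6) -> float:
    """Full-pipeline composite velocity through the bone-only slab (1-D)."""
    medium = bone_slab_medium(frequency)
    record, reference, _ = run_case(medium, frequency, cfl=cfl,
                                    duration=duration)
    fld = velocity_field(record.pressure, _reference_trace(reference),
                         record.dt, frequency, method=method,
                         thickness=PHANTOM_THICKNESS)
    return fld.mean


def cfl_convergence_test(medium: MediumMaps, frequency: float,
                         cfl: float | None = None, factor: float = 2.0,
                         methods: tuple[str, ...] = ("group", "phase"),
                         duration: float = 20e-6) -> dict[str, float]:
    """Average percentage velocity change when the CFL is divided by ``factor``.

    Returns ``{method: mean over plane of 100 * |V_fine - V_coarse| / V_fine}``.
    """
    if cfl is None:
        cfl = default_cfl(frequency)
    results = {}
    for label, c in (("coarse", cfl), ("fine", cfl / factor)):
        record, reference, _ = run_case(medium, frequency, cfl=c,
                                        duration=duration)
        ref = _reference_trace(reference)
        results[label] = {
            m: velocity_field(record.pressure, ref, record.dt, frequency,
                              method=m, thickness=PHANTOM_THICKNESS).values
            for m in methods}
    return {m: float(np.mean(
        100.0 * np.abs(results["fine"][m] - results["coarse"][m])
        / results["fine"][m])) for m in methods}


def duration_convergence_test(medium: MediumMaps, frequency: float,
                              cfl: float | None = None,
                              duration: float = 80e-6,
                              factor: float = 2.0) -> float:
    """Max percentage change in steady-state phase when the run is lengthened.

    Runs the continuous-wave case at ``duration`` and ``factor * duration``
    and returns the maximum percentage difference of the per-pixel
    steady-state phase across the measurement plane.
    """
    phases = []
    for dur in (duration, factor * duration):
        record, reference, _ = run_case(medium, frequency,
                                        kind="continuous", cfl=cfl,
                                        duration=dur)
        m = _measure_cell(record, reference, "steady_state_phase",
                          frequency, dur)
        phases.append(m["field"].values)
    base, doubled = phases
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(doubled - base) / np.abs(base)
    return float(np.max(pct))


def make_report(table: pd.DataFrame, out_dir: str | Path,
                phase_fields: dict | None = None) -> dict:
    """Velocity-porosity figures and summary files from a sweep table.

    Writes ``velocity_vs_porosity_<method>.svg`` per velocity method (one
    panel per frequency, one curve per pore diameter, std error bars), an
    optional steady-state phase histogram grid, ``summary.csv`` and
    ``summary.json``.  Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if table.empty:
        raise ValueError("empty result table")

    for method in sorted(set(table["method"])):
        sub = table[table["method"] == method]
        if method == "steady_state_phase" or sub.empty:
            continue
        freqs = sorted(set(sub["frequency"]))
        fig, axes = plt.subplots(1, len(freqs),
                                 figsize=(4 * len(freqs), 3.2),
                                 squeeze=False, sharey=True)
        for ax, f in zip(axes[0], freqs):
            for d in sorted(set(sub["pore_diameter_mm"])):
                cell = sub[(sub["frequency"] == f)
                           & (sub["pore_diameter_mm"] == d)]
                cell = cell.sort_values("porosity_target")
                ax.errorbar(cell["porosity_target"], cell["mean"],
                            yerr=cell["std"], marker="o", capsize=2,
                            label=f"{d} mm")
            ax.set_xlabel("porosity")
            ax.set_title(f"{f / 1e3:.0f} kHz")
        axes[0][0].set_ylabel(f"{method} velocity (m/s)")
        axes[0][-1].legend(fontsize=8)
        path = out_dir / f"velocity_vs_porosity_{method}.svg"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written[f"figure_{method}"] = path

    if phase_fields:
        keys = sorted(phase_fields)
        fig, axes = plt.subplots(len(keys), 1, figsize=(4, 2 * len(keys)),
                                 squeeze=False)
        for ax, key in zip(axes[:, 0], keys):
            hist = phase_histogram(phase_fields[key].values)
            edges = np.arange(len(hist.probabilities) + 1) * hist.bin_width
            ax.bar(edges[:-1], hist.probabilities, width=hist.bin_width,
                   align="edge")
            ax.set_title(str(key), fontsize=8)
            ax.set_xlim(0, 2 * np.pi)
        path = out_dir / "phase_histograms.svg"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written["figure_phase_histograms"] = path

    csv_path = out_dir / "summary.csv"
    table.to_csv(csv_path, index=False)
    written["summary_csv"] = csv_path
    json_path = out_dir / "summary.json"
    json_path.write_text(table.to_json(orient="records", indent=2))
    written["summary_json"] = json_path
    return written
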
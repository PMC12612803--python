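"""Stochastic digital phantoms of porous bone.

A phantom is a voxelized block of cortical bone into which spherical red-marrow
pores of a single diameter are carved at uniformly random positions until a
target porosity (marrow volume fraction) is reached.  Pores may overlap, which
mimics the connected pore space of trabecular bone; in 2-D and 1-D modes the
spheres degenerate to disks and segments.

Voxels are labeled ``CORTICAL`` (0) or ``MARROW`` (1).  Porosity is simply the
marrow voxel fraction, so the achieved value is always recomputable from the
label grid itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CORTICAL",
    "MARROW",
    "PhantomSpec",
    "PhantomVolume",
    "rasterize_sphere",
    "measure_porosity",
    "generate_phantom",
    "save_phantom",
    "load_phantom",
]

CORTICAL = 0
MARROW = 1


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single-pore-size, uniform-porosity phantom.

    Parameters
    ----------
    pore_diameter : float
        Pore diameter in mm.  Must be at least two voxels so that a pore
        rasterizes to a non-degenerate neighborhood.
    target_porosity : float
        Desired marrow volume fraction in ``[0, 1)``.
    extent : tuple of float
        Physical phantom size in mm, one entry per axis; the last axis is the
        propagation (z) axis.  Default ``(12.8, 12.8, 8.0)``.
    voxel_size : float
        Isotropic voxel edge length in mm (default 0.05).
    rng_seed : int
        Seed of the phantom's private random stream.
    porosity_tolerance : float
        Maximum allowed absolute deviation of achieved from target porosity
        (default 0.005); generation fails if the first crossing of the target
        overshoots by more than this.
    """

    pore_diameter: float
    target_porosity: float
    extent: tuple[float, ...] = (12.8, 12.8, 8.0)
    voxel_size: float = 0.05
    rng_seed: int = 0
    porosity_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.pore_diameter <= 0:
            raise ValueError("pore_diameter must be positive")
        if self.pore_diameter < 2 * self.voxel_size:
            raise ValueError(
                "pore_diameter must be at least two voxel sizes "
                f"({2 * self.voxel_size} mm), got {self.pore_diameter} mm"
            )
        if not 0.0 <= self.target_porosity < 1.0:
            raise ValueError("target_porosity must lie in [0, 1)")
        if len(self.extent) not in (1, 2, 3):
            raise ValueError("extent must have 1, 2 or 3 axes")
        for L in self.extent:
            n = L / self.voxel_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {L} mm is not an integer multiple of the "
                    f"voxel size {self.voxel_size} mm"
                )
        object.__setattr__(self, "extent", tuple(float(L) for L in self.extent))

    @property
    def dimensionality(self) -> int:
        return len(self.extent)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(int(round(L / self.voxel_size)) for L in self.extent)


@dataclass
class PhantomVolume:
    """A generated phantom: label grid plus provenance."""

    labels: np.ndarray  # uint8, CORTICAL/MARROW
    spec: PhantomSpec
    achieved_porosity: float
    n_spheres_placed: int
    centers: np.ndarray = field(repr=False, default=None)  # (n, ndim) mm

    def __post_init__(self) -> None:
        if self.labels.shape != self.spec.shape:
            raise ValueError("label grid does not match spec shape")


def rasterize_sphere(
    center: np.ndarray,
    diameter: float,
    shape: tuple[int, ...],
    voxel_size: float,
) -> tuple[np.ndarray, ...]:
    """Voxel indices strictly inside a sphere (disk / segment in 2-D / 1-D).

    A voxel belongs to the sphere when its *center*, located at
    ``(i + 0.5) * voxel_size``, lies strictly within ``diameter / 2`` of
    ``center``.  The sphere is clipped at the grid boundary.

    Returns an index tuple suitable for fancy indexing into the label grid.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    center = np.atleast_1d(np.asarray(center, dtype=float))
    if center.shape != (len(shape),):
        raise ValueError("center dimensionality does not match grid")
    # work in voxel units: voxel centers sit on the integer lattice, so
    # distances between lattice points are exact and the strict-inequality
    # boundary is not blurred by floating-point unit conversions
    c_vox = center / voxel_size - 0.5
    r_vox = diameter / (2.0 * voxel_size)
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1,
                    np.asarray(shape))
    if np.any(hi <= lo):
        return tuple(np.empty(0, dtype=np.intp) for _ in shape)
    axes = [np.arange(l, h) - c for l, h, c in zip(lo, hi, c_vox)]
    d2 = np.zeros(tuple(len(a) for a in axes))
    for ax, a in enumerate(axes):
        sh = [1] * len(axes)
        sh[ax] = len(a)
        d2 = d2 + (a ** 2).reshape(sh)
    inside = np.nonzero(d2 < r_vox * r_vox)
    return tuple(idx + off for idx, off in zip(inside, lo))


def measure_porosity(volume: PhantomVolume | np.ndarray) -> float:
    """Marrow voxel fraction of a phantom (or raw label grid)."""
    labels = volume.labels if isinstance(volume, PhantomVolume) else np.asarray(volume)
    if labels.size == 0:
        raise ValueError("empty label grid")
    return float(np.count_nonzero(labels == MARROW) / labels.size)


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Carve random overlapping pores until the target porosity is crossed.

    Pore centers are drawn uniformly over the phantom extent; each pore is
    rasterized with strict-inequality voxelization and clipped at the faces.
    Placement stops at the first iteration where the marrow fraction reaches
    the target.  Deterministic for a fixed ``rng_seed``.

    Raises
    ------
    RuntimeError
        If the achieved porosity at the first crossing differs from the
        target by more than ``porosity_tolerance`` (pores too coarse for the
        requested precision); the message reports the closest achieved value.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    total = labels.size
    centers: list[np.ndarray] = []
    n_marrow = 0
    extent = np.asarray(spec.extent)
    # worst case bound on iterations: non-overlapping pores would need
    # target * total / pore_voxels spheres; allow a generous multiple.
    while n_marrow / total < spec.target_porosity:
        c = rng.uniform(0.0, extent)
        idx = rasterize_sphere(c, spec.pore_diameter, spec.shape, spec.voxel_size)
        n_marrow += int(np.count_nonzero(labels[idx] == CORTICAL))
        labels[idx] = MARROW
        centers.append(c)
        if len(centers) > 100 * total:
            raise RuntimeError("pore placement failed to reach target porosity")
    achieved = n_marrow / total
    if abs(achieved - spec.target_porosity) > spec.porosity_tolerance:
        raise RuntimeError(
            f"closest achievable porosity {achieved:.4f} misses target "
            f"{spec.target_porosity:.4f} by more than the tolerance "
            f"{spec.porosity_tolerance}; decrease the pore diameter or "
            "loosen the tolerance"
        )
    return PhantomVolume(
        labels=labels,
        spec=spec,
        achieved_porosity=achieved,
        n_spheres_placed=len(centers),
        centers=np.asarray(centers).reshape(len(centers), spec.dimensionality),
    )


def save_phantom(volume: PhantomVolume, path: str | Path) -> None:
    """Write labels as NIfTI (1 byte/voxel) with a JSON provenance sidecar."""
    import nibabel as nib

    path = Path(path)
    arr = volume.labels
    if arr.ndim < 3:  # NIfTI is 3-D; pad degenerate axes
        arr = arr.reshape(arr.shape + (1,) * (3 - arr.ndim))
    affine = np.diag([volume.spec.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.uint8), affine), str(path))
    sidecar = {
        "pore_diameter_mm": volume.spec.pore_diameter,
        "target_porosity": volume.spec.target_porosity,
        "extent_mm": list(volume.spec.extent),
        "voxel_size_mm": volume.spec.voxel_size,
        "rng_seed": volume.spec.rng_seed,
        "porosity_tolerance": volume.spec.porosity_tolerance,
        "achieved_porosity": volume.achieved_porosity,
        "n_spheres_placed": volume.n_spheres_placed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: str | Path) -> PhantomVolume:
    """Inverse of :func:`save_phantom`."""
    import nibabel as nib

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = PhantomSpec(
        pore_diameter=meta["pore_diameter_mm"],
        target_porosity=meta["target_porosity"],
        extent=tuple(meta["extent_mm"]),
        voxel_size=meta["voxel_size_mm"],
        rng_seed=meta["rng_seed"],
        porosity_tolerance=meta["porosity_tolerance"],
    )
    arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.uint8)
    arr = arr.reshape(spec.shape)
    return PhantomVolume(
        labels=arr,
        spec=spec,
        achieved_porosity=meta["achieved_porosity"],
        n_spheres_placed=meta["n_spheres_placed"],
    )
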
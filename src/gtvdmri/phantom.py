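"""Synthetic multi-tensor diffusion phantom with crossing-fiber structure.

The phantom is a configurable block geometry: cuboid fiber regions each carry
one or more tensor principal directions, so a volume contains single-fiber
voxels, balanced crossing voxels (where regions overlap) and isotropic
background — the structures a spatioangular denoiser must preserve.  The
noiseless signal follows the standard multi-tensor attenuation model

    S(q̂, b) = s0 * mean_t exp(-b q̂ᵀ D_t q̂)

with axially symmetric tensors D_t = d_r I + (d_a - d_r) u_t u_tᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DWIVolume, GradientTable

__all__ = [
    "FiberRegion",
    "PhantomConfig",
    "NoiseSpec",
    "default_fiber_regions",
    "make_gradient_table",
    "simulate_phantom",
    "add_noise",
]


@dataclass(frozen=True)
class FiberRegion:
    """A cuboid region carrying one or more fiber orientations.

    ``bounds`` are half-open voxel index ranges ((x0, x1), (y0, y1), (z0, z1));
    ``directions`` are the tensor principal axes (normalized on use).
    """

    bounds: tuple
    directions: tuple

    def mask(self, dims: Sequence[int]) -> np.ndarray:
        m = np.zeros(tuple(dims), dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        m[x0:x1, y0:y1, z0:z1] = True
        return m


def default_fiber_regions(dims: Sequence[int]) -> list:
    """Two orthogonal fiber slabs whose overlap forms a 90-degree crossing.

    Scaled to the volume: a slab along x and a slab along y, each spanning the
    central half of the two transverse axes. Voxels in both slabs mix the two
    tensors with equal weights; voxels in neither are isotropic background.
    """
    nx, ny, nz = dims
    zlo, zhi = nz // 4, max(3 * nz // 4, nz // 4 + 1)
    return [
        FiberRegion(
            bounds=((0, nx), (ny // 4, max(3 * ny // 4, ny // 4 + 1)), (zlo, zhi)),
            directions=((1.0, 0.0, 0.0),),
        ),
        FiberRegion(
            bounds=((nx // 4, max(3 * nx // 4, nx // 4 + 1)), (0, ny), (zlo, zhi)),
            directions=((0.0, 1.0, 0.0),),
        ),
    ]


@dataclass
class PhantomConfig:
    """Geometry and signal model of the synthetic dataset.

    Defaults emulate a single-shell acquisition: b = 1000 s/mm^2, 30
    noncollinear directions plus one b=0, 2 mm isotropic voxels, s0 = 1000 so
    that additive noise deviations of 100-300 correspond to 10-30% of the
    baseline signal. ``diffusivities`` is the (axial, radial) pair in mm^2/s;
    background voxels carry an isotropic tensor of ``iso_diffusivity``.
    """

    dims: tuple = (16, 16, 16)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    s0: float = 1000.0
    b_value: float = 1000.0
    n_directions: int = 30
    fiber_regions: list = None
    diffusivities: tuple = (1.7e-3, 0.3e-3)
    iso_diffusivity: float = 0.7e-3
    include_b0: bool = True

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be three positive integers")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        ax, rad = self.diffusivities
        if not ax >= rad > 0:
            raise ValueError("need axial diffusivity >= radial diffusivity > 0")
        if self.fiber_regions is None:
            self.fiber_regions = default_fiber_regions(self.dims)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: ``gaussian`` or ``rician`` with deviation sigma."""

    model: str = "gaussian"
    sigma: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def make_gradient_table(
    n_directions: int,
    b_value: float = 1000.0,
    include_b0: bool = True,
    seed: int = 0,
) -> GradientTable:
    """Build a table of approximately uniform, pairwise noncollinear directions.

    Directions follow a Fibonacci spiral on the upper hemisphere, then a
    seeded random rotation, so the set is deterministic given ``seed``. When
    ``include_b0`` is set the table starts with a single b=0 entry.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    i = np.arange(n_directions, dtype=np.float64)
    # z in (0, 1]: strictly upper hemisphere, so no two points are antipodal.
    z = (i + 0.5) / n_directions
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(1.0 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    rng = np.random.default_rng(seed)
    # Random rotation via QR of a Gaussian matrix (sign-fixed for determinism).
    q, rmat = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(rmat))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    dirs = dirs @ q.T
    bvals = np.full(n_directions, float(b_value))
    if include_b0:
        bvals = np.concatenate([[0.0], bvals])
        dirs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals, dirs)


def simulate_phantom(cfg: PhantomConfig, gradients: GradientTable) -> DWIVolume:
    """Noiseless multi-tensor signal on the block phantom; fully deterministic."""
    ax, rad = cfg.diffusivities
    bvals = gradients.bvals
    bvecs = gradients.bvecs
    V = len(gradients)

    # Isotropic attenuation per volume (background voxels).
    att_iso = np.exp(-bvals * cfg.iso_diffusivity)

    acc = np.zeros(cfg.dims + (V,), dtype=np.float64)
    ncomp = np.zeros(cfg.dims, dtype=np.int64)
    for region in cfg.fiber_regions:
        mask = region.mask(cfg.dims)
        for u in region.directions:
            u = np.asarray(u, dtype=np.float64)
            u = u / np.linalg.norm(u)
            proj2 = (bvecs @ u) ** 2
            att = np.exp(-bvals * (rad + (ax - rad) * proj2))
            acc[mask] += att
        ncomp[mask] += len(region.directions)

    signal = np.empty_like(acc)
    bg = ncomp == 0
    signal[bg] = cfg.s0 * att_iso
    fg = ~bg
    signal[fg] = cfg.s0 * acc[fg] / ncomp[fg][:, None]
    return DWIVolume(signal, gradients, np.asarray(cfg.voxel_size, dtype=np.float64))


def add_noise(vol: DWIVolume, spec: NoiseSpec) -> DWIVolume:
    """Return a noisy copy of ``vol``; the input is left untouched.

    Gaussian: S + n with n ~ N(0, sigma^2).  Rician: sqrt((S + n1)^2 + n2^2)
    with independent n1, n2 ~ N(0, sigma^2) — the magnitude-MRI model, which
    is nonnegative and positively biased at low SNR.
    """
    rng = np.random.default_rng(spec.seed)
    data = vol.data
    if spec.model == "gaussian":
        noisy = data + rng.normal(0.0, spec.sigma, size=data.shape)
    else:
        n1 = rng.normal(0.0, spec.sigma, size=data.shape)
        n2 = rng.normal(0.0, spec.sigma, size=data.shape)
        noisy = np.sqrt((data + n1) ** 2 + n2**2)
    return DWIVolume(noisy, vol.gradients, vol.voxel_size.copy())
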
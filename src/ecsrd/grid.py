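"""Voxelized extracellular region.

The macroscopic (volume-averaged) description of brain tissue replaces
explicit cell geometry with two per-voxel fields: the free volume fraction
``alpha`` (the accessible portion of tissue volume; concentrations are
expressed relative to it) and the tortuosity ``lambda`` (the average
multiplicative path-length increase a diffusing particle suffers due to
obstacles).  The effective diffusion coefficient is ``D* = D / lambda**2``.

Units: coordinates and voxel edges in um, diffusion coefficients in um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECSGrid",
    "build_grid",
    "effective_diffusion",
    "materialize_field",
    "edema_alpha",
    "edema_tortuosity",
]


def materialize_field(spec, grid: "ECSGrid", name: str = "field") -> np.ndarray:
    """Evaluate a field specification on the voxel grid.

    ``spec`` may be a scalar, an array of shape ``(nx, ny, nz)``, or a
    function of the voxel-center coordinates ``(x, y, z)`` in um.  Functions
    are sampled at voxel centers.  Returns a float array of shape
    ``(nx, ny, nz)``.
    """
    shape = (grid.nx, grid.ny, grid.nz)
    if callable(spec):
        X, Y, Z = grid.center_mesh()
        try:
            out = np.asarray(spec(X, Y, Z), dtype=float)
            if out.shape != shape:
                out = np.broadcast_to(out, shape).astype(float)
        except Exception:
            # scalar-only functions (e.g. with python conditionals)
            out = np.vectorize(spec, otypes=[float])(X, Y, Z)
        return np.ascontiguousarray(out)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape != shape:
        raise ValueError(
            f"{name}: array field has shape {arr.shape}, expected {shape}"
        )
    return arr.copy()


@dataclass
class ECSGrid:
    """Axis-aligned voxel grid with per-voxel alpha and (per-axis) tortuosity.

    Voxel ``(i, j, k)`` spans ``[xlo + i*dx, xlo + (i+1)*dx)`` etc. (half-open
    upper bound); its center is at ``xlo + (i + 1/2)*dx``.  When an extent is
    not an integer multiple of the voxel edge the grid is extended upward to
    ``ceil((hi - lo)/dx)`` voxels.
    """

    xlo: float
    ylo: float
    zlo: float
    xhi: float
    yhi: float
    zhi: float
    dx: float
    dy: float
    dz: float
    nx: int
    ny: int
    nz: int
    alpha: np.ndarray = field(repr=False)
    lam: np.ndarray = field(repr=False)  # shape (3, nx, ny, nz): per-axis

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    def axes_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = self.xlo + (np.arange(self.nx) + 0.5) * self.dx
        y = self.ylo + (np.arange(self.ny) + 0.5) * self.dy
        z = self.zlo + (np.arange(self.nz) + 0.5) * self.dz
        return x, y, z

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = self.axes_centers()
        return np.meshgrid(x, y, z, indexing="ij")

    def voxel_of(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        """Voxel index containing the point, half-open upper convention.

        Points outside the materialized domain (including the upper faces)
        are an error: a source there would silently lose substance.
        """
        i = int(np.floor((x - self.xlo) / self.dx))
        j = int(np.floor((y - self.ylo) / self.dy))
        k = int(np.floor((z - self.zlo) / self.dz))
        if not (0 <= i < self.nx and 0 <= j < self.ny and 0 <= k < self.nz):
            raise ValueError(
                f"point ({x}, {y}, {z}) um is outside the extracellular domain"
            )
        return i, j, k

    def voxel_center(self, i: int, j: int, k: int) -> tuple[float, float, float]:
        return (
            self.xlo + (i + 0.5) * self.dx,
            self.ylo + (j + 0.5) * self.dy,
            self.zlo + (k + 0.5) * self.dz,
        )

    def free_volume(self) -> float:
        """Total accessible volume, sum of alpha * voxel volume (um^3)."""
        return float(self.alpha.sum() * self.voxel_volume)


def build_grid(
    xlo: float,
    ylo: float,
    zlo: float,
    xhi: float,
    yhi: float,
    zhi: float,
    dx,
    volume_fraction=1.0,
    tortuosity=1.0,
) -> ECSGrid:
    """Construct the voxelized region.

    ``dx`` is the edge of a cubic voxel, or a 3-tuple of per-axis edges.
    ``volume_fraction`` and ``tortuosity`` are field specifications (scalar,
    ``(nx, ny, nz)`` array, or function of ``x, y, z``); tortuosity may also
    be a 3-tuple of such specifications for anisotropic tissue.
    """
    if not (xhi > xlo and yhi > ylo and zhi > zlo):
        raise ValueError("upper corner must be strictly above lower corner")
    if np.isscalar(dx):
        dxs = (float(dx),) * 3
    else:
        dxs = tuple(float(v) for v in dx)
        if len(dxs) != 3:
            raise ValueError("dx must be a scalar or a 3-tuple")
    if any(v <= 0 for v in dxs):
        raise ValueError("voxel edges must be positive")

    nx = int(np.ceil((xhi - xlo) / dxs[0] - 1e-12))
    ny = int(np.ceil((yhi - ylo) / dxs[1] - 1e-12))
    nz = int(np.ceil((zhi - zlo) / dxs[2] - 1e-12))

    grid = ECSGrid(
        xlo, ylo, zlo, xhi, yhi, zhi,
        dxs[0], dxs[1], dxs[2], max(nx, 1), max(ny, 1), max(nz, 1),
        alpha=np.empty(0), lam=np.empty(0),
    )

    alpha = materialize_field(volume_fraction, grid, "volume_fraction")
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValueError("volume_fraction must lie in (0, 1] at every voxel")
    grid.alpha = alpha

    if isinstance(tortuosity, tuple) and len(tortuosity) == 3:
        lam = np.stack(
            [materialize_field(t, grid, "tortuosity") for t in tortuosity]
        )
    else:
        lam1 = materialize_field(tortuosity, grid, "tortuosity")
        lam = np.broadcast_to(lam1, (3,) + lam1.shape).copy()
    if np.any(lam < 1):
        raise ValueError("tortuosity must be >= 1 at every voxel")
    grid.lam = lam
    return grid


def effective_diffusion(d, lam):
    """Effective diffusion coefficient D* = D / lambda^2 (um^2/ms).

    Either argument may be a 3-tuple for anisotropy; per-axis values combine
    per axis.  Returns a scalar, or a 3-tuple if either input was one.
    """
    d_arr = np.asarray(d, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("diffusion coefficient must be >= 0")
    if np.any(lam_arr < 1):
        raise ValueError("tortuosity must be >= 1")
    out = d_arr / lam_arr**2
    if out.ndim == 0:
        return float(out)
    return tuple(float(v) for v in np.broadcast_to(out, (3,)))


# ---------------------------------------------------------------------------
# Built-in heterogeneous fields: cytotoxic edema around an ischemic core.
# Cell swelling shrinks the ECS at the core (low alpha, high tortuosity) with
# a linear recovery to normal tissue values moving outward from radius r0.

def edema_alpha(alpha0=0.07, alpha1=0.2, r0=100.0, L=1000.0, center=(0.0, 0.0, 0.0)):
    """Radial free-volume-fraction ramp: ``alpha0`` inside ``r0``, rising
    linearly with slope ``(alpha1-alpha0)/(L/2)`` outside, capped at
    ``alpha1`` (normal tissue)."""
    cx, cy, cz = center

    def f(x, y, z):
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        ramp = alpha0 + (alpha1 - alpha0) * (r - r0) / (L / 2.0)
        return np.where(r < r0, alpha0, np.minimum(alpha1, ramp))

    return f


def edema_tortuosity(tort0=1.8, tort1=1.6, r0=100.0, L=1000.0, center=(0.0, 0.0, 0.0)):
    """Radial tortuosity ramp: ``tort0`` at the core, falling linearly to the
    normal-tissue ``tort1`` outside radius ``r0``."""
    cx, cy, cz = center

    def f(x, y, z):
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        ramp = tort0 - (tort0 - tort1) * (r - r0) / (L / 2.0)
        return np.where(r < r0, tort0, np.maximum(tort1, ramp))

    return f
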
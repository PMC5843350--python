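"""Calcium morphogen field on a regular 3D grid.

The extracellular calcium concentration ``s`` obeys a reaction-diffusion
equation: crowding-dependent diffusion, first-order decay at rate ``ds``,
and secretion sourced by mature spinous (rate ``delta_s1`` per cell) and
granular cells (``delta_s2``, twice the spinous rate by default).  Each
element of a secreting cell deposits its per-cell share into the voxel it
occupies, so per-cell totals are exact; cells sample the field back as the
mean of the voxels their elements sit in.

Diffusivity per voxel is the baseline divided by the local element count
(floored at one element), averaged over the voxel and its face neighbors —
dense tissue slows transport.  The discretization is a conservative
flux-form second-order central difference with forward-Euler substeps; with
zero-flux boundaries and no decay it conserves mass to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tissue import Cell, Tissue

__all__ = [
    "MorphogenGrid",
    "deposit_secretion",
    "local_diffusivity",
    "step_field",
    "sample_field",
]


@dataclass
class MorphogenGrid:
    """Regular grid holding the calcium field and its PDE parameters.

    ``s`` has shape (nx, ny, nz) with voxel size ``h`` (micrometres) and the
    origin at the basement-membrane corner (0, 0, 0).  Amounts are stored
    per voxel in arbitrary units.
    """

    shape: tuple[int, int, int]
    h: float = 1.0
    Ds_base: float = 2.0        # baseline diffusivity, um^2/s
    ds_decay: float = 0.02      # decay rate, 1/s
    delta_s1: float = 0.005     # secretion per mature spinous cell, units/s
    delta_s2: float = 0.010     # secretion per granular cell (2x spinous)
    dt_pde: Optional[float] = None  # forward-Euler substep, s; None -> 80% of
                                # the stability bound h^2/(6 Ds_base), so the
                                # relaxation block reaches quasi-steady state
    n_substeps: int = 1000
    top_absorbing: bool = False
    periodic_xy: bool = True
    s: np.ndarray = field(default=None)  # type: ignore[assignment]
    clip_events: int = 0
    clamped_elements: int = 0

    def __post_init__(self) -> None:
        if self.s is None:
            self.s = np.zeros(self.shape)
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")
        if self.dt_pde is None:
            self.dt_pde = 0.8 * self.h**2 / (6.0 * self.Ds_base)
        self.check_stability(self.Ds_base)

    def check_stability(self, dmax: float) -> None:
        bound = self.h**2 / (6.0 * dmax) if dmax > 0 else np.inf
        if self.dt_pde > bound:
            raise ValueError(
                f"unstable PDE step: dt_pde={self.dt_pde} exceeds h^2/(6 Dmax)={bound:.3g}"
            )

    @classmethod
    def for_box(cls, box: tuple[float, float, float], h: float = 1.0, **kw) -> "MorphogenGrid":
        shape = tuple(max(1, int(round(b / h))) for b in box)
        return cls(shape=shape, h=h, **kw)

    def total_mass(self) -> float:
        return float(self.s.sum())


def _voxel_indices(grid: MorphogenGrid, pos: np.ndarray) -> tuple[np.ndarray, int]:
    """Map element positions to voxel indices; clamp out-of-domain elements."""
    idx = np.floor(pos / grid.h).astype(np.int64)
    nx, ny, nz = grid.shape
    n_clamped = 0
    if grid.periodic_xy:
        idx[:, 0] %= nx
        idx[:, 1] %= ny
    else:
        before = idx[:, :2].copy()
        idx[:, 0] = np.clip(idx[:, 0], 0, nx - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
        n_clamped += int((before != idx[:, :2]).any(axis=1).sum())
    zc = np.clip(idx[:, 2], 0, nz - 1)
    n_clamped += int((zc != idx[:, 2]).sum())
    idx[:, 2] = zc
    return idx, n_clamped


def deposit_secretion(tissue: Tissue, grid: MorphogenGrid) -> np.ndarray:
    """Per-voxel secretion source (units/s).

    Each element of a mature spinous (C2) cell deposits ``delta_s1 / k`` and
    of a granular (C3) cell ``delta_s2 / k`` (k = its cell's element count),
    so the per-cell totals are exactly ``delta_s1`` and ``delta_s2``.
    """
    source = np.zeros(grid.shape)
    for c in tissue.cells:
        if c.stage == 2:
            rate = grid.delta_s1
        elif c.stage == 3:
            rate = grid.delta_s2
        else:
            continue
        if c.n_elements == 0:
            continue
        idx, ncl = _voxel_indices(grid, c.elements)
        grid.clamped_elements += ncl
        share = rate / c.n_elements
        np.add.at(source, (idx[:, 0], idx[:, 1], idx[:, 2]), share)
    return source


def element_density(tissue: Tissue, grid: MorphogenGrid) -> np.ndarray:
    """Element counts per voxel."""
    counts = np.zeros(grid.shape)
    for c in tissue.cells:
        if c.n_elements == 0:
            continue
        idx, _ = _voxel_indices(grid, c.elements)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return counts


def local_diffusivity(grid: MorphogenGrid, counts: np.ndarray) -> np.ndarray:
    """Crowding-reduced diffusivity field.

    Per-voxel reciprocal-density diffusivity ``Ds_base / max(count, 1)``,
    then averaged over the voxel and its face (first-degree) neighbors.
    Empty voxels use a density floor of one element.
    """
    if (counts < 0).any():
        raise ValueError("element counts must be nonnegative")
    d = grid.Ds_base / np.maximum(counts, 1.0)
    total = d.copy()
    denom = np.ones_like(d)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(d, shift, axis=axis)
            valid = np.ones_like(d, dtype=bool)
            if axis == 2 or not grid.periodic_xy:
                sl = [slice(None)] * 3
                sl[axis] = 0 if shift == 1 else -1
                valid[tuple(sl)] = False
            total += np.where(valid, rolled, 0.0)
            denom += valid
    return total / denom


def step_field(
    grid: MorphogenGrid,
    source: Optional[np.ndarray] = None,
    diffusivity: Optional[np.ndarray] = None,
    n_substeps: Optional[int] = None,
) -> MorphogenGrid:
    """Advance the field by ``n_substeps`` forward-Euler updates (in place).

    Uses the conservative flux form ``div(D grad s)`` with face-averaged
    diffusivity, zero-flux boundaries (optionally an absorbing top face),
    plus source and first-order decay.  Raises if the stability bound
    ``dt <= h^2 / (6 max D)`` is violated.
    """
    from . import _kernels

    n = grid.n_substeps if n_substeps is None else n_substeps
    if diffusivity is None:
        diffusivity = np.full(grid.shape, grid.Ds_base)
    grid.check_stability(float(diffusivity.max()))
    if source is None:
        source = np.zeros(grid.shape)
    # face-averaged diffusivity on the +x/+y/+z faces of each voxel
    dfx = 0.5 * (diffusivity + np.roll(diffusivity, -1, axis=0))
    dfy = 0.5 * (diffusivity + np.roll(diffusivity, -1, axis=1))
    dfz = 0.5 * (diffusivity + np.roll(diffusivity, -1, axis=2))
    grid.clip_events += int(
        _kernels.relax_field(
            grid.s, np.ascontiguousarray(source, dtype=np.float64),
            dfx, dfy, dfz,
            grid.ds_decay, grid.dt_pde, grid.h**2, int(n),
            grid.periodic_xy, grid.top_absorbing,
        )
    )
    return grid


def sample_field(cell: Cell, grid: MorphogenGrid) -> float:
    """Local signal level for a cell: mean of ``s`` over the voxels that
    contain its elements (uniform-weight linear combination)."""
    if cell.n_elements == 0:
        return 0.0
    idx, _ = _voxel_indices(grid, cell.elements)
    return float(grid.s[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
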
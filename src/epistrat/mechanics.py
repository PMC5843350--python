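"""Subcellular-element mechanics: potentials, force assembly, position updates.

Three interactions act on the point elements that make up each cell:

* an all-pairs harmonic spring ``V = mu (r - r0)^2 / 2`` between elements of
  the same cell, which relaxes an isolated cell to a roughly spherical
  cluster of preferred size;
* a Lennard-Jones-type potential ``V = F eps ((sigma/r)^12 - (sigma/r)^6)``
  between elements of different cells, repulsive below the equilibrium
  separation ``sigma`` and attractive (with fast fall-off) above it.  The
  prefactor is ``Fa`` for cells of the same class and ``Fb`` across classes
  — the selective-adhesion mechanism — and the interaction is truncated to
  exactly zero beyond ``inter_cutoff``;
* a constant-magnitude attraction ``V = eps_external |z|`` toward the
  basement membrane (z = 0), felt only by the membrane-adherent elements of
  basal cells and only within ``membrane_cutoff``.

Element motion is overdamped with additive Gaussian noise:
``Y <- Y + mobility * F * dt + noise_amp * sqrt(dt) * xi``.  Setting
``noise_amp = 0`` recovers the deterministic gradient flow.  A stiff,
purely numerical wall force below z = 0 keeps the membrane impenetrable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .tissue import Tissue, stage_to_class

__all__ = [
    "MechanicsParams",
    "NeighborIndex",
    "intra_pair_force",
    "inter_pair_force",
    "external_force",
    "assemble_forces",
    "step_positions",
    "total_potential",
]


@dataclass(frozen=True)
class MechanicsParams:
    """Force constants, cutoffs, and integration settings (micrometre/second
    units; forces in arbitrary units absorbed by ``mobility``)."""

    mu_spring: float = 0.2      # intra-cell spring constant, force/um
    r0: float = 2.0             # spring rest length, um (keeps cells solid: see docs)
    eps: float = 2.0            # LJ energy scale
    sigma: float = 4.5          # LJ zero-crossing separation, um
    Fa: float = 2.0             # same-class adhesion multiplier
    Fb: float = 0.5             # cross-class adhesion multiplier
    inter_cutoff: float = 9.0   # hard LJ truncation radius, um (2 sigma)
    eps_external: float = 3.0   # membrane attraction magnitude
    membrane_cutoff: float = 3.5  # membrane attraction range, um
    mobility: float = 1e-3      # um per force unit per s
    noise_amp: float = 0.010    # um / sqrt(s)
    dt_mech: float = 36.0       # s per mechanics step
    wall_k: float = 50.0        # numerical wall stiffness below z = 0
    cell_diameter: float = 4.75 # packed cell diameter, um (derived, see docs)
    skin: float = 3.0           # neighbor-list skin, um
    rmin_frac: float = 0.05     # LJ clamping floor as a fraction of sigma
    max_disp_frac: float = 0.15 # per-step displacement cap as a fraction of sigma
    polarized_adhesion: bool = True  # restrict Eq-7-style membrane pull to
                                # adherent elements of basal cells; when False
                                # (Base variant) every element near the
                                # membrane feels the same substrate pull

    def __post_init__(self) -> None:
        if self.Fa < 0 or self.Fb < 0:
            raise ValueError("adhesion strengths Fa, Fb must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.inter_cutoff <= self.sigma:
            raise ValueError("inter_cutoff must exceed sigma")
        if self.membrane_cutoff <= 0 or self.dt_mech <= 0:
            raise ValueError("cutoffs and dt_mech must be positive")


class NeighborIndex:
    """Verlet-style candidate pair list over a cell-linked binning.

    Pairs are built with radius ``inter_cutoff + skin`` and stay valid until
    some element has moved more than ``skin / 2`` since the build (or the
    element set changed), which the caller checks via :meth:`stale`.
    """

    def __init__(self, tissue: Tissue, params: MechanicsParams):
        self.params = params
        self.build(tissue)

    def build(self, tissue: Tissue) -> None:
        pos, cell_start, cell_class, adherent, basal = tissue.flatten()
        self.pos_ref = pos.copy()
        self.cell_start = cell_start
        self.adherent = adherent
        self.basal = basal
        n = pos.shape[0]
        cell_of = np.empty(n, dtype=np.int64)
        elem_class = np.empty(n, dtype=np.int8)
        for i in range(len(cell_start) - 1):
            cell_of[cell_start[i]:cell_start[i + 1]] = i
            elem_class[cell_start[i]:cell_start[i + 1]] = cell_class[i]
        self.cell_of = cell_of
        self.elem_class = elem_class
        lx, ly, _ = tissue.box
        self.pairs = _kernels.build_pairs(
            pos, cell_of, lx, ly, tissue.periodic_xy,
            self.params.inter_cutoff + self.params.skin,
        )
        self.n_elements = n

    def stale(self, pos: np.ndarray) -> bool:
        if pos.shape[0] != self.n_elements:
            return True
        d = pos - self.pos_ref
        return bool((d * d).sum(axis=1).max() > (self.params.skin * 0.5) ** 2)


def intra_pair_force(
    ri: np.ndarray, rj: np.ndarray, params: MechanicsParams
) -> np.ndarray:
    """Spring force on element i from same-cell element j."""
    d = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    r = np.linalg.norm(d)
    if r == 0.0:
        raise ValueError("coincident elements; jitter before force evaluation")
    return -params.mu_spring * (r - params.r0) * d / r


def inter_pair_force(
    ri: np.ndarray,
    rj: np.ndarray,
    same_cell_type: bool,
    params: MechanicsParams,
) -> np.ndarray:
    """Truncated Lennard-Jones force on element i from other-cell element j."""
    d = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    r = np.linalg.norm(d)
    if r > params.inter_cutoff or r == 0.0:
        return np.zeros(3)
    r_eff = max(r, params.rmin_frac * params.sigma)
    f = params.Fa if same_cell_type else params.Fb
    s6 = (params.sigma / r_eff) ** 6
    mag_over_r = f * params.eps * (12.0 * s6 * s6 - 6.0 * s6) / (r_eff * r_eff)
    return mag_over_r * d

def inter_pair_potential(
    r: float, same_cell_type: bool, params: MechanicsParams
) -> float:
    """Truncated Lennard-Jones pair potential at separation ``r``."""
    if r > params.inter_cutoff:
        return 0.0
    f = params.Fa if same_cell_type else params.Fb
    s6 = (params.sigma / max(r, params.rmin_frac * params.sigma)) ** 6
    return f * params.eps * (s6 * s6 - s6)


def external_force(
    position: np.ndarray,
    adherent: bool,
    basal: bool,
    params: MechanicsParams,
    membrane_z: float = 0.0,
) -> np.ndarray:
    """Membrane adhesion force on one element.

    Constant-magnitude pull toward the basement membrane for the
    membrane-adherent elements of basal cells within ``membrane_cutoff``;
    zero otherwise (suprabasal cells detach).
    """
    out = np.zeros(3)
    if not (adherent and basal):
        return out
    dz = float(position[2]) - membrane_z
    if 0.0 < abs(dz) <= params.membrane_cutoff:
        out[2] = -params.eps_external * np.sign(dz)
    return out


def assemble_forces(
    tissue: Tissue,
    index: NeighborIndex,
    params: MechanicsParams,
    pos: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int]:
    """Total force on every element (flat order); returns (forces, n_clamped).

    Sums the intra-cell springs, the selective inter-cell Lennard-Jones
    interactions over the neighbor index, the basement-membrane attraction,
    and the numerical wall below z = 0.  Pairwise internal contributions are
    accumulated antisymmetrically, so they sum to zero over the tissue.
    """
    if pos is None:
        pos, *_ = tissue.flatten()
    if index.stale(pos):
        index.build(tissue)
        pos2, *_ = tissue.flatten()
        if pos.shape != pos2.shape:
            raise RuntimeError("neighbor index inconsistent with tissue")
    forces = np.zeros_like(pos)
    lx, ly, _ = tissue.box
    n_clamped = _kernels.accumulate_inter(
        pos, index.pairs, index.elem_class, forces,
        lx, ly, tissue.periodic_xy,
        params.Fa, params.Fb, params.eps, params.sigma,
        params.inter_cutoff, params.rmin_frac * params.sigma,
    )
    _kernels.accumulate_intra(pos, index.cell_start, forces, params.mu_spring, params.r0)

    # basement-membrane attraction: polarized -> adherent basal elements only
    z = pos[:, 2]
    if params.polarized_adhesion:
        pulled = index.adherent & index.basal & (np.abs(z) <= params.membrane_cutoff) & (z != 0.0)
    else:
        pulled = (np.abs(z) <= params.membrane_cutoff) & (z != 0.0)
    forces[:, 2] -= np.where(pulled, params.eps_external * np.sign(z), 0.0)
    # impenetrable membrane (numerical wall, all elements)
    below = z < 0.0
    forces[below, 2] += params.wall_k * (-z[below])
    return forces, n_clamped


def step_positions(
    pos: np.ndarray,
    forces: np.ndarray,
    params: MechanicsParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, int]:
    """One overdamped Euler-Maruyama step; returns (new positions, n_capped).

    Elements whose displacement would exceed ``max_disp_frac * sigma``
    (transient overlaps right after a division produce near-singular
    repulsion) have their own displacement rescaled to that bound; the rest
    of the tissue takes the full step.  The cap is kept below half the
    neighbor-list skin so capped elements cannot outrun the pair list.  The
    number of capped elements is returned so callers can log them.
    """
    dt = params.dt_mech
    disp = params.mobility * dt * forces
    if rng is not None and params.noise_amp > 0.0:
        disp = disp + params.noise_amp * np.sqrt(dt) * rng.standard_normal(pos.shape)
    if disp.size == 0:
        return pos.copy(), 0
    max_disp = params.max_disp_frac * params.sigma
    norms = np.sqrt((disp * disp).sum(axis=1))
    over = norms > max_disp
    n_capped = int(over.sum())
    if n_capped:
        disp[over] *= (max_disp / norms[over])[:, None]
    return pos + disp, n_capped


def total_potential(tissue: Tissue, params: MechanicsParams) -> float:
    """Total potential energy (springs + truncated LJ + membrane + wall)."""
    pos, cell_start, cell_class, adherent, basal = tissue.flatten()
    n = pos.shape[0]
    cell_of = np.empty(n, dtype=np.int64)
    elem_class = np.empty(n, dtype=np.int8)
    for i in range(len(cell_start) - 1):
        cell_of[cell_start[i]:cell_start[i + 1]] = i
        elem_class[cell_start[i]:cell_start[i + 1]] = cell_class[i]
    lx, ly, _ = tissue.box
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            if tissue.periodic_xy:
                d[0] -= lx * np.rint(d[0] / lx)
                d[1] -= ly * np.rint(d[1] / ly)
            r = np.linalg.norm(d)
            if cell_of[i] == cell_of[j]:
                e += 0.5 * params.mu_spring * (r - params.r0) ** 2
            elif r <= params.inter_cutoff:
                e += inter_pair_potential(
                    r, elem_class[i] == elem_class[j], params
                )
        z = pos[i, 2]
        if adherent[i] and basal[i] and abs(z) <= params.membrane_cutoff:
            e += params.eps_external * abs(z)
        if z < 0:
            e += 0.5 * params.wall_k * z * z
    return e
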
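"""Cell-level events: growth, oriented division, fate transitions, removal.

Cells grow by adding one element at regularly scheduled intervals until they
reach their target size.  When a proliferative cell (basal C0 or spinous C1)
completes its cycle at full size it divides:

* symmetric division uses a plane roughly perpendicular to the basement
  membrane (daughters end up side by side) and produces two cells of the
  same stage: a C0 self-renews with probability ``p0``, otherwise both
  daughters are C1; a C1 stays proliferative with probability ``p1``,
  otherwise both daughters exit the cycle as C2;
* in the asymmetric-division variant a C0 instead divides asymmetrically
  with probability ``2 (1 - p0)`` — a plane roughly parallel to the membrane
  yields one basal and one suprabasal (C1) daughter — and self-renews
  symmetrically with probability ``2 p0 - 1``.  These weights preserve the
  expected offspring composition of the population model and require
  ``p0 >= 1/2``.

Mature spinous cells convert to granular either at a fixed maturation age
(the default: age ``1/d2_eff``, whose mean residence matches the population
model) or with the memoryless per-step hazard ``1 - exp(-d2_eff dt)``; a
granular cell that reaches its lifetime shrinks by losing one element per
tick until it disappears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lineage import LineageParams
from .tissue import Cell, Tissue

__all__ = [
    "LifecycleParams",
    "DivisionEvent",
    "new_cycle_length",
    "init_growth",
    "grow_cell",
    "decide_division",
    "divide_cell",
    "differentiate_mature",
    "remove_granular",
]


@dataclass(frozen=True)
class LifecycleParams:
    """Timing and geometry knobs for cell-level events."""

    cycle_hours: float = 24.0        # fallback cycle length (ln2 / v0 preferred)
    cycle_jitter: float = 0.1        # uniform fractional jitter on cycle lengths
    target_elements: int = 6         # mature element count
    removal_interval: float = 4.0    # h over which a dying granular cell shrinks
    plane_jitter_deg: float = 15.0   # division-plane angular tolerance
    placement_radius: float = 1.0    # um, new-element offset from the centroid
    daughter_separation: float = 2.0  # um, anaphase-like push of the daughters
                                      # apart along the division axis
    maturation: str = "fixed_age"    # C2->C3 timing: "fixed_age" (age 1/d2)
                                      # or "hazard" (memoryless rate d2)

    def __post_init__(self) -> None:
        if self.target_elements < 2:
            raise ValueError("target_elements must be at least 2")
        if not (0.0 <= self.cycle_jitter < 1.0):
            raise ValueError("cycle_jitter must lie in [0, 1)")
        if self.removal_interval <= 0:
            raise ValueError("removal_interval must be positive")


@dataclass(frozen=True)
class DivisionEvent:
    """A committed division: mode, oriented plane, and daughter stages."""

    parent_id: int
    mode: str  # "symmetric" | "asymmetric"
    plane_normal: np.ndarray
    daughter_stages: tuple[int, int]


def new_cycle_length(
    rate: float, rng: np.random.Generator, jitter: float, fallback: float = 24.0
) -> float:
    """Cycle length ln2/rate with multiplicative uniform jitter."""
    base = np.log(2.0) / rate if rate > 0 else fallback
    if jitter > 0:
        base *= 1.0 + jitter * (2.0 * rng.random() - 1.0)
    return base


def init_growth(cell: Cell, now: float, params: LifecycleParams) -> None:
    """Set a newborn cell's growth schedule toward its target size."""
    missing = params.target_elements - cell.n_elements
    if missing <= 0 or cell.cycle_length <= 0:
        cell.growth_interval = np.inf
        cell.next_growth = np.inf
    else:
        cell.growth_interval = cell.cycle_length / missing
        cell.next_growth = now + cell.growth_interval


def grow_cell(
    cell: Cell,
    now: float,
    params: LifecycleParams,
    rng: np.random.Generator,
) -> bool:
    """Add one element near the centroid if the schedule says so."""
    if cell.shrinking or cell.n_elements >= params.target_elements:
        return False
    if now < cell.next_growth:
        return False
    offset = rng.standard_normal(3)
    norm = np.linalg.norm(offset)
    if norm == 0.0:
        offset = np.array([params.placement_radius, 0.0, 0.0])
    else:
        offset *= params.placement_radius * rng.random() ** (1 / 3) / norm
    new = cell.centroid() + offset
    cell.elements = np.vstack([cell.elements, new])
    cell.adherent = np.append(cell.adherent, False)
    cell.next_growth += cell.growth_interval
    return True


def _jittered_normal(
    target: np.ndarray, jitter_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit vector within ``jitter_deg`` of ``target`` (uniform tilt)."""
    theta = np.deg2rad(jitter_deg) * rng.random()
    phi = 2.0 * np.pi * rng.random()
    # orthonormal frame around target
    t = target / np.linalg.norm(target)
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return np.cos(theta) * t + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)


def decide_division(
    cell: Cell,
    lineage: LineageParams,
    variant: str,
    rng: np.random.Generator,
    params: Optional[LifecycleParams] = None,
) -> Optional[DivisionEvent]:
    """Division outcome for a cycle-complete, fully grown C0 or C1 cell.

    Returns None when the cell is not ready.  ``variant`` selects whether
    basal cells may divide asymmetrically (any of the variant names other
    than "base" and "sym-only" behave identically here; only the flag
    matters).
    """
    params = params or LifecycleParams()
    if cell.stage not in (0, 1):
        return None
    if cell.cycle_clock < cell.cycle_length or cell.n_elements < params.target_elements:
        return None
    asym_enabled = variant in ("asym_division", "selective_adhesion", "signal")

    if cell.stage == 0:
        if asym_enabled:
            # offspring composition matches the population model for any p0:
            # for p0 >= 1/2 divisions are asymmetric w.p. 2(1-p0), else
            # symmetric self-renewal; for p0 < 1/2 (reachable only through
            # signal feedback) asymmetric w.p. 2 p0, else symmetric
            # differentiation.  A static configuration with p0 < 1/2 is
            # rejected at validation time.
            u = rng.random()
            if lineage.p0 >= 0.5:
                if u < 2.0 * (1.0 - lineage.p0):
                    mode, stages = "asymmetric", (0, 1)
                else:
                    mode, stages = "symmetric", (0, 0)
            else:
                if u < 2.0 * lineage.p0:
                    mode, stages = "asymmetric", (0, 1)
                else:
                    mode, stages = "symmetric", (1, 1)
        else:
            if rng.random() < lineage.p0:
                mode, stages = "symmetric", (0, 0)
            else:
                mode, stages = "symmetric", (1, 1)
    else:  # C1
        if rng.random() < lineage.p1:
            mode, stages = "symmetric", (1, 1)
        else:
            mode, stages = "symmetric", (2, 2)

    if mode == "asymmetric":
        normal = _jittered_normal(np.array([0.0, 0.0, 1.0]), params.plane_jitter_deg, rng)
    else:
        phi = 2.0 * np.pi * rng.random()
        horiz = np.array([np.cos(phi), np.sin(phi), 0.0])
        normal = _jittered_normal(horiz, params.plane_jitter_deg, rng)
    return DivisionEvent(
        parent_id=cell.cell_id, mode=mode, plane_normal=normal, daughter_stages=stages
    )


def divide_cell(
    tissue: Tissue,
    cell: Cell,
    event: DivisionEvent,
    rng: np.random.Generator,
    cycle_lengths: tuple[float, float],
    params: Optional[LifecycleParams] = None,
) -> tuple[Cell, Cell]:
    """Split a cell's elements across the division plane into two daughters.

    Elements are ranked by signed distance to the plane through the centroid
    and split at the median, so the partition is never degenerate and each
    daughter receives at least floor(n/2) elements.  In asymmetric mode the
    daughter farther from the membrane (greater mean z) takes the
    differentiated stage.  Daughter clocks restart and growth schedules are
    reinitialized.
    """
    params = params or LifecycleParams()
    n = cell.n_elements
    if n < 2:
        raise ValueError("cannot divide a single-element cell")
    centroid = cell.centroid()
    signed = (cell.elements - centroid) @ event.plane_normal
    order = np.argsort(signed, kind="stable")
    lower_idx, upper_idx = order[: n // 2], order[n // 2 :]

    halves = [cell.elements[lower_idx].copy(), cell.elements[upper_idx].copy()]
    # anaphase-like separation: push the daughters apart along the division
    # axis so they resolve into two distinct bodies within a few steps
    sep = 0.5 * params.daughter_separation * event.plane_normal
    halves[0] -= sep
    halves[1] += sep
    if event.mode == "asymmetric":
        # the membrane is impenetrable; let the separation act upward only
        halves[0] += sep
    stages = list(event.daughter_stages)
    if event.mode == "asymmetric":
        # ensure the spatially upper half takes the differentiated stage
        mean_z = [h[:, 2].mean() for h in halves]
        hi = int(np.argmax(mean_z))
        stages = [min(event.daughter_stages)] * 2
        stages[hi] = max(event.daughter_stages)

    daughters = []
    for half, stage, clen in zip(halves, stages, cycle_lengths):
        d = Cell(
            cell_id=tissue.new_cell_id(),
            stage=stage,
            elements=half,
            adherent=np.zeros(len(half), dtype=bool),
            cycle_clock=0.0,
            cycle_length=clen,
            target_elements=params.target_elements,
        )
        init_growth(d, tissue.time, params)
        daughters.append(d)
    return daughters[0], daughters[1]


def differentiate_mature(
    cell: Cell,
    d2_eff: float,
    dt: float,
    rng: np.random.Generator,
    mode: str = "fixed_age",
) -> bool:
    """Decide a C2 -> C3 transition over one step of length ``dt``.

    ``mode="hazard"`` is the memoryless Bernoulli event with probability
    ``1 - exp(-d2_eff dt)``, whose aggregate statistics match the population
    model exactly.  ``mode="fixed_age"`` (default) matures the cell when its
    stage clock reaches the mean residence ``1 / d2_eff``; the mean residence
    matches the population model, while the low timing variance keeps the
    spinous-granular boundary coherent with the age-ordered tissue.
    """
    if cell.stage != 2 or d2_eff <= 0.0:
        return False
    if mode == "hazard":
        return bool(rng.random() < 1.0 - np.exp(-d2_eff * dt))
    if mode == "fixed_age":
        return cell.cycle_clock >= 1.0 / d2_eff
    raise ValueError(f"unknown maturation mode {mode!r}")


def remove_granular(
    cell: Cell,
    now: float,
    params: LifecycleParams,
) -> tuple[int, bool]:
    """Advance a granular cell's shrink schedule.

    Entry: once its lifetime clock elapses, the cell starts shrinking and
    thereafter loses one element per tick (removal_interval / element count
    at onset).  Returns (elements removed this call, cell fully removed).
    """
    if cell.stage != 3:
        return 0, False
    if not cell.shrinking:
        if cell.cycle_clock < cell.cycle_length:
            return 0, False
        cell.shrinking = True
        cell.shrink_interval = params.removal_interval / max(cell.n_elements, 1)
        cell.next_shrink = now
    removed = 0
    while cell.shrinking and cell.n_elements > 0 and now >= cell.next_shrink - 1e-12:
        cell.elements = cell.elements[:-1]
        cell.adherent = cell.adherent[:-1]
        cell.next_shrink += cell.shrink_interval
        removed += 1
    return removed, cell.n_elements == 0
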
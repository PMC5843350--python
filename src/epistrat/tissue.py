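"""Discrete tissue representation for the subcellular-element model.

A :class:`Cell` is a cluster of point elements (positions in micrometres);
a :class:`Tissue` is the collection of cells living in a box domain sitting
on the basement membrane at ``z = 0``.  Element positions are stored
unwrapped; when the domain is periodic in x-y the minimum-image convention is
applied during force evaluation and rasterization, so a cell's elements always
stay contiguous in storage coordinates.

Lineage stages are integer coded: 0 basal (C0), 1 proliferative spinous (C1),
2 mature spinous (C2), 3 granular (C3).  For adhesion and slice labelling,
stages collapse to three classes (basal / spinous / granular); see
:func:`stage_to_class`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Cell", "Tissue", "stage_to_class", "STAGE_NAMES"]

STAGE_NAMES = ("C0", "C1", "C2", "C3")

#: map lineage stage (0..3) to adhesion / label class: 0 basal, 1 spinous
#: (C1 and C2 behave identically for adhesion and slice imaging), 2 granular.
_STAGE_CLASS = np.array([0, 1, 1, 2], dtype=np.int8)


def stage_to_class(stage: int | np.ndarray) -> int | np.ndarray:
    """Collapse the four lineage stages onto the three cell classes."""
    return _STAGE_CLASS[stage]


@dataclass
class Cell:
    """One cell: a set of subcellular elements plus its lineage bookkeeping."""

    cell_id: int
    stage: int
    elements: np.ndarray  # (k, 3) float64 positions, micrometres
    adherent: np.ndarray  # (k,) bool, True = membrane-adherent element type
    cycle_clock: float = 0.0  # hours since birth (or since entering C3)
    cycle_length: float = 24.0  # hours; for C3 this is the lifetime before shrinking
    target_elements: int = 10
    next_growth: float = 0.0  # tissue time (hours) of the next element addition
    growth_interval: float = np.inf  # hours between element additions
    shrinking: bool = False
    next_shrink: float = np.inf  # tissue time of next element removal while shrinking
    shrink_interval: float = np.inf
    signal: float = 0.0  # last sampled local morphogen level

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def centroid(self) -> np.ndarray:
        return self.elements.mean(axis=0)

    def copy(self) -> "Cell":
        return Cell(
            cell_id=self.cell_id,
            stage=self.stage,
            elements=self.elements.copy(),
            adherent=self.adherent.copy(),
            cycle_clock=self.cycle_clock,
            cycle_length=self.cycle_length,
            target_elements=self.target_elements,
            next_growth=self.next_growth,
            growth_interval=self.growth_interval,
            shrinking=self.shrinking,
            next_shrink=self.next_shrink,
            shrink_interval=self.shrink_interval,
            signal=self.signal,
        )


@dataclass
class Tissue:
    """The whole simulated tissue: cells, domain geometry, and clocks."""

    cells: list[Cell] = field(default_factory=list)
    box: tuple[float, float, float] = (58.0, 58.0, 40.0)
    periodic_xy: bool = True
    time: float = 0.0  # hours
    next_cell_id: int = 0

    def new_cell_id(self) -> int:
        cid = self.next_cell_id
        self.next_cell_id += 1
        return cid

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_elements(self) -> int:
        return sum(c.n_elements for c in self.cells)

    def __iter__(self) -> Iterator[Cell]:
        return iter(self.cells)

    def flatten(self):
        """Concatenate per-cell element data into flat arrays for the kernels.

        Returns ``(pos, cell_start, cell_class, adherent, basal)`` where
        ``cell_start`` has length ``n_cells + 1`` and delimits each cell's
        contiguous element range, ``cell_class`` is the per-cell adhesion
        class and ``basal``/``adherent`` are per-element flags for the
        membrane force.
        """
        n = self.n_elements
        pos = np.empty((n, 3), dtype=np.float64)
        adherent = np.empty(n, dtype=np.bool_)
        cell_start = np.empty(self.n_cells + 1, dtype=np.int64)
        cell_class = np.empty(self.n_cells, dtype=np.int8)
        basal = np.empty(n, dtype=np.bool_)
        k = 0
        for i, c in enumerate(self.cells):
            m = c.n_elements
            cell_start[i] = k
            pos[k : k + m] = c.elements
            adherent[k : k + m] = c.adherent
            basal[k : k + m] = c.stage == 0
            cell_class[i] = _STAGE_CLASS[c.stage]
            k += m
        cell_start[self.n_cells] = k
        return pos, cell_start, cell_class, adherent, basal

    def scatter(self, pos: np.ndarray) -> None:
        """Write flat positions back into the per-cell arrays."""
        k = 0
        for c in self.cells:
            m = c.n_elements
            c.elements[:] = pos[k : k + m]
            k += m
        if k != pos.shape[0]:
            raise ValueError("position array does not match tissue element count")

    def centroids(self) -> np.ndarray:
        """(n_cells, 3) array of cell centroids (storage coordinates)."""
        if not self.cells:
            return np.empty((0, 3))
        return np.array([c.centroid() for c in self.cells])

    def stages(self) -> np.ndarray:
        return np.array([c.stage for c in self.cells], dtype=np.int8)

    def relabel_adherent(self) -> None:
        """Refresh element types: the lower half (by z) of each basal cell's
        elements is membrane-adherent; all other elements are interior."""
        for c in self.cells:
            c.adherent[:] = False
            if c.stage == 0 and c.n_elements > 0:
                k = max(1, c.n_elements // 2)
                order = np.argsort(c.elements[:, 2], kind="stable")
                c.adherent[order[:k]] = True

    def copy(self) -> "Tissue":
        t = Tissue(
            cells=[c.copy() for c in self.cells],
            box=self.box,
            periodic_xy=self.periodic_xy,
            time=self.time,
            next_cell_id=self.next_cell_id,
        )
        return t
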
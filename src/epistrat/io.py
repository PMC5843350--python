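"""Snapshot, event-log and manifest readers/writers.

Snapshots are plain text for auditability: an element table CSV, a cell
table CSV, and (when present) a whole-grid text dump of the morphogen
field.  Floats are written with 17 significant digits so a round trip
reproduces positions, clocks and field values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .morphogen import MorphogenGrid
from .tissue import Cell, Tissue

__all__ = [
    "SCHEMA_VERSION",
    "write_snapshot",
    "read_snapshot",
    "write_manifest",
    "rng_state",
    "restore_rng",
]

SCHEMA_VERSION = 1

_CELL_COLUMNS = [
    "cell_id", "type", "cycle_clock", "cycle_length", "target_elements",
    "next_growth", "growth_interval", "shrinking", "next_shrink",
    "shrink_interval", "signal",
]


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_snapshot(tissue: Tissue, grid: Optional[MorphogenGrid], path: str | Path) -> Path:
    """Write a tissue (and optional morphogen grid) under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    elem_rows = []
    eid = 0
    for c in tissue.cells:
        for k in range(c.n_elements):
            elem_rows.append(
                {
                    "element_id": eid,
                    "cell_id": c.cell_id,
                    "cell_type": f"C{c.stage}",
                    "element_type": "membrane_adherent" if c.adherent[k] else "interior",
                    "x": _fmt(c.elements[k, 0]),
                    "y": _fmt(c.elements[k, 1]),
                    "z": _fmt(c.elements[k, 2]),
                }
            )
            eid += 1
    pd.DataFrame(
        elem_rows,
        columns=["element_id", "cell_id", "cell_type", "element_type", "x", "y", "z"],
    ).to_csv(path / "elements.csv", index=False)

    cell_rows = []
    for c in tissue.cells:
        cell_rows.append(
            {
                "cell_id": c.cell_id,
                "type": f"C{c.stage}",
                "cycle_clock": _fmt(c.cycle_clock),
                "cycle_length": _fmt(c.cycle_length),
                "target_elements": c.target_elements,
                "next_growth": _fmt(c.next_growth),
                "growth_interval": _fmt(c.growth_interval),
                "shrinking": int(c.shrinking),
                "next_shrink": _fmt(c.next_shrink),
                "shrink_interval": _fmt(c.shrink_interval),
                "signal": _fmt(c.signal),
            }
        )
    pd.DataFrame(cell_rows, columns=_CELL_COLUMNS).to_csv(path / "cells.csv", index=False)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "time": tissue.time,
        "box": list(tissue.box),
        "periodic_xy": tissue.periodic_xy,
        "next_cell_id": tissue.next_cell_id,
    }
    (path / "tissue.json").write_text(json.dumps(meta, indent=1))

    if grid is not None:
        with open(path / "grid.txt", "w") as fh:
            nx, ny, nz = grid.shape
            fh.write(f"# schema {SCHEMA_VERSION}\n")
            fh.write(f"dims {nx} {ny} {nz}\n")
            fh.write(f"spacing {_fmt(grid.h)}\n")
            fh.write("origin 0 0 0\n")
            for v in grid.s.ravel(order="C"):
                fh.write(_fmt(v) + "\n")
    return path


def read_snapshot(path: str | Path) -> tuple[Tissue, Optional[MorphogenGrid]]:
    """Read a snapshot directory back into a Tissue (+ grid if dumped)."""
    path = Path(path)
    meta = json.loads((path / "tissue.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported snapshot schema: {meta.get('schema_version')}")
    tissue = Tissue(
        box=tuple(meta["box"]),
        periodic_xy=bool(meta["periodic_xy"]),
        time=float(meta["time"]),
        next_cell_id=int(meta["next_cell_id"]),
    )
    elems = pd.read_csv(path / "elements.csv", dtype={"x": str, "y": str, "z": str})
    cells = pd.read_csv(path / "cells.csv")
    grouped = {cid: df for cid, df in elems.groupby("cell_id", sort=False)}
    for _, row in cells.iterrows():
        cid = int(row["cell_id"])
        df = grouped.get(cid)
        if df is None:
            pos = np.empty((0, 3))
            adher = np.zeros(0, dtype=bool)
        else:
            pos = np.column_stack(
                [df["x"].astype(float), df["y"].astype(float), df["z"].astype(float)]
            )
            adher = (df["element_type"] == "membrane_adherent").to_numpy()
        tissue.cells.append(
            Cell(
                cell_id=cid,
                stage=int(str(row["type"]).lstrip("C")),
                elements=pos,
                adherent=adher,
                cycle_clock=float(row["cycle_clock"]),
                cycle_length=float(row["cycle_length"]),
                target_elements=int(row["target_elements"]),
                next_growth=float(row["next_growth"]),
                growth_interval=float(row["growth_interval"]),
                shrinking=bool(row["shrinking"]),
                next_shrink=float(row["next_shrink"]),
                shrink_interval=float(row["shrink_interval"]),
                signal=float(row["signal"]),
            )
        )

    grid = None
    grid_path = path / "grid.txt"
    if grid_path.exists():
        with open(grid_path) as fh:
            lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
        dims = tuple(int(v) for v in lines[0].split()[1:4])
        h = float(lines[1].split()[1])
        vals = np.array([float(v) for v in lines[3:]])
        if vals.size != int(np.prod(dims)):
            raise ValueError(
                f"grid dump at {grid_path} has {vals.size} values, expected {np.prod(dims)}"
            )
        grid = MorphogenGrid(shape=dims, h=h, periodic_xy=tissue.periodic_xy)
        grid.s = vals.reshape(dims)
    return tissue, grid


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_manifest(config, path: str | Path, extra: Optional[dict] = None) -> Path:
    """Write the resolved run manifest (full config echo + provenance)."""
    from . import __version__

    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": _jsonable(config),
    }
    if extra:
        doc.update(_jsonable(extra))
    path.write_text(json.dumps(doc, indent=1, default=str))
    return path


def rng_state(rngs: dict[str, np.random.Generator]) -> dict:
    """JSON-serializable snapshot of the named RNG streams."""
    return {name: g.bit_generator.state for name, g in rngs.items()}


def restore_rng(states: dict) -> dict[str, np.random.Generator]:
    out = {}
    for name, st in states.items():
        g = np.random.Generator(np.random.PCG64())
        g.bit_generator.state = st
        out[name] = g
    return out
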
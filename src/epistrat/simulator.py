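"""Multiscale orchestration: mechanics, lifecycle, and morphogen coupling.

One simulated hour consists of a block of overdamped mechanics substeps,
followed by the cell-level events in a fixed order (granular removal, then
divisions, then C2->C3 differentiation, then growth), followed — in the
Signal variant — by secretion deposition, a relaxation block of the calcium
field, and resampling of each cell's local signal.

Four nested model variants are supported, each adding one mechanism:

* ``base`` — lineage dynamics only: symmetric divisions, isotropic adhesion
  (Fa = Fb), no signaling;
* ``asym_division`` — basal cells may divide asymmetrically (plane parallel
  to the membrane, one basal + one suprabasal daughter);
* ``selective_adhesion`` — adds class-selective adhesion (Fa > Fb);
* ``signal`` — adds the calcium feedback: the local field raises the
  effective Ovol1 level inside mature spinous cells (faster terminal
  differentiation) and the effective Ovol2 level inside basal cells (slower
  self-renewal/proliferation), closing a negative feedback loop that can
  bring the populations to a steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .lineage import (
    GENOTYPE_PRESETS,
    LineageParams,
    OvolRegulation,
    ovol_modulate,
)
from .lifecycle import (
    DivisionEvent,
    LifecycleParams,
    decide_division,
    differentiate_mature,
    divide_cell,
    grow_cell,
    init_growth,
    new_cycle_length,
    remove_granular,
)
from .mechanics import MechanicsParams, NeighborIndex, assemble_forces, step_positions
from .metrics import MetricsReport, compute_report
from .morphogen import (
    MorphogenGrid,
    deposit_secretion,
    element_density,
    local_diffusivity,
    sample_field,
    step_field,
)
from .tissue import Cell, Tissue, stage_to_class

__all__ = [
    "VARIANTS",
    "SignalFeedback",
    "SimulationConfig",
    "RunResult",
    "effective_rates",
    "init_tissue",
    "run",
    "sweep",
    "classify_pattern",
]

VARIANTS = ("base", "asym_division", "selective_adhesion", "signal")

#: fixed spawn order of the named child RNG streams
RNG_STREAMS = ("placement", "mechanics_noise", "division", "differentiation", "lifecycle")


@dataclass(frozen=True)
class SignalFeedback:
    """Saturating (Hill-type) gains of local calcium on effective Ovol levels.

    ``alpha_eff = alpha (1 + k_alpha s / (s_half + s))`` inside mature
    spinous cells (raises d2); ``beta_eff = beta (1 + k_beta s/(s_half+s))``
    inside basal cells (lowers v0 and p0).  Both effects vanish at s = 0 and
    saturate for s >> s_half.
    """

    k_alpha: float = 3.0
    k_beta: float = 600.0
    s_half: float = 0.18

    def __post_init__(self) -> None:
        if self.k_alpha < 0 or self.k_beta < 0 or self.s_half <= 0:
            raise ValueError("feedback gains must be nonnegative and s_half positive")

    def hill(self, s: float) -> float:
        s = max(float(s), 0.0)
        return s / (self.s_half + s)


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run (see the [simulation] config
    section and friends)."""

    variant: str = "base"
    genotype: str = "WT"
    duration: float = 120.0          # simulated hours
    seed: int = 0
    box: tuple[float, float, float] = (58.0, 58.0, 40.0)
    periodic_xy: bool = True
    nx_cells: int = 10
    ny_cells: int = 10
    dt_life: float = 1.0             # h between lifecycle updates
    snapshot_every: float = 24.0     # h between metric snapshots
    max_elements: int = 80_000       # early-stop cap
    iso_adhesion: float = 1.2        # Fa = Fb value forced in base/asym variants
    relax_steps: int = 300           # noise-free pre-equilibration steps
    mech_substeps: int = 40          # mechanics relaxation substeps per lifecycle step
    grid_h: float = 3.0              # morphogen voxel size, um
    mech: MechanicsParams = field(default_factory=MechanicsParams)
    life: LifecycleParams = field(default_factory=LifecycleParams)
    reg: OvolRegulation = field(default_factory=OvolRegulation)
    feedback: SignalFeedback = field(default_factory=SignalFeedback)
    morphogen: dict = field(default_factory=dict)  # extra MorphogenGrid kwargs

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")
        if self.genotype not in GENOTYPE_PRESETS:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; pick from {tuple(GENOTYPE_PRESETS)}"
            )
        if self.duration < 0 or self.dt_life <= 0:
            raise ValueError("duration must be >= 0 and dt_life > 0")
        # each variant is the previous plus one mechanism
        if self.variant in ("base", "asym_division"):
            object.__setattr__(self, "mech", replace(
                self.mech, Fa=self.iso_adhesion, Fb=self.iso_adhesion))
        if self.variant == "base":
            # the asym_division variant introduces polarized adhesion together
            # with oriented division; the base model has neither
            object.__setattr__(self, "mech", replace(
                self.mech, polarized_adhesion=False))
        if self.variant in ("asym_division", "selective_adhesion", "signal"):
            reg = self.genotype_regulation()
            p0 = ovol_modulate(reg).p0
            if p0 < 0.5:
                raise ValueError(
                    f"asymmetric division requires p0 >= 1/2, got p0={p0:.4f} "
                    "(2 p0 - 1 would be a negative probability)"
                )

    def genotype_regulation(self) -> OvolRegulation:
        g = GENOTYPE_PRESETS[self.genotype]
        return replace(self.reg, alpha=g.alpha, beta=g.beta)

    def spawn_rngs(self, seed: Optional[int] = None) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed if seed is None else seed)
        children = ss.spawn(len(RNG_STREAMS))
        return {name: np.random.Generator(np.random.PCG64(c))
                for name, c in zip(RNG_STREAMS, children)}


def effective_rates(
    stage: int,
    reg: OvolRegulation,
    local_signal: float,
    feedback: Optional[SignalFeedback],
    variant: str,
) -> LineageParams:
    """Lineage rates seen by one cell, after any calcium feedback.

    Non-signal variants (or zero signal) reduce exactly to the genotype's
    Ovol modulation.  In the Signal variant the saturating calcium response
    raises the effective Ovol1 level of mature spinous cells and the
    effective Ovol2 level of basal cells.
    """
    if variant != "signal" or feedback is None:
        return ovol_modulate(reg)
    h = feedback.hill(local_signal)
    if stage == 0:
        reg = replace(reg, beta=reg.beta * (1.0 + feedback.k_beta * h))
    elif stage == 2:
        reg = replace(reg, alpha=reg.alpha * (1.0 + feedback.k_alpha * h))
    return ovol_modulate(reg)


def _sphere_points(
    n: int, radius: float, center: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radii = radius * rng.random((n, 1)) ** (1 / 3)
    return center + pts / norms * radii


def init_tissue(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tissue:
    """Build and mechanically relax the initial basal monolayer.

    ``nx x ny`` basal cells on a square grid at z = 0, each a ball of
    elements at the mature size with a uniformly random cell-cycle phase,
    pre-relaxed by noise-free mechanics steps so t = 0 starts from
    quasi-equilibrium.  Deterministic given the seed.
    """
    if rng is None:
        rng = config.spawn_rngs()["placement"]
    lx, ly, _ = config.box
    spacing_x = lx / config.nx_cells
    spacing_y = ly / config.ny_cells
    d = config.mech.cell_diameter
    if min(spacing_x, spacing_y) < 0.5 * d:
        raise ValueError(
            f"initial layout overcrowded: grid spacing {min(spacing_x, spacing_y):.2f} um "
            f"is below half a cell diameter ({0.5 * d:.2f} um)"
        )
    reg = config.genotype_regulation()
    base = ovol_modulate(reg)
    tissue = Tissue(box=config.box, periodic_xy=config.periodic_xy)
    z0 = 0.35 * d
    for i in range(config.nx_cells):
        for j in range(config.ny_cells):
            center = np.array([(i + 0.5) * spacing_x, (j + 0.5) * spacing_y, z0])
            k = config.life.target_elements
            pts = _sphere_points(k, 0.45 * d, center, rng)
            pts[:, 2] = np.abs(pts[:, 2] - z0) * 0.8 + 0.1 * d  # keep above membrane
            clen = new_cycle_length(base.v0, rng, config.life.cycle_jitter)
            cell = Cell(
                cell_id=tissue.new_cell_id(),
                stage=0,
                elements=pts,
                adherent=np.zeros(k, dtype=bool),
                cycle_clock=rng.random() * clen,
                cycle_length=clen,
                target_elements=config.life.target_elements,
            )
            init_growth(cell, 0.0, config.life)
            tissue.cells.append(cell)
    tissue.relabel_adherent()
    # noise-free relaxation to mechanical quasi-equilibrium
    index = NeighborIndex(tissue, config.mech)
    pos, *_ = tissue.flatten()
    for _ in range(config.relax_steps):
        forces, _ = assemble_forces(tissue, index, config.mech, pos=pos)
        pos, _ = step_positions(pos, forces, config.mech, rng=None)
        if index.stale(pos):
            tissue.scatter(pos)
            index.build(tissue)
    tissue.scatter(pos)
    tissue.relabel_adherent()
    return tissue


@dataclass
class RunResult:
    """Outputs of one simulation run."""

    config: SimulationConfig
    tissue: Tissue
    grid: Optional[MorphogenGrid]
    reports: list[MetricsReport]
    events: pd.DataFrame
    counts: pd.DataFrame  # per-hour per-stage cell counts
    stopped_early: bool = False

    def final_report(self) -> MetricsReport:
        return self.reports[-1]


def _make_grid(config: SimulationConfig) -> MorphogenGrid:
    kw = dict(config.morphogen)
    return MorphogenGrid.for_box(
        config.box, h=config.grid_h, periodic_xy=config.periodic_xy, **kw
    )


def run(config: SimulationConfig, progress: bool = False) -> RunResult:
    """Run the multiscale simulation described by ``config``.

    Bit-reproducible for a fixed config and seed: all randomness flows from
    named child streams of the top-level seed, so disabling one mechanism
    does not shift another's draws.
    """
    rngs = config.spawn_rngs()
    tissue = init_tissue(config, rngs["placement"])
    reg = config.genotype_regulation()
    base_params = ovol_modulate(reg)
    grid = _make_grid(config) if config.variant == "signal" else None

    mech = config.mech
    life = config.life
    n_sub = max(1, int(round(config.dt_life * config.mech_substeps)))
    index = NeighborIndex(tissue, mech)

    events: list[dict] = []
    reports: list[MetricsReport] = []
    count_rows: list[dict] = []
    next_snapshot = 0.0
    stopped = False

    def snapshot() -> None:
        reports.append(compute_report(tissue, cell_diameter=mech.cell_diameter))

    def log_counts() -> None:
        stages = tissue.stages()
        count_rows.append(
            {
                "t": tissue.time,
                "C0": int((stages == 0).sum()),
                "C1": int((stages == 1).sum()),
                "C2": int((stages == 2).sum()),
                "C3": int((stages == 3).sum()),
                "total": int(len(stages)),
            }
        )

    snapshot()
    log_counts()
    next_snapshot = config.snapshot_every

    t = 0.0
    noise_rng = rngs["mechanics_noise"] if mech.noise_amp > 0 else None
    while t < config.duration - 1e-9:
        # --- mechanics block ---
        pos, *_ = tissue.flatten()
        for _ in range(n_sub):
            if index.stale(pos):
                tissue.scatter(pos)
                index.build(tissue)
            forces, _ = assemble_forces(tissue, index, mech, pos=pos)
            pos, _ = step_positions(pos, forces, mech, rng=noise_rng)
        tissue.scatter(pos)

        t += config.dt_life
        tissue.time = t
        for c in tissue.cells:
            c.cycle_clock += config.dt_life

        # --- lifecycle: removal, then division, then differentiation, growth ---
        survivors: list[Cell] = []
        for c in tissue.cells:
            if c.stage == 3:
                removed, gone = remove_granular(c, t, life)
                if removed:
                    events.append(
                        {"time": t, "event": "shrink", "cell_id": c.cell_id,
                         "details": f"-{removed} elements"}
                    )
                if gone:
                    events.append(
                        {"time": t, "event": "remove", "cell_id": c.cell_id, "details": ""}
                    )
                    continue
            survivors.append(c)
        tissue.cells = survivors

        div_rng = rngs["division"]
        new_cells: list[Cell] = []
        for c in tissue.cells:
            event: Optional[DivisionEvent] = None
            if c.stage in (0, 1):
                params_eff = effective_rates(
                    c.stage, reg, c.signal, config.feedback, config.variant
                )
                event = decide_division(c, params_eff, config.variant, div_rng, life)
            if event is None:
                new_cells.append(c)
                continue
            clens = tuple(
                new_cycle_length(
                    params_eff.v0 if st == 0 else params_eff.v1,
                    div_rng, life.cycle_jitter,
                )
                for st in event.daughter_stages
            )
            d1, d2c = divide_cell(tissue, c, event, div_rng, clens, life)
            d1.signal = d2c.signal = c.signal
            new_cells.extend([d1, d2c])
            events.append(
                {
                    "time": t,
                    "event": "divide_asym" if event.mode == "asymmetric" else "divide_sym",
                    "cell_id": c.cell_id,
                    "details": f"-> {d1.cell_id}({d1.stage}), {d2c.cell_id}({d2c.stage})",
                }
            )
        tissue.cells = new_cells

        diff_rng = rngs["differentiation"]
        for c in tissue.cells:
            if c.stage != 2:
                continue
            params_eff = effective_rates(
                c.stage, reg, c.signal, config.feedback, config.variant
            )
            if differentiate_mature(c, params_eff.d2, config.dt_life, diff_rng,
                                    mode=life.maturation):
                c.stage = 3
                c.cycle_clock = 0.0
                c.cycle_length = new_cycle_length(
                    params_eff.d3, diff_rng, life.cycle_jitter
                )
                events.append(
                    {"time": t, "event": "differentiate", "cell_id": c.cell_id,
                     "details": "C2->C3"}
                )

        life_rng = rngs["lifecycle"]
        for c in tissue.cells:
            if grow_cell(c, t, life, life_rng):
                events.append(
                    {"time": t, "event": "grow", "cell_id": c.cell_id, "details": ""}
                )
        tissue.relabel_adherent()

        # --- morphogen block (Signal variant only) ---
        if grid is not None:
            counts = element_density(tissue, grid)
            diffusivity = local_diffusivity(grid, counts)
            source = deposit_secretion(tissue, grid)
            step_field(grid, source=source, diffusivity=diffusivity)
            for c in tissue.cells:
                c.signal = sample_field(c, grid)

        index = NeighborIndex(tissue, mech)  # topology changed
        log_counts()
        if t >= next_snapshot - 1e-9:
            snapshot()
            next_snapshot += config.snapshot_every
        if tissue.n_elements > config.max_elements:
            stopped = True
            break
        if progress:
            print(f"t={t:7.1f} h  cells={tissue.n_cells}", flush=True)

    if not reports or reports[-1].time < tissue.time:
        snapshot()
    ev = pd.DataFrame(events, columns=["time", "event", "cell_id", "details"])
    return RunResult(
        config=config,
        tissue=tissue,
        grid=grid,
        reports=reports,
        events=ev,
        counts=pd.DataFrame(count_rows),
        stopped_early=stopped,
    )


# ---------------------------------------------------------------------------
# pattern classification and parameter sweeps


@dataclass(frozen=True)
class PatternThresholds:
    """Rule-based thresholds replacing the by-eye pattern calls."""

    purity_min: float = 0.7        # dominant-class fraction per slice
    purity_slice_frac: float = 0.7  # fraction of slices that must be pure
    isolation_max: float = 0.1     # per-type Isolation Ratio bound
    cavity_frac_max: float = 0.10  # empty interior voxel fraction
    salt_pepper_si: float = 0.25   # suprabasal SI below this -> salt-pepper


def _slice_purity(tissue: Tissue, thickness: float) -> list[float]:
    pts = tissue.centroids()
    if len(pts) == 0:
        return []
    classes = stage_to_class(tissue.stages())
    zmax = pts[:, 2].max()
    out = []
    for k in range(max(1, int(np.ceil((zmax + 1e-9) / thickness)))):
        sel = (pts[:, 2] >= k * thickness) & (pts[:, 2] < (k + 1) * thickness)
        if sel.sum() == 0:
            continue
        counts = np.bincount(classes[sel], minlength=3)
        out.append(counts.max() / counts.sum())
    return out


def _cavity_fraction(tissue: Tissue, voxel: float) -> float:
    """Fraction of below-surface voxels containing no element."""
    pos = np.vstack([c.elements for c in tissue.cells]) if tissue.cells else np.empty((0, 3))
    if len(pos) == 0:
        return 0.0
    lx, ly, _ = tissue.box
    nx = max(1, int(round(lx / voxel)))
    ny = max(1, int(round(ly / voxel)))
    nz = max(1, int(np.ceil((pos[:, 2].max() + 1e-9) / voxel)))
    ix = np.clip((pos[:, 0] % lx / lx * nx).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, 1] % ly / ly * ny).astype(int), 0, ny - 1)
    iz = np.clip((pos[:, 2] / voxel).astype(int), 0, nz - 1)
    occ = np.zeros((nx, ny, nz), dtype=bool)
    occ[ix, iy, iz] = True
    interior = empty = 0
    for a in range(nx):
        for b in range(ny):
            col = occ[a, b]
            if not col.any():
                continue
            top = np.flatnonzero(col).max()
            interior += top + 1
            empty += int((~col[: top + 1]).sum())
    return empty / interior if interior else 0.0


def classify_pattern(
    tissue: Tissue,
    cell_diameter: float = 9.0,
    thresholds: PatternThresholds = PatternThresholds(),
) -> str:
    """Classify a final tissue into one of the qualitative outcome patterns:
    ``stratified``, ``salt_pepper``, ``cavity``, or ``mixed``."""
    cavity = _cavity_fraction(tissue, cell_diameter)
    if cavity > thresholds.cavity_frac_max:
        return "cavity"
    purity = _slice_purity(tissue, cell_diameter)
    purity_ok = (
        len(purity) > 0
        and np.mean([p >= thresholds.purity_min for p in purity])
        >= thresholds.purity_slice_frac
    )
    report = compute_report(tissue, cell_diameter=cell_diameter)
    iso_ok = all(
        not np.isfinite(report.isolation[cls]) or report.isolation[cls] <= thresholds.isolation_max
        for cls in (1, 2)
    )
    if purity_ok and iso_ok:
        return "stratified"
    supra = report.slice_si[1:]
    supra = supra[np.isfinite(supra)]
    if len(supra) and np.median(supra) < thresholds.salt_pepper_si:
        return "salt_pepper"
    return "mixed"


def sweep(
    config_template: SimulationConfig,
    axis: str,
    values,
    seeds=(0, 1, 2),
) -> pd.DataFrame:
    """Replicate runs along one config axis, with pattern classification.

    ``axis`` may name a SimulationConfig / MechanicsParams / LifecycleParams /
    OvolRegulation field, or the derived ratio ``Fa_over_Fb`` (sets Fa with
    Fb held at the template value).
    """
    rows = []
    for v in values:
        for seed in seeds:
            cfg = _config_with(config_template, axis, v)
            cfg = dataclasses.replace(cfg, seed=int(seed))
            res = run(cfg)
            rep = res.final_report()
            si = rep.slice_si[np.isfinite(rep.slice_si)]
            rows.append(
                {
                    "axis": axis,
                    "value": v,
                    "seed": seed,
                    "pattern": classify_pattern(res.tissue, cfg.mech.cell_diameter),
                    "median_SI": float(np.median(si)) if len(si) else np.nan,
                    "iso_spinous": rep.isolation[1],
                    "iso_granular": rep.isolation[2],
                    "n_cells": rep.counts["total"],
                    "stopped_early": res.stopped_early,
                }
            )
    return pd.DataFrame(rows)


def _config_with(template: SimulationConfig, axis: str, value) -> SimulationConfig:
    if axis == "Fa_over_Fb":
        mech = replace(template.mech, Fa=value * template.mech.Fb)
        return dataclasses.replace(template, mech=mech)
    for holder_name in ("mech", "life", "reg", "feedback"):
        holder = getattr(template, holder_name)
        if hasattr(holder, axis):
            return dataclasses.replace(
                template, **{holder_name: replace(holder, **{axis: value})}
            )
    if hasattr(template, axis):
        return dataclasses.replace(template, **{axis: value})
    raise ValueError(f"unknown sweep axis {axis!r}")
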
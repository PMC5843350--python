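"""Stratification metrics: slice images, Sharpness Index, Isolation Ratio,
per-slice Ripley's K, and per-type counts.

A tissue is cut into horizontal slices of about one cell diameter.  Each
slice is rasterized into a 10 x 10 label image (0 basal, 1 spinous — the
proliferative and mature stages share a label — 2 granular).  The Sharpness
Index of a slice image is one minus the mean squared central difference over
the interior pixels,

    SI = 1 - (1 / (2 #I)) * sum_I [(g(x+1,y)-g(x-1,y))^2 + (g(x,y+1)-g(x,y-1))^2],

so a perfectly uniform (fully polarized) slice scores 1 and strong label
mixing drives the score down (the floor is -3 for labels in {0,1,2}).

The Isolation Ratio of a cell type is the fraction of that type's cells
lying outside its largest, appropriately positioned connected cluster
(cells are "touching" when their centroids are within 1.2 cell diameters);
0 means perfect self-aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .tissue import Tissue, stage_to_class

__all__ = [
    "SliceImage",
    "MetricsReport",
    "rasterize_slice",
    "sharpness_index",
    "isolation_ratio",
    "ripley_k",
    "count_cells",
    "compute_report",
]

N_PIX = 10


@dataclass
class SliceImage:
    """A 10 x 10 label image of one horizontal slice.

    ``pixels`` holds labels in {0, 1, 2}; ``mask`` is True where at least one
    cell centroid fell in the pixel (unoccupied pixels are filled from the
    nearest occupied pixel but stay masked out of the Sharpness Index).
    """

    pixels: np.ndarray
    mask: np.ndarray
    z: float
    thickness: float

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())


def _labels_from_stages(stages: np.ndarray) -> np.ndarray:
    return stage_to_class(stages).astype(np.int64)


def rasterize_slice(
    tissue_or_points,
    z: float,
    thickness: float,
    stages: Optional[np.ndarray] = None,
    bounds: Optional[tuple[float, float, float, float]] = None,
) -> SliceImage:
    """Rasterize the cells with centroid in [z, z + thickness) to a label image.

    Accepts either a :class:`Tissue` or an (n, 3) centroid array plus
    ``stages``.  Pixel label = modal cell-class among the centroids in the
    pixel's x-y bin, ties broken toward the lowest label; empty pixels are
    filled from the nearest occupied pixel and masked.
    """
    if thickness <= 0:
        raise ValueError("slice thickness must be positive")
    if isinstance(tissue_or_points, Tissue):
        tissue = tissue_or_points
        pts = tissue.centroids()
        stages = tissue.stages()
        lx, ly, _ = tissue.box
        if tissue.periodic_xy and len(pts):
            pts = pts.copy()
            pts[:, 0] %= lx
            pts[:, 1] %= ly
        bounds = (0.0, lx, 0.0, ly)
    else:
        pts = np.asarray(tissue_or_points, dtype=float)
        if stages is None:
            raise ValueError("stages required when passing raw centroids")
        if bounds is None:
            raise ValueError("bounds required when passing raw centroids")
    x0, x1, y0, y1 = bounds

    labels = _labels_from_stages(np.asarray(stages))
    in_slice = (pts[:, 2] >= z) & (pts[:, 2] < z + thickness) if len(pts) else np.array([], bool)
    pix = np.zeros((N_PIX, N_PIX), dtype=np.int64)
    mask = np.zeros((N_PIX, N_PIX), dtype=bool)
    if in_slice.any():
        p = pts[in_slice]
        lab = labels[in_slice]
        ix = np.clip(((p[:, 0] - x0) / (x1 - x0) * N_PIX).astype(int), 0, N_PIX - 1)
        iy = np.clip(((p[:, 1] - y0) / (y1 - y0) * N_PIX).astype(int), 0, N_PIX - 1)
        for px in range(N_PIX):
            for py in range(N_PIX):
                sel = (ix == px) & (iy == py)
                if not sel.any():
                    continue
                counts = np.bincount(lab[sel], minlength=3)
                pix[px, py] = int(np.argmax(counts))  # argmax -> lowest label on ties
                mask[px, py] = True
        if not mask.all():
            occ = np.argwhere(mask)
            emp = np.argwhere(~mask)
            tree = cKDTree(occ)
            _, nearest = tree.query(emp)
            pix[emp[:, 0], emp[:, 1]] = pix[occ[nearest, 0], occ[nearest, 1]]
    return SliceImage(pixels=pix, mask=mask, z=z, thickness=thickness)


def sharpness_index(img: SliceImage | np.ndarray) -> float:
    """Sharpness Index of a slice image (NaN if no occupied interior pixel).

    Evaluated over the interior domain (the image minus its boundary ring),
    restricted to occupied pixels when a mask is present.
    """
    if isinstance(img, SliceImage):
        g = np.asarray(img.pixels, dtype=float)
        mask = img.mask
    else:
        g = np.asarray(img, dtype=float)
        mask = np.ones_like(g, dtype=bool)
    nx, ny = g.shape
    interior = np.zeros_like(mask)
    interior[1 : nx - 1, 1 : ny - 1] = True
    valid = interior & mask
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    dx = g[2:, 1:-1] - g[:-2, 1:-1]
    dy = g[1:-1, 2:] - g[1:-1, :-2]
    sq = dx**2 + dy**2
    total = sq[valid[1 : nx - 1, 1 : ny - 1]].sum()
    return 1.0 - total / (2.0 * n)


def _clusters(points: np.ndarray, link_radius: float) -> np.ndarray:
    """Connected-component labels for centroids linked within ``link_radius``."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    g = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, lab = connected_components(g, directed=False)
    return lab


def isolation_ratio(
    tissue_or_points,
    cell_type: Optional[int] = None,
    cell_diameter: float = 9.0,
    link_factor: float = 1.2,
    expected_z: Optional[float] = None,
) -> float:
    """Fraction of a type's cells outside its main connected cluster.

    ``cell_type`` is an adhesion class (0 basal, 1 spinous, 2 granular).
    Ties for the largest cluster are broken toward the cluster whose mean
    height is closest to ``expected_z`` (the type's expected layer band;
    defaults to the stacked mean height of the type).  NaN if the type is
    absent.
    """
    if isinstance(tissue_or_points, Tissue):
        tissue = tissue_or_points
        pts = tissue.centroids()
        classes = stage_to_class(tissue.stages())
        if cell_type is None:
            raise ValueError("cell_type required")
        pts = pts[classes == cell_type]
    else:
        pts = np.asarray(tissue_or_points, dtype=float)
    n = len(pts)
    if n == 0:
        return float("nan")
    lab = _clusters(pts, link_factor * cell_diameter)
    sizes = np.bincount(lab)
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        ref = float(np.mean(pts[:, 2])) if expected_z is None else expected_z
        zdist = [abs(pts[lab == c, 2].mean() - ref) for c in candidates]
        target = candidates[int(np.argmin(zdist))]
    else:
        target = candidates[0]
    return float(n - sizes[target]) / n


def ripley_k(
    points_xy: np.ndarray,
    area: float,
    radii: Sequence[float],
    box: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Ripley's K function of a 2D point pattern.

    ``K(r) = A / (n (n-1)) * sum_{i != j} 1[d_ij <= r]``.  If ``box`` is
    given, distances use the periodic minimum image (no edge correction is
    then needed).  Requires at least two points (NaN otherwise).
    """
    pts = np.asarray(points_xy, dtype=float)
    n = len(pts)
    radii = np.asarray(radii, dtype=float)
    if n < 2:
        return np.full(len(radii), np.nan)
    d = pts[:, None, :] - pts[None, :, :]
    if box is not None:
        d[..., 0] -= box[0] * np.rint(d[..., 0] / box[0])
        d[..., 1] -= box[1] * np.rint(d[..., 1] / box[1])
    dist = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu]
    counts = np.array([(pair_d <= r).sum() * 2 for r in radii], dtype=float)
    return area * counts / (n * (n - 1))


def count_cells(tissue: Tissue) -> dict[str, int]:
    """Exact per-stage cell counts, plus the combined K1+ spinous pool."""
    stages = tissue.stages()
    out = {f"C{i}": int((stages == i).sum()) for i in range(4)}
    out["C1+C2"] = out["C1"] + out["C2"]
    out["total"] = int(len(stages))
    return out


@dataclass
class MetricsReport:
    """Per-snapshot stratification metrics."""

    time: float
    slice_z: np.ndarray
    slice_si: np.ndarray
    isolation: dict[int, float]
    counts: dict[str, int]
    ripley: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "z": self.slice_z, "SI": self.slice_si})


def compute_report(
    tissue: Tissue,
    cell_diameter: float = 9.0,
    thickness: Optional[float] = None,
    ripley_radii: Optional[Sequence[float]] = None,
) -> MetricsReport:
    """Slice the tissue, compute SI per slice, isolation per class, counts.

    The default slice thickness is three quarters of the packed cell
    diameter: the simulated cells are oblate (their vertical size is smaller
    than their in-plane diameter), so "about one cell size" along z is
    thinner than the lateral packing distance.
    """
    thickness = 0.75 * cell_diameter if thickness is None else thickness
    pts = tissue.centroids()
    zmax = pts[:, 2].max() if len(pts) else 0.0
    n_slices = max(1, int(np.ceil((zmax + 1e-9) / thickness)))
    zs, sis = [], []
    for k in range(n_slices):
        img = rasterize_slice(tissue, k * thickness, thickness)
        zs.append(k * thickness)
        sis.append(sharpness_index(img))
    classes = stage_to_class(tissue.stages()) if tissue.n_cells else np.array([], dtype=int)
    isolation = {}
    for cls in (0, 1, 2):
        if (classes == cls).any():
            isolation[cls] = isolation_ratio(
                tissue, cell_type=cls, cell_diameter=cell_diameter
            )
        else:
            isolation[cls] = float("nan")
    rip = None
    if ripley_radii is not None:
        lx, ly, _ = tissue.box
        rows = []
        for k in range(n_slices):
            in_slice = (pts[:, 2] >= k * thickness) & (pts[:, 2] < (k + 1) * thickness)
            kk = ripley_k(
                pts[in_slice][:, :2] % [lx, ly],
                lx * ly,
                ripley_radii,
                box=(lx, ly) if tissue.periodic_xy else None,
            )
            for r, v in zip(ripley_radii, kk):
                rows.append({"z": k * thickness, "r": r, "K": v})
        rip = pd.DataFrame(rows)
    return MetricsReport(
        time=tissue.time,
        slice_z=np.array(zs),
        slice_si=np.array(sis),
        isolation=isolation,
        counts=count_cells(tissue),
        ripley=rip,
    )
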
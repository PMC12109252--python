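"""Spatial diagnostics: global Moran's I and kernel-density surfaces.

Moran's I measures global spatial autocorrelation of a raster field under a
contiguity weight matrix (queen or rook neighborhoods, row-standardized by
default, truncated at the grid edge, zero diagonal):

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),   z = x - mean(x)

+1 indicates clustering, the permutation-null expectation is -1/(n-1), and
-1 is perfect dispersion (e.g. a checkerboard under rook weights).

Kernel density evaluates a Gaussian kernel sum at cell centers (per-m^2
units), so the surface integrated over the grid approximately recovers the
point count when the bandwidth is small relative to the extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .errors import ConfigError, InputError, StatisticError
from .grid import GridSpec, Raster
from .matching import OccurrencePoint


@dataclass(frozen=True)
class SpatialWeights:
    """Contiguity scheme for raster cells."""

    scheme: str = "queen"
    row_standardized: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in {"rook", "queen"}:
            raise ConfigError("scheme must be 'rook' or 'queen'")


_OFFSETS = {
    "rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "queen": [(-1, 0), (1, 0), (0, -1), (0, 1),
              (-1, -1), (-1, 1), (1, -1), (1, 1)],
}


def _weight_matrix(mask: np.ndarray, scheme: str) -> sparse.csr_matrix:
    """Sparse symmetric binary contiguity matrix over valid cells."""
    n_rows, n_cols = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(mask.sum())
    rows_i, rows_j = [], []
    rr, cc = np.nonzero(mask)
    for dr, dc in _OFFSETS[scheme]:
        r2, c2 = rr + dr, cc + dc
        inb = (r2 >= 0) & (r2 < n_rows) & (c2 >= 0) & (c2 < n_cols)
        r1, c1, r2, c2 = rr[inb], cc[inb], r2[inb], c2[inb]
        ok = mask[r2, c2]
        rows_i.append(idx[r1[ok], c1[ok]])
        rows_j.append(idx[r2[ok], c2[ok]])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    n = int(mask.sum())
    return sparse.csr_matrix((np.ones_like(i, dtype=float), (i, j)),
                             shape=(n, n))


def morans_i(raster: Raster, weights: SpatialWeights = SpatialWeights()) -> float:
    """Global Moran's I of a raster field under contiguity weights."""
    mask = raster.mask
    n = int(mask.sum())
    if n < 2:
        raise StatisticError("Moran's I needs at least two valid cells")
    x = raster.values[mask]
    z = x - x.mean()
    denom = float((z ** 2).sum())
    if denom == 0:
        raise StatisticError("Moran's I is undefined for a constant field")
    w = _weight_matrix(mask, weights.scheme)
    if weights.row_standardized:
        rowsum = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(rowsum > 0, 1.0 / rowsum, 0.0)
        w = sparse.diags(inv) @ w
    s0 = float(w.sum())
    num = float(z @ (w @ z))
    return (n / s0) * num / denom


def morans_i_permutation_p(raster: Raster,
                           weights: SpatialWeights = SpatialWeights(),
                           n_perm: int = 199, seed: int = 0) -> tuple[float, float]:
    """Moran's I with a simple one-sided permutation p-value."""
    obs = morans_i(raster, weights)
    rng = np.random.default_rng(seed)
    mask = raster.mask
    vals = raster.values[mask].copy()
    count = 0
    for _ in range(n_perm):
        perm = raster.values.copy()
        perm[mask] = rng.permutation(vals)
        if morans_i(Raster(raster.grid, perm, raster.nodata), weights) >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)


def kernel_density(points: Sequence[OccurrencePoint], grid: GridSpec,
                   bandwidth: float) -> Raster:
    """Gaussian kernel-density surface (per m^2) at cell centers."""
    pts = list(points)
    if not pts:
        raise InputError("kernel density needs at least one point")
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be positive")
    cx, cy = grid.cell_centers()
    out = np.zeros(grid.shape)
    norm = 1.0 / (2.0 * np.pi * bandwidth ** 2)
    xs = np.array([p.x for p in pts])
    ys = np.array([p.y for p in pts])
    for i in range(0, len(xs), 256):
        dx = cx[..., None] - xs[i:i + 256]
        dy = cy[..., None] - ys[i:i + 256]
        out += norm * np.exp(-(dx ** 2 + dy ** 2)
                             / (2.0 * bandwidth ** 2)).sum(axis=-1)
    return Raster(grid, out, nodata=-9999.0)
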
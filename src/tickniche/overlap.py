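"""Niche overlap in gridded climate space: densities, Schoener's D, equivalency.

The retained PCA axes are discretized into an r-per-axis grid (d = 2 or 3).
For each species three normalized densities live on that grid:

* ``o`` — Gaussian-kernel-smoothed density of the species' occurrence scores;
* ``e`` — the same smoothing applied to the background (availability) scores,
  i.e. the density of climates that exist in the study window at all;
* ``z`` — occupancy: with availability correction on (the default),
  ``z ∝ o/e`` on inhabitable cells (e above a mass floor) renormalized to sum
  to 1, which measures use relative to availability rather than raw record
  density; with correction off, ``z = o``.

Overlap between two species is Schoener's D::

    D = 1 - 0.5 * Σ_cells |z1 - z2|      (0 = disjoint, 1 = identical)

The equivalency test asks whether two species' niches are interchangeable:
the pooled occurrence scores are randomly re-partitioned into the original
sample sizes (without replacement), D is recomputed through the full density
pipeline per replicate, and the one-sided lower-tail p-value is
``(1 + #{D_null <= D_obs}) / (N + 1)``.  Equivalency is rejected when the
observed niches are less similar than random reallocation produces.

Kernels are separable product Gaussians, so a d-dimensional density is a
tensor contraction of per-axis point-by-bin Gaussian matrices; this keeps
r = 100 grids fast even inside a permutation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Cells whose availability is below this fraction of total background mass
#: are treated as uninhabitable (z forced to 0) under availability correction.
EPSILON_MASS = 1e-12


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular d-dimensional partition of the retained climate axes.

    Per-axis bounds are the pooled [min, max] of background and occurrence
    scores expanded by ``margin`` (a fraction of the range on each side).
    Bins are half-open [low, high) with the last bin closed, so every score
    lies in exactly one cell and edge points go to the higher bin.
    """

    d: int
    r: int
    bounds: tuple[tuple[float, float], ...]
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.d not in (2, 3) and self.d != 1:  # d=1 kept for tests/diagnostics
            raise ValueError("d must be 1, 2 or 3")
        if self.r < 2:
            raise ValueError("need at least 2 bins per axis")
        if len(self.bounds) != self.d:
            raise ValueError("bounds must have one (min, max) pair per axis")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"degenerate axis: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.r,) * self.d

    @property
    def widths(self) -> np.ndarray:
        return np.array([(hi - lo) / self.r for lo, hi in self.bounds])

    def centers(self, axis: int) -> np.ndarray:
        lo, hi = self.bounds[axis]
        w = (hi - lo) / self.r
        return lo + w * (np.arange(self.r) + 0.5)

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Cell index per point, shape (n, d).  Raises if a point is outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.d:
            raise ValueError(f"points must be {self.d}-dimensional")
        idx = np.empty(pts.shape, dtype=int)
        for a, (lo, hi) in enumerate(self.bounds):
            x = pts[:, a]
            if (x < lo).any() or (x > hi).any():
                raise ValueError(f"point outside grid bounds on axis {a}")
            w = (hi - lo) / self.r
            i = np.floor((x - lo) / w).astype(int)
            i[x == hi] = self.r - 1          # close the last bin
            idx[:, a] = np.minimum(i, self.r - 1)
        return idx


def make_grid(
    background_scores: np.ndarray,
    occurrence_scores: np.ndarray | None = None,
    d: int = 2,
    r: int = 100,
    margin: float = 0.05,
) -> GridSpec:
    """Build the climate-space grid covering all supplied scores."""
    pools = [np.atleast_2d(np.asarray(background_scores, dtype=float))]
    if occurrence_scores is not None and len(occurrence_scores):
        pools.append(np.atleast_2d(np.asarray(occurrence_scores, dtype=float)))
    pooled = np.vstack([p[:, :d] for p in pools])
    if pooled.size == 0:
        raise ValueError("no scores supplied")
    bounds = []
    for a in range(d):
        lo, hi = float(pooled[:, a].min()), float(pooled[:, a].max())
        if lo == hi:
            raise ValueError(f"degenerate axis {a}: all scores equal {lo}")
        pad = margin * (hi - lo)
        bounds.append((lo - pad, hi + pad))
    return GridSpec(d=d, r=r, bounds=tuple(bounds), margin=margin)


# ---------------------------------------------------------------------------
# Kernel density on the grid
# ---------------------------------------------------------------------------


def silverman_bandwidths(points: np.ndarray, multiplier: float = 1.0) -> np.ndarray:
    """Per-axis Gaussian bandwidths by Silverman's d-dimensional rule.

    h_a = sigma_a * (4 / (n * (d + 2)))**(1 / (d + 4)) * multiplier, with a
    floor at a tiny positive value so degenerate samples stay usable.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    sigma = pts.std(axis=0, ddof=1) if n > 1 else np.ones(d)
    factor = (4.0 / (n * (d + 2))) ** (1.0 / (d + 4))
    h = sigma * factor * multiplier
    return np.maximum(h, 1e-12)


def kernel_density(
    points: np.ndarray, grid: GridSpec, bandwidths: float | Sequence[float] | np.ndarray
) -> np.ndarray:
    """Normalized product-Gaussian mixture density at all cell centers.

    Evaluates ``Σ_p Π_a exp(-((c_a - x_pa)/h_a)² / 2)`` at every center and
    renormalizes to sum to 1 over the grid (the Gaussian constant cancels).
    Separable kernels make this a per-axis matrix contraction.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[1] != grid.d:
        raise ValueError(f"points must be {grid.d}-dimensional")
    h = np.broadcast_to(np.asarray(bandwidths, dtype=float), (grid.d,)).copy()
    if (h <= 0).any():
        raise ValueError("bandwidths must be positive")
    # G[a] has shape (n_points, r): Gaussian factor along axis a.
    G = [
        np.exp(-0.5 * ((grid.centers(a)[None, :] - pts[:, a][:, None]) / h[a]) ** 2)
        for a in range(grid.d)
    ]
    if grid.d == 1:
        dens = G[0].sum(axis=0)
    elif grid.d == 2:
        dens = G[0].T @ G[1]
    else:
        dens = np.einsum("ni,nj,nk->ijk", G[0], G[1], G[2])
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density vanished on the grid (bandwidth too small?)")
    return dens / total


def occupancy(
    o: np.ndarray, e: np.ndarray, correct_by_availability: bool = True
) -> np.ndarray:
    """Availability-corrected occupancy z from occurrence and background densities."""
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if o.shape != e.shape:
        raise ValueError("o and e must live on the same grid")
    if not correct_by_availability:
        return o.copy()
    habitable = e > EPSILON_MASS
    if not habitable.any():
        raise ValueError("availability density entirely below the mass floor")
    z = np.zeros_like(o)
    z[habitable] = o[habitable] / e[habitable]
    total = z.sum()
    if total == 0:
        raise ValueError("occurrence density has no mass on habitable cells")
    return z / total


@dataclass
class NicheDensity:
    """Kernel-smoothed occupancy of one species on the climate-space grid."""

    species: str
    grid: GridSpec
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    bandwidths: np.ndarray
    n_occurrences: int


def niche_density(
    species: str,
    occurrence_scores: np.ndarray,
    background_scores: np.ndarray,
    grid: GridSpec | None = None,
    d: int = 2,
    r: int = 100,
    margin: float = 0.05,
    bandwidth_mult: float = 1.0,
    correct_by_availability: bool = True,
    e: np.ndarray | None = None,
) -> NicheDensity:
    """Run the full density pipeline for one species.

    Occurrence bandwidths follow Silverman's rule on the occurrence scores
    (times ``bandwidth_mult``); the availability density ``e`` uses its own
    Silverman bandwidths on the background unless supplied precomputed (the
    background does not change between species on a shared grid).
    """
    occ = np.atleast_2d(np.asarray(occurrence_scores, dtype=float))[:, :d]
    bg = np.atleast_2d(np.asarray(background_scores, dtype=float))[:, :d]
    if grid is None:
        grid = make_grid(bg, occ, d=d, r=r, margin=margin)
    h = silverman_bandwidths(occ, bandwidth_mult)
    o = kernel_density(occ, grid, h)
    if e is None:
        e = kernel_density(bg, grid, silverman_bandwidths(bg, bandwidth_mult))
    z = occupancy(o, e, correct_by_availability)
    return NicheDensity(
        species=species, grid=grid, o=o, e=e, z=z,
        bandwidths=h, n_occurrences=occ.shape[0],
    )


# ---------------------------------------------------------------------------
# Schoener's D and the equivalency test
# ---------------------------------------------------------------------------


def schoener_d(z1: np.ndarray | NicheDensity, z2: np.ndarray | NicheDensity) -> float:
    """Schoener's D = 1 - 0.5 Σ|z1 - z2| between two normalized occupancies."""
    if isinstance(z1, NicheDensity) and isinstance(z2, NicheDensity):
        if z1.grid != z2.grid:
            raise ValueError("densities are on different grids")
        z1, z2 = z1.z, z2.z
    a = np.asarray(z1, dtype=float)
    b = np.asarray(z2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("occupancies must share a grid")
    d = 1.0 - 0.5 * np.abs(a - b).sum()
    return float(min(1.0, max(0.0, d)))


@dataclass
class OverlapResult:
    """Observed D for a species pair with its permutation null."""

    species: tuple[str, str]
    D: float
    n_permutations: int
    null_D: np.ndarray
    p_value: float
    seed: int | None = None


def equivalency_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    background_scores: np.ndarray,
    labels: tuple[str, str] = ("species_1", "species_2"),
    d: int = 2,
    r: int = 100,
    margin: float = 0.05,
    bandwidth_mult: float = 1.0,
    correct_by_availability: bool = True,
    n_permutations: int = 99,
    seed: int | None = None,
) -> OverlapResult:
    """Warren-style niche equivalency test on the full density pipeline.

    The grid and the availability density are fixed by the pooled inputs
    (permutation does not alter which climates exist); occurrence densities
    and their Silverman bandwidths are recomputed per replicate, exactly as
    for the observed statistic.  Requires >= 5 occurrences per species and
    >= 19 permutations.  Reproducible for a fixed seed.
    """
    occ1 = np.atleast_2d(np.asarray(occ1, dtype=float))[:, :d]
    occ2 = np.atleast_2d(np.asarray(occ2, dtype=float))[:, :d]
    for label, occ in zip(labels, (occ1, occ2)):
        if occ.shape[0] < 5:
            raise ValueError(f"{label}: need at least 5 occurrences, got {occ.shape[0]}")
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    bg = np.atleast_2d(np.asarray(background_scores, dtype=float))[:, :d]
    pooled = np.vstack([occ1, occ2])
    grid = make_grid(bg, pooled, d=d, r=r, margin=margin)
    e = kernel_density(bg, grid, silverman_bandwidths(bg, bandwidth_mult))

    def pair_d(a: np.ndarray, b: np.ndarray) -> float:
        za = occupancy(kernel_density(a, grid, silverman_bandwidths(a, bandwidth_mult)),
                       e, correct_by_availability)
        zb = occupancy(kernel_density(b, grid, silverman_bandwidths(b, bandwidth_mult)),
                       e, correct_by_availability)
        return schoener_d(za, zb)

    d_obs = pair_d(occ1, occ2)
    rng = np.random.default_rng(seed)
    n1 = occ1.shape[0]
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        null[i] = pair_d(pooled[perm[:n1]], pooled[perm[n1:]])
    p = (1.0 + np.count_nonzero(null <= d_obs)) / (n_permutations + 1.0)
    return OverlapResult(
        species=tuple(labels), D=d_obs, n_permutations=n_permutations,
        null_D=null, p_value=float(p), seed=seed,
    )


def overlap_matrix(densities: Mapping[str, NicheDensity]) -> pd.DataFrame:
    """Pairwise Schoener's D table; diagonal 1 by definition.

    Species with no occurrences are omitted with a warning.  All densities
    must share one grid.
    """
    import logging

    usable = {}
    for name, nd in densities.items():
        if nd.n_occurrences == 0:
            logging.getLogger("tickniche").warning(
                "overlap_matrix: omitting %s (no occurrences)", name
            )
            continue
        usable[name] = nd
    names = list(usable)
    if len(names) < 2:
        raise ValueError("need at least two species with occurrences")
    grid0 = usable[names[0]].grid
    for name in names[1:]:
        if usable[name].grid != grid0:
            raise ValueError(f"density for {name} is on a different grid")
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            dab = schoener_d(usable[a].z, usable[b].z)
            table.loc[a, b] = dab
            table.loc[b, a] = dab
    return table
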
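"""Unsupervised habitat classification from seasonal LST/NDVI and cross-tabs.

Every valid raster cell is described by its 24-dimensional seasonal profile
(12 monthly LST + 12 monthly NDVI values), standardized per (variable, month)
column, and clustered with k-means (k-means++ initialization, best of
``n_restarts`` by within-cluster sum of squares, fixed seed for
determinism).  Each resulting category therefore has a unique seasonal
pattern of temperature and greenness.  Cells with nodata in any layer stay
unlabeled.

The same record-by-category cross-tabulation serves both this k-means raster
and an externally supplied categorical raster (e.g. land biomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .rasters import GridGeometry, RasterStack
from .records import RecordSet

logger = logging.getLogger("tickniche")

#: Label used for valid-but-unclassified or nodata cells in label rasters.
UNASSIGNED = 0


@dataclass
class HabitatClassification:
    """k-means category raster plus everything needed to reproduce it.

    ``labels`` is an integer grid with categories 1..k on valid cells and
    :data:`UNASSIGNED` elsewhere.  ``centroids`` live in standardized feature
    space (rows = categories, columns = ``variables`` order).
    """

    geometry: GridGeometry
    labels: np.ndarray
    k: int
    variables: list[tuple[str, int]]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int | None


@dataclass
class CategoricalRaster:
    """An integer category grid (biomes or k-means classes) on a geometry."""

    geometry: GridGeometry
    labels: np.ndarray

    def category_at(self, lon: float, lat: float) -> int:
        cell = self.geometry.nearest_cell(lon, lat)
        if cell is None:
            return UNASSIGNED
        return int(self.labels[cell])


def kmeans_classify(
    stack: RasterStack,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
) -> HabitatClassification:
    """Classify the territory into k seasonal-climate categories.

    Requires the stack to hold 12 LST and 12 NDVI layers.  Features are
    standardized per column; the solution is the best of ``n_restarts``
    k-means++ runs by within-cluster sum of squares and is deterministic for
    a fixed seed.
    """
    keys = [("LST", m) for m in range(1, 13)] + [("NDVI", m) for m in range(1, 13)]
    missing = [key for key in keys if key not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks required layer(s) {missing}")
    if k < 1:
        raise ValueError("k must be at least 1")
    X, flat_mask, keys = stack.to_matrix(keys)
    if X.shape[0] < k:
        raise ValueError(f"only {X.shape[0]} valid cells for k={k}")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)  # constant columns carry no information
    Z = (X - means) / sds

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    fitted = km.fit(Z)

    geom = stack.geometry
    labels = np.full(geom.nrows * geom.ncols, UNASSIGNED, dtype=int)
    labels[flat_mask] = fitted.labels_ + 1
    return HabitatClassification(
        geometry=geom,
        labels=labels.reshape(geom.nrows, geom.ncols),
        k=k,
        variables=keys,
        feature_means=means,
        feature_sds=sds,
        centroids=fitted.cluster_centers_,
        inertia=float(fitted.inertia_),
        seed=seed,
    )


def category_stats(cls: HabitatClassification, stack: RasterStack) -> pd.DataFrame:
    """Per (category, variable, month) mean, population sd and cell count.

    Every (category, variable) pair contributes all 12 monthly rows; empty
    categories appear with ``n_cells = 0`` and NaN statistics.
    """
    if not cls.geometry.matches(stack.geometry):
        raise ValueError("classification and stack are not co-registered")
    rows = []
    flat_labels = cls.labels.ravel()
    for cat in range(1, cls.k + 1):
        member = flat_labels == cat
        n = int(member.sum())
        if n == 0:
            logger.warning("category %d is empty", cat)
        for var, month in cls.variables:
            vals = stack.layers[(var, month)].ravel()[member]
            rows.append(
                {
                    "category": cat,
                    "variable": var,
                    "month": month,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sd": float(vals.std(ddof=0)) if n else np.nan,
                    "n_cells": n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CategoryCrosstab:
    """Species x habitat-category counts and row percentages.

    Percentages are over each species' *assigned* records; records on nodata
    cells or outside the raster extent are tallied in the ``unassigned``
    count column only.
    """

    counts: pd.DataFrame       # includes an "unassigned" column
    percentages: pd.DataFrame  # assigned categories only, rows sum to ~100


def crosstab_categorical(
    rs: RecordSet, categories: "CategoricalRaster | HabitatClassification"
) -> CategoryCrosstab:
    """Cross-tabulate records against a categorical raster."""
    if isinstance(categories, HabitatClassification):
        categories = CategoricalRaster(geometry=categories.geometry, labels=categories.labels)
    cell: dict[tuple[str, int], int] = {}
    for rec in rs.records:
        species = rec.species or rec.species_raw
        cat = categories.category_at(rec.lon, rec.lat)
        cell[(species, cat)] = cell.get((species, cat), 0) + 1
    species_labels = sorted({s for s, _ in cell})
    cats = sorted({c for _, c in cell if c != UNASSIGNED})
    counts = pd.DataFrame(0, index=species_labels, columns=cats + ["unassigned"], dtype=int)
    for (s, c), n in cell.items():
        counts.loc[s, "unassigned" if c == UNASSIGNED else c] = n
    assigned = counts[cats]
    denom = assigned.sum(axis=1)
    pct = assigned.div(denom.where(denom > 0), axis=0) * 100.0
    from .records import round_half_up

    pct = pct.map(lambda v: np.nan if pd.isna(v) else round_half_up(v, 1))
    return CategoryCrosstab(counts=counts, percentages=pct)
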
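"""Synthetic data with known structure for exercising every pipeline stage.

The generator emulates the shape of the real inputs — smooth monthly
environmental fields with sinusoidal seasonality, occurrence samples drawn
from Gaussian niches defined in environmental (or climate-axis) space, and
record-level metadata including curation defects — while keeping every
generating parameter known, so downstream estimates (PCA structure,
Schoener's D, filter tallies) can be checked against construction.

All generators are pure functions of (spec, seed): identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .rasters import GridGeometry, RasterStack
from .records import OccurrenceRecord, RecordSet

TWO_PI = 2.0 * np.pi

#: Hosts sampled for synthetic metadata (names resolvable by the default
#: host taxonomy) — a surveillance-like mix of livestock, dogs and wildlife.
_HOSTS = ("cattle", "sheep", "dog", "human", "hedgehog", "hare", "blackbird")
_STAGES = ("adult", "nymph", "larva")
_STAGE_P = (0.7, 0.2, 0.1)   # adults dominate published tick records


@dataclass(frozen=True)
class VariableField:
    """One environmental variable's spatial + seasonal structure.

    layer(v, m)[cell] = base + lon_gradient*(lon-lon0) + lat_gradient*(lat-lat0)
                        + amplitude*cos(2*pi*(m - phase_month)/12) + noise
    """

    base: float
    lon_gradient: float = 0.0
    lat_gradient: float = 0.0
    amplitude: float = 0.0
    phase_month: float = 7.0   # month of seasonal peak (July default)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SeasonalFieldSpec:
    """Grid shape plus per-variable seasonal field parameters."""

    variables: Mapping[str, VariableField]
    nrows: int = 40
    ncols: int = 40
    xllcenter: float = -10.0
    yllcenter: float = 30.0
    cellsize: float = 1.0
    nodata: float = -9999.0
    seed: int = 0

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            ncols=self.ncols, nrows=self.nrows,
            xllcenter=self.xllcenter, yllcenter=self.yllcenter,
            cellsize=self.cellsize, nodata=self.nodata,
        )


#: Study-window-like default: LST in degC with a strong north-south gradient
#: and continental seasonal swing; NDVI unitless with opposite-phase
#: seasonality and milder gradients.  Amplitudes/gradients sized so the
#: simulated window spans a Mediterranean-to-boreal range.
DEFAULT_FIELDS: Mapping[str, VariableField] = {
    "LST": VariableField(base=22.0, lon_gradient=0.05, lat_gradient=-0.45,
                         amplitude=10.0, phase_month=7.0, noise_sd=0.5),
    "NDVI": VariableField(base=0.45, lon_gradient=-0.001, lat_gradient=0.004,
                          amplitude=0.15, phase_month=5.0, noise_sd=0.01),
}


def default_field_spec(seed: int = 0, nrows: int = 40, ncols: int = 40) -> SeasonalFieldSpec:
    return SeasonalFieldSpec(variables=DEFAULT_FIELDS, nrows=nrows, ncols=ncols, seed=seed)


def simulate_raster_stack(spec: SeasonalFieldSpec) -> RasterStack:
    """Generate 12 monthly layers per variable; deterministic per seed."""
    geom = spec.geometry
    rng = np.random.default_rng(spec.seed)
    lon = np.asarray(geom.lon_of_col(np.arange(geom.ncols)))[None, :]
    lat = np.asarray(geom.lat_of_row(np.arange(geom.nrows)))[:, None]
    stack = RasterStack(geometry=geom)
    for var in sorted(spec.variables):
        f = spec.variables[var]
        surface = (
            f.base
            + f.lon_gradient * (lon - geom.xllcenter)
            + f.lat_gradient * (lat - geom.yllcenter)
        )
        for month in range(1, 13):
            seasonal = f.amplitude * np.cos(TWO_PI * (month - f.phase_month) / 12.0)
            noise = (
                rng.normal(0.0, f.noise_sd, size=(geom.nrows, geom.ncols))
                if f.noise_sd > 0 else 0.0
            )
            stack.add(var, month, surface + seasonal + noise)
    return stack


# ---------------------------------------------------------------------------
# Niches and occurrence sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NicheSpec:
    """A Gaussian niche in environmental-variable (or climate-axis) space.

    ``features`` names the (variable, month) coordinates the niche lives on
    when ``space='env'``; with ``space='climate'`` the mean/cov are read
    directly on climate-space axes (for direct overlap-oracle tests).
    """

    species: str
    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]
    n_records: int
    features: tuple[tuple[str, int], ...] = ()
    space: str = "env"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        c = np.asarray(self.cov, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if self.space not in ("env", "climate"):
            raise ValueError("space must be 'env' or 'climate'")
        if self.space == "env" and len(self.features) != len(self.mean):
            raise ValueError("features must match the niche dimensionality")


def sample_niche_scores(niche: NicheSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_records`` points straight from the niche Gaussian.

    Used for climate-space-defined niches where overlap is known by
    construction (no rasters involved).
    """
    return rng.multivariate_normal(
        np.asarray(niche.mean), np.asarray(niche.cov), size=niche.n_records
    )


#: Curation-defect kinds the generator can inject, with how each manifests.
DEFECT_KINDS = (
    "genus_only", "admin_division", "ambiguous_name",
    "unaccepted_name", "outside_window",
)


def simulate_occurrences(
    niches: Sequence[NicheSpec],
    stack: RasterStack,
    seed: int = 0,
    defect_rates: Mapping[str, float] | None = None,
    bias: np.ndarray | None = None,
    host_rate: float = 0.6,
) -> tuple[RecordSet, dict]:
    """Sample occurrence records from Gaussian niches over a raster stack.

    Cells are drawn (with replacement) with probability proportional to the
    niche density at each cell's environmental vector, times an optional
    spatial ``bias`` field; coordinates are jittered uniformly within the
    source cell.  Metadata (host, stage, method) and curation defects are
    injected at the configured per-record rates; at most one defect per
    record, so the injected tally maps one-to-one onto filter rules.

    Returns ``(RecordSet, truth)`` where ``truth`` holds the per-species
    source cells and the exact injected defect counts per rule.
    """
    rates = dict(defect_rates or {})
    unknown = set(rates) - set(DEFECT_KINDS)
    if unknown:
        raise ValueError(f"unknown defect kind(s) {sorted(unknown)}")
    if sum(rates.values()) > 1.0:
        raise ValueError("defect rates sum above 1")
    rng = np.random.default_rng(seed)
    geom = stack.geometry
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != (geom.nrows, geom.ncols):
            raise ValueError("bias field shape does not match the grid")
        if (bias < 0).any():
            raise ValueError("bias must be non-negative")

    rs = RecordSet(provenance=f"simulate_occurrences(seed={seed})")
    truth: dict = {"injected_defects": {}, "cells": {}, "seed": seed}
    half = geom.cellsize / 2.0
    for niche in niches:
        if niche.space != "env":
            raise ValueError(
                f"{niche.species}: climate-space niches are sampled with "
                "sample_niche_scores, not from a raster stack"
            )
        X, flat_mask, _ = stack.to_matrix(list(niche.features))
        if X.shape[0] == 0:
            raise ValueError(f"{niche.species}: no valid cells for its features")
        dens = multivariate_normal(np.asarray(niche.mean), np.asarray(niche.cov)).pdf(X)
        dens = np.atleast_1d(dens).astype(float)
        if bias is not None:
            dens = dens * bias.ravel()[flat_mask]
        total = dens.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(f"{niche.species}: zero total suitability on this stack")
        flat_idx = np.flatnonzero(flat_mask)
        chosen = rng.choice(flat_idx, size=niche.n_records, p=dens / total)
        truth["cells"][niche.species] = chosen.copy()
        rows, cols = np.unravel_index(chosen, (geom.nrows, geom.ncols))
        lons = np.asarray(geom.lon_of_col(cols)) + rng.uniform(-half, half, niche.n_records)
        lats = np.asarray(geom.lat_of_row(rows)) + rng.uniform(-half, half, niche.n_records)
        for i in range(niche.n_records):
            rec = OccurrenceRecord(
                species_raw=niche.species,
                lon=float(lons[i]),
                lat=float(lats[i]),
                locality_quality="coordinates",
                host_name=(
                    _HOSTS[rng.integers(len(_HOSTS))] if rng.random() < host_rate else None
                ),
                stage=_STAGES[rng.choice(len(_STAGES), p=_STAGE_P)],
                collection_method="host" if rng.random() < 0.5 else "dragging",
                source_id=f"sim-{niche.species.split()[0][:2]}-{i}",
            )
            _maybe_inject_defect(rec, rates, rng, truth["injected_defects"])
            rs.records.append(rec)
    return rs, truth


def _maybe_inject_defect(
    rec: OccurrenceRecord,
    rates: Mapping[str, float],
    rng: np.random.Generator,
    tally: dict[str, int],
) -> None:
    u = float(rng.random())
    acc = 0.0
    for kind in DEFECT_KINDS:
        acc += rates.get(kind, 0.0)
        if u < acc:
            _apply_defect(rec, kind)
            tally[kind] = tally.get(kind, 0) + 1
            return


def _apply_defect(rec: OccurrenceRecord, kind: str) -> None:
    if kind in ("genus_only", "admin_division", "ambiguous_name"):
        rec.locality_quality = kind
        if kind == "genus_only":
            rec.species_raw = rec.species_raw.split()[0] + " sp."
    elif kind == "unaccepted_name":
        # A deliberately invalid synthetic binomial, absent from all tables.
        rec.species_raw = "Ixodes imaginarius"
    elif kind == "outside_window":
        rec.lat = 80.0   # north of any study window used here
    rec.species = None
    rec.species_accepted = None


# ---------------------------------------------------------------------------
# Overlap truth by dense numeric integration
# ---------------------------------------------------------------------------


def true_schoener_d(
    mean1: Sequence[float],
    cov1,
    mean2: Sequence[float],
    cov2,
    bounds: Sequence[tuple[float, float]] | None = None,
    n_grid: int = 400,
) -> float:
    """Numerically integrated Schoener's D between two Gaussian densities.

    Evaluates both pdfs on a dense 2-D grid covering ``bounds`` (default:
    both means +/- 6 pooled sd per axis), renormalizes each on the grid and
    returns 1 - 0.5 * sum|f1 - f2|.  Serves as the construction-known oracle
    for pipeline D estimates.
    """
    m1, m2 = np.asarray(mean1, float), np.asarray(mean2, float)
    c1, c2 = np.asarray(cov1, float), np.asarray(cov2, float)
    d = m1.size
    if d != 2:
        raise ValueError("oracle implemented for 2-D niches")
    if bounds is None:
        sd = np.sqrt(np.maximum(np.diag(c1), np.diag(c2)))
        lo = np.minimum(m1, m2) - 6.0 * sd
        hi = np.maximum(m1, m2) + 6.0 * sd
        bounds = list(zip(lo, hi))
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
    xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    f1 = multivariate_normal(m1, c1).pdf(pts)
    f2 = multivariate_normal(m2, c2).pdf(pts)
    f1 /= f1.sum()
    f2 /= f2.sum()
    return float(1.0 - 0.5 * np.abs(f1 - f2).sum())


def separated_gaussian_pair(
    overlap: str = "mid",
    n_records: int = 2000,
    sd: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[NicheSpec, NicheSpec]:
    """Two isotropic 2-D climate-space niches with a chosen overlap regime.

    For equal isotropic Gaussians separated by delta, D = 2*Phi(-delta/(2*sd)):
    ``overlap='none'`` uses delta = 6 sd (D ~ 0.003), ``'mid'`` uses
    delta = 1.349 sd (D ~ 0.5), ``'high'`` uses delta = 0.251 sd (D ~ 0.9).
    """
    deltas = {"none": 6.0, "mid": 1.349, "high": 0.251}
    if overlap not in deltas:
        raise ValueError(f"overlap must be one of {sorted(deltas)}")
    delta = deltas[overlap] * sd
    cov = ((sd * sd, 0.0), (0.0, sd * sd))
    cx, cy = center
    a = NicheSpec(species="synthetic A", mean=(cx - delta / 2.0, cy), cov=cov,
                  n_records=n_records, space="climate")
    b = NicheSpec(species="synthetic B", mean=(cx + delta / 2.0, cy), cov=cov,
                  n_records=n_records, space="climate")
    return a, b


# ---------------------------------------------------------------------------
# Printed-table fixture
# ---------------------------------------------------------------------------


def table1_fixture() -> dict[str, int]:
    """The published per-species record counts of the compiled data set.

    16 species (the sanguineus group counted as one label); counts sum to
    10,280.  Used to check tabulation arithmetic against the printed table.
    """
    return {
        "Dermacentor marginatus": 734,
        "Dermacentor reticulatus": 882,
        "Haemaphysalis punctata": 479,
        "Haemaphysalis sulcata": 298,
        "Hyalomma anatolicum": 12,
        "Hyalomma excavatum": 211,
        "Hyalomma impeltatum": 8,
        "Hyalomma lusitanicum": 526,
        "Hyalomma marginatum": 787,
        "Hyalomma scupense": 135,
        "Ixodes canisuga": 8,
        "Ixodes hexagonus": 7,
        "Ixodes ricinus": 4554,
        "Rhipicephalus annulatus": 201,
        "Rhipicephalus bursa": 960,
        "Rhipicephalus sanguineus group": 478,
    }


#: Published half-up one-decimal percentages for the same 16 species.
TABLE1_PERCENT = {
    "Dermacentor marginatus": 7.1,
    "Dermacentor reticulatus": 8.6,
    "Haemaphysalis punctata": 4.7,
    "Haemaphysalis sulcata": 2.9,
    "Hyalomma anatolicum": 0.1,
    "Hyalomma excavatum": 2.1,
    "Hyalomma impeltatum": 0.1,
    "Hyalomma lusitanicum": 5.1,
    "Hyalomma marginatum": 7.7,
    "Hyalomma scupense": 1.3,
    "Ixodes canisuga": 0.1,
    "Ixodes hexagonus": 0.1,
    "Ixodes ricinus": 44.3,
    "Rhipicephalus annulatus": 2.0,
    "Rhipicephalus bursa": 9.3,
    "Rhipicephalus sanguineus group": 4.6,
}
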
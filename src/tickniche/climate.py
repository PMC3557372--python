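"""Reduced climate space: correlation PCA of monthly LST/NDVI variables.

The 24 monthly land-surface-temperature and NDVI values per grid cell are
reduced to a handful of orthogonal axes.  Because LST (kelvin-like) and NDVI
(unitless, [-1, 1]) have incommensurable units, the PCA is of the
*correlation* matrix: each column is centered and scaled by its sample
standard deviation before eigendecomposition.

The space is fitted on the background environment (all valid raster cells in
the study window, optionally subsampled with a fixed seed); occurrence
records are *projected* into it, never used for fitting, so that species can
be compared against the same availability background.

Axis signs from an eigendecomposition are arbitrary; each axis is oriented
so that its largest-magnitude loading is positive, which makes loadings
reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rasters import RasterStack


@dataclass
class ClimateSpace:
    """Fitted PCA basis plus the background scores that define the space."""

    variables: list[tuple[str, int]]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray        # (p variables) x (p axes), orthonormal columns
    eigenvalues: np.ndarray     # length p, non-increasing
    n_axes: int
    background_scores: np.ndarray = field(default=None)  # type: ignore[assignment]
    record_scores: np.ndarray | None = None

    @property
    def variance_explained(self) -> np.ndarray:
        """Per-axis fraction of total variance; sums to 1 over all axes."""
        return self.eigenvalues / self.eigenvalues.sum()


def fit_pca(
    env_matrix: np.ndarray,
    variables: Sequence[tuple[str, int]] | None = None,
    n_axes: int = 3,
) -> ClimateSpace:
    """Fit the climate space by PCA of the correlation matrix.

    ``env_matrix`` has one row per background cell and one column per
    (variable, month).  Requires at least two rows, no missing values and no
    constant column.  Retains ``n_axes`` axes (2 or 3) for scores while
    keeping the full eigensystem for variance accounting.
    """
    X = np.asarray(env_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 background rows")
    if np.isnan(X).any():
        raise ValueError(
            "missing values in environmental matrix; drop incomplete "
            "EnvVectors before fitting (see attach_environment)"
        )
    p = X.shape[1]
    if variables is None:
        variables = [("var", i + 1) for i in range(p)]
    variables = list(variables)
    if len(variables) != p:
        raise ValueError("variables length does not match matrix columns")
    if n_axes not in (2, 3) or n_axes > p:
        raise ValueError("n_axes must be 2 or 3 and not exceed the variable count")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        names = [variables[i] for i in constant]
        raise ValueError(f"constant column(s) {names}: correlation undefined")

    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)          # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)     # clip fp-negative tails
    loadings = eigvecs[:, order]
    # Deterministic orientation: largest-|loading| entry of each axis positive.
    for j in range(p):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]

    cs = ClimateSpace(
        variables=variables,
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigvals,
        n_axes=n_axes,
    )
    cs.background_scores = Z @ loadings[:, :n_axes]
    return cs


def fit_pca_from_stack(
    stack: RasterStack,
    n_axes: int = 3,
    subsample: int | None = None,
    seed: int | None = None,
) -> ClimateSpace:
    """Fit the climate space on a stack's valid cells (optionally subsampled)."""
    X, _, keys = stack.to_matrix()
    if subsample is not None and subsample < X.shape[0]:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=subsample, replace=False)]
    return fit_pca(X, variables=keys, n_axes=n_axes)


def project(cs: ClimateSpace, env: np.ndarray) -> np.ndarray:
    """Project rows of ``env`` (same column order as ``cs.variables``).

    Scores are the standardized vector times the loadings, first ``n_axes``
    columns; projecting the training background reproduces
    ``background_scores``.
    """
    X = np.asarray(env, dtype=float)
    one = X.ndim == 1
    if one:
        X = X[None, :]
    if X.shape[1] != len(cs.variables):
        raise ValueError(
            f"need {len(cs.variables)} variables {cs.variables}, got {X.shape[1]} columns"
        )
    scores = ((X - cs.means) / cs.sds) @ cs.loadings[:, : cs.n_axes]
    return scores[0] if one else scores


def derived_climate_vars(
    env: np.ndarray, variables: Sequence[tuple[str, int]]
) -> dict[str, np.ndarray]:
    """Per-row annual summaries used to interpret the axes.

    Returns ``annual_mean_LST`` (mean over the 12 monthly LST values),
    ``annual_LST_range`` (max minus min monthly LST) and ``annual_mean_NDVI``
    for whichever of LST/NDVI are present.
    """
    X = np.asarray(env, dtype=float)
    out: dict[str, np.ndarray] = {}
    for var in ("LST", "NDVI"):
        idx = [i for i, (v, _) in enumerate(variables) if v == var]
        if not idx:
            continue
        block = X[:, idx]
        out[f"annual_mean_{var}"] = block.mean(axis=1)
        if var == "LST":
            out["annual_LST_range"] = block.max(axis=1) - block.min(axis=1)
    return out


def interpret_axes(
    cs: ClimateSpace, derived_vars: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Pearson correlation of each retained axis with each derived variable.

    Descriptive output, not a pass/fail gate: the sign of an axis is a
    convention, so readers should attend to |r| and to which variable
    dominates each axis.  A zero-variance derived variable yields NaN.
    """
    if cs.background_scores is None:
        raise ValueError("background scores unavailable; fit the space first")
    scores = cs.background_scores
    rows = {}
    for name, values in derived_vars.items():
        v = np.asarray(values, dtype=float)
        if v.shape[0] != scores.shape[0]:
            raise ValueError(f"derived variable {name!r} length mismatch")
        col = []
        for j in range(cs.n_axes):
            if v.std() == 0 or scores[:, j].std() == 0:
                col.append(np.nan)
            else:
                col.append(float(np.corrcoef(scores[:, j], v)[0, 1]))
        rows[name] = col
    return pd.DataFrame(rows, index=[f"axis_{j + 1}" for j in range(cs.n_axes)])
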
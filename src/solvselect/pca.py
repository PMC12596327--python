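"""Autoscaled principal component analysis via NIPALS, tolerant of missing cells.

The descriptor block of a solvent catalog is autoscaled (each column centred
to mean 0 and scaled to sample standard deviation 1, computed over observed
entries only) and decomposed with the NIPALS algorithm: components are
extracted one at a time by alternating regressions of scores on loadings and
loadings on scores, each inner product running over observed cells only, so
incomplete rows contribute exactly the information they carry.  After
convergence the rank-1 reconstruction is subtracted at observed positions
and the next component is extracted from the residual.

On complete data this reproduces classical PCA (eigendecomposition of the
covariance matrix) up to component sign; the sign is fixed here by orienting
each loading vector so its largest-magnitude element is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, SolventLookupError

__all__ = [
    "ScaledMatrix",
    "PCAModel",
    "ComponentConvergence",
    "autoscale",
    "nipals_pca",
    "project",
    "pc_window",
]


@dataclass(frozen=True)
class ScaledMatrix:
    """Autoscaled solvent x descriptor matrix with the scaling statistics.

    ``data`` keeps NaN for missing cells; ``column_means``/``column_sds``
    allow the inverse transform and projection of new rows.  ``dropped``
    records descriptors removed for zero variance or insufficient data.
    """

    data: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    dropped: tuple[tuple[str, str], ...] = ()

    @property
    def rows(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ComponentConvergence:
    component: int
    iterations: int
    residual: float
    converged: bool


@dataclass(frozen=True)
class PCAModel:
    """Loadings, scores and explained variance of a NIPALS fit.

    ``loadings`` is components x descriptors (rows ``PC1..PCk``, unit
    Euclidean norm); ``scores`` is solvents x components.
    """

    n_components: int
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    convergence_info: tuple[ComponentConvergence, ...] = field(default=())

    def component_names(self) -> list[str]:
        return list(self.loadings.index)


def autoscale(matrix: pd.DataFrame) -> ScaledMatrix:
    """Centre each column to mean 0 and scale to sample (n-1) sd 1.

    Moments are computed over non-missing entries only and missing entries
    stay missing.  Columns with zero variance or fewer than two observed
    values cannot be scaled; they are dropped with a warning and recorded in
    ``dropped`` rather than raising.
    """
    if matrix.shape[0] < 2:
        raise ValueError("autoscaling needs at least two rows")
    values = matrix.astype(float)
    means = values.mean(axis=0, skipna=True)
    sds = values.std(axis=0, ddof=1, skipna=True)
    counts = values.notna().sum(axis=0)

    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    for column in values.columns:
        if counts[column] < 2:
            dropped.append((column, "fewer than two observed values"))
        elif not np.isfinite(sds[column]) or sds[column] == 0:
            dropped.append((column, "zero variance"))
        else:
            keep.append(column)
    if dropped:
        warnings.warn(
            "dropped descriptors during autoscaling: "
            + ", ".join(f"{name} ({reason})" for name, reason in dropped),
            stacklevel=2,
        )
    scaled = (values[keep] - means[keep]) / sds[keep]
    return ScaledMatrix(
        data=scaled,
        column_means=means[keep],
        column_sds=sds[keep],
        dropped=tuple(dropped),
    )


def _as_scaled(x: ScaledMatrix | pd.DataFrame) -> ScaledMatrix:
    if isinstance(x, ScaledMatrix):
        return x
    zeros = pd.Series(0.0, index=x.columns)
    ones = pd.Series(1.0, index=x.columns)
    return ScaledMatrix(data=x.astype(float), column_means=zeros, column_sds=ones)


def _orient(loading: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: largest-|.| loading element positive
    pivot = int(np.argmax(np.abs(loading)))
    if loading[pivot] < 0:
        return -loading, -score
    return loading, score


def nipals_pca(
    x: ScaledMatrix | pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PCAModel:
    """Extract *n_components* principal components by NIPALS.

    Missing cells are skipped in every inner product and the deflation only
    touches observed cells.  The initial score vector of each component is
    the residual column with the largest observed variance (deterministic).
    A component that has not met *tol* after *max_iter* iterations is flagged
    in ``convergence_info`` and extraction continues.
    """
    scaled = _as_scaled(x)
    data = scaled.data.to_numpy(dtype=float)
    n, p = data.shape
    if n_components < 1 or n_components > min(n, p):
        raise ValueError(
            f"n_components must be in [1, {min(n, p)}], got {n_components}"
        )
    mask = np.isfinite(data)
    if not mask.any(axis=1).all():
        bad = [scaled.rows[i] for i in np.where(~mask.any(axis=1))[0]]
        raise ValueError(f"rows with all cells missing: {bad}")

    residual = np.where(mask, data, 0.0)  # zeros at missing cells, masked in sums
    total_var = float(np.sum(residual**2))
    if total_var == 0:
        raise ValueError("matrix has no variance")

    scores = np.zeros((n, n_components))
    loadings = np.zeros((n_components, p))
    ev = np.zeros(n_components)
    info: list[ComponentConvergence] = []

    for k in range(n_components):
        col_var = np.sum(residual**2, axis=0)
        t = residual[:, int(np.argmax(col_var))].copy()
        if not np.any(t):
            t = np.ones(n)
        converged = False
        iterations = 0
        change = np.inf
        for iterations in range(1, max_iter + 1):
            # loading regression over observed cells of each column
            denom_p = mask.T @ (t**2)
            numer_p = residual.T @ t
            with np.errstate(invalid="ignore", divide="ignore"):
                pvec = np.where(denom_p > 0, numer_p / np.where(denom_p > 0, denom_p, 1.0), 0.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            # score regression over observed cells of each row
            denom_t = mask @ (pvec**2)
            numer_t = residual @ pvec
            t_new = np.where(denom_t > 0, numer_t / np.where(denom_t > 0, denom_t, 1.0), 0.0)
            scale = np.linalg.norm(t_new)
            change = np.linalg.norm(t_new - t) / scale if scale > 0 else 0.0
            t = t_new
            if change < tol:
                converged = True
                break
        pvec, t = _orient(pvec, t)
        scores[:, k] = t
        loadings[k] = pvec
        before = float(np.sum(residual**2))
        residual = residual - np.where(mask, np.outer(t, pvec), 0.0)
        after = float(np.sum(residual**2))
        ev[k] = max(before - after, 0.0) / total_var
        info.append(
            ComponentConvergence(
                component=k + 1,
                iterations=iterations,
                residual=float(change),
                converged=converged,
            )
        )
        if not converged:
            warnings.warn(
                f"NIPALS component {k + 1} did not converge in {max_iter} iterations "
                f"(last relative score change {change:.2e})",
                stacklevel=2,
            )

    names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAModel(
        n_components=n_components,
        loadings=pd.DataFrame(loadings, index=names, columns=scaled.columns),
        scores=pd.DataFrame(scores, index=scaled.rows, columns=names),
        explained_variance_fraction=ev,
        convergence_info=tuple(info),
    )


def project(model: PCAModel, x: ScaledMatrix | pd.DataFrame) -> pd.DataFrame:
    """Least-squares scores of new (already autoscaled) rows in model space.

    For each row the scores solve ``min ||x_obs - P_obs' t||`` over the
    observed cells, which reproduces the training scores on complete data.
    """
    scaled = _as_scaled(x)
    if list(scaled.columns) != list(model.loadings.columns):
        raise SchemaError(
            "descriptor columns do not match the model "
            f"(got {list(scaled.columns)[:5]}..., expected "
            f"{list(model.loadings.columns)[:5]}...)"
        )
    data = scaled.data.to_numpy(dtype=float)
    loadings = model.loadings.to_numpy()  # k x p
    out = np.zeros((data.shape[0], model.n_components))
    for i, row in enumerate(data):
        obs = np.isfinite(row)
        if not obs.any():
            raise ValueError(f"row {scaled.rows[i]!r} has no observed cells")
        sub = loadings[:, obs]  # k x m
        out[i], *_ = np.linalg.lstsq(sub.T, row[obs], rcond=None)
    return pd.DataFrame(out, index=scaled.rows, columns=model.component_names())


def pc_window(
    scores: pd.DataFrame,
    reference: str,
    axis: int | str = 1,
    half_width: float = 1.0,
) -> list[str]:
    """Names whose score on *axis* lies within +/- *half_width* of the reference.

    *axis* may be a 1-based component index or a column name like ``"PC1"``.
    The reference itself is excluded; order follows the score table.
    """
    column = f"PC{axis}" if isinstance(axis, int) else axis
    if column not in scores.columns:
        raise SchemaError(f"component {column!r} not in scores")
    if reference not in scores.index:
        raise SolventLookupError(f"reference {reference!r} has no scores")
    centre = float(scores.at[reference, column])
    offsets = (scores[column] - centre).abs()
    selected = scores.index[(offsets <= half_width) & (scores.index != reference)]
    return list(selected)
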
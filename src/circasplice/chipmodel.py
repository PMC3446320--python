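"""Probe-level modelling: quantile normalization, per-cluster median-polish
fits, transcript-level expression estimates, and splice-departure scores.

The probe model is the additive log2 decomposition
``log2 I = m + c_i + p_k + r_ki`` fitted by Tukey median polish per
transcript cluster, with samples as columns and all of a cluster's probes
(across its probesets) as rows. The per-probeset, per-sample departure score
is ``2 ** median_k(r_ki)`` over the probeset's probes, so 1 means no
departure from the transcript-level estimate ``theta_i = m + c_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterFit",
    "quantile_normalize",
    "median_polish",
    "fit_clusters",
    "firma_scores",
]

BACKGROUND_MODES = ("none", "modal")


@dataclass
class ClusterFit:
    """Additive median-polish decomposition of one cluster's log2 data."""

    cluster_id: str
    overall: float
    chip_effects: pd.Series       # per sample, log2
    probe_effects: pd.Series      # per probe, log2
    residuals: pd.DataFrame       # probe x sample, log2
    iterations: int
    converged: bool

    def reconstruct(self) -> pd.DataFrame:
        """overall + chip + probe + residual; equals the fitted log2 input."""
        return (
            self.residuals
            + self.overall
            + self.chip_effects.to_numpy()[None, :]
            + self.probe_effects.to_numpy()[:, None]
        )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean of the sorted columns.

    Ties within a column receive the mean of the reference values their
    ranks span (the average-rank rule), which preserves within-column rank
    order and makes the transform idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("intensities must be positive and finite")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    table: np.ndarray, max_iter: int = 10, tol: float = 1e-8
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Tukey median polish of a 2-D grid.

    Alternates row and column median sweeps (rows first), re-centring the
    effect vectors on zero median after each sweep, until the largest
    absolute adjustment drops below ``tol`` or ``max_iter`` is reached.
    Returns (overall, row_effects, col_effects, residuals, iterations,
    converged); the decomposition reconstructs the input exactly.
    """
    z = np.asarray(table, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish needs a non-empty 2-D grid")
    if not np.all(np.isfinite(z)):
        raise ValueError("median_polish input must be finite")
    z = z.copy()
    overall = 0.0
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        cshift = np.median(col)
        col -= cshift
        overall += cshift

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        rshift = np.median(row)
        row -= rshift
        overall += rshift

        adjustment = max(np.abs(rdelta).max(), np.abs(cdelta).max())
        if adjustment < tol:
            converged = True
            break
    return overall, row, col, z, iterations, converged


def _modal_background(column: np.ndarray, n_bins: int = 64) -> float:
    hist, edges = np.histogram(column, bins=n_bins)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def _validate_layout(layout: pd.DataFrame) -> None:
    required = {"probe_id", "probeset_id", "cluster_id"}
    if not required <= set(layout.columns):
        raise ValueError(f"layout must have columns {sorted(required)}")
    if layout["probe_id"].duplicated().any():
        dup = layout.loc[layout["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id in layout: {dup}")


def fit_clusters(
    intensities: pd.DataFrame,
    layout: pd.DataFrame,
    background: str = "none",
    normalize: bool = True,
    floor: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-8,
) -> tuple[dict[str, ClusterFit], pd.DataFrame]:
    """Preprocess and fit the probe model per transcript cluster.

    Optional background subtraction (per-sample modal intensity, floored at
    ``floor``), optional quantile normalization, log2 transform, then a
    median polish per cluster. Returns the per-cluster fits and the
    transcript-level expression estimates ``theta_i = m + c_i`` as a
    cluster x sample table.
    """
    _validate_layout(layout)
    if background not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {background!r}; choose from {BACKGROUND_MODES}")
    unknown = set(intensities.index) - set(layout["probe_id"])
    if unknown:
        raise ValueError(f"layout does not cover probes: {sorted(unknown)[:5]}")

    matrix = intensities
    if background == "modal":
        values = matrix.to_numpy(dtype=float).copy()
        for j in range(values.shape[1]):
            values[:, j] = np.maximum(values[:, j] - _modal_background(values[:, j]), floor)
        matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    if normalize:
        matrix = quantile_normalize(matrix)
    log2_matrix = np.log2(matrix)

    probe_to_cluster = layout.set_index("probe_id")["cluster_id"]
    fits: dict[str, ClusterFit] = {}
    theta_rows = {}
    for cluster_id, probes in probe_to_cluster.groupby(probe_to_cluster).groups.items():
        probes = [p for p in probes if p in log2_matrix.index]
        if not probes:
            raise ValueError(f"cluster {cluster_id} has no probes in the intensity matrix")
        block = log2_matrix.loc[probes]
        overall, row, col, resid, iterations, converged = median_polish(
            block.to_numpy(), max_iter=max_iter, tol=tol
        )
        fit = ClusterFit(
            cluster_id=cluster_id,
            overall=overall,
            chip_effects=pd.Series(col, index=block.columns),
            probe_effects=pd.Series(row, index=block.index),
            residuals=pd.DataFrame(resid, index=block.index, columns=block.columns),
            iterations=iterations,
            converged=converged,
        )
        fits[cluster_id] = fit
        theta_rows[cluster_id] = overall + col
    theta = pd.DataFrame.from_dict(theta_rows, orient="index", columns=log2_matrix.columns)
    theta.index.name = "cluster_id"
    return fits, theta


def firma_scores(
    fits: dict[str, ClusterFit],
    layout: pd.DataFrame,
    standardize: bool = False,
) -> pd.DataFrame:
    """Per-probeset, per-sample splice-departure scores on the linear scale.

    The score is ``2 ** median`` of the probeset's probe residuals in that
    sample (mean-of-middle-two median for even probe counts), so a score of
    1 indicates no departure. ``standardize=True`` divides residuals by the
    cluster's MAD-based residual scale first.
    """
    _validate_layout(layout)
    missing = set(layout["cluster_id"]) - set(fits)
    if missing:
        raise ValueError(f"fits do not cover clusters: {sorted(missing)[:5]}")

    rows = {}
    columns = None
    for (cluster_id, probeset_id), group in layout.groupby(
        ["cluster_id", "probeset_id"], sort=True
    ):
        fit = fits[cluster_id]
        probes = [p for p in group["probe_id"] if p in fit.residuals.index]
        if not probes:
            raise ValueError(f"probeset {probeset_id} absent from fit of cluster {cluster_id}")
        resid = fit.residuals.loc[probes].to_numpy()
        if standardize:
            scale = stats.median_abs_deviation(
                fit.residuals.to_numpy(), axis=None, scale="normal"
            )
            if scale > 0:
                resid = resid / scale
        rows[probeset_id] = np.median(resid, axis=0)
        columns = fit.residuals.columns
    scores = np.exp2(pd.DataFrame.from_dict(rows, orient="index", columns=columns))
    scores.index.name = "probeset_id"
    return scores.sort_index()
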
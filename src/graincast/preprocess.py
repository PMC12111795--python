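"""Panel preprocessing: missing-cell repair and outlier removal.

Imputation combines two estimators with equal weight:

* a temporal estimate — linear interpolation (linear extrapolation at the
  ends) along the cell's own (condition, replicate) time series, and
* a condition-space estimate — a least-squares plane in (temperature,
  moisture) fitted to the observed values of the same indicator at the
  same time node and replicate across the other design cells.

Outliers are screened per (condition, time) replicate group: a record is
removed when any indicator's residual from the replicate mean exceeds the
z threshold in absolute value (population-sd z-scores, ``|z| >= thresh``).
Removal is a single pass; re-running on the filtered panel can in
principle flag further records because the group statistics change.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .exceptions import InsufficientDataError
from .panel import (
    INDICATORS,
    MOIST_COL,
    QualityPanel,
    REP_COL,
    TEMP_COL,
    TIME_COL,
)

log = logging.getLogger(__name__)


def _interp_extrap(t: np.ndarray, t_obs: np.ndarray, v_obs: np.ndarray) -> np.ndarray:
    """np.interp plus linear extrapolation from the edge segments."""
    out = np.interp(t, t_obs, v_obs)
    if len(t_obs) >= 2:
        lo = t < t_obs[0]
        hi = t > t_obs[-1]
        if lo.any():
            slope = (v_obs[1] - v_obs[0]) / (t_obs[1] - t_obs[0])
            out[lo] = v_obs[0] + slope * (t[lo] - t_obs[0])
        if hi.any():
            slope = (v_obs[-1] - v_obs[-2]) / (t_obs[-1] - t_obs[-2])
            out[hi] = v_obs[-1] + slope * (t[hi] - t_obs[-1])
    return out


def _grid_estimate(df, col, time, rep, temp, moist):
    """Least-squares plane v ~ 1 + temperature + moisture at one time node."""
    peers = df[
        (df[TIME_COL] == time) & (df[REP_COL] == rep) & df[col].notna()
    ]
    if len(peers) == 0:
        return None
    if len(peers) < 3:
        return float(peers[col].mean())
    A = np.column_stack(
        [
            np.ones(len(peers)),
            peers[TEMP_COL].to_numpy(dtype=float),
            peers[MOIST_COL].to_numpy(dtype=float),
        ]
    )
    y = peers[col].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef @ [1.0, temp, moist])


def impute_missing(panel: QualityPanel) -> QualityPanel:
    """Fill every missing indicator cell; observed cells are untouched."""
    out = panel.copy()
    df = out.df
    n_filled = 0
    for key in out.series_keys():
        temp, moist, rep = key
        series = out.series(key)
        for col in INDICATORS:
            vals = series[col].to_numpy(dtype=float)
            miss = np.isnan(vals)
            if not miss.any():
                continue
            t = series[TIME_COL].to_numpy(dtype=float)
            if (~miss).sum() < 2:
                raise InsufficientDataError(
                    f"series (temperature={temp}, moisture={moist}, "
                    f"replicate={rep}) has fewer than 2 observed "
                    f"{col!r} values"
                )
            time_est = _interp_extrap(t[miss], t[~miss], vals[~miss])
            for row_pos, est_t in zip(series.index[miss], time_est):
                est_g = _grid_estimate(
                    panel.df, col, df.loc[row_pos, TIME_COL], rep, temp, moist
                )
                df.loc[row_pos, col] = (
                    est_t if est_g is None else 0.5 * (est_t + est_g)
                )
                n_filled += 1
    log.info("imputed %d missing cells", n_filled)
    return out


def remove_outliers(panel: QualityPanel, z_threshold: float = 3.0):
    """Drop records with extreme replicate residuals.

    Returns ``(filtered_panel, removed_records)``. Cells with fewer than
    two replicates are skipped with a warning. Z-scores use the population
    sd of the replicate group; a record is flagged when any indicator has
    ``|z| >= z_threshold``.
    """
    if not z_threshold > 0:
        raise ValueError("z_threshold must be positive")
    df = panel.df
    flagged = np.zeros(len(df), dtype=bool)
    for _, group in df.groupby([TEMP_COL, MOIST_COL, TIME_COL], sort=False):
        if len(group) < 2:
            warnings.warn(
                "outlier screen skipped a cell with fewer than 2 replicates",
                stacklevel=2,
            )
            continue
        for col in INDICATORS:
            vals = group[col].to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            if obs.sum() < 2:
                continue
            sd = vals[obs].std()
            if sd == 0:
                continue
            z = np.abs(vals - vals[obs].mean()) / sd
            bad = obs & (z >= z_threshold)
            flagged[df.index.get_indexer(group.index[bad])] = True
    removed = df[flagged].copy()
    out = QualityPanel(df[~flagged].reset_index(drop=True), dict(panel.scaler))
    log.info("removed %d outlier records", len(removed))
    return out, removed
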
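"""Long-format storage-quality panels and their standardization.

A panel is a long-format table of storage-experiment records: one row per
(moisture, temperature, sampling time, replicate) with the three measured
quality indicators — germination rate (%), fatty acid value (mg KOH/100 g)
and bulk density (g/L). Environmental settings (temperature, moisture) are
carried as columns so the forecaster can consume them as input variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateScaleError, ParseError, SchemaError

TIME_COL = "time_days"
TEMP_COL = "temperature_c"
MOIST_COL = "moisture_pct"
REP_COL = "replicate"
INDICATORS = ("germination_pct", "fatty_acid_mg100g", "bulk_density_gL")
ENV_COLS = (TEMP_COL, MOIST_COL)
META_COLS = (TIME_COL, TEMP_COL, MOIST_COL, REP_COL)
ALL_COLS = META_COLS + INDICATORS

#: columns the forecaster treats as series variables, in node order
MODEL_VARIABLES = ENV_COLS + INDICATORS


@dataclass
class QualityPanel:
    """A table of quality records plus (optional) standardization parameters.

    ``scaler`` maps column name -> parameter dict: ``{"method": "zscore",
    "mean": mu, "sd": sigma}`` or ``{"method": "range", "min": lo, "max": hi}``.
    Parameters are stored so standardization is invertible.
    """

    df: pd.DataFrame
    scaler: dict = field(default_factory=dict)

    def copy(self) -> "QualityPanel":
        return QualityPanel(self.df.copy(), dict(self.scaler))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_missing_cells(self) -> int:
        return int(self.df[list(INDICATORS)].isna().sum().sum())

    def series_keys(self):
        """Unique (temperature, moisture, replicate) series identifiers."""
        return sorted(
            set(zip(self.df[TEMP_COL], self.df[MOIST_COL], self.df[REP_COL]))
        )

    def series(self, key) -> pd.DataFrame:
        temp, moist, rep = key
        mask = (
            (self.df[TEMP_COL] == temp)
            & (self.df[MOIST_COL] == moist)
            & (self.df[REP_COL] == rep)
        )
        return self.df[mask].sort_values(TIME_COL)


def read_panel(path) -> QualityPanel:
    """Read a panel CSV; empty indicator fields become missing cells."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ALL_COLS:
        if col not in raw.columns:
            raise SchemaError(f"panel file is missing required column {col!r}")
    out = {}
    for col in ALL_COLS:
        vals = raw[col].str.strip()
        blank = vals == ""
        if col not in INDICATORS and blank.any():
            row = int(np.flatnonzero(blank.to_numpy())[0]) + 2
            raise ParseError(f"empty value in column {col!r} at line {row}")
        try:
            num = pd.to_numeric(vals.where(~blank, other=np.nan))
        except (ValueError, TypeError):
            bad = ~blank & pd.to_numeric(vals, errors="coerce").isna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(
                f"non-numeric value {vals.iloc[row - 2]!r} in column {col!r} "
                f"at line {row}"
            ) from None
        out[col] = num
    df = pd.DataFrame(out)
    df[TIME_COL] = df[TIME_COL].astype(int)
    df[REP_COL] = df[REP_COL].astype(int)
    return QualityPanel(df)


def write_panel(panel: QualityPanel, path) -> None:
    """Write the panel as CSV (UTF-8, header); missing cells as empty fields."""
    panel.df.to_csv(path, index=False, columns=list(ALL_COLS), na_rep="")


def standardize(
    panel: QualityPanel, method: str = "zscore", columns=None
) -> QualityPanel:
    """Standardize indicator columns (z-score or range transform).

    Z-score uses the population standard deviation (divide by n), computed
    over non-missing cells; the range transform maps observed [min, max]
    to [0, 1]. Parameters are stored on the returned panel for inversion.
    """
    if method not in ("zscore", "range"):
        raise ValueError(f"unknown standardization method {method!r}")
    columns = list(INDICATORS) if columns is None else list(columns)
    out = panel.copy()
    for col in columns:
        vals = out.df[col].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size < 2 or np.unique(obs).size < 2:
            raise DegenerateScaleError(f"column {col!r} is constant or near-empty")
        if method == "zscore":
            mu = float(obs.mean())
            sd = float(obs.std())  # population convention
            out.df[col] = (vals - mu) / sd
            out.scaler[col] = {"method": "zscore", "mean": mu, "sd": sd}
        else:
            lo, hi = float(obs.min()), float(obs.max())
            out.df[col] = (vals - lo) / (hi - lo)
            out.scaler[col] = {"method": "range", "min": lo, "max": hi}
    return out


def destandardize(panel: QualityPanel, columns=None) -> QualityPanel:
    """Invert :func:`standardize` using the stored parameters."""
    out = panel.copy()
    columns = list(panel.scaler) if columns is None else list(columns)
    for col in columns:
        params = panel.scaler[col]
        vals = out.df[col].to_numpy(dtype=float)
        out.df[col] = invert_values(vals, params)
        del out.scaler[col]
    return out


def invert_values(vals: np.ndarray, params: dict) -> np.ndarray:
    if params["method"] == "zscore":
        return vals * params["sd"] + params["mean"]
    return vals * (params["max"] - params["min"]) + params["min"]


def apply_scaler(vals: np.ndarray, params: dict) -> np.ndarray:
    if params["method"] == "zscore":
        return (vals - params["mean"]) / params["sd"]
    return (vals - params["min"]) / (params["max"] - params["min"])
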
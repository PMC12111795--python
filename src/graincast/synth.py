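"""Synthetic storage-experiment generator.

Emulates a full-factorial wheat storage trial: grain conditioned to a set
of moisture contents is held at a set of temperatures in climate chambers
(relative humidity fixed at the grain's equilibrium value, so moisture
stays constant), sampled at regular intervals, with replicate measurements
of germination rate, fatty acid value and bulk density.

The default design is 4 moisture levels x 4 temperatures x 7 time nodes
(0..180 days, every 30 days) x 5 replicates = 560 records, with 1.2%
random missingness injected downstream.

Degradation kinetics are deliberately simple closed forms so tests can
check simulated trajectories against direct evaluation:

* germination  g(t) = g0 * exp(-k_g * r(T, M) * t), clipped to [0, 100]
* fatty acid   f(t) = f0 + k_f * r(T, M) * t
* bulk density d(t) = d0 - k_d * r(T, M) * t

with a shared Arrhenius-style environment multiplier
``r(T, M) = exp(alpha_T * (T - 15) + alpha_M * (M - 12.5))``: degradation
accelerates exponentially with temperature and moisture, matching the
qualitative behaviour of storage trials (germination falls, free fatty
acids accumulate, kernels lose density; all faster when warm and damp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .exceptions import DesignError, InvalidRateError
from .panel import (
    INDICATORS,
    MOIST_COL,
    QualityPanel,
    REP_COL,
    TEMP_COL,
    TIME_COL,
)

DEFAULT_MOISTURES = (12.5, 13.0, 13.5, 14.0)
DEFAULT_TEMPERATURES = (15.0, 20.0, 25.0, 30.0)
DEFAULT_TIME_NODES = tuple(range(0, 181, 30))  # 7 nodes, every 30 days
DEFAULT_REPLICATES = 5
DEFAULT_MISSING_RATE = 0.012

#: Equilibrium relative humidity (%) keeping grain moisture constant,
#: indexed by (moisture %, temperature degC).
EQUILIBRIUM_RH = {
    (12.5, 15.0): 56, (12.5, 20.0): 58, (12.5, 25.0): 60, (12.5, 30.0): 62,
    (13.0, 15.0): 60, (13.0, 20.0): 61, (13.0, 25.0): 63, (13.0, 30.0): 65,
    (13.5, 15.0): 63, (13.5, 20.0): 65, (13.5, 25.0): 66, (13.5, 30.0): 68,
    (14.0, 15.0): 67, (14.0, 20.0): 69, (14.0, 25.0): 71, (14.0, 30.0): 73,
}


@dataclass(frozen=True)
class StorageCondition:
    """One cell of the factorial design: grain moisture and chamber temperature."""

    moisture: float
    temperature: float

    @property
    def equilibrium_rh(self) -> float | None:
        """Chamber RH (%) that holds this moisture constant, if tabulated."""
        return EQUILIBRIUM_RH.get((self.moisture, self.temperature))


@dataclass
class KineticsConfig:
    """Closed-form degradation kinetics for the three quality indicators.

    Baselines are fresh-grain values; ``k_*`` are per-day rates at the
    reference condition (15 degC, 12.5% moisture); ``alpha_t`` (per degC)
    and ``alpha_m`` (per % moisture) control how fast degradation
    accelerates with temperature and moisture. ``noise_sd`` holds the
    replicate measurement noise per indicator (original units).
    """

    germination0: float = 98.0
    fatty_acid0: float = 8.0
    bulk_density0: float = 812.0
    k_germination: float = 2.6e-4
    k_fatty_acid: float = 0.011
    k_bulk_density: float = 0.012
    alpha_t: float = 0.12
    alpha_m: float = 0.8
    t_ref: float = 15.0
    m_ref: float = 12.5
    noise_sd: dict = field(
        default_factory=lambda: {
            "germination_pct": 1.5,
            "fatty_acid_mg100g": 0.8,
            "bulk_density_gL": 2.0,
        }
    )

    def __post_init__(self):
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be >= 0")

    def rate_multiplier(self, temperature, moisture):
        return np.exp(
            self.alpha_t * (np.asarray(temperature, dtype=float) - self.t_ref)
            + self.alpha_m * (np.asarray(moisture, dtype=float) - self.m_ref)
        )

    def expected_germination(self, temperature, moisture, time_days):
        r = self.rate_multiplier(temperature, moisture)
        g = self.germination0 * np.exp(-self.k_germination * r * np.asarray(time_days))
        return np.clip(g, 0.0, 100.0)

    def expected_fatty_acid(self, temperature, moisture, time_days):
        r = self.rate_multiplier(temperature, moisture)
        return self.fatty_acid0 + self.k_fatty_acid * r * np.asarray(time_days)

    def expected_bulk_density(self, temperature, moisture, time_days):
        r = self.rate_multiplier(temperature, moisture)
        return self.bulk_density0 - self.k_bulk_density * r * np.asarray(time_days)


def generate_design(
    moistures=DEFAULT_MOISTURES,
    temperatures=DEFAULT_TEMPERATURES,
    time_nodes=DEFAULT_TIME_NODES,
    replicates: int = DEFAULT_REPLICATES,
) -> QualityPanel:
    """Full-factorial design skeleton (indicator cells unset).

    Records are emitted in deterministic lexicographic order
    (moisture, temperature, time, replicate).
    """
    for name, factor in (
        ("moistures", moistures),
        ("temperatures", temperatures),
        ("time_nodes", time_nodes),
    ):
        if len(tuple(factor)) == 0:
            raise DesignError(f"factor list {name!r} is empty")
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    rows = [
        {
            MOIST_COL: m,
            TEMP_COL: t,
            TIME_COL: int(d),
            REP_COL: r,
        }
        for m, t, d, r in product(
            sorted(moistures), sorted(temperatures), sorted(time_nodes),
            range(1, replicates + 1),
        )
    ]
    df = pd.DataFrame(rows)
    for col in INDICATORS:
        df[col] = np.nan
    from .panel import ALL_COLS

    return QualityPanel(df[list(ALL_COLS)])


def simulate_quality(
    skeleton: QualityPanel, kinetics: KineticsConfig | None = None, seed: int = 0
) -> QualityPanel:
    """Fill indicator cells from the kinetics plus seeded replicate noise."""
    kinetics = kinetics or KineticsConfig()
    rng = np.random.default_rng(seed)
    out = skeleton.copy()
    temp = out.df[TEMP_COL].to_numpy(dtype=float)
    moist = out.df[MOIST_COL].to_numpy(dtype=float)
    days = out.df[TIME_COL].to_numpy(dtype=float)
    expected = {
        "germination_pct": kinetics.expected_germination(temp, moist, days),
        "fatty_acid_mg100g": kinetics.expected_fatty_acid(temp, moist, days),
        "bulk_density_gL": kinetics.expected_bulk_density(temp, moist, days),
    }
    for col in INDICATORS:
        sd = kinetics.noise_sd.get(col, 0.0)
        vals = expected[col] + (rng.normal(0.0, sd, len(out.df)) if sd > 0 else 0.0)
        if col == "germination_pct":
            vals = np.clip(vals, 0.0, 100.0)
        out.df[col] = vals
    return out


def inject_missing(panel: QualityPanel, rate: float = DEFAULT_MISSING_RATE,
                   seed: int = 0) -> QualityPanel:
    """Blank out exactly ``round(rate * n_cells)`` indicator cells at random.

    Positions are drawn uniformly without replacement over the
    records x indicators grid; the same seed reproduces the same mask.
    """
    if not 0.0 <= rate < 1.0:
        raise InvalidRateError(f"missing rate must be in [0, 1), got {rate}")
    out = panel.copy()
    n_cells = len(out.df) * len(INDICATORS)
    n_missing = int(round(rate * n_cells))
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_missing, replace=False)
    mat = out.df[list(INDICATORS)].to_numpy(dtype=float)
    mat[np.unravel_index(flat, mat.shape)] = np.nan
    out.df[list(INDICATORS)] = mat
    return out
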
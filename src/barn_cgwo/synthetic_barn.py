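"""Synthetic winter-barn sensor tables.

Generates 10-minute multivariate sensor series with the schema and magnitude
ranges of a semi-enclosed sheep barn in winter: cold air temperature,
humidity around 75–85 %, CO₂ in the 700–1400 mL/m³ band, modest light, and
particulate/gas channels.  Humidity is driven, by construction, by exactly
four exogenous columns (temperature, CO₂, light, PM2.5) plus an AR(1)
disturbance, so feature-selection and forecasting stages have a known ground
truth.  Noise, NH₃ and H₂S are independent of humidity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "generate", "COLUMNS", "FEATURE_COLUMNS", "TARGET_COLUMN", "corrupt"]

TARGET_COLUMN = "air_humidity"

#: canonical column order of a sensor table (after the timestamp index)
COLUMNS = [
    "air_temp",
    "air_humidity",
    "co2",
    "pm25",
    "pm10",
    "light",
    "noise",
    "tsp",
    "nh3",
    "h2s",
]

#: candidate predictors (the target is excluded)
FEATURE_COLUMNS = [c for c in COLUMNS if c != TARGET_COLUMN]

#: the four columns that drive humidity by construction
DRIVER_COLUMNS = ["co2", "light", "air_temp", "pm25"]

_DIURNAL = 144  # steps per day at 10-min sampling


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic humidity process.

    ``humidity_t = base + β·(drivers_t − centers) + φ·resid_{t−1} + ε_t``,
    clipped to [0, 100].  With ``noise_sd = 0`` and ``ar = 0`` humidity is an
    exact deterministic function of the drivers.
    """

    n_rows: int = 2000
    seed: int | None = None
    humidity_base: float = 80.0
    beta_temp: float = -0.9  # %/°C
    beta_co2: float = 0.005  # % per mL/m³
    beta_light: float = -0.02  # %/lx
    beta_pm25: float = 0.15  # % per µg/m³
    ar: float = 0.7
    noise_sd: float = 0.4
    # exogenous channel centers/amplitudes, invented but range-faithful
    temp_center: float = 5.5
    temp_amp: float = 1.0
    co2_center: float = 1050.0
    co2_amp: float = 120.0
    light_center: float = 150.0
    light_amp: float = 40.0
    pm25_center: float = 15.0
    pm25_amp: float = 2.0
    driver_ar: float = 0.9  # persistence of the stochastic driver component
    start: str = "2021-02-08 17:10:00"
    corrupt_frac: float = 0.0  # fraction of rows given a missing value or spike

    def __post_init__(self) -> None:
        if self.n_rows < 20:
            raise ValueError("n_rows must be >= 20")
        if not -1.0 < self.ar < 1.0:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.corrupt_frac < 0.5:
            raise ValueError("corrupt_frac must be in [0, 0.5)")


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path; the innovation sd is scaled so the marginal
    standard deviation equals ``sd`` regardless of ``phi``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0, innov_sd, n)
    out = np.empty(n)
    out[0] = rng.normal(0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def generate(config: GeneratorConfig = GeneratorConfig()) -> pd.DataFrame:
    """Build one sensor table; identical output for identical config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    t = np.arange(n)
    day = 2.0 * np.pi * t / _DIURNAL
    phi_d = config.driver_ar

    # drivers = diurnal sinusoid + persistent stochastic weather component,
    # so forecastability genuinely decays with horizon
    temp = config.temp_center + config.temp_amp * np.sin(day - 0.8) + _ar1(rng, n, phi_d, 1.2)
    co2 = config.co2_center + config.co2_amp * np.sin(day + 2.2) + _ar1(rng, n, phi_d, 150.0)
    light = np.clip(
        config.light_center + config.light_amp * np.sin(day - 1.3) + _ar1(rng, n, phi_d, 45.0),
        0,
        None,
    )
    pm25 = np.clip(
        config.pm25_center + config.pm25_amp * np.sin(day + 0.5) + _ar1(rng, n, phi_d, 4.0),
        0.5,
        None,
    )
    pm10 = np.clip(3.2 * pm25 + rng.normal(0, 12.0, n), 1.0, None)
    tsp = np.clip(5.5 * pm25 + rng.normal(0, 25.0, n), 1.0, None)
    noise_db = np.clip(42.0 + rng.normal(0, 9.0, n), 20.0, None)
    nh3 = np.clip(rng.normal(0.0, 0.05, n), 0.0, None)
    h2s = np.clip(4.5 + rng.normal(0, 1.2, n), 0.0, None)

    det = (
        config.humidity_base
        + config.beta_temp * (temp - config.temp_center)
        + config.beta_co2 * (co2 - config.co2_center)
        + config.beta_light * (light - config.light_center)
        + config.beta_pm25 * (pm25 - config.pm25_center)
    )
    eps = rng.normal(0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    humidity = np.empty(n)
    resid = 0.0
    for i in range(n):
        resid = config.ar * resid + eps[i]
        humidity[i] = det[i] + resid
    humidity = np.clip(humidity, 0.0, 100.0)

    index = pd.date_range(config.start, periods=n, freq="10min", name="timestamp")
    table = pd.DataFrame(
        {
            "air_temp": temp,
            "air_humidity": humidity,
            "co2": co2,
            "pm25": pm25,
            "pm10": pm10,
            "light": light,
            "noise": noise_db,
            "tsp": tsp,
            "nh3": nh3,
            "h2s": h2s,
        },
        index=index,
    )[COLUMNS]
    if config.corrupt_frac > 0:
        table = corrupt(table, config.corrupt_frac, rng)
    return table


def corrupt(table: pd.DataFrame, frac: float, rng: np.random.Generator) -> pd.DataFrame:
    """Inject missing values and out-of-range spikes for the repair stage.

    Half of the affected rows get a NaN in a random sensor column, the other
    half an implausible spike (humidity above 100 or a negative reading).
    First and last rows are left intact so interpolation stays bounded.
    """
    table = table.copy()
    n = len(table)
    n_bad = int(frac * n)
    rows = rng.choice(np.arange(1, n - 1), size=n_bad, replace=False)
    cols = rng.choice(len(COLUMNS), size=n_bad)
    for r, c in zip(rows, cols):
        col = COLUMNS[c]
        if rng.random() < 0.5:
            table.iloc[r, table.columns.get_loc(col)] = np.nan
        elif col == "air_humidity":
            table.iloc[r, table.columns.get_loc(col)] = 250.0
        else:
            table.iloc[r, table.columns.get_loc(col)] = -abs(table.iloc[r][col]) - 10.0
    return table
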
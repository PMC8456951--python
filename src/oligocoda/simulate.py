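"""Synthetic coastal oligotype time series with known generating truth.

The generator emulates an 8-year, roughly monthly amplicon time series of
six *Synechococcus* oligotypes at a temperate coastal site: sinusoidal
incident radiation peaking near the summer solstice, sea temperature
lagging light by a few weeks, lognormal nutrient noise, and a latent
composition that responds linearly — in ilr coordinates, per season — to
temperature and weekly averaged light.  Observed read counts are drawn
multinomially at depths spanning ~15 to ~20 000 reads, so depth-driven
zeros arise exactly as they do in real libraries.  Because the generating
model is the same model class the regression fits, every stage of the
analysis can be validated by parameter recovery.

The default preset reproduces the qualitative MVCO phenology: O1 dominant
in winter–spring, a sharp mid-summer O2 pulse, O4/O5 rising together in
fall with a near-constant ratio, and a quasi-constant O3 share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .balances import SBP, ilr, ilr_inverse, mvco_sbp
from .geometry import closure
from .preprocess import CountTable, assign_season

__all__ = [
    "SeasonParams",
    "SimConfig",
    "SimTruth",
    "SimOutput",
    "MockCommunity",
    "mvco_like_params",
    "simulate_environment",
    "simulate_composition_series",
    "sample_counts",
    "simulate_dataset",
    "simulate_mock_community",
]

LABELS = ("O1", "O2", "O3", "O4", "O5", "O6")


@dataclass(frozen=True)
class SeasonParams:
    """Generating parameters of one season's linear ilr response.

    ``mean_composition`` is the expected composition at the season's
    typical covariate values (``mean_covariates``); the implied intercept
    in ilr coordinates is ilr(mean) − Σ slope·mean_covariate.  Slopes are
    per covariate unit (°C, MJ m⁻² d⁻¹).
    """

    mean_composition: tuple[float, ...]
    slopes: dict[str, tuple[float, ...]]
    mean_covariates: dict[str, float]

    def intercept_coords(self, sbp: SBP) -> np.ndarray:
        y = ilr(closure(np.asarray(self.mean_composition)), sbp)
        for var, b in self.slopes.items():
            y = y - np.asarray(b) * self.mean_covariates[var]
        return y


def mvco_like_params() -> dict[str, SeasonParams]:
    """Default generating truth mirroring the observed seasonal phenology.

    Effect sizes are strong, as in the field data (temperature alone
    explains most within-season compositional variance there); each
    season responds to temperature and weekly light only, leaving the
    nutrient covariates as true nulls.
    """
    return {
        "winter_spring": SeasonParams(
            mean_composition=(0.55, 0.02, 0.12, 0.05, 0.04, 0.22),
            slopes={
                "temperature": (-0.06, -0.10, 0.0, -0.05, 0.0),
                "weekly_light": (0.0, -0.075, 0.0, -0.095, 0.0),
            },
            mean_covariates={"temperature": 7.0, "weekly_light": 17.0},
        ),
        "summer": SeasonParams(
            mean_composition=(0.25, 0.25, 0.15, 0.12, 0.10, 0.13),
            slopes={
                "temperature": (-0.22, -0.10, 0.0, 0.0, 0.05),
                "weekly_light": (-0.15, 0.08, 0.05, 0.0, 0.0),
            },
            mean_covariates={"temperature": 17.0, "weekly_light": 24.0},
        ),
        "fall": SeasonParams(
            mean_composition=(0.25, 0.05, 0.15, 0.25, 0.20, 0.10),
            slopes={
                "temperature": (-0.10, 0.06, 0.01, 0.0, -0.02),
                "weekly_light": (0.08, 0.10, 0.0, -0.05, 0.0),
            },
            mean_covariates={"temperature": 12.0, "weekly_light": 13.0},
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic time series."""

    n_samples: int = 129
    start_year: int = 2010
    n_years: int = 8
    labels: tuple[str, ...] = LABELS
    # read-depth model: log-uniform between the two bounds
    depth_min: int = 15
    depth_max: int = 20000
    # environment: light sinusoid peaking near the solstice, temperature
    # sinusoid lagging it, lognormal nutrients
    light_min: float = 5.0
    light_max: float = 28.0
    light_peak_day: int = 172
    light_jitter: float = 6.0
    temp_min: float = 1.0
    temp_max: float = 20.0
    temp_lag_days: int = 35
    temp_jitter: float = 1.5
    nutrient_means: dict = field(
        default_factory=lambda: {
            "nitrate_nitrite": 1.0,
            "phosphate": 0.3,
            "ammonium": 0.5,
            "silicate": 2.0,
        }
    )
    nutrient_sigma: float = 0.5
    noise_scale: float = 0.3  # sd of Gaussian ilr noise per coordinate
    season_params: dict[str, SeasonParams] = field(default_factory=mvco_like_params)

    def with_depth(self, depth_min: int, depth_max: int | None = None) -> "SimConfig":
        return replace(
            self, depth_min=depth_min, depth_max=depth_max or self.depth_max
        )


@dataclass
class SimTruth:
    """Generating quantities kept aside for parameter-recovery checks."""

    season_params: dict[str, SeasonParams]
    sbp: SBP
    coords: pd.DataFrame  # latent ilr coordinates (noise included)
    expected: pd.DataFrame  # latent compositions, rows sum to 1
    depths: pd.Series

    def intercepts(self) -> dict[str, np.ndarray]:
        return {s: p.intercept_coords(self.sbp) for s, p in self.season_params.items()}


@dataclass
class SimOutput:
    counts: CountTable
    env: pd.DataFrame
    daily_light: pd.Series
    truth: SimTruth


def _sample_dates(config: SimConfig, rng: np.random.Generator) -> pd.DatetimeIndex:
    """Monthly visits with day jitter, doubled in summer, trimmed to n_samples."""
    dates = []
    for year in range(config.start_year, config.start_year + config.n_years):
        for month in range(1, 13):
            day = int(np.clip(15 + rng.integers(-6, 7), 1, 28))
            dates.append(pd.Timestamp(year=year, month=month, day=day))
            if month in (6, 7, 8, 9, 10, 11):  # denser summer/fall sampling
                extra = int(np.clip(5 + rng.integers(-3, 4), 1, 28))
                dates.append(pd.Timestamp(year=year, month=month, day=extra))
    dates = sorted(set(dates))
    if len(dates) > config.n_samples:
        keep = np.sort(
            rng.choice(len(dates), size=config.n_samples, replace=False)
        )
        dates = [dates[i] for i in keep]
    return pd.DatetimeIndex(dates)


def _light_curve(yearday: np.ndarray, config: SimConfig) -> np.ndarray:
    phase = 2.0 * np.pi * (yearday - config.light_peak_day) / 365.25
    amp = (config.light_max - config.light_min) / 2.0
    return config.light_min + amp * (1.0 + np.cos(phase))


def _temp_curve(yearday: np.ndarray, config: SimConfig) -> np.ndarray:
    peak = config.light_peak_day + config.temp_lag_days
    phase = 2.0 * np.pi * (yearday - peak) / 365.25
    amp = (config.temp_max - config.temp_min) / 2.0
    return config.temp_min + amp * (1.0 + np.cos(phase))


def simulate_environment(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DatetimeIndex, pd.DataFrame, pd.Series]:
    """Sampling dates, per-sample covariates, and the daily light series.

    ``weekly_light`` is the mean of the simulated daily radiation over the
    seven days before each sampling date — the same windowing applied to
    field radiometer data.
    """
    dates = _sample_dates(config, rng)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    days = pd.date_range(start, dates[-1], freq="D")
    daily = _light_curve(days.dayofyear.to_numpy(dtype=float), config)
    daily = np.maximum(daily + rng.normal(0.0, config.light_jitter, len(days)), 0.0)
    daily_light = pd.Series(daily, index=days, name="incident_radiation")

    ids = [f"S{i + 1:03d}" for i in range(len(dates))]
    yearday = dates.dayofyear.to_numpy(dtype=float)
    temp = _temp_curve(yearday, config) + rng.normal(0.0, config.temp_jitter, len(dates))
    weekly = np.array(
        [
            daily_light[(days >= d - pd.Timedelta(days=7)) & (days <= d - pd.Timedelta(days=1))].mean()
            if d > days[0]
            else daily_light.iloc[:1].mean()
            for d in dates
        ]
    )
    env = pd.DataFrame({"temperature": temp, "weekly_light": weekly}, index=ids)
    for name, mean in config.nutrient_means.items():
        env[name] = mean * rng.lognormal(0.0, config.nutrient_sigma, len(dates))
    return dates, env, daily_light


def simulate_composition_series(
    env: pd.DataFrame,
    dates: pd.DatetimeIndex,
    season_params: dict[str, SeasonParams],
    sbp: SBP,
    noise_scale: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent compositions: ilr⁻¹(intercept + slopes·covariates + noise)."""
    coords = np.empty((len(env), sbp.D - 1))
    for i, (sid, d) in enumerate(zip(env.index, dates)):
        p = season_params[assign_season(d)]
        y = p.intercept_coords(sbp).copy()
        for var, b in p.slopes.items():
            y += np.asarray(b) * float(env.loc[sid, var])
        coords[i] = y + rng.normal(0.0, noise_scale, sbp.D - 1)
    coords_df = pd.DataFrame(coords, index=env.index)
    comps = ilr_inverse(coords, sbp)
    return (
        pd.DataFrame(comps, index=env.index, columns=list(sbp.labels)),
        coords_df,
    )


def sample_counts(
    expected: pd.DataFrame,
    config: SimConfig,
    dates: pd.DatetimeIndex,
    rng: np.random.Generator,
) -> tuple[CountTable, pd.Series]:
    """Multinomial read counts at log-uniform depths.

    At low depth (tens of reads) rare parts drop out of the counts
    entirely, producing the structural-looking zeros the imputation stage
    exists for.
    """
    n = expected.shape[0]
    depths = np.exp(
        rng.uniform(np.log(config.depth_min), np.log(config.depth_max), n)
    ).astype(int)
    depths = np.maximum(depths, 1)
    counts = np.vstack(
        [rng.multinomial(depths[i], expected.iloc[i].to_numpy()) for i in range(n)]
    )
    table = CountTable(
        pd.DataFrame(counts, index=expected.index, columns=expected.columns),
        pd.Series(dates, index=expected.index),
    )
    return table, pd.Series(depths, index=expected.index, name="depth")


def simulate_dataset(
    config: SimConfig | None = None, seed: int = 0, sbp: SBP | None = None
) -> SimOutput:
    """End-to-end draw: environment → latent compositions → read counts.

    All randomness flows from ``seed``; equal (config, seed) pairs give
    identical output.
    """
    config = config or SimConfig()
    sbp = sbp or mvco_sbp()
    rng = np.random.default_rng(seed)
    dates, env, daily_light = simulate_environment(config, rng)
    expected, coords = simulate_composition_series(
        env, dates, config.season_params, sbp, config.noise_scale, rng
    )
    counts, depths = sample_counts(expected, config, dates, rng)
    truth = SimTruth(
        season_params=config.season_params,
        sbp=sbp,
        coords=coords,
        expected=expected,
        depths=depths,
    )
    return SimOutput(counts=counts, env=env, daily_light=daily_light, truth=truth)


@dataclass
class MockCommunity:
    """Counts and expected proportions for an equal-concentration strain mix."""

    counts: pd.Series
    expected: pd.Series


def simulate_mock_community(
    n_strains: int,
    depth: int = 50000,
    bias: np.ndarray | None = None,
    copy_number: float = 2.0,
    seed: int = 0,
) -> MockCommunity:
    """Mock community of strains mixed at equal cell concentration.

    Each strain contributes ``copy_number`` 16S copies per cell times a
    per-strain recovery ``bias`` (1 = unbiased), so the expected read
    proportion is the closure of copy_number × bias — exactly 1/n for an
    unbiased equal mix.  Counts are multinomial at the given depth.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    b = np.ones(n_strains) if bias is None else np.asarray(bias, dtype=float)
    if b.size != n_strains or np.any(b <= 0):
        raise ValueError("bias must be positive, one value per strain")
    expected = closure(copy_number * b)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, expected)
    idx = [f"strain{i + 1}" for i in range(n_strains)]
    return MockCommunity(
        counts=pd.Series(counts, index=idx, name="reads"),
        expected=pd.Series(expected, index=idx, name="expected_proportion"),
    )
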
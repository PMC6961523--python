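"""Synthetic daily pelagic forcing for the benthic model.

Generates seeded, deterministic daily series of bottom temperature, detrital
fluxes, bottom-water solute concentrations, tidal bed stress and a surface
chlorophyll proxy, with the seasonal structure the benthic model assumes:
a spring-bloom pulse (optionally with a smaller autumn bloom), summer
stratification with bottom-water oxygen drawdown, winter nutrient plateaus
with post-bloom drawdown, and an M2+S2 bed-stress series carrying the
spring-neap beat.

Also provides the synthetic observation-fixture generator used by the
model-observation comparison harness.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import (
    DAYS_PER_YEAR,
    M2_PERIOD_HOURS,
    MMOL_C_PER_G,
    S2_PERIOD_HOURS,
    VON_KARMAN,
)


class ForcingConfigError(ValueError):
    """Raised for invalid forcing configurations."""


# Winter bottom-water nutrient defaults (mmol m^-3). These are plausible
# shelf-sea magnitudes chosen for the synthetic driver; they are NOT
# literature values and are freely configurable.
DEFAULT_BW_NUTRIENT_WINTER = {
    "NO3": 8.0,
    "NH4": 0.5,
    "PO4": 0.6,
    "Si": 5.0,
}


@dataclass
class ForcingConfig:
    """Configuration for :func:`generate_forcing`.

    Parameters with physical meaning carry their units in the comment; all
    defaults are synthetic-driver calibration values unless noted.
    """

    years: int = 2
    t_start: _dt.date = _dt.date(2000, 1, 1)
    bloom_day: int = 110               # day-of-year of spring-bloom peak
    bloom_width_days: float = 12.0     # Gaussian s.d. of the bloom pulse
    annual_benthic_C_input: float = 20.0   # g C m^-2 yr^-1
    autumn_bloom_fraction: float = 0.15    # fraction of annual input in autumn pulse
    autumn_bloom_day: int = 280
    bloom_scale: float = 1.0           # overall amplitude multiplier (0 silences input)
    temp_mean: float = 11.0            # degC
    temp_amplitude: float = 3.5        # degC, seasonal half-range at the surface
    strat_onset_doy: int = 120
    remix_doy: int = 330
    bw_O2_winter: float = 280.0        # mmol m^-3
    bw_O2_summer_drawdown_frac: float = 0.15
    bw_nutrient_winter: dict = field(
        default_factory=lambda: dict(DEFAULT_BW_NUTRIENT_WINTER)
    )
    nutrient_drawdown_frac: float = 0.7
    m2_current_amp: float = 0.03       # m s^-1
    s2_current_amp: float = 0.01       # m s^-1
    bed_roughness_z0: float = 0.03 / 7.0   # m, ripple height / 7
    stress_ref_height: float = 0.1     # m
    water_density: float = 1010.0      # kg m^-3
    detritus_si_to_c: float = 15.0 / 106.0   # molar Si:C of detritus
    chl_per_flux: float = 25.0         # mg Chl m^-3 per (g C m^-2 d^-1), proxy scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ForcingConfigError("years must be >= 1")
        if self.annual_benthic_C_input <= 0:
            raise ForcingConfigError("annual_benthic_C_input must be > 0")
        if not (0.0 <= self.autumn_bloom_fraction < 1.0):
            raise ForcingConfigError("autumn_bloom_fraction must be in [0, 1)")
        if self.bloom_scale < 0:
            raise ForcingConfigError("bloom_scale must be >= 0")
        if self.temp_amplitude < 0 or self.m2_current_amp < 0 or self.s2_current_amp < 0:
            raise ForcingConfigError("amplitudes must be >= 0")
        if not (0 < self.strat_onset_doy < self.remix_doy <= DAYS_PER_YEAR):
            raise ForcingConfigError(
                "need 0 < strat_onset_doy < remix_doy <= 365 (remix follows onset)"
            )
        if not (0 < self.bloom_day <= DAYS_PER_YEAR):
            raise ForcingConfigError("bloom_day outside calendar")
        if self.bed_roughness_z0 <= 0 or self.stress_ref_height <= self.bed_roughness_z0:
            raise ForcingConfigError("need 0 < z0 < reference height")


@dataclass
class ForcingSeries:
    """Daily pelagic boundary conditions at the sediment-water interface.

    All arrays share the common daily grid ``time`` (days since ``t_start``,
    length years*365, no leap handling).
    """

    time: np.ndarray                  # days since t_start
    t_start: _dt.date
    bottom_temperature: np.ndarray    # degC
    detritus_C_flux: np.ndarray       # g C m^-2 day^-1
    detritus_N_flux: np.ndarray       # mmol N m^-2 day^-1
    detritus_P_flux: np.ndarray       # mmol P m^-2 day^-1
    detritus_Si_flux: np.ndarray      # mmol Si m^-2 day^-1
    bw_O2: np.ndarray                 # mmol m^-3
    bw_NO3: np.ndarray
    bw_NH4: np.ndarray
    bw_PO4: np.ndarray
    bw_Si: np.ndarray
    bed_stress: np.ndarray            # Pa (daily mean of instantaneous stress)
    surface_chl_proxy: np.ndarray     # mg Chl m^-3

    _COLUMNS = {
        "bottom_temperature": "degC",
        "detritus_C_flux": "gC_m-2_d-1",
        "detritus_N_flux": "mmolN_m-2_d-1",
        "detritus_P_flux": "mmolP_m-2_d-1",
        "detritus_Si_flux": "mmolSi_m-2_d-1",
        "bw_O2": "mmol_m-3",
        "bw_NO3": "mmol_m-3",
        "bw_NH4": "mmol_m-3",
        "bw_PO4": "mmol_m-3",
        "bw_Si": "mmol_m-3",
        "bed_stress": "Pa",
        "surface_chl_proxy": "mgChl_m-3",
    }

    def __len__(self) -> int:
        return len(self.time)

    def dates(self) -> pd.DatetimeIndex:
        """ISO calendar dates of the daily grid (365-day years, no leap)."""
        base = pd.Timestamp(self.t_start)
        return base + pd.to_timedelta(self.time, unit="D")

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as a DataFrame with unit-bearing column names."""
        data = {"date": self.dates().strftime("%Y-%m-%d"), "time_days": self.time}
        for name, unit in self._COLUMNS.items():
            data[f"{name}_{unit}"] = getattr(self, name)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        df = pd.read_csv(path)
        t_start = _dt.date.fromisoformat(df["date"].iloc[0])
        kwargs = {"time": df["time_days"].to_numpy(float), "t_start": t_start}
        for name, unit in cls._COLUMNS.items():
            kwargs[name] = df[f"{name}_{unit}"].to_numpy(float)
        return cls(**kwargs)

    def sample(self, i: int) -> dict:
        """Forcing values on day ``i`` as a plain dict (simulator interface)."""
        return {name: float(getattr(self, name)[i]) for name in self._COLUMNS}


def _gaussian_pulse(doy: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump in day-of-year, truncated at +/- 4 s.d., wrap-around safe."""
    # distance on the circular 365-day calendar
    d = np.abs(doy - center)
    d = np.minimum(d, DAYS_PER_YEAR - d)
    out = np.exp(-0.5 * (d / width) ** 2)
    out[d > 4.0 * width] = 0.0
    return out


def tidal_stress(
    m2_amp: float,
    s2_amp: float,
    z0: float,
    time_days: np.ndarray,
    z_r: float = 0.1,
    rho: float = 1010.0,
) -> np.ndarray:
    """Instantaneous tidal bed shear stress (Pa) on an arbitrary time grid.

    The near-bed speed is the modulus of the superposed M2 and S2
    constituents, ``u(t) = |m2 cos(w_M2 t) + s2 cos(w_S2 t)|``, and the
    stress is quadratic, ``tau_b = rho C_d u^2``, with the drag coefficient
    from the log law at the reference height,
    ``C_d = (kappa / ln(z_r/z0))^2``. The envelope modulates at the
    spring-neap beat of the two constituents (~14.77 days).
    """
    if m2_amp < 0 or s2_amp < 0:
        raise ValueError("current amplitudes must be >= 0")
    if z0 <= 0 or z_r <= z0:
        raise ValueError("need 0 < z0 < z_r")
    t = np.asarray(time_days, dtype=float)
    w_m2 = 2.0 * np.pi / (M2_PERIOD_HOURS / 24.0)
    w_s2 = 2.0 * np.pi / (S2_PERIOD_HOURS / 24.0)
    u = np.abs(m2_amp * np.cos(w_m2 * t) + s2_amp * np.cos(w_s2 * t))
    c_d = (VON_KARMAN / np.log(z_r / z0)) ** 2
    return rho * c_d * u**2


def _bottom_temperature(cfg: ForcingConfig, doy: np.ndarray) -> np.ndarray:
    """Bottom temperature by relaxation toward a surface-like sinusoid.

    During stratification the relaxation timescale lengthens, so the bottom
    lags and damps the surface cycle (summer maximum arrives late, as under
    a seasonal thermocline).
    """
    # surface-like cycle peaking around day 230
    t_surface = cfg.temp_mean + cfg.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - 230.0) / DAYS_PER_YEAR
    )
    tau_mixed, tau_strat = 10.0, 60.0
    n = len(doy)

    def _tau(d: float) -> float:
        return tau_strat if cfg.strat_onset_doy <= d < cfg.remix_doy else tau_mixed

    t_b = cfg.temp_mean
    # one throwaway year removes the initial condition
    for i in range(min(n, DAYS_PER_YEAR)):
        t_b += (t_surface[i] - t_b) / _tau(doy[i])
    out = np.empty(n)
    for i in range(n):
        t_b += (t_surface[i] - t_b) / _tau(doy[i])
        out[i] = t_b
    return out


def _bw_oxygen(cfg: ForcingConfig, doy: np.ndarray) -> np.ndarray:
    """Winter plateau, linear drawdown while stratified, fast post-remix recovery."""
    low = cfg.bw_O2_winter * (1.0 - cfg.bw_O2_summer_drawdown_frac)
    xp = [0.0, float(cfg.strat_onset_doy), float(cfg.remix_doy),
          min(cfg.remix_doy + 20.0, 364.0), 364.0]
    fp = [cfg.bw_O2_winter, cfg.bw_O2_winter, low, cfg.bw_O2_winter, cfg.bw_O2_winter]
    return np.interp(doy, xp, fp)


def _bw_nutrient(cfg: ForcingConfig, doy: np.ndarray, winter_value: float) -> np.ndarray:
    """Winter plateau, post-bloom drawdown, gradual recovery after remixing."""
    low = winter_value * (1.0 - cfg.nutrient_drawdown_frac)
    xp = [0.0,
          max(cfg.bloom_day - 10.0, 1.0),
          min(cfg.bloom_day + 30.0, cfg.remix_doy - 1.0),
          float(cfg.remix_doy),
          min(cfg.remix_doy + 40.0, 364.0),
          364.0]
    fp = [winter_value, winter_value, low, low, winter_value, winter_value]
    return np.interp(doy, xp, fp)


def generate_forcing(config: ForcingConfig) -> ForcingSeries:
    """Generate the full daily forcing series from a configuration.

    The detrital carbon flux integrates over each simulated year to
    ``annual_benthic_C_input`` (exactly, by discrete normalisation of the
    bloom pulses); detrital N and P follow Redfield molar stoichiometry
    (C:N = 106:16, C:P = 106:1) and Si the configured Si:C ratio. The
    output is deterministic for a given configuration.
    """
    n = config.years * DAYS_PER_YEAR
    time = np.arange(n, dtype=float)
    doy_offset = config.t_start.timetuple().tm_yday - 1
    doy = (time + doy_offset) % DAYS_PER_YEAR

    # --- detritus pulse, exactly normalised per year ---
    spring = _gaussian_pulse(doy, config.bloom_day, config.bloom_width_days)
    autumn = _gaussian_pulse(doy, config.autumn_bloom_day,
                             config.bloom_width_days * 1.5)
    flux_c = np.zeros(n)
    for y in range(config.years):
        sl = slice(y * DAYS_PER_YEAR, (y + 1) * DAYS_PER_YEAR)
        year_flux = np.zeros(DAYS_PER_YEAR)
        s_sum = spring[sl].sum()
        a_sum = autumn[sl].sum()
        if s_sum > 0:
            year_flux += (
                (1.0 - config.autumn_bloom_fraction)
                * config.annual_benthic_C_input * spring[sl] / s_sum
            )
        if a_sum > 0 and config.autumn_bloom_fraction > 0:
            year_flux += (
                config.autumn_bloom_fraction
                * config.annual_benthic_C_input * autumn[sl] / a_sum
            )
        flux_c[sl] = year_flux * config.bloom_scale

    flux_c_mmol = flux_c * MMOL_C_PER_G
    flux_n = flux_c_mmol * (16.0 / 106.0)
    flux_p = flux_c_mmol / 106.0
    flux_si = flux_c_mmol * config.detritus_si_to_c

    # --- daily-mean bed stress from hourly sub-sampling ---
    hourly = np.arange(n * 24, dtype=float) / 24.0
    tau_hourly = tidal_stress(
        config.m2_current_amp, config.s2_current_amp, config.bed_roughness_z0,
        hourly, z_r=config.stress_ref_height, rho=config.water_density,
    )
    bed_stress = tau_hourly.reshape(n, 24).mean(axis=1)

    nut = {
        name: _bw_nutrient(config, doy, config.bw_nutrient_winter[name])
        for name in ("NO3", "NH4", "PO4", "Si")
    }

    return ForcingSeries(
        time=time,
        t_start=config.t_start,
        bottom_temperature=_bottom_temperature(config, doy),
        detritus_C_flux=flux_c,
        detritus_N_flux=flux_n,
        detritus_P_flux=flux_p,
        detritus_Si_flux=flux_si,
        bw_O2=_bw_oxygen(config, doy),
        bw_NO3=nut["NO3"],
        bw_NH4=nut["NH4"],
        bw_PO4=nut["PO4"],
        bw_Si=nut["Si"],
        bed_stress=bed_stress,
        surface_chl_proxy=flux_c * config.chl_per_flux,
    )


def generate_observation_fixtures(
    truth: pd.DataFrame,
    noise_cv: float,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Scatter replicate 'observations' around model truth.

    ``truth`` needs columns ``site, date, quantity, value``. Noise is
    multiplicative lognormal with coefficient of variation ``noise_cv`` and
    the bias correction ``exp(-sigma^2/2)`` applied, so the replicate mean
    converges to truth as replicates grow. ``noise_cv = 0`` reproduces truth
    exactly in every replicate.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    required = {"site", "date", "quantity", "value"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for _, rec in truth.iterrows():
        for rep in range(1, replicates + 1):
            if sigma > 0:
                mult = np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
            else:
                mult = 1.0
            rows.append(
                {
                    "site": rec["site"],
                    "date": rec["date"],
                    "quantity": rec["quantity"],
                    "replicate": rep,
                    "value": rec["value"] * mult,
                    "source": "synthetic",
                }
            )
    return pd.DataFrame(rows)


def config_to_yaml(config: ForcingConfig, path) -> None:
    """Serialise a forcing configuration to YAML."""
    import yaml

    data = asdict(config)
    data["t_start"] = config.t_start.isoformat()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> ForcingConfig:
    """Load a forcing configuration from YAML, rejecting unknown keys."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(ForcingConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ForcingConfigError(f"unknown forcing config keys: {sorted(unknown)}")
    if "t_start" in data and isinstance(data["t_start"], str):
        data["t_start"] = _dt.date.fromisoformat(data["t_start"])
    return ForcingConfig(**data)
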
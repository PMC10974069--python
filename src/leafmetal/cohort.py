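"""Synthetic paired (leaf spectra, soil metal) cohorts.

Generates cohorts whose soil Cd/As marginals follow truncated log-normal
distributions calibrated by moment matching, coupled through a Gaussian
copula whose parameter is numerically inverted so the output Pearson
correlation hits a configured target.  Leaf spectra are vegetation-shaped
reflectance curves (chlorophyll absorption wells at 450/670 nm, green peak
near 550 nm, logistic red edge, high NIR plateau) whose well depths shrink
linearly with a metal-driven stress index, followed by per-spectrum affine
scatter and channel noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortConfig",
    "SoilTable",
    "SpectraSet",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortError",
]


class CohortError(ValueError):
    """Raised for invalid cohort configurations or inconsistent cohorts."""


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class SoilTable:
    """Per-site soil chemistry: pH and heavy-metal concentrations (mg/kg)."""

    site_ids: np.ndarray  # str array, unique
    ph: np.ndarray
    cd: np.ndarray
    as_: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=str)
        self.ph = np.asarray(self.ph, dtype=float)
        self.cd = np.asarray(self.cd, dtype=float)
        self.as_ = np.asarray(self.as_, dtype=float)
        n = len(self.site_ids)
        if not (len(self.ph) == len(self.cd) == len(self.as_) == n):
            raise CohortError("soil table column lengths differ")
        if len(np.unique(self.site_ids)) != n:
            raise CohortError("site ids must be unique")
        if np.any(self.cd <= 0) or np.any(self.as_ <= 0):
            raise CohortError("metal concentrations must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def metal(self, name: str) -> np.ndarray:
        key = name.lower().rstrip("_")
        if key == "cd":
            return self.cd
        if key == "as":
            return self.as_
        raise KeyError(f"unknown metal {name!r}; expected 'cd' or 'as'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_ids, "ph": self.ph,
             "cd_mg_kg": self.cd, "as_mg_kg": self.as_}
        )


@dataclass
class SpectraSet:
    """Sample x wavelength reflectance matrix with explicit grid and ids."""

    site_ids: np.ndarray
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray  # [n_sites, n_channels]

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=str)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.reflectance.shape != (len(self.site_ids), len(self.wavelengths_nm)):
            raise CohortError("reflectance shape inconsistent with ids/grid")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise CohortError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise CohortError("reflectance must be finite")

    @property
    def n_sites(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    def replace(self, reflectance=None, wavelengths_nm=None, site_ids=None) -> "SpectraSet":
        return SpectraSet(
            site_ids=self.site_ids if site_ids is None else site_ids,
            wavelengths_nm=self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm,
            reflectance=self.reflectance if reflectance is None else reflectance,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance,
                          columns=[repr(float(w)) for w in self.wavelengths_nm])
        df.insert(0, "site_id", self.site_ids)
        return df


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Metal ranges are interpreted as the 0.5th/99.5th percentiles of the
    underlying log-normal and double as hard truncation bounds.
    """

    n_sites: int = 22
    wavelength_start_nm: float = 301.0
    wavelength_step_nm: float = 3.3
    wavelength_end_nm: float = 1145.0
    cd_mean: float = 0.29
    cd_range: tuple[float, float] = (0.13, 0.97)
    as_mean: float = 5.64
    as_range: tuple[float, float] = (3.23, 9.32)
    cd_as_corr: float = 0.33
    ph_mean: float = 5.86
    ph_sd: float = 0.30
    stress_slope_cd: float = 0.50   # per mg/kg Cd
    stress_slope_as: float = 0.035  # per mg/kg As
    stress_noise_sd: float = 0.015
    scatter_sd_add: float = 0.01
    scatter_sd_mult: float = 0.05
    channel_noise_sd: float = 0.0015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise CohortError("n_sites must be positive")
        if not (self.cd_range[0] < self.cd_mean < self.cd_range[1]):
            raise CohortError(
                f"cd_mean {self.cd_mean} outside cd_range {self.cd_range}: "
                "moment calibration infeasible"
            )
        if not (self.as_range[0] < self.as_mean < self.as_range[1]):
            raise CohortError(
                f"as_mean {self.as_mean} outside as_range {self.as_range}: "
                "moment calibration infeasible"
            )
        if self.cd_range[0] <= 0 or self.as_range[0] <= 0:
            raise CohortError("metal ranges must be positive")
        if not -1 < self.cd_as_corr < 1:
            raise CohortError("cd_as_corr must lie in (-1, 1)")
        if self.wavelength_step_nm <= 0:
            raise CohortError("wavelength step must be positive")
        n_above_380 = np.sum(self.wavelength_grid() >= 380.0)
        if n_above_380 < 50:
            raise CohortError("fewer than 50 channels at or above 380 nm")

    def wavelength_grid(self) -> np.ndarray:
        k_max = int(np.floor(
            (self.wavelength_end_nm - self.wavelength_start_nm) / self.wavelength_step_nm
        ))
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(k_max + 1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text())
        if "cd_range" in raw:
            raw["cd_range"] = tuple(raw["cd_range"])
        if "as_range" in raw:
            raw["as_range"] = tuple(raw["as_range"])
        return cls(**raw)


# --------------------------------------------------------------------------
# truncated log-normal marginals and the Gaussian copula
# --------------------------------------------------------------------------

_RANGE_TAIL = 0.005  # range endpoints treated as 0.5th/99.5th percentiles


@dataclass(frozen=True)
class _TruncLogNormal:
    """Log-normal truncated to [lo, hi], calibrated to a target mean."""

    mu: float
    sigma: float
    lo: float
    hi: float

    @property
    def _plo(self) -> float:
        return stats.norm.cdf((np.log(self.lo) - self.mu) / self.sigma)

    @property
    def _phi(self) -> float:
        return stats.norm.cdf((np.log(self.hi) - self.mu) / self.sigma)

    def mean(self) -> float:
        a = (np.log(self.lo) - self.mu) / self.sigma
        b = (np.log(self.hi) - self.mu) / self.sigma
        denom = stats.norm.cdf(b) - stats.norm.cdf(a)
        if denom < 1e-300:  # truncation window deep in a tail: limit value
            return self.lo if a > 0 else self.hi
        num = stats.norm.cdf(b - self.sigma) - stats.norm.cdf(a - self.sigma)
        return float(np.exp(self.mu + 0.5 * self.sigma**2) * num / denom)

    def from_gauss(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws through the truncated quantile function."""
        p = self._plo + stats.norm.cdf(z) * (self._phi - self._plo)
        return np.exp(self.mu + self.sigma * stats.norm.ppf(p))


def _calibrate_marginal(mean: float, lo: float, hi: float) -> _TruncLogNormal:
    """Solve (mu, sigma): sigma from the percentile range, mu from the mean."""
    z = stats.norm.ppf(1.0 - _RANGE_TAIL)
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * z)

    def gap(mu: float) -> float:
        return _TruncLogNormal(mu, sigma, lo, hi).mean() - mean

    lo_mu = np.log(lo) - 6.0 * sigma
    hi_mu = np.log(hi) + 6.0 * sigma
    mu = optimize.brentq(gap, lo_mu, hi_mu, xtol=1e-13)
    return _TruncLogNormal(mu, sigma, lo, hi)


def _pearson_under_copula(rho: float, m1: _TruncLogNormal, m2: _TruncLogNormal,
                          n_nodes: int = 48) -> float:
    """Pearson r of (X1, X2) under a Gaussian copula, by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)  # E[f(Z)] = sum w_i f(x_i)

    x1 = m1.from_gauss(nodes)
    x2 = m2.from_gauss(nodes)
    e1, e2 = weights @ x1, weights @ x2
    v1 = weights @ (x1 - e1) ** 2
    v2 = weights @ (x2 - e2) ** 2

    # z2 | z1 = rho*z1 + sqrt(1-rho^2)*w
    z2 = rho * nodes[:, None] + np.sqrt(1.0 - rho**2) * nodes[None, :]
    e12 = weights @ (x1 * (m2.from_gauss(z2) @ weights))
    return float((e12 - e1 * e2) / np.sqrt(v1 * v2))


def _invert_copula_rho(target_r: float, m1: _TruncLogNormal,
                       m2: _TruncLogNormal) -> float:
    if target_r == 0.0:
        return 0.0
    f = lambda rho: _pearson_under_copula(rho, m1, m2) - target_r
    return optimize.brentq(f, -0.999, 0.999, xtol=1e-10)


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

# base-curve constants (reflectance fractions / nm)
_VIS_BASE = 0.12
_NIR_PLATEAU = 0.48
_RED_EDGE_CENTER = 718.0
_RED_EDGE_WIDTH = 11.0
_GREEN_PEAK_AMP = 0.07
_WELL_450_DEPTH = 0.055
_WELL_670_DEPTH = 0.075
_MIN_WELL_SCALE = 0.02


def _vegetation_curve(wl: np.ndarray, well_scale: float) -> np.ndarray:
    """Stress-modulated leaf reflectance: chlorophyll wells shrink with stress."""
    red_edge = _VIS_BASE + (_NIR_PLATEAU - _VIS_BASE) / (
        1.0 + np.exp(-(wl - _RED_EDGE_CENTER) / _RED_EDGE_WIDTH)
    )
    green = _GREEN_PEAK_AMP * np.exp(-0.5 * ((wl - 550.0) / 32.0) ** 2)
    well_blue = well_scale * _WELL_450_DEPTH * np.exp(-0.5 * ((wl - 450.0) / 22.0) ** 2)
    well_red = well_scale * _WELL_670_DEPTH * np.exp(-0.5 * ((wl - 670.0) / 24.0) ** 2)
    return red_edge + green - well_blue - well_red


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[SpectraSet, SoilTable]:
    """Draw one synthetic cohort: paired leaf spectra and soil chemistry.

    Deterministic given ``config.seed``: the root seed is split into one
    sub-stream for the soil table and one per site for spectral noise, so
    outputs are bit-identical across calls with equal configs.
    """
    n = config.n_sites
    wl = config.wavelength_grid()

    m_cd = _calibrate_marginal(config.cd_mean, *config.cd_range)
    m_as = _calibrate_marginal(config.as_mean, *config.as_range)
    rho = _invert_copula_rho(config.cd_as_corr, m_cd, m_as)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n + 1)
    soil_rng = np.random.default_rng(children[0])

    z = soil_rng.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], size=n
    )
    cd = m_cd.from_gauss(z[:, 0])
    as_ = m_as.from_gauss(z[:, 1])
    ph = soil_rng.normal(config.ph_mean, config.ph_sd, size=n)

    width = max(2, len(str(n)))
    site_ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)])

    stress = (
        config.stress_slope_cd * cd
        + config.stress_slope_as * as_
        + soil_rng.normal(0.0, config.stress_noise_sd, size=n)
        if config.stress_noise_sd > 0
        else config.stress_slope_cd * cd + config.stress_slope_as * as_
    )
    well_scale = np.clip(1.0 - stress, _MIN_WELL_SCALE, None)

    reflectance = np.empty((n, wl.size))
    for i in range(n):
        rng_i = np.random.default_rng(children[i + 1])
        base = _vegetation_curve(wl, well_scale[i])
        gain = 1.0 + rng_i.normal(0.0, config.scatter_sd_mult) if config.scatter_sd_mult > 0 else 1.0
        offset = rng_i.normal(0.0, config.scatter_sd_add) if config.scatter_sd_add > 0 else 0.0
        row = gain * base + offset
        if config.channel_noise_sd > 0:
            row = row + rng_i.normal(0.0, config.channel_noise_sd, size=wl.size)
        reflectance[i] = np.clip(row, 1e-4, 1.0)

    spectra = SpectraSet(site_ids=site_ids, wavelengths_nm=wl, reflectance=reflectance)
    soil = SoilTable(site_ids=site_ids, ph=ph, cd=cd, as_=as_)
    return spectra, soil


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------


def write_cohort(spectra: SpectraSet, soil: SoilTable,
                 spectra_path: str | Path, soil_path: str | Path) -> None:
    """Write the two cohort CSVs; round-trips losslessly with read_cohort."""
    if spectra.n_sites == 0:
        raise CohortError("refusing to write an empty cohort")
    if not np.array_equal(spectra.site_ids, soil.site_ids):
        raise CohortError("spectra and soil site ids do not match")
    write_spectra(spectra, spectra_path)
    write_soil(soil, soil_path)


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    if spectra.n_sites == 0:
        raise CohortError("refusing to write empty spectra")
    spectra.to_frame().to_csv(path, index=False)


def write_soil(soil: SoilTable, path: str | Path) -> None:
    soil.to_frame().to_csv(path, index=False)


def read_spectra(path: str | Path) -> SpectraSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "site_id":
        raise CohortError("spectra CSV must start with a site_id column")
    wl = np.array([float(c) for c in df.columns[1:]])
    return SpectraSet(
        site_ids=df["site_id"].astype(str).to_numpy(),
        wavelengths_nm=wl,
        reflectance=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def read_soil(path: str | Path) -> SoilTable:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["site_id", "ph", "cd_mg_kg", "as_mg_kg"]
    if list(df.columns) != expected:
        raise CohortError(f"soil CSV columns must be {expected}")
    return SoilTable(
        site_ids=df["site_id"].astype(str).to_numpy(),
        ph=df["ph"].to_numpy(float),
        cd=df["cd_mg_kg"].to_numpy(float),
        as_=df["as_mg_kg"].to_numpy(float),
    )


def read_cohort(spectra_path: str | Path, soil_path: str | Path) -> tuple[SpectraSet, SoilTable]:
    spectra = read_spectra(spectra_path)
    soil = read_soil(soil_path)
    if not np.array_equal(spectra.site_ids, soil.site_ids):
        raise CohortError("spectra and soil site ids do not match")
    return spectra, soil
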
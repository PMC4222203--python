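"""Synthetic ocean generator for desk-scale end-to-end testing.

Produces WOA-shaped environmental layers (annual + 12 monthly stacks of
SST, salinity, nitrate, silicate on a masked regular grid), a known "true"
suitability surface driven mainly by nitrate and SST, seasonally biased
presence samples, and perturbed warmed/nutrient-depleted future layers for
several pseudo-GCMs.

Structure emulated rather than real values: meridional SST and nutrient
gradients, sinusoidal monthly SST seasonality (Southern-Hemisphere February
warmest), a strong nitrate-silicate correlation broken inside a silicate-
depleted band at the northern range edge, and random smooth land blobs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigurationError, InputError
from .grids import EnvGrid, EnvStack, month_tag
from .occurrences import OccurrenceRecord, OccurrenceSet
from .projection import SuitabilityMap


@dataclass
class OceanParams:
    """Geometry and gradient parameters of the synthetic ocean."""

    grid_step: float = 2.0
    lat_range: tuple[float, float] = (-78.0, 80.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    sst_pole: float = -5.0
    sst_equator: float = 12.0
    seasonal_amp: float = 2.0
    nitrate_max: float = 30.0
    nutrient_decay_lat: float = 8.0
    nitrate_mid_lat: float = -45.0  # latitude where nitrate crosses half max
    si_decouple_band: tuple[float, float] = (-48.0, -38.0)
    si_ratio: float = 1.5
    land_fraction: float = 0.2
    noise_amp_deg: float = 2.0  # amplitude of the smooth latitude-warp noise
    noise_corr_deg: float = 15.0  # correlation length of noise fields
    seed: int = 0

    def __post_init__(self) -> None:
        lat_span = self.lat_range[1] - self.lat_range[0]
        lon_span = self.lon_range[1] - self.lon_range[0]
        if lat_span <= 0 or lon_span <= 0:
            raise ConfigurationError("empty lat/lon range")
        for span, name in ((lat_span, "lat"), (lon_span, "lon")):
            n = span / self.grid_step
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(f"grid_step does not divide the {name} span evenly")
        if self.sst_pole >= self.sst_equator:
            raise ConfigurationError("sst_pole must be colder than sst_equator")
        if self.seasonal_amp < 0:
            raise ConfigurationError("seasonal_amp must be >= 0")
        if not 0.0 <= self.land_fraction <= 0.3:
            raise ConfigurationError("land_fraction must lie in [0, 0.3]")
        lo, hi = self.si_decouple_band
        if not (self.lat_range[0] <= lo < hi <= self.lat_range[1]):
            raise ConfigurationError("si_decouple_band must lie inside lat_range")

    @property
    def lat_centers(self) -> np.ndarray:
        n = int(round((self.lat_range[1] - self.lat_range[0]) / self.grid_step))
        return self.lat_range[0] + self.grid_step * (np.arange(n) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        n = int(round((self.lon_range[1] - self.lon_range[0]) / self.grid_step))
        return self.lon_range[0] + self.grid_step * (np.arange(n) + 0.5)


@dataclass
class TruthParams:
    """True suitability: product of a nitrate and an (inverted) SST logistic."""

    nitrate_mid: float = 15.0
    nitrate_slope: float = 2.0
    sst_max: float = 7.5
    sst_slope: float = 0.5

    def __post_init__(self) -> None:
        if self.nitrate_slope <= 0 or self.sst_slope <= 0:
            raise ConfigurationError("slopes must be positive")


class OceanLayers(NamedTuple):
    annual: EnvStack
    monthly: list[EnvStack]


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Zero-mean unit-SD smooth random field, wrapping in longitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_cells, mode=["nearest", "wrap"])
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _grid(params: OceanParams, variable: str, units: str, values: np.ndarray, mask: np.ndarray) -> EnvGrid:
    return EnvGrid(
        variable=variable, units=units,
        lat=params.lat_centers, lon=params.lon_centers,
        values=np.where(mask, values, np.nan), mask=mask,
    )


def seasonal_anomaly(lat: np.ndarray, month: int, amp: float) -> np.ndarray:
    """Monthly SST anomaly; hemisphere-antisymmetric, SH peaks in February."""
    phase = np.cos(2.0 * np.pi * (month - 2) / 12.0)
    return -np.sign(lat) * amp * phase


def make_environment(params: OceanParams) -> OceanLayers:
    """Generate the annual stack and 12 monthly stacks of the four variables.

    Deterministic for a fixed seed. The annual stack equals the per-cell
    mean of the monthly stacks; nitrate decreases monotonically from the
    south pole toward the equator (the smooth latitude-warp noise is kept
    gentle enough to preserve monotonicity per column).
    """
    rng = np.random.default_rng(params.seed)
    lat = params.lat_centers
    lon = params.lon_centers
    nlat, nlon = lat.size, lon.size
    lat2 = np.broadcast_to(lat[:, None], (nlat, nlon))
    sigma = max(params.noise_corr_deg / params.grid_step / 2.0, 1.0)

    # land: smooth blobs thresholded at the requested areal fraction
    blob = _smooth_noise(rng, (nlat, nlon), sigma)
    if params.land_fraction > 0:
        mask = blob >= np.quantile(blob, params.land_fraction)
    else:
        mask = np.ones((nlat, nlon), dtype=bool)

    # independent smooth latitude-warps decouple SST from the nutrient field
    warp_t = params.noise_amp_deg * _smooth_noise(rng, (nlat, nlon), sigma)
    warp_n = params.noise_amp_deg * _smooth_noise(rng, (nlat, nlon), sigma)
    noise_sal = _smooth_noise(rng, (nlat, nlon), sigma)
    noise_si = _smooth_noise(rng, (nlat, nlon), sigma)
    noise_si_dec = _smooth_noise(rng, (nlat, nlon), sigma)

    sst_annual = params.sst_equator + (params.sst_pole - params.sst_equator) * (
        np.abs(np.clip(lat2 + warp_t, -90.0, 90.0)) / 90.0
    )
    nitrate = params.nitrate_max * expit(
        (params.nitrate_mid_lat - (lat2 + warp_n)) / params.nutrient_decay_lat
    )
    salinity = 34.0 + 0.5 * noise_sal
    silicate_coupled = params.si_ratio * nitrate + 1.5 * noise_si
    lo, hi = params.si_decouple_band
    band = expit((lat2 - lo) / 0.6) * expit((hi - lat2) / 0.6)
    silicate_depleted = 2.0 + 1.0 * np.abs(noise_si_dec)
    silicate = (1.0 - band) * silicate_coupled + band * silicate_depleted
    silicate = np.maximum(silicate, 0.0)

    def stack_for(sst_field: np.ndarray, tag: str) -> EnvStack:
        return EnvStack(
            grids={
                "sst": _grid(params, "sst", "degC", sst_field, mask),
                "salinity": _grid(params, "salinity", "PSU", salinity, mask),
                "nitrate": _grid(params, "nitrate", "umol/L", nitrate, mask),
                "silicate": _grid(params, "silicate", "umol/L", silicate, mask),
            },
            time_tag=tag,
        )

    annual = stack_for(sst_annual, "annual")
    monthly = [
        stack_for(
            sst_annual + seasonal_anomaly(lat2, m, params.seasonal_amp), month_tag(m)
        )
        for m in range(1, 13)
    ]
    return OceanLayers(annual=annual, monthly=monthly)


def true_suitability(stack: EnvStack, truth: TruthParams) -> SuitabilityMap:
    """Known suitability surface: sigma(n_slope*(nitrate - mid)) * sigma(sst_slope*(sst_max - sst))."""
    for v in ("nitrate", "sst"):
        if v not in stack.grids:
            raise InputError(f"stack lacks variable {v!r}")
    nit = stack.grids["nitrate"].values
    sst = stack.grids["sst"].values
    s = expit(truth.nitrate_slope * (nit - truth.nitrate_mid)) * expit(
        truth.sst_slope * (truth.sst_max - sst)
    )
    ref = stack.reference()
    grid = ref.with_values(np.where(stack.mask, s, np.nan), variable="suitability", units="1")
    return SuitabilityMap(grid=grid, model_id="truth", time_tag=stack.time_tag,
                          scenario_tag=stack.scenario_tag, gcm_tag=stack.gcm_tag)


def default_month_weights() -> np.ndarray:
    """Austral-summer-biased sampling weights: w_m proportional to 1 + cos(2 pi (m-1)/12)."""
    m = np.arange(1, 13)
    w = 1.0 + np.cos(2.0 * np.pi * (m - 1) / 12.0)
    return w / w.sum()


def sample_presences(
    truth_maps: Sequence[SuitabilityMap],
    n: int,
    bias: EnvGrid | None = None,
    month_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw presence records with P(cell, month) ~ truth * bias * month weight.

    Sampling is with replacement (revisits are real in survey data and are
    handled downstream by dedupe). Records carry the cell-center lon/lat and
    the drawn month; only ocean cells can be drawn.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if len(truth_maps) != 12:
        raise InputError("need 12 monthly truth maps")
    mw = np.asarray(month_weights if month_weights is not None else default_month_weights(), dtype=float)
    if mw.size != 12 or np.any(mw < 0) or abs(mw.sum() - 1.0) > 1e-9:
        raise InputError("month_weights must be 12 non-negative proportions summing to 1")
    ref = truth_maps[0].grid
    weights = np.zeros((12,) + ref.shape)
    for m, tmap in enumerate(truth_maps):
        if not tmap.grid.same_geometry(ref):
            raise InputError("truth maps do not share geometry")
        w = np.where(tmap.grid.mask, np.nan_to_num(tmap.grid.values), 0.0)
        if bias is not None:
            w = w * np.where(np.isfinite(bias.values), bias.values, 0.0)
        weights[m] = mw[m] * w
    total = weights.sum()
    if total <= 0:
        raise InputError("all sampling weights are zero")
    p = weights.ravel() / total
    rng = np.random.default_rng(seed)
    draws = rng.choice(p.size, size=n, replace=True, p=p)
    midx, ii, jj = np.unravel_index(draws, weights.shape)
    records = [
        OccurrenceRecord(
            lon=float(ref.lon[j]), lat=float(ref.lat[i]),
            month=int(m) + 1, source="synthetic",
        )
        for m, i, j in zip(midx, ii, jj)
    ]
    return OccurrenceSet(records=records, mode="raw", n_input=n)


def make_future(
    monthly: Sequence[EnvStack],
    delta_sst: float = 2.0,
    nitrate_scale: float = 0.7,
    n_gcms: int = 5,
    seed: int = 0,
    perturb: float = 0.05,
    scenario: str = "rcp85",
) -> list[list[EnvStack]]:
    """Pseudo-GCM future layers: warmed SST, scaled-down nutrients.

    Each GCM g applies SST + delta_sst*(1+eps_g) and multiplies nitrate and
    silicate by nitrate_scale*(1+eps'_g), with eps drawn once per GCM.
    Salinity and the land mask are unchanged. Returns one 12-month stack
    list per GCM, tagged with scenario and GCM ids.
    """
    if n_gcms < 1:
        raise ConfigurationError("n_gcms must be >= 1")
    if not 0.0 < nitrate_scale <= 1.0:
        raise ConfigurationError("nitrate_scale must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    eps_sst = rng.normal(0.0, 1.0, size=n_gcms) * perturb
    eps_nut = rng.normal(0.0, 1.0, size=n_gcms) * perturb
    out: list[list[EnvStack]] = []
    for g in range(n_gcms):
        gcm = f"gcm{g + 1:02d}"
        shift = delta_sst * (1.0 + eps_sst[g])
        scale = nitrate_scale * (1.0 + eps_nut[g])
        stacks = []
        for stack in monthly:
            grids = {}
            for v, grid in stack.grids.items():
                if v == "sst":
                    vals = grid.values + shift
                elif v in ("nitrate", "silicate"):
                    vals = np.maximum(grid.values * scale, 0.0)
                else:
                    vals = grid.values.copy()
                grids[v] = grid.with_values(vals)
            stacks.append(EnvStack(grids=grids, time_tag=stack.time_tag,
                                   scenario_tag=scenario, gcm_tag=gcm))
        out.append(stacks)
    return out
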
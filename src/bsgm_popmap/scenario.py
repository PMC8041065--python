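"""Synthetic country scenarios with known ground truth.

Every downstream stage (covariate derivation, BSGMi, dasymetric population
mapping, importance meta-analysis) is exercised on scenarios produced here:
a planar pixel grid carrying a water mask, a partition into contiguous
subnational units, smooth static covariate fields, a monotone annual
built-settlement (BS) growth process, lights-at-night (LAN) radiance coupled
to settlement density, and annual unit population counts whose log density is
tied to BS proximity with known coefficients.

The generator is a pure function of its configuration: one master seed, with
independent sub-streams derived per operation by fixed offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "ScenarioBundle",
    "generate_landscape",
    "simulate_settlement_growth",
    "emulate_coarse_annual_extents",
    "simulate_lan",
    "simulate_population",
    "generate_scenario",
]

# fixed per-operation offsets into the master seed stream
_STREAM_LANDSCAPE = 1
_STREAM_GROWTH = 2
_STREAM_LAN = 3
_STREAM_POPULATION = 4
_STREAM_RS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one operation of one scenario."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic country scenario.

    Parameters
    ----------
    rows, cols
        Grid shape; pixels are unit squares on a planar lattice.
    n_units
        Number of contiguous subnational units partitioning the land area.
    years
        Consecutive integer years; the first and last are the "observed"
        epochs handed to BSGMi, interim years are withheld truth.
    seed
        Master seed; all randomness derives from it.
    growth_rate
        Expected per-year fraction of candidate (non-BS land) pixels that
        transition to BS, in [0, 1].
    settlement_effect
        Coefficient linking BS proximity to pixel log population density.
    noise_sd
        SD of pixel-level log-density noise.
    lan_noise_sd
        SD of additive Gaussian noise on LAN radiance.
    coarse_factor
        Block size of the coarse annual settlement product (e.g. 3 emulates a
        300 m product on a 100 m grid).
    """

    rows: int = 64
    cols: int = 64
    n_units: int = 4
    years: Sequence[int] = tuple(range(2000, 2013))
    seed: int = 0
    growth_rate: float = 0.05
    settlement_effect: float = 2.0
    noise_sd: float = 0.25
    lan_noise_sd: float = 0.5
    coarse_factor: int = 3
    water_fraction: float = 0.08
    covariate_effect: float = 0.15
    growth_heterogeneity: float = 0.75
    settlement_scale: float = 6.0
    lan_footprint: float = 4.0
    rs_omission: float = 0.35
    rs_commission: float = 0.01

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.n_units > self.rows * self.cols:
            raise ValueError("n_units exceeds pixel count")
        years = list(self.years)
        if len(years) < 3:
            raise ValueError("need at least 3 years (one interim between epochs)")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ValueError("years must be consecutive integers")
        if not 0.0 <= self.growth_rate <= 1.0:
            raise ValueError("growth_rate must lie in [0, 1]")
        for name in ("noise_sd", "lan_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be a positive integer")
        if not 0.0 <= self.water_fraction < 1.0:
            raise ValueError("water_fraction must lie in [0, 1)")
        if self.growth_heterogeneity < 0:
            raise ValueError("growth_heterogeneity must be nonnegative")
        if self.settlement_scale <= 0 or self.lan_footprint <= 0:
            raise ValueError("settlement_scale and lan_footprint must be positive")
        for name in ("rs_omission", "rs_commission"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class Landscape:
    """Static spatial scaffold: units, covariate fields, water."""

    unit_map: np.ndarray  # int labels 1..n_units, 0 on water
    static_covariates: dict[str, np.ndarray]
    water_mask: np.ndarray  # bool, True = water


@dataclass
class ScenarioTruth:
    """Withheld ground truth used only by tests and accuracy scoring."""

    years: list[int]
    true_bs_series: list[np.ndarray]  # one binary grid per year, monotone
    density_coefficients: dict[str, float]
    bs_population_series: pd.DataFrame  # columns unit_id, year, bs_population

    def extent(self, year: int) -> np.ndarray:
        return self.true_bs_series[self.years.index(year)]


@dataclass
class ScenarioBundle:
    """Everything the modelled pipeline is allowed to see."""

    config: ScenarioConfig
    unit_map: np.ndarray
    static_covariates: dict[str, np.ndarray]
    water_mask: np.ndarray
    observed_bs_t0: np.ndarray
    observed_bs_t1: np.ndarray
    coarse_annual_bs: dict[int, np.ndarray]
    lan_series: dict[int, np.ndarray]
    population: pd.DataFrame  # columns unit_id, year, population
    years: list[int] = field(default_factory=list)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardised Gaussian-filtered white noise (a smooth random field)."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else raw


def generate_landscape(config: ScenarioConfig) -> Landscape:
    """Generate the static landscape: unit partition, covariates, water.

    Units are the nearest-seed (Voronoi) regions of ``n_units`` seed pixels
    drawn on land, which keeps them contiguous and guarantees each at least
    its own seed pixel. Static covariates are smooth random fields plus
    Euclidean distance transforms of synthetic water / road / protected-area
    features, all in pixel units.
    """
    rng = _rng(config.seed, _STREAM_LANDSCAPE)
    shape = (config.rows, config.cols)

    # water: low tail of a smooth field
    wet = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 10))
    if config.water_fraction > 0:
        thr = np.quantile(wet, config.water_fraction)
        water = wet < thr
    else:
        water = np.zeros(shape, dtype=bool)
    if water.all():  # pathological tiny grids: keep at least one land pixel
        water.flat[0] = False

    land_idx = np.flatnonzero(~water)
    if config.n_units > land_idx.size:
        raise ValueError("n_units exceeds number of land pixels")
    seeds = rng.choice(land_idx, size=config.n_units, replace=False)
    seed_grid = np.zeros(shape, dtype=np.int32)
    seed_grid.flat[seeds] = np.arange(1, config.n_units + 1)
    # nearest seed pixel assigns the unit label
    _, (ii, jj) = ndimage.distance_transform_edt(seed_grid == 0, return_indices=True)
    unit_map = seed_grid[ii, jj].astype(np.int32)
    unit_map[water] = 0

    elevation = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 8)) * 200.0 + 500.0
    gy, gx = np.gradient(elevation)
    slope = np.hypot(gy, gx)

    dist_water = (
        ndimage.distance_transform_edt(~water)
        if water.any()
        else np.full(shape, float(max(shape)))
    )

    # a couple of straight "roads" through random land points
    road = np.zeros(shape, dtype=bool)
    for _ in range(2):
        r0, c0 = rng.integers(0, config.rows), rng.integers(0, config.cols)
        if rng.random() < 0.5:
            road[r0, :] = True
        else:
            road[:, c0] = True
    dist_road = ndimage.distance_transform_edt(~road)

    # protected area: one smooth blob
    prot = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 6))
    protected = prot > np.quantile(prot, 0.9)
    dist_protected = (
        ndimage.distance_transform_edt(~protected)
        if protected.any()
        else np.full(shape, float(max(shape)))
    )

    covs = {
        "elevation": elevation.astype(np.float64),
        "slope": slope.astype(np.float64),
        "dist_water": dist_water.astype(np.float64),
        "dist_road": dist_road.astype(np.float64),
        "dist_protected": dist_protected.astype(np.float64),
    }
    return Landscape(unit_map=unit_map, static_covariates=covs, water_mask=water)


def _seed_initial_bs(rng: np.random.Generator, landscape: Landscape, config: ScenarioConfig) -> np.ndarray:
    """Small initial settlement blobs, at least one per unit where possible."""
    shape = landscape.water_mask.shape
    bs = np.zeros(shape, dtype=bool)
    land = ~landscape.water_mask
    target = max(config.n_units, int(0.02 * land.sum()))
    centers = rng.choice(np.flatnonzero(land), size=min(target, land.sum()), replace=False)
    bs.flat[centers] = True
    # grow one dilation step to form clusters rather than isolated pixels
    bs = ndimage.binary_dilation(bs, iterations=1) & land
    return bs


def simulate_settlement_growth(landscape: Landscape, config: ScenarioConfig) -> ScenarioTruth:
    """Simulate monotone annual BS growth and the coincident BS population.

    Each year every candidate pixel (land, currently non-BS) transitions with
    probability ``growth_rate * s / mean(s)``, so the expected fraction of
    candidates transitioning per year is ``growth_rate``. The suitability
    ``s`` is the product of a proximity term decaying with distance to
    existing settlement (bounded dynamic range 1..5) and a per-unit growth
    propensity (lognormal with log-SD ``growth_heterogeneity``): urbanization
    pressure differs between administrative regions, which is what makes an
    annually updated settlement layer informative beyond the initial extent.

    The per-unit BS population follows the growing BS area with a gently
    rising density, yielding a logistic-like unit growth path.
    """
    rng = _rng(config.seed, _STREAM_GROWTH)
    years = list(config.years)
    land = ~landscape.water_mask

    unit_propensity = np.ones(config.n_units + 1)
    if config.growth_heterogeneity > 0:
        unit_propensity[1:] = rng.lognormal(0.0, config.growth_heterogeneity, config.n_units)
    propensity_grid = unit_propensity[landscape.unit_map]

    bs = _seed_initial_bs(rng, landscape, config)
    series = [bs.copy()]
    for _ in years[1:]:
        candidates = land & ~bs
        n_cand = int(candidates.sum())
        if n_cand == 0:
            if config.growth_rate > 0:
                warnings.warn("no candidate pixels left; settlement growth saturated")
            series.append(bs.copy())
            continue
        if config.growth_rate == 0:
            series.append(bs.copy())
            continue
        dte = ndimage.distance_transform_edt(~bs) if bs.any() else np.zeros(bs.shape)
        suit = (1.0 + 4.0 * np.exp(-dte / 5.0)) * propensity_grid
        s = suit[candidates]
        p = np.minimum(config.growth_rate * s / s.mean(), 1.0)
        new = np.zeros_like(bs)
        new[candidates] = rng.random(n_cand) < p
        bs = bs | new
        series.append(bs.copy())

    # unit BS population: density rises linearly t0->t1; population = density*area
    coeffs = {
        "alpha": 1.0,
        "settlement_effect": config.settlement_effect,
        "covariate_effect": config.covariate_effect,
        "noise_sd": config.noise_sd,
        "density_t0": 20.0,
        "density_growth": 0.5,
    }
    records = []
    span = max(len(years) - 1, 1)
    for k, (year, extent) in enumerate(zip(years, series)):
        dens = coeffs["density_t0"] * (1.0 + coeffs["density_growth"] * k / span)
        for u in range(1, config.n_units + 1):
            area = int((extent & (landscape.unit_map == u)).sum())
            records.append({"unit_id": u, "year": year, "bs_population": dens * area})
    bs_pop = pd.DataFrame.from_records(records)

    return ScenarioTruth(
        years=years,
        true_bs_series=[e.astype(np.uint8) for e in series],
        density_coefficients=coeffs,
        bs_population_series=bs_pop,
    )


def emulate_coarse_annual_extents(true_bs: np.ndarray, factor: int) -> np.ndarray:
    """Degrade a binary extent to a coarser annual product and upsample back.

    Majority vote within each ``factor``x``factor`` block (ties and exact
    halves vote 0), then nearest-neighbour upsampling back to the full grid.
    Edge blocks are truncated and vote over their actual pixel count.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(true_bs).astype(bool)
    if factor == 1:
        return arr.astype(np.uint8)
    rows, cols = arr.shape
    out = np.zeros_like(arr)
    for i0 in range(0, rows, factor):
        for j0 in range(0, cols, factor):
            block = arr[i0 : i0 + factor, j0 : j0 + factor]
            vote = 2 * int(block.sum()) > block.size
            out[i0 : i0 + factor, j0 : j0 + factor] = vote
    return out.astype(np.uint8)


def emulate_rs_classification(
    extent: np.ndarray,
    detectability: np.ndarray,
    false_positives: np.ndarray,
) -> np.ndarray:
    """Apply persistent classification error to a true extent.

    Remote-sensing settlement classifications systematically miss part of the
    built area (small or scattered structures, spectral confusion) and
    misfire on a little bare ground; both error fields are persistent across
    years — the same settlement stays undetected by the same sensor and
    algorithm — so they are drawn once per scenario and reused for every
    annual layer. ``detectability`` and ``false_positives`` are boolean
    grids; the classified extent is (true & detectable) | false_positives.
    """
    ext = np.asarray(extent).astype(bool)
    return ((ext & detectability) | false_positives).astype(np.uint8)


def rs_error_fields(
    landscape: Landscape, config: ScenarioConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded persistent omission/commission fields for the RS-product
    emulation (pixel detectable with probability 1 - rs_omission; spurious
    detections on land with probability rs_commission)."""
    rng = _rng(config.seed, _STREAM_RS)
    shape = landscape.water_mask.shape
    detect = rng.random(shape) >= config.rs_omission
    false_pos = (rng.random(shape) < config.rs_commission) & ~landscape.water_mask
    return detect, false_pos


def simulate_lan(truth: ScenarioTruth, landscape: Landscape, config: ScenarioConfig) -> dict[int, np.ndarray]:
    """Annual lights-at-night radiance coupled to local settlement density.

    radiance = baseline + gain * (local BS density) + N(0, lan_noise_sd),
    truncated at zero. Local density is the mean BS indicator in a Gaussian
    neighbourhood of ``lan_footprint`` pixels — the sensor's effective
    footprint is several times the analysis grid spacing, as with nighttime
    lights products — so pixels that transition show an expected radiance
    step-up in the year of transition, smeared over the footprint.
    """
    rng = _rng(config.seed, _STREAM_LAN)
    baseline, gain = 2.0, 20.0
    out: dict[int, np.ndarray] = {}
    for year, extent in zip(truth.years, truth.true_bs_series):
        local = ndimage.gaussian_filter(
            extent.astype(float), sigma=config.lan_footprint, mode="constant"
        )
        noise = rng.normal(0.0, config.lan_noise_sd, size=extent.shape) if config.lan_noise_sd > 0 else 0.0
        out[year] = np.maximum(baseline + gain * local + noise, 0.0)
    return out


def simulate_population(
    truth: ScenarioTruth, landscape: Landscape, config: ScenarioConfig
) -> pd.DataFrame:
    """Annual unit population counts with a known density mechanism.

    Pixel latent log density for year t is

        alpha + settlement_effect * exp(-DTE_t / settlement_scale) + gamma * z + noise

    where DTE_t is the distance to the nearest true BS pixel in year t and z
    is a standardised static covariate field. The decay scale extends the
    density gradient well beyond the settlement edge (peri-urban population),
    farther than the lights footprint reaches. The unit-year count is the sum
    of pixel densities over the unit's land pixels, rounded to an integer
    (never negative).
    """
    rng = _rng(config.seed, _STREAM_POPULATION)
    c = truth.density_coefficients
    land = ~landscape.water_mask
    elev = landscape.static_covariates["elevation"]
    z = (elev - elev.mean()) / (elev.std() or 1.0)

    records = []
    for year, extent in zip(truth.years, truth.true_bs_series):
        ext = extent.astype(bool)
        dte = ndimage.distance_transform_edt(~ext) if ext.any() else np.full(ext.shape, np.inf)
        log_dens = (
            c["alpha"]
            + c["settlement_effect"] * np.exp(-dte / config.settlement_scale)
            + c["covariate_effect"] * z
        )
        if c["noise_sd"] > 0:
            log_dens = log_dens + rng.normal(0.0, c["noise_sd"], size=ext.shape)
        dens = np.exp(log_dens)
        dens[~land] = 0.0
        for u in range(1, config.n_units + 1):
            total = float(dens[landscape.unit_map == u].sum())
            records.append({"unit_id": u, "year": year, "population": int(round(total))})
    return pd.DataFrame.from_records(records)


def generate_scenario(config: ScenarioConfig) -> tuple[ScenarioBundle, ScenarioTruth]:
    """Run the full generator and split outputs into bundle (visible to the
    pipeline) and truth (withheld for scoring)."""
    landscape = generate_landscape(config)
    truth = simulate_settlement_growth(landscape, config)
    lan = simulate_lan(truth, landscape, config)
    population = simulate_population(truth, landscape, config)
    # the annual RS-derived product sees the truth through a persistent
    # classification filter, then at degraded resolution
    detect, false_pos = rs_error_fields(landscape, config)
    coarse = {
        year: emulate_coarse_annual_extents(
            emulate_rs_classification(ext, detect, false_pos), config.coarse_factor
        )
        for year, ext in zip(truth.years, truth.true_bs_series)
    }
    bundle = ScenarioBundle(
        config=config,
        unit_map=landscape.unit_map,
        static_covariates=landscape.static_covariates,
        water_mask=landscape.water_mask,
        observed_bs_t0=truth.true_bs_series[0].copy(),
        observed_bs_t1=truth.true_bs_series[-1].copy(),
        coarse_annual_bs=coarse,
        lan_series=lan,
        population=population,
        years=list(config.years),
    )
    return bundle, truth
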